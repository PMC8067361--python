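"""Trial protocol and ensemble experiment tests (reduced scale)."""

import math
from dataclasses import replace

import numpy as np
import pytest

from manduca import (
    InjurySpec,
    MothTemplate,
    ResponseSet,
    TrialConfig,
    accept_instance,
    equal_loss_ratios,
    experiment_qn_ratio,
    run_trial,
)
from manduca.errors import ConfigurationError
from manduca.protocols import ExperimentResult, TrialRecord


def rs(peaks, sp=0.1, stage=""):
    return ResponseSet(peaks=np.asarray(peaks, dtype=float), spontaneous=sp, stage=stage)


class TestAcceptInstance:
    def test_inside_envelope_accepted(self):
        assert accept_instance(rs([10, 11], sp=2.0), (2.0, None))

    def test_no_odor_response_rejected_by_any_minimum(self):
        zero = rs([0.0, 0.0], sp=1.0)
        assert not accept_instance(zero, (0.1, None))

    def test_maximum_bound_when_configured(self):
        assert not accept_instance(rs([100.0, 90.0], sp=1.0), (2.0, 50.0))

    def test_open_envelope_accepts_everything(self):
        assert accept_instance(rs([1.0], sp=0.0), (None, None))  # SSNR = inf


class TestRunTrial:
    def test_zero_injury_normalized_response_near_one(self, small_template):
        rec = run_trial(
            small_template,
            TrialConfig(injury=InjurySpec(site="rn_channel", level=0.0), seed=5),
        )
        # naive and post-injury stages use different noise streams, so the
        # ratio deviates slightly from 1 but not systematically
        assert rec.normalized_mean("post_injury") == pytest.approx(1.0, abs=0.15)

    def test_stage_ordering_and_presence(self, small_template):
        rec = run_trial(
            small_template,
            TrialConfig(injury=InjurySpec(site="pn_qn_channel", level=0.3), seed=6),
        )
        assert set(rec.responses) == {"naive", "post_injury", "post_training"}
        assert rec.responses["naive"].n == 15
        assert rec.responses["post_injury"].n == 15

    def test_training_skippable(self, small_template):
        rec = run_trial(
            small_template,
            TrialConfig(
                injury=InjurySpec(site="rn_channel", level=0.3),
                include_training=False,
                seed=7,
            ),
        )
        assert "post_training" not in rec.responses

    def test_trial_is_deterministic(self, small_template):
        cfg = TrialConfig(injury=InjurySpec(site="rn_channel", level=0.4), seed=8)
        a = run_trial(small_template, cfg)
        b = run_trial(small_template, cfg)
        for stage in a.responses:
            assert np.array_equal(a.responses[stage].peaks, b.responses[stage].peaks)

    def test_discrimination_pretraining_shifts_fisher_upward(self, small_template):
        # intrinsic odor-pair asymmetry dominates the absolute Fd, so the
        # contract tested is the within-seed shift caused by pre-training
        shifts = []
        for seed in (9, 11, 12):
            fds = {}
            for n_pre in (0, 3):
                rec = run_trial(
                    small_template,
                    TrialConfig(
                        injury=InjurySpec(site="rn_channel", level=0.2),
                        mode="discrimination",
                        n_puffs_pretrain=n_pre,
                        seed=seed,
                    ),
                )
                assert {"naive", "post_injury", "post_training"} <= set(rec.fisher)
                fds[n_pre] = rec.fisher["naive"]
            shifts.append(fds[3] - fds[0])
        assert np.mean(shifts) > 0

    def test_invalid_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            TrialConfig(mode="banana")


class TestRejectionBehaviour:
    def test_extreme_templates_reject_more_instances(self, small_template):
        extreme = replace(small_template, n_qn_per_glom=7, al_noise_factor=1.33)
        def rejected_fraction(tpl):
            flags = [
                run_trial(tpl, TrialConfig(include_training=False, seed=s)).accepted
                for s in range(10)
            ]
            return 1.0 - np.mean(flags)

        assert rejected_fraction(extreme) > rejected_fraction(small_template)


@pytest.fixture(scope="module")
def tiny_result():
    tpl = MothTemplate(n_kc=300)
    return experiment_qn_ratio(
        tpl, qn_counts=(0,), levels=(0.0, 0.4), n_instances=3, seed=21
    )


class TestExperimentGrid:
    def test_quota_met_per_condition(self, tiny_result):
        assert all(len(recs) == 3 for recs in tiny_result.records)

    def test_tidy_frame_shape_and_columns(self, tiny_result):
        frame = tiny_result.to_frame()
        assert {"experiment", "stage", "metric", "value", "level"} <= set(frame.columns)
        assert set(frame["stage"]) == {"naive", "post_injury", "post_training"}

    def test_rerun_is_bit_identical(self, tiny_result):
        tpl = MothTemplate(n_kc=300)
        again = experiment_qn_ratio(
            tpl, qn_counts=(0,), levels=(0.0, 0.4), n_instances=3, seed=21
        )
        a, b = tiny_result.to_frame(), again.to_frame()
        assert a.equals(b)


class TestEqualLossRatios:
    def _fake_result(self, fas_losses, abl_losses, levels):
        """Build an ExperimentResult with prescribed mean loss curves."""
        conditions, records = [], []
        for kind, losses in (("fas", fas_losses), ("ablation", abl_losses)):
            for lv, loss in zip(levels, losses):
                conditions.append({"site": "rn_channel", "kind": kind, "level": lv})
                rec = TrialRecord(
                    instance_seed=0,
                    trial_seed=0,
                    responses={
                        "naive": rs([1.0, 1.0, 1.0]),
                        "post_injury": rs([1.0 - loss] * 3),
                    },
                    accepted=True,
                    naive_ssnr=10.0,
                )
                records.append([rec])
        return ExperimentResult(
            name="ablation_vs_fas",
            conditions=conditions,
            records=records,
            rejections=[0] * len(conditions),
            seed=0,
            n_instances=1,
        )

    def test_linear_curves_recover_slope_ratio(self):
        # loss_fas = 0.57 * level, loss_abl = level  ->  equal-loss ratio 1/0.57
        levels = (0.0, 0.15, 0.3, 0.45, 0.6)
        fas = [0.57 * lv for lv in levels]
        abl = list(levels)
        info = self._fake_result(fas, abl, levels)
        out = equal_loss_ratios(info, "rn_channel")
        assert out["ratios"], "no usable ablation levels"
        for r in out["ratios"]:
            assert r == pytest.approx(1 / 0.57, rel=0.02)

    def test_out_of_range_ablation_levels_skipped(self):
        levels = (0.0, 0.3, 0.6)
        info = self._fake_result([0.0, 0.1, 0.2], [0.0, 0.5, 0.9], levels)
        out = equal_loss_ratios(info, "rn_channel")
        assert out["ratios"] == []
        assert math.isnan(out["mean_ratio"])
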
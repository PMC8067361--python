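"""Network generation, simulation dynamics, and response extraction tests."""

import numpy as np
import pytest

from manduca import (
    MothTemplate,
    StagePlan,
    Timecourse,
    build_schedule,
    extract_responses,
    generate_instance,
    simulate,
)
from manduca.errors import (
    ConfigurationError,
    DimensionMismatchError,
)
from manduca.stimuli import generate_odor


def one_puff_schedule(template, seed=0, octopamine=False, n_puffs=1):
    odor = generate_odor(
        template.n_glomeruli, template.n_odor_targets, seed=seed,
        magnitude=template.odor_magnitude,
    )
    return build_schedule(
        [StagePlan(n_puffs=n_puffs, octopamine=octopamine)],
        odors=[odor],
        template=template,
        seed=seed,
    )


class TestGenerateInstance:
    def test_no_qn_channel_when_count_zero(self, tiny_template):
        inst = generate_instance(tiny_template, 0)
        assert inst.W_qn_kc.shape == (tiny_template.n_kc, 0)

    def test_deterministic_entry_for_entry(self, tiny_template):
        a = generate_instance(tiny_template, 7)
        b = generate_instance(tiny_template, 7)
        for attr in ("w_rn_al", "W_pn_kc", "W_qn_kc", "W_kc_en"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))
        assert a.mb_theta == b.mb_theta

    def test_each_qn_innervates_exactly_one_glomerulus(self):
        tpl = MothTemplate(n_glomeruli=10, n_kc=80, n_odor_targets=5, n_qn_per_glom=3)
        inst = generate_instance(tpl, 1)
        assert inst.glom_of_qn.shape == (30,)
        counts = np.bincount(inst.glom_of_qn, minlength=10)
        assert np.all(counts == 3)

    def test_kc_fanin_and_nonnegative_weights(self, tiny_template):
        inst = generate_instance(tiny_template, 3)
        fanin = (inst.W_pn_kc > 0).sum(axis=1)
        assert np.all(fanin <= tiny_template.kc_fanin_pn)
        # truncation at zero can only remove, never flip sign
        for W in (inst.W_pn_kc, inst.W_qn_kc, inst.W_kc_en, inst.w_rn_al):
            assert np.all(W >= 0)

    def test_weight_means_converge_to_template_mean(self, tiny_template):
        # law of large numbers over 30 instances: the mean of non-zero
        # excitatory AL->MB weights approaches the template's Gaussian mean
        vals = []
        for seed in range(30):
            inst = generate_instance(tiny_template, seed)
            w = inst.W_pn_kc[inst.W_pn_kc > 0]
            vals.append(w.mean())
        # truncation at 0 biases N(1, 0.3) upward by < 0.2%
        assert np.mean(vals) == pytest.approx(tiny_template.w_pn_kc_mean, rel=0.02)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            MothTemplate(n_kc=0)
        with pytest.raises(ConfigurationError):
            MothTemplate(mb_sparsity=1.5)


class TestSimulate:
    def test_no_odor_no_noise_en_stays_near_zero(self, small_template):
        inst = generate_instance(small_template, 1)
        sched = build_schedule([], odors=[], template=small_template, seed=0)
        # pad duration so there is something to integrate
        sched = build_schedule(
            [StagePlan(n_puffs=0)], odors=[], template=small_template, seed=0
        )
        tc = simulate(inst, sched, al_noise_factor=0.0)
        assert tc.en1.max() <= 0.05  # healthy odor peak is ~1

    def test_healthy_single_puff_peak_near_one(self, small_template):
        inst = generate_instance(small_template, 1)
        sched = one_puff_schedule(small_template, seed=1)
        tc = simulate(inst, sched)
        rs = extract_responses(tc, sched)
        assert 0.6 < rs.peaks[0] < 1.5

    def test_all_weights_zero_gives_identically_zero_en(self, tiny_template):
        inst = generate_instance(tiny_template, 1)
        zero = inst.with_weights(
            np.zeros_like(inst.W_pn_kc),
            np.zeros_like(inst.W_qn_kc),
            np.zeros_like(inst.W_kc_en),
        )
        # the inhibition floor is non-negative, so zero input stays below it
        object.__setattr__(zero, "mb_theta", max(zero.mb_theta, 0.0))
        tc = simulate(zero, one_puff_schedule(tiny_template, seed=2))
        assert np.all(tc.en1 == 0.0)

    def test_rates_nonnegative_and_finite_everywhere(self, tiny_template):
        inst = generate_instance(tiny_template, 4)
        tc = simulate(inst, one_puff_schedule(tiny_template, seed=3), record="all")
        for arr in (tc.en, tc.rn, tc.al, tc.kc):
            assert np.all(np.isfinite(arr))
            assert np.all(arr >= 0)

    def test_kc_sparsity_within_band_during_odor(self, small_template):
        inst = generate_instance(small_template, 5)
        sched = one_puff_schedule(small_template, seed=5)
        tc = simulate(inst, sched, record="all")
        on, off = sched.puff_windows[0]
        # look at the settled half of the puff window
        mask = (tc.t >= on + 0.1) & (tc.t <= off)
        frac = (tc.kc[mask] > 0).mean(axis=1)
        target = small_template.mb_sparsity
        assert np.all(frac >= 0.5 * target)
        assert np.all(frac <= 1.5 * target)

    def test_octopamine_boosts_al_rates_elementwise(self, small_template):
        inst = generate_instance(small_template, 6)
        plain = one_puff_schedule(small_template, seed=6, octopamine=False)
        boosted = one_puff_schedule(small_template, seed=6, octopamine=True)
        tc0 = simulate(inst, plain, record="al")
        tc1 = simulate(inst, boosted, record="al")
        # identical noise stream (same schedule seed): gain can only raise rates
        assert np.all(tc1.al >= tc0.al - 1e-12)

    def test_zero_noise_factor_gives_identical_puff_peaks(self, small_template):
        inst = generate_instance(small_template, 7)
        sched = one_puff_schedule(small_template, seed=7, n_puffs=6)
        tc = simulate(inst, sched, al_noise_factor=0.0)
        rs = extract_responses(tc, sched)
        assert rs.std <= 1e-9 * max(rs.mean, 1.0)

    def test_peak_variability_nondecreasing_in_noise_factor(self, small_template):
        sigmas = []
        for factor in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(3):
                inst = generate_instance(small_template, seed)
                sched = one_puff_schedule(small_template, seed=seed + 1, n_puffs=8)
                tc = simulate(inst, sched, al_noise_factor=factor)
                vals.append(extract_responses(tc, sched).std)
            sigmas.append(np.mean(vals))
        assert sigmas[0] <= sigmas[1] <= sigmas[2]

    def test_bit_identical_given_same_inputs(self, tiny_template):
        inst = generate_instance(tiny_template, 8)
        sched = one_puff_schedule(tiny_template, seed=9, n_puffs=3)
        a = simulate(inst, sched)
        b = simulate(inst, sched)
        assert np.array_equal(a.en, b.en)

    def test_dimension_mismatch_rejected(self, tiny_template):
        inst = generate_instance(tiny_template, 1)
        odor = generate_odor(33, 10, seed=0)
        sched = build_schedule([StagePlan(n_puffs=1)], odors=[odor], seed=0)
        with pytest.raises(DimensionMismatchError):
            simulate(inst, sched)


class TestExtractResponses:
    def test_constant_trace_gives_constant_peaks_and_sp(self, tiny_template):
        sched = one_puff_schedule(tiny_template, seed=1, n_puffs=3)
        nt = int(np.ceil(sched.duration / tiny_template.dt))
        t = (np.arange(nt) + 1) * tiny_template.dt
        tc = Timecourse(t=t, en=np.full((nt, 1), 2.5))
        rs = extract_responses(tc, sched)
        assert rs.peaks.tolist() == [2.5, 2.5, 2.5]
        assert rs.spontaneous == pytest.approx(2.5)

    def test_peaks_match_brute_force_window_scan(self, tiny_template, rng):
        sched = one_puff_schedule(tiny_template, seed=2, n_puffs=5)
        nt = int(np.ceil(sched.duration / tiny_template.dt))
        t = (np.arange(nt) + 1) * tiny_template.dt
        en = rng.random((nt, 1))
        tc = Timecourse(t=t, en=en)
        rs = extract_responses(tc, sched, response_margin=0.05)
        for k, (on, off) in enumerate(sched.puff_windows):
            brute = max(
                en[i, 0] for i in range(nt) if on <= t[i] <= off + 0.05
            )
            assert rs.peaks[k] == pytest.approx(brute)

    def test_trace_shorter_than_first_window_rejected(self, tiny_template):
        sched = one_puff_schedule(tiny_template, seed=3, n_puffs=1)
        t = np.arange(1, 10) * tiny_template.dt  # ends before the first puff
        tc = Timecourse(t=t, en=np.zeros((9, 1)))
        with pytest.raises(ConfigurationError):
            extract_responses(tc, sched)

    def test_empty_puff_list_rejected(self, tiny_template):
        sched = build_schedule([], odors=[], template=tiny_template, seed=0)
        tc = Timecourse(t=np.array([0.1]), en=np.zeros((1, 1)))
        with pytest.raises(ConfigurationError):
            extract_responses(tc, sched)
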
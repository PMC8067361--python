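"""Staged injury/training trials and the four ensemble experiments.

A single trial injures and then retrains one network instance, in stages:

0. (discrimination only) pre-training: trained odor + octopamine, 3 puffs;
1. naive baseline: odor without octopamine (15 puffs);
2. injury;
3. post-injury assessment: odor without octopamine (15 puffs);
4. training: odor + octopamine with plasticity (5 puffs by default);
5. post-training assessment: odor without octopamine (15 puffs).

Instances whose naive signal-to-spontaneous ratio falls outside the
template's acceptance envelope are discarded and regenerated, so every
condition ends with the configured number of accepted instances.

The experiments sweep condition grids and aggregate per-instance records:

* learning recovery — FAS level x injury site, recovery curves;
* QN ratio — parallel inhibitory channel counts vs injury;
* AL noise — upstream noise factors vs injury, top-tranche preservation;
* ablation vs FAS — paired injury kinds, empirical equal-loss level ratios.

Noise-stream pairing: the post-injury and post-training assessments share
one noise seed (common random numbers), so training with the octopamine
gate closed reproduces the post-injury responses exactly; the naive
assessment uses its own stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import ConfigurationError
from .injury import InjurySpec, apply_injury, fas_ablation_ratio
from .metrics import (
    ResponseSet,
    fisher_discriminant,
    snr,
    ssnr,
    top_end_preservation,
    top_tranche,
)
from .network import MothTemplate, generate_instance, extract_responses, simulate
from .plasticity import PlasticityConfig, training_pass
from .stimuli import StagePlan, build_schedule, generate_odor, make_discrimination_pair

__all__ = [
    "TrialConfig",
    "TrialRecord",
    "ExperimentResult",
    "run_trial",
    "accept_instance",
    "experiment_learning_recovery",
    "experiment_qn_ratio",
    "experiment_al_noise",
    "experiment_ablation_vs_fas",
    "summarize",
    "equal_loss_ratios",
]

STAGES = ("naive", "post_injury", "post_training")


@dataclass(frozen=True)
class TrialConfig:
    """Configuration of one staged trial.

    ``mode`` is ``"magnitude"`` (EN response magnitude; no pre-training) or
    ``"discrimination"`` (two stimuli, pre-training stage, Fisher
    discriminant readout).  ``octopamine_during_training=False`` runs the
    training stage with the reward gate closed — a control in which learning
    must fail.  ``include_training=False`` stops after the post-injury
    assessment (used by the ablation-vs-FAS comparison).
    """

    injury: Optional[InjurySpec] = None
    n_puffs_assess: int = 15
    n_puffs_train: int = 5
    n_puffs_pretrain: int = 3
    include_training: bool = True
    octopamine_during_training: bool = True
    mode: str = "magnitude"
    discrimination_mode: str = "two_odors"
    noise_factor: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("magnitude", "discrimination"):
            raise ConfigurationError(f"unknown trial mode: {self.mode!r}")
        if self.n_puffs_assess < 1:
            raise ConfigurationError("assessment stages need at least one puff")


@dataclass
class TrialRecord:
    """Per-stage response sets and normalized summaries for one instance.

    All ``normalized_*`` quantities divide by the same naive-stage value of
    this trial.  For discrimination trials, ``fisher`` maps stages to raw
    Fisher discriminants and response sets carry ``_trained``/``_control``
    suffixes.
    """

    instance_seed: int
    trial_seed: int
    responses: Dict[str, ResponseSet]
    accepted: bool
    naive_ssnr: float
    fisher: Dict[str, float] = field(default_factory=dict)

    def normalized_mean(self, stage: str, suffix: str = "") -> float:
        """Stage mean EN response divided by the naive mean."""
        return (
            self.responses[stage + suffix].mean
            / self.responses["naive" + suffix].mean
        )

    def preservation(self, stage: str) -> float:
        """Top-end preservation P of ``stage`` responses vs naive (raw)."""
        return top_end_preservation(
            self.responses["naive"], self.responses[stage]
        ).raw

    def tranche_preservation(self, stage: str, q: float = 0.15) -> float:
        """Mean of the top rank tranche of ``stage`` over the naive tranche."""
        healthy = top_tranche(self.responses["naive"], q)
        later = top_tranche(self.responses[stage], q)
        return later.mean / healthy.mean


def accept_instance(
    naive: ResponseSet,
    envelope: Tuple[Optional[float], Optional[float]],
) -> bool:
    """True iff the naive SSNR lies within the acceptance envelope.

    The envelope rejects signal-starved instances (templates with many QNs
    or very high AL noise produce more of them).  ``None`` bounds are open.
    """
    value = ssnr(naive)
    lo, hi = envelope
    if lo is not None and value < lo:
        return False
    if hi is not None and value > hi:
        return False
    return True


def _seed_ints(ss: np.random.SeedSequence, n: int) -> List[int]:
    """Derive ``n`` independent 31-bit seeds from a SeedSequence."""
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def run_trial(template: MothTemplate, config: TrialConfig) -> TrialRecord:
    """Execute one staged trial on a freshly generated instance."""
    tpl = template
    (
        s_inst,
        s_odor,
        s_naive,
        s_paired,
        s_train,
        s_pre,
        s_injury,
        s_naive2,
        s_paired2,
    ) = _seed_ints(np.random.SeedSequence(config.seed), 9)

    instance = generate_instance(tpl, s_inst)
    plast = PlasticityConfig.from_template(tpl)

    if config.mode == "discrimination":
        trained_odor, control_odor = make_discrimination_pair(
            config.discrimination_mode,
            tpl.n_glomeruli,
            tpl.n_odor_targets,
            noise_factor=config.noise_factor,
            magnitude=tpl.odor_magnitude,
            seed=s_odor,
        )
        odors = [trained_odor, control_odor]
    else:
        odors = [
            generate_odor(
                tpl.n_glomeruli,
                tpl.n_odor_targets,
                seed=s_odor,
                magnitude=tpl.odor_magnitude,
            )
        ]

    def assess(inst, seeds, stage):
        """Assessment stage: n_puffs_assess puffs per odor, no octopamine."""
        out: Dict[str, ResponseSet] = {}
        for j, odor in enumerate(odors):
            sched = build_schedule(
                [StagePlan(n_puffs=config.n_puffs_assess, odor_index=j)],
                odors=odors,
                template=tpl,
                seed=seeds[j],
            )
            tc = simulate(inst, sched)
            suffix = "" if len(odors) == 1 else ("_trained" if j == 0 else "_control")
            out[stage + suffix] = extract_responses(
                tc,
                sched,
                stage=stage,
                response_margin=tpl.response_margin,
                baseline_margin=tpl.baseline_margin,
            )
        return out

    def train(inst, n_puffs, seed):
        sched = build_schedule(
            [
                StagePlan(
                    n_puffs=n_puffs,
                    odor_index=0,
                    octopamine=config.octopamine_during_training,
                )
            ],
            odors=odors,
            template=tpl,
            seed=seed,
        )
        return training_pass(inst, sched, plast)

    responses: Dict[str, ResponseSet] = {}
    fisher: Dict[str, float] = {}

    if config.mode == "discrimination" and config.n_puffs_pretrain > 0:
        instance = train(instance, config.n_puffs_pretrain, s_pre)

    assess_seeds_naive = [s_naive, s_naive2]
    assess_seeds_paired = [s_paired, s_paired2]
    responses.update(assess(instance, assess_seeds_naive, "naive"))
    naive_key = "naive" if len(odors) == 1 else "naive_trained"
    accepted = accept_instance(responses[naive_key], tpl.ssnr_acceptance)

    injured = instance
    if config.injury is not None:
        injured = apply_injury(instance, replace(config.injury, seed=s_injury))
    responses.update(assess(injured, assess_seeds_paired, "post_injury"))

    if config.include_training:
        trained = train(injured, config.n_puffs_train, s_train)
        # paired seeds: gate-closed training reproduces post-injury exactly
        responses.update(assess(trained, assess_seeds_paired, "post_training"))

    if config.mode == "discrimination":
        for stage in STAGES:
            if stage + "_trained" in responses:
                fisher[stage] = fisher_discriminant(
                    responses[stage + "_trained"], responses[stage + "_control"]
                )

    return TrialRecord(
        instance_seed=s_inst,
        trial_seed=config.seed,
        responses=responses,
        accepted=accepted,
        naive_ssnr=ssnr(responses[naive_key]),
        fisher=fisher,
    )


# ---------------------------------------------------------------------------
# Ensemble experiments
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    """Grid of conditions with per-instance trial records.

    ``conditions[i]`` is a dict of the varied parameters for condition ``i``
    and ``records[i]`` its accepted trial records; ``rejections[i]`` counts
    instances discarded by the SSNR envelope before the quota was met.
    """

    name: str
    conditions: List[Dict]
    records: List[List[TrialRecord]]
    rejections: List[int]
    seed: int
    n_instances: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format metric table, one row per (condition, instance,
        stage, metric)."""
        rows = []
        for cond, recs in zip(self.conditions, self.records):
            for rec in recs:
                for stage in STAGES:
                    key = stage if stage in rec.responses else stage + "_trained"
                    if key not in rec.responses:
                        continue
                    rs = rec.responses[key]
                    suffix = "" if stage in rec.responses else "_trained"
                    metrics = {
                        "mean_peak": rs.mean,
                        "std_peak": rs.std,
                        "spontaneous": rs.spontaneous,
                        "ssnr": ssnr(rs),
                        "snr": snr(rs),
                        "normalized_mean": rec.normalized_mean(stage, suffix),
                    }
                    if stage != "naive" and suffix == "":
                        metrics["preservation"] = rec.preservation(stage)
                        metrics["tranche_preservation"] = rec.tranche_preservation(stage)
                    if stage in rec.fisher:
                        metrics["fisher"] = rec.fisher[stage]
                        if rec.fisher.get("naive"):
                            metrics["normalized_fisher"] = (
                                rec.fisher[stage] / rec.fisher["naive"]
                            )
                    for metric, value in metrics.items():
                        rows.append(
                            {
                                "experiment": self.name,
                                **cond,
                                "instance_seed": rec.instance_seed,
                                "stage": stage,
                                "metric": metric,
                                "value": value,
                            }
                        )
        return pd.DataFrame(rows)


def _run_condition(
    template: MothTemplate,
    trial_config: TrialConfig,
    n_instances: int,
    seed_seq: np.random.SeedSequence,
    max_attempt_factor: int = 6,
) -> Tuple[List[TrialRecord], int]:
    """Run trials until ``n_instances`` pass the acceptance envelope."""
    records: List[TrialRecord] = []
    rejected = 0
    max_attempts = max(max_attempt_factor * n_instances, n_instances + 10)
    seeds = _seed_ints(seed_seq, max_attempts)
    for s in seeds:
        rec = run_trial(template, replace(trial_config, seed=s))
        if rec.accepted:
            records.append(rec)
            if len(records) == n_instances:
                return records, rejected
        else:
            rejected += 1
    raise ConfigurationError(
        f"could not accept {n_instances} instances in {max_attempts} attempts "
        f"({rejected} rejected); check the SSNR acceptance envelope"
    )


def _run_grid(
    name: str,
    template_for,
    conditions: List[Dict],
    trial_for,
    n_instances: int,
    seed: int,
) -> ExperimentResult:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(conditions))
    records, rejections = [], []
    for cond, child in zip(conditions, children):
        recs, rej = _run_condition(
            template_for(cond), trial_for(cond), n_instances, child
        )
        records.append(recs)
        rejections.append(rej)
    return ExperimentResult(
        name=name,
        conditions=conditions,
        records=records,
        rejections=rejections,
        seed=seed,
        n_instances=n_instances,
    )


DEFAULT_LEVELS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


def experiment_learning_recovery(
    template: MothTemplate,
    levels: Sequence[float] = DEFAULT_LEVELS,
    sites: Sequence[str] = ("rn_channel", "pn_qn_channel"),
    n_instances: int = 30,
    seed: int = 0,
    mode: str = "magnitude",
) -> ExperimentResult:
    """Hebbian recovery: FAS over ``levels`` at each site, with training.

    Uses 0 QNs and natural AL noise.  ``mode="discrimination"`` adds
    pre-training and reports Fisher discriminants as well.
    """
    tpl = replace(template, n_qn_per_glom=0, al_noise_factor=1.0)
    conditions = [
        {"site": site, "kind": "fas", "level": float(lv)}
        for site in sites
        for lv in levels
    ]
    return _run_grid(
        "learning_recovery",
        lambda cond: tpl,
        conditions,
        lambda cond: TrialConfig(
            injury=InjurySpec(site=cond["site"], kind="fas", level=cond["level"]),
            mode=mode,
        ),
        n_instances,
        seed,
    )


def experiment_qn_ratio(
    template: MothTemplate,
    qn_counts: Sequence[int] = (0, 2, 4, 5, 7),
    levels: Sequence[float] = DEFAULT_LEVELS,
    n_instances: int = 30,
    seed: int = 0,
) -> ExperimentResult:
    """Parallel inhibition: PN+QN-channel FAS for each QN-per-glomerulus count."""
    conditions = [
        {"qn_per_glom": int(qn), "site": "pn_qn_channel", "kind": "fas", "level": float(lv)}
        for qn in qn_counts
        for lv in levels
    ]
    return _run_grid(
        "qn_ratio",
        lambda cond: replace(
            template, n_qn_per_glom=cond["qn_per_glom"], al_noise_factor=1.0
        ),
        conditions,
        lambda cond: TrialConfig(
            injury=InjurySpec(site="pn_qn_channel", kind="fas", level=cond["level"])
        ),
        n_instances,
        seed,
    )


def experiment_al_noise(
    template: MothTemplate,
    noise_factors: Sequence[float] = (0.0, 0.33, 0.67, 1.0, 1.33),
    levels: Sequence[float] = DEFAULT_LEVELS,
    n_instances: int = 30,
    seed: int = 0,
) -> ExperimentResult:
    """Upstream noise: RN-channel FAS for each AL noise factor (0 QNs)."""
    conditions = [
        {"al_noise_factor": float(nf), "site": "rn_channel", "kind": "fas", "level": float(lv)}
        for nf in noise_factors
        for lv in levels
    ]
    return _run_grid(
        "al_noise",
        lambda cond: replace(
            template, n_qn_per_glom=0, al_noise_factor=cond["al_noise_factor"]
        ),
        conditions,
        lambda cond: TrialConfig(
            injury=InjurySpec(site="rn_channel", kind="fas", level=cond["level"])
        ),
        n_instances,
        seed,
    )


def experiment_ablation_vs_fas(
    template: MothTemplate,
    levels: Sequence[float] = DEFAULT_LEVELS,
    sites: Sequence[str] = ("rn_channel", "pn_qn_channel"),
    n_instances: int = 30,
    seed: int = 0,
) -> ExperimentResult:
    """Paired FAS and ablation ensembles per site (no training stages)."""
    tpl = replace(template, n_qn_per_glom=0, al_noise_factor=1.0)
    conditions = [
        {"site": site, "kind": kind, "level": float(lv)}
        for site in sites
        for kind in ("fas", "ablation")
        for lv in levels
    ]
    return _run_grid(
        "ablation_vs_fas",
        lambda cond: tpl,
        conditions,
        lambda cond: TrialConfig(
            injury=InjurySpec(site=cond["site"], kind=cond["kind"], level=cond["level"]),
            include_training=False,
        ),
        n_instances,
        seed,
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def summarize(result: ExperimentResult) -> pd.DataFrame:
    """Condition-level mean, sample std, and standard error per metric."""
    frame = result.to_frame()
    keys = [c for c in frame.columns if c not in ("instance_seed", "value")]
    grouped = frame.groupby(keys, dropna=False)["value"]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    out["sem"] = out["std"] / np.sqrt(out["count"])
    return out


def _mean_loss_curve(
    result: ExperimentResult, site: str, kind: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean EN loss (1 - normalized post-injury response) vs injury level."""
    levels, losses = [], []
    for cond, recs in zip(result.conditions, result.records):
        if cond.get("site") != site or cond.get("kind") != kind:
            continue
        vals = [1.0 - r.normalized_mean("post_injury") for r in recs]
        levels.append(cond["level"])
        losses.append(float(np.mean(vals)))
    order = np.argsort(levels)
    return np.asarray(levels)[order], np.asarray(losses)[order]


def equal_loss_ratios(result: ExperimentResult, site: str) -> Dict[str, object]:
    """Empirical FAS:ablation level ratio producing equal EN loss at a site.

    For each non-zero ablation grid level whose mean loss falls inside the
    FAS loss curve's range, the FAS level with the same loss is found by
    monotone interpolation of the mean FAS curve; the ratio is FAS level /
    ablation level.  The analytic factor ``1/(1 - expected retained)`` is
    reported alongside for comparison.
    """
    lv_f, loss_f = _mean_loss_curve(result, site, "fas")
    lv_a, loss_a = _mean_loss_curve(result, site, "ablation")
    # enforce monotone non-decreasing mean curves for stable inversion, then
    # fit a monotone (PCHIP) curve so convexity does not bias the inversion
    loss_f = np.maximum.accumulate(loss_f)
    fit = PchipInterpolator(lv_f, loss_f)
    grid = np.linspace(lv_f[0], lv_f[-1], 601)
    fas_curve = np.maximum.accumulate(fit(grid))
    ratios = []
    for n, la in zip(lv_a, loss_a):
        if n <= 0 or la <= fas_curve[0] or la > fas_curve[-1]:
            continue
        m = float(grid[int(np.searchsorted(fas_curve, la))])
        ratios.append(m / n)
    return {
        "site": site,
        "ratios": ratios,
        "mean_ratio": float(np.mean(ratios)) if ratios else float("nan"),
        "analytic_factor": fas_ablation_ratio(),
    }
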
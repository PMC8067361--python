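"""Firing-rate model of the moth olfactory cascade RN -> AL -> MB -> EN.

Architecture
------------
Receptor neurons (RNs) in the antennae pool ~500 biological receptors per
glomerulus and drive the antennal lobe (AL).  Each AL glomerulus houses 5
excitatory projection neurons (PNs) and 0-7 inhibitory projection neurons
(QNs) that feed forward in parallel to the Kenyon cells (KCs) of the
mushroom body (MB).  KCs fire sparsely under global inhibition and project
to one or more readout extrinsic neurons (ENs) whose peak firing rate per
odor puff is the system's actionable output.  Reward releases octopamine,
which multiplicatively boosts AL input drive (not KC gain) and gates Hebbian
plasticity on the AL->MB and MB->EN connections; intra-AL connections are
not plastic.

Dynamics
--------
AL neurons follow leaky rectified-linear dynamics integrated with explicit
Euler steps::

    tau * da = (-a + rectify(input)) * dt + sigma * sqrt(dt) * N(0, 1)

with rates clipped at zero after the noise kick.  RN, KC and EN stages are
instantaneous maps of their inputs: RN = rectify(drive * injury attenuation
+ noise); KC = rectify(summed input - global inhibition), where the
inhibition level blends the per-step (1 - mb_sparsity) quantile of KC
inputs (which keeps ~10% of KCs active) with a fixed per-instance floor
calibrated at generation (which makes the readout sensitive to mean input
shifts, so injured inputs drop below threshold); EN = rectify(weights .
KC rates).
The KC input is the signed sum ``w+ . u+ - w- . u-`` of excitatory PN and
inhibitory QN rates; both weight families are stored as non-negative
magnitudes, the sign being applied here.

Units are arbitrary but calibrated so a healthy instance's peak EN odor
response is ~1 and its no-odor response ~0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .errors import (
    ConfigurationError,
    DimensionMismatchError,
    SimulationDivergedError,
)
from .injury import DamageLabel, InjuryState, lowpass_factor
from .metrics import ResponseSet
from .stimuli import StimulusSchedule

__all__ = [
    "MothTemplate",
    "MothInstance",
    "Timecourse",
    "generate_instance",
    "simulate",
    "extract_responses",
]


@dataclass(frozen=True)
class MothTemplate:
    """Generative parameter set from which network instances are drawn.

    Counts
    ------
    n_glomeruli : 60 antennal-lobe glomeruli.
    n_pn_per_glom : excitatory PNs per glomerulus; fixed at 5 in the study.
    n_qn_per_glom : inhibitory QNs per glomerulus, 0-7.
    rn_pool_per_glom : biological receptor neurons pooled into each model RN.
    n_kc : Kenyon cells (free calibration parameter; 2000 by default).
    n_en : readout neurons (single EN in the study).

    Noise
    -----
    al_noise_factor : multiplicative factor on *all* upstream Gaussian noise
        (RN input noise and AL state noise); 1.0 is the "natural" level and
        the study sweeps 0-1.33.
    rn_noise / al_noise : natural-level noise scales for the RN input and
        the AL state kick respectively.
    rn_noise_rule : how pooled RN injury inflates RN noise — ``"inverse"``
        (1/(1-n), default) or ``"inverse_sqrt"`` (1/sqrt(1-n)).

    Weights, plasticity, sparsity
    -----------------------------
    Per-connection-type Gaussian mean/std for initial weights (truncated at
    zero).  The MB->EN mean is expressed as ``w_kc_en_scale`` divided by the
    expected number of active KCs, so the EN calibration survives changes of
    ``n_kc``.  ``hebbian_rate`` is the dimensionless Hebbian rate constant
    (calibrated so ~5 octopamine puffs approach the cap),
    ``weight_cap_factor`` the saturation cap relative to initial weights,
    ``octopamine_gain`` the multiplicative AL input boost during reward, and
    ``mb_sparsity`` the target fraction of active KCs.

    ``ssnr_acceptance`` is the (min, max) naive-SSNR envelope for instance
    rejection; ``None`` disables a bound.
    """

    n_glomeruli: int = 60
    n_pn_per_glom: int = 5
    n_qn_per_glom: int = 0
    rn_pool_per_glom: int = 500
    n_kc: int = 2000
    n_en: int = 1
    # noise
    al_noise_factor: float = 1.0
    rn_noise: float = 0.08
    al_noise: float = 0.16
    rn_noise_rule: str = "inverse"
    # input stage
    rn_gain: float = 1.0
    rn_spont: float = 0.12
    lateral_inhibition: float = 0.1
    #: divisive gain-control coefficient of the AL pre-amplifier: glomerular
    #: drive is divided by (1 + g * mean RN rate), so a uniform loss of RN
    #: input is partially renormalized before reaching the MB
    al_gain_control: float = 10.0
    octopamine_gain: float = 2.5
    # weights
    w_rn_al_mean: float = 1.0
    w_rn_al_std: float = 0.2
    kc_fanin_pn: int = 4
    w_pn_kc_mean: float = 1.0
    w_pn_kc_std: float = 0.3
    w_qn_kc_mean: float = 1.0
    w_qn_kc_std: float = 0.3
    #: QN->KC edges are this factor denser than PN->KC (per-weight strength is
    #: divided by the same factor, so the mean inhibitory load is unchanged
    #: while QN-induced input variance shrinks)
    qn_fanin_factor: float = 3.0
    w_kc_en_scale: float = 11.1
    w_kc_en_rel_std: float = 0.3
    # plasticity
    hebbian_rate: float = 1.4
    al_mb_rate_ratio: float = 0.007
    weight_cap_factor: float = 1.5
    # mushroom body
    mb_sparsity: float = 0.10
    #: fraction of the calibrated inhibition floor actually applied; slightly
    #: below 1 leaves a trickle of spontaneous KC activity between puffs
    mb_theta_scale: float = 1.0
    #: weight of the fixed calibrated floor vs the per-step sparsity quantile
    #: in the global inhibition level: 0 = pure adaptive quantile (readout
    #: insensitive to mean input shifts), 1 = pure fixed threshold (losses
    #: amplified hard); intermediate values give partial gain control
    mb_theta_blend: float = 0.5
    # integration and measurement windows
    dt: float = 0.004
    tau_al: float = 0.02
    puff_duration: float = 0.2
    puff_gap: float = 0.3
    lead_in: float = 0.5
    response_margin: float = 0.05
    baseline_margin: float = 0.1
    # stimuli
    odor_magnitude: float = 1.0
    n_odor_targets: int = 25
    # instance acceptance
    ssnr_acceptance: Tuple[Optional[float], Optional[float]] = (2.5, None)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_glomeruli,
            self.n_pn_per_glom,
            self.rn_pool_per_glom,
            self.n_kc,
            self.n_en,
            self.kc_fanin_pn,
        )
        if any(c < 1 for c in counts):
            raise ConfigurationError("all neuron counts must be positive")
        if self.n_qn_per_glom < 0:
            raise ConfigurationError("QN count must be non-negative")
        if self.al_noise_factor < 0:
            raise ConfigurationError("al_noise_factor must be non-negative")
        if not 0.0 < self.mb_sparsity < 1.0:
            raise ConfigurationError("mb_sparsity must lie in (0, 1)")
        if self.weight_cap_factor <= 1.0:
            raise ConfigurationError("weight_cap_factor must exceed 1")
        if self.hebbian_rate < 0:
            raise ConfigurationError("hebbian_rate must be non-negative")
        if self.dt <= 0 or self.tau_al <= 0 or self.dt > self.tau_al:
            raise ConfigurationError("need 0 < dt <= tau_al for stable Euler steps")
        if self.rn_noise_rule not in ("inverse", "inverse_sqrt"):
            raise ConfigurationError("rn_noise_rule must be 'inverse' or 'inverse_sqrt'")

    @property
    def n_pn_total(self) -> int:
        return self.n_glomeruli * self.n_pn_per_glom

    @property
    def n_qn_total(self) -> int:
        return self.n_glomeruli * self.n_qn_per_glom

    @property
    def w_kc_en_mean(self) -> float:
        """Effective MB->EN weight mean, normalized by expected active KCs."""
        return self.w_kc_en_scale / (self.mb_sparsity * self.n_kc)


@dataclass(frozen=True)
class MothInstance:
    """One realized network drawn from a template.

    Weight conventions: ``W_pn_kc`` (w+) and ``W_qn_kc`` (w-) hold
    non-negative magnitudes; the inhibitory sign is applied in the KC input
    sum.  ``*_init`` copies anchor the plastic saturation cap
    (``weight_cap_factor * initial``).  ``injury`` is ``None`` for a healthy
    instance.
    """

    template: MothTemplate
    instance_seed: int
    glom_of_pn: np.ndarray
    glom_of_qn: np.ndarray
    w_rn_al: np.ndarray  # per AL neuron (PNs then QNs) input weight
    W_pn_kc: np.ndarray  # (n_kc, n_pn_total) excitatory, >= 0
    W_qn_kc: np.ndarray  # (n_kc, n_qn_total) inhibitory magnitude, >= 0
    W_kc_en: np.ndarray  # (n_en, n_kc), >= 0
    W_pn_kc_init: np.ndarray
    W_qn_kc_init: np.ndarray
    W_kc_en_init: np.ndarray
    #: Calibrated Lateral-Horn inhibition floor: the KC-input quantile under a
    #: healthy reference odor, fixed at generation and NOT recalibrated after
    #: injury or training (the enforced sparsity level is assumed stable).
    mb_theta: float = 0.0
    injury: Optional[InjuryState] = None

    @property
    def n_pn_total(self) -> int:
        return int(self.glom_of_pn.size)

    @property
    def n_qn_total(self) -> int:
        return int(self.glom_of_qn.size)

    @property
    def n_al(self) -> int:
        return self.n_pn_total + self.n_qn_total

    def injury_probe_seed(self) -> int:
        """Stable derived seed for the injury reference probe."""
        return int((self.instance_seed * 2654435761 + 97) % (2**31 - 1))

    def with_weights(
        self, W_pn_kc: np.ndarray, W_qn_kc: np.ndarray, W_kc_en: np.ndarray
    ) -> "MothInstance":
        return replace(self, W_pn_kc=W_pn_kc, W_qn_kc=W_qn_kc, W_kc_en=W_kc_en)


@dataclass
class Timecourse:
    """Time-indexed firing rates from one simulation run.

    ``en`` is always recorded (shape ``(n_steps, n_en)``); ``rn``, ``al``
    and ``kc`` are populated according to the ``record`` level requested
    (recording KC rates is memory-hungry and meant for short diagnostics).
    """

    t: np.ndarray
    en: np.ndarray
    rn: Optional[np.ndarray] = None
    al: Optional[np.ndarray] = None
    kc: Optional[np.ndarray] = None
    #: (W_pn_kc, W_qn_kc, W_kc_en) after online plasticity, if it ran
    updated_weights: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None

    @property
    def en1(self) -> np.ndarray:
        """Trace of the first (in the study, only) readout neuron."""
        return self.en[:, 0]


def _truncated_normal(rng: np.random.Generator, mean, std, size) -> np.ndarray:
    """Gaussian draws truncated at zero (negative mass moved to 0)."""
    return np.clip(rng.normal(mean, std, size=size), 0.0, None)


def generate_instance(template: MothTemplate, seed: int) -> MothInstance:
    """Draw one network instance from a template, deterministically per seed.

    Non-zero connections are assigned per the architectural constraints
    (each PN/QN innervates exactly one glomerulus; each KC samples
    ``kc_fanin_pn`` distinct PNs, and each QN->KC edge exists with the same
    per-neuron probability), then weights are drawn from the template's
    Gaussian parameters truncated at zero.
    """
    tpl = template
    rng = np.random.default_rng(seed)
    n_pn, n_qn, n_kc = tpl.n_pn_total, tpl.n_qn_total, tpl.n_kc
    glom_of_pn = np.repeat(np.arange(tpl.n_glomeruli), tpl.n_pn_per_glom)
    glom_of_qn = np.repeat(np.arange(tpl.n_glomeruli), tpl.n_qn_per_glom)

    w_rn_al = _truncated_normal(rng, tpl.w_rn_al_mean, tpl.w_rn_al_std, n_pn + n_qn)

    fanin = min(tpl.kc_fanin_pn, n_pn)
    scores = rng.random((n_kc, n_pn))
    kept = np.argpartition(scores, fanin - 1, axis=1)[:, :fanin]
    M_pn = np.zeros((n_kc, n_pn), dtype=bool)
    np.put_along_axis(M_pn, kept, True, axis=1)
    W_pn_kc = _truncated_normal(rng, tpl.w_pn_kc_mean, tpl.w_pn_kc_std, (n_kc, n_pn))
    W_pn_kc *= M_pn

    if n_qn > 0:
        p_edge = min(tpl.qn_fanin_factor * fanin / n_pn, 1.0)
        M_qn = rng.random((n_kc, n_qn)) < p_edge
        W_qn_kc = _truncated_normal(
            rng,
            tpl.w_qn_kc_mean / tpl.qn_fanin_factor,
            tpl.w_qn_kc_std / tpl.qn_fanin_factor,
            (n_kc, n_qn),
        )
        W_qn_kc *= M_qn
    else:
        W_qn_kc = np.zeros((n_kc, 0))

    mean_en = tpl.w_kc_en_mean
    W_kc_en = _truncated_normal(
        rng, mean_en, tpl.w_kc_en_rel_std * mean_en, (tpl.n_en, n_kc)
    )

    # calibrate the global-inhibition floor: noise-free steady-state KC input
    # under a reference odor, thresholded so ~mb_sparsity of KCs are active
    from .stimuli import generate_odor  # deferred (stimuli is stateless)

    probe_seed = int((seed * 2654435761 + 97) % (2**31 - 1))
    ref_odor = generate_odor(
        tpl.n_glomeruli, tpl.n_odor_targets, seed=probe_seed,
        magnitude=tpl.odor_magnitude,
    )
    r = tpl.rn_gain * (ref_odor.drive + tpl.rn_spont)
    d = np.clip(r - tpl.lateral_inhibition * r.mean(), 0.0, None)
    d /= 1.0 + tpl.al_gain_control * r.mean()
    a_ss = w_rn_al * d[np.concatenate([glom_of_pn, glom_of_qn])]
    u_ref = W_pn_kc @ a_ss[:n_pn]
    if n_qn:
        u_ref -= W_qn_kc @ a_ss[n_pn:]
    k_quant = min(max(int(np.floor((1 - tpl.mb_sparsity) * n_kc)), 0), n_kc - 1)
    mb_theta = tpl.mb_theta_scale * float(np.partition(u_ref, k_quant)[k_quant])

    return MothInstance(
        template=tpl,
        instance_seed=seed,
        glom_of_pn=glom_of_pn,
        glom_of_qn=glom_of_qn,
        w_rn_al=w_rn_al,
        W_pn_kc=W_pn_kc,
        W_qn_kc=W_qn_kc,
        W_kc_en=W_kc_en,
        W_pn_kc_init=W_pn_kc.copy(),
        W_qn_kc_init=W_qn_kc.copy(),
        W_kc_en_init=W_kc_en.copy(),
        mb_theta=mb_theta,
    )


def _window_steps(windows: np.ndarray, dt: float, nt: int) -> np.ndarray:
    """Boolean step mask for a set of (on, off) windows."""
    mask = np.zeros(nt, dtype=bool)
    for on, off in windows:
        i0 = max(int(np.floor(on / dt)), 0)
        i1 = min(int(np.ceil(off / dt)), nt)
        mask[i0:i1] = True
    return mask


def simulate(
    instance: MothInstance,
    schedule: StimulusSchedule,
    *,
    plasticity=None,
    record: str = "en",
    al_noise_factor: Optional[float] = None,
) -> Timecourse:
    """Integrate the cascade over a stimulus schedule.

    Parameters
    ----------
    plasticity
        Optional :class:`~manduca.plasticity.PlasticityConfig`; when given,
        Hebbian updates run online on every step inside an octopamine
        window, mutating the returned instance's weights **in place on a
        copy** — use :func:`~manduca.plasticity.training_pass` for the
        instance-updating entry point.  Plasticity outside octopamine
        windows never occurs (the gate is the octopamine window itself).
    record
        ``"en"`` (default), ``"al"`` (adds RN and AL rates), or ``"all"``
        (adds KC rates; short schedules only).
    al_noise_factor
        Override of the template's noise factor (used e.g. for noise-free
        probes).

    Notes
    -----
    The noise stream is seeded by ``schedule.seed``, so identical
    (instance, schedule) pairs produce bit-identical output.
    """
    tpl = instance.template
    if schedule.odors and schedule.odors[0].n_glomeruli != tpl.n_glomeruli:
        raise DimensionMismatchError(
            "schedule odors and template disagree on glomerulus count"
        )
    noise_factor = (
        tpl.al_noise_factor if al_noise_factor is None else al_noise_factor
    )
    dt, tau = tpl.dt, tpl.tau_al
    nt = int(np.ceil(schedule.duration / dt))
    if nt < 1:
        nt = 1
    rng = np.random.default_rng(schedule.seed)

    n_glom, n_pn, n_qn = tpl.n_glomeruli, instance.n_pn_total, instance.n_qn_total
    n_al = n_pn + n_qn

    # --- precompute per-step stimulus drive and octopamine gate -----------
    odor_idx = np.full(nt, -1, dtype=int)
    for k in range(schedule.n_puffs):
        on, off = schedule.puff_windows[k]
        i0, i1 = max(int(np.floor(on / dt)), 0), min(int(np.ceil(off / dt)), nt)
        odor_idx[i0:i1] = schedule.puff_odor[k]
    octo_open = _window_steps(schedule.octopamine_windows, dt, nt)

    drives = np.zeros((len(schedule.odors) + 1, n_glom))
    for j, odor in enumerate(schedule.odors):
        drives[j] = odor.drive
    base_drive = tpl.rn_gain * (drives[odor_idx] + tpl.rn_spont)  # (nt, n_glom)

    # --- injury precomputation --------------------------------------------
    inj = instance.injury
    rn_atten = np.ones((1, n_glom))
    sigma_rn = tpl.rn_noise * noise_factor
    al_static = None
    al_lowpass = None
    if inj is not None and inj.spec.site == "rn_channel":
        sigma_rn *= inj.rn_noise_scale
        rn_atten = np.full((nt, n_glom), 1.0 - inj.rn_ablation_level)
        if inj.rn_lowpass_share > 0:
            # the low-pass share of the damage tracks the odor-driven rate,
            # so the realized attenuation fluctuates around (1 - n)
            lo = np.percentile(base_drive, 5, axis=0)
            hi = np.percentile(base_drive, 95, axis=0)
            g = lowpass_factor(base_drive, lo, hi, inj.spec.lowpass_band)
            nominal = inj.spec.lowpass_band[0]
            rn_atten = rn_atten + inj.rn_lowpass_share * (g - nominal)
    elif inj is not None:
        al_static = inj.static_multiplier
        if inj.lowpass_mask is not None and inj.lowpass_mask.any():
            al_lowpass = (
                inj.lowpass_mask,
                inj.rate_lo,
                inj.rate_hi,
                inj.spec.lowpass_band,
            )

    # --- plasticity precomputation ----------------------------------------
    plastic = plasticity is not None and plasticity.hebbian_rate > 0
    if plastic:
        cap = plasticity.weight_cap_factor
        W_pn = instance.W_pn_kc.copy()
        W_qn = instance.W_qn_kc.copy()
        W_en = instance.W_kc_en.copy()
        cap_pn = cap * instance.W_pn_kc_init
        cap_qn = cap * instance.W_qn_kc_init
        cap_en = cap * instance.W_kc_en_init
        mask_pn = instance.W_pn_kc_init > 0
        mask_qn = instance.W_qn_kc_init > 0
        mask_en = instance.W_kc_en_init > 0
        eta = plasticity.hebbian_rate * dt
        # AL->MB growth runs slower than MB->EN: the subtractive KC threshold
        # amplifies input-weight growth superlinearly at the readout, so the
        # readout synapse carries most of the learning
        eta_pn = eta * plasticity.al_mb_rate_ratio * tpl.w_pn_kc_mean
        eta_qn = eta * plasticity.al_mb_rate_ratio * tpl.w_qn_kc_mean
        eta_en = eta * tpl.w_kc_en_mean
    else:
        W_pn, W_qn, W_en = instance.W_pn_kc, instance.W_qn_kc, instance.W_kc_en

    # --- state and recording ----------------------------------------------
    a = np.zeros(n_al)  # AL neuron rates (PNs then QNs)
    glom_of_al = np.concatenate([instance.glom_of_pn, instance.glom_of_qn])
    w_rn = instance.w_rn_al
    sig_al = tpl.al_noise * noise_factor * np.sqrt(dt)
    k_quant = int(np.floor((1.0 - tpl.mb_sparsity) * tpl.n_kc))
    k_quant = min(max(k_quant, 0), tpl.n_kc - 1)

    en_tr = np.empty((nt, tpl.n_en))
    rn_tr = np.empty((nt, n_glom)) if record in ("al", "all") else None
    al_tr = np.empty((nt, n_al)) if record in ("al", "all") else None
    kc_tr = np.empty((nt, tpl.n_kc)) if record == "all" else None

    for it in range(nt):
        # receptor stage: pooled-RN drive, injury attenuation, input noise
        atten = rn_atten[it] if rn_atten.shape[0] > 1 else rn_atten[0]
        r = base_drive[it] * atten
        if sigma_rn > 0:
            r = r + sigma_rn * rng.standard_normal(n_glom)
        np.clip(r, 0.0, None, out=r)
        # AL pre-amplifier: subtractive lateral inhibition between glomeruli
        # plus divisive gain control of the population drive
        r_mean = r.mean()
        d = np.clip(r - tpl.lateral_inhibition * r_mean, 0.0, None)
        d /= 1.0 + tpl.al_gain_control * r_mean
        gain = tpl.octopamine_gain if octo_open[it] else 1.0
        inp = gain * w_rn * d[glom_of_al]
        a += (dt / tau) * (inp - a)
        if sig_al > 0:
            a += sig_al * rng.standard_normal(n_al)
        np.clip(a, 0.0, None, out=a)
        # AL output with per-neuron injury filters (PN+QN channel)
        out = a
        if al_static is not None:
            out = a * al_static
            if al_lowpass is not None:
                lmask, lo, hi, band = al_lowpass
                out[lmask] = a[lmask] * lowpass_factor(
                    a[lmask], lo[lmask], hi[lmask], band
                )
        p = out[:n_pn]
        q = out[n_pn:]
        # mushroom body: signed summed input, global sparsity-setting inhibition
        u = W_pn @ p
        if n_qn:
            u -= W_qn @ q
        # global inhibition: blend of the per-step sparsity quantile and the
        # calibrated Lateral-Horn floor — the fixed floor component makes the
        # readout sensitive to mean input shifts (injury pushes KCs below
        # threshold), the quantile component provides partial gain control
        blend = tpl.mb_theta_blend
        theta = blend * instance.mb_theta + (1.0 - blend) * (
            np.partition(u, k_quant)[k_quant]
        )
        kc = np.clip(u - theta, 0.0, None)
        en = np.clip(W_en @ kc, 0.0, None)

        if plastic and octo_open[it]:
            # Hebbian growth, gated by octopamine, capped at c * w_init
            np.minimum(W_pn + eta_pn * np.outer(kc, p) * mask_pn, cap_pn, out=W_pn)
            if n_qn:
                np.minimum(W_qn + eta_qn * np.outer(kc, q) * mask_qn, cap_qn, out=W_qn)
            np.minimum(W_en + eta_en * en[:, None] * kc[None, :] * mask_en, cap_en, out=W_en)

        en_tr[it] = en
        if rn_tr is not None:
            rn_tr[it] = r
            al_tr[it] = a
        if kc_tr is not None:
            kc_tr[it] = kc

    if not np.isfinite(en_tr).all():
        raise SimulationDivergedError("non-finite EN firing rate encountered")

    tc = Timecourse(
        t=(np.arange(nt) + 1) * dt, en=en_tr, rn=rn_tr, al=al_tr, kc=kc_tr
    )
    if plastic:
        tc.updated_weights = (W_pn, W_qn, W_en)  # consumed by training_pass
    return tc


def extract_responses(
    timecourse: Timecourse,
    schedule: StimulusSchedule,
    stage: str = "",
    odor_index: Optional[int] = None,
    response_margin: float = 0.05,
    baseline_margin: float = 0.1,
) -> ResponseSet:
    """Reduce an EN trace to its per-puff response set.

    ``F`` holds the peak EN rate within each puff window (extended by
    ``response_margin`` to catch the rise); ``Sp`` is the mean EN rate over
    the inter-puff baseline windows.  ``odor_index`` restricts ``F`` to
    puffs of one odor (for discrimination stages with interleaved stimuli).
    """
    if schedule.n_puffs < 1:
        raise ConfigurationError("schedule contains no odor puffs")
    t, en = timecourse.t, timecourse.en1
    peaks = []
    for k in range(schedule.n_puffs):
        if odor_index is not None and schedule.puff_odor[k] != odor_index:
            continue
        on, off = schedule.puff_windows[k]
        mask = (t >= on) & (t <= off + response_margin)
        if not mask.any():
            raise ConfigurationError(
                "timecourse does not cover puff window "
                f"[{on:.3f}, {off:.3f}] (trace ends at t={t[-1]:.3f})"
            )
        peaks.append(float(en[mask].max()))
    if not peaks:
        raise ConfigurationError("no puffs matched the requested odor index")
    base = schedule.baseline_windows(baseline_margin)
    base_mask = np.zeros(t.size, dtype=bool)
    for on, off in base:
        base_mask |= (t >= on) & (t <= off)
    sp = float(en[base_mask].mean()) if base_mask.any() else 0.0
    return ResponseSet(peaks=np.asarray(peaks), spontaneous=sp, stage=stage)
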
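"""Focal-axonal-swelling (FAS) and ablation injury at the firing-rate level.

FAS compromises spike propagation along an axon; at the firing-rate level it
is modeled as one of four per-neuron filters applied to the healthy rate:

================  =======================================================
transmit          rate unaffected (x 1)
reflect           rate cut by half (x 0.5)
ablate            rate destroyed (x 0)
lowpass           rate multiplied by 0.7-0.9, high rates hit harder
================  =======================================================

Damage types are allocated among injured neurons in fixed proportions,
default (0.15, 0.35, 0.35, 0.15).  Unlike ablation, FAS leaves most injured
neurons with reduced but non-zero output.

Two injury sites are supported:

* **PN+QN channel** (AL -> MB): projection neurons are modeled one-to-one, so
  each injured neuron gets its own filter.
* **RN channel** (antennae -> AL): each model receptor neuron pools ~500
  biological RNs, so injury is applied as an average over the pool — drive
  attenuated by ``(1 - n)`` and input noise inflated by ``1 / (1 - n)`` where
  ``n`` is the ablation-equivalent injury level (fewer inputs are averaged,
  so less noise cancellation).  The low-pass share of the damage makes the
  effective attenuation fluctuate slightly with the odor-driven rate.

The module also exposes the analytic FAS <-> ablation correspondence: with
the default fractions and multipliers an injured neuron retains on average
``0.15*1 + 0.35*0.5 + 0.35*0 + 0.15*0.7 = 0.43`` of its rate, so ablating
``n%`` of a large pooled population removes the same summed rate as FAS
injury to ``m = n / 0.57 ~= 1.75 n`` percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import TYPE_CHECKING, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, InjuryDomainError

if TYPE_CHECKING:  # pragma: no cover
    from .network import MothInstance

__all__ = [
    "DamageLabel",
    "InjurySpec",
    "InjuryState",
    "DEFAULT_FRACTIONS",
    "DEFAULT_MULTIPLIERS",
    "DEFAULT_LOWPASS_BAND",
    "fas_filter",
    "lowpass_factor",
    "assign_damage",
    "expected_retained_fraction",
    "fas_ablation_ratio",
    "fas_to_ablation",
    "ablation_to_fas",
    "apply_injury",
    "apply_injury_pn_qn",
    "apply_injury_rn",
]


class DamageLabel(Enum):
    """Damage type assigned to one injured neuron."""

    TRANSMIT = 0
    REFLECT = 1
    ABLATE = 2
    LOWPASS = 3


#: Damage-type proportions (transmit, reflect, ablate, lowpass).
DEFAULT_FRACTIONS: Tuple[float, float, float, float] = (0.15, 0.35, 0.35, 0.15)
#: Firing-rate multipliers per damage type; 0.7 is the nominal low-pass value.
DEFAULT_MULTIPLIERS: Tuple[float, float, float, float] = (1.0, 0.5, 0.0, 0.7)
#: Low-pass multiplier range, applied 0.9 at low rates down to 0.7 at high rates.
DEFAULT_LOWPASS_BAND: Tuple[float, float] = (0.7, 0.9)


@dataclass(frozen=True)
class InjurySpec:
    """Specification of one injury event.

    Parameters
    ----------
    site
        ``"rn_channel"`` (antennae -> AL) or ``"pn_qn_channel"`` (AL -> MB).
    kind
        ``"fas"`` or ``"ablation"``.
    level
        Fraction of neurons injured, 0-0.6 in the experiments.
    fractions
        Damage-type proportions (transmit, reflect, ablate, lowpass); must
        sum to 1.
    lowpass_band
        (low, high) multipliers for the rate-dependent low-pass filter.
    seed
        Seed for neuron selection and label placement.
    """

    site: str = "pn_qn_channel"
    kind: str = "fas"
    level: float = 0.0
    fractions: Tuple[float, float, float, float] = DEFAULT_FRACTIONS
    lowpass_band: Tuple[float, float] = DEFAULT_LOWPASS_BAND
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site not in ("rn_channel", "pn_qn_channel"):
            raise ConfigurationError(f"unknown injury site: {self.site!r}")
        if self.kind not in ("fas", "ablation"):
            raise ConfigurationError(f"unknown injury kind: {self.kind!r}")
        if not 0.0 <= self.level <= 1.0:
            raise ConfigurationError("injury level must lie in [0, 1]")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigurationError("damage-type fractions must sum to 1")
        lo, hi = self.lowpass_band
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError("lowpass multipliers must lie in (0, 1]")


@dataclass(frozen=True)
class InjuryState:
    """Realized per-neuron injury carried by a :class:`~manduca.network.MothInstance`.

    For the PN+QN site, ``static_multiplier`` holds the per-AL-neuron rate
    factor (1, 0.5 or 0; 1 also for low-pass neurons, whose rate-dependent
    factor is applied separately via ``lowpass_mask`` and the healthy-rate
    percentiles ``rate_lo``/``rate_hi``).  For the RN site the pooled
    treatment is summarized by the nominal ablation-equivalent level
    ``rn_ablation_level`` and the noise inflation ``rn_noise_scale``.
    """

    spec: InjurySpec
    # PN+QN channel fields (arrays over the AL neuron population)
    labels: Optional[np.ndarray] = None  # int codes, -1 = uninjured
    static_multiplier: Optional[np.ndarray] = None
    lowpass_mask: Optional[np.ndarray] = None
    rate_lo: Optional[np.ndarray] = None
    rate_hi: Optional[np.ndarray] = None
    # RN channel fields
    rn_fas_level: float = 0.0
    rn_ablation_level: float = 0.0
    rn_noise_scale: float = 1.0
    rn_lowpass_share: float = 0.0  # fraction of the population that is low-pass injured


def lowpass_factor(
    rates: np.ndarray,
    rate_lo: np.ndarray | float,
    rate_hi: np.ndarray | float,
    band: Tuple[float, float] = DEFAULT_LOWPASS_BAND,
) -> np.ndarray:
    """Rate-dependent low-pass multiplier.

    Interpolates linearly from ``band[1]`` (0.9) at ``rate_lo`` down to
    ``band[0]`` (0.7) at ``rate_hi``, clamped to the band.  High firing rates
    are affected more strongly, mirroring the preferential loss of
    closely-bunched spikes.  A degenerate reference range collapses to the
    harsher end of the band (the nominal 0.7 used in the analytic
    correspondence).
    """
    lo_mult, hi_mult = band
    rates = np.asarray(rates, dtype=float)
    span = np.asarray(rate_hi, dtype=float) - np.asarray(rate_lo, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(span > 0, (rates - rate_lo) / np.where(span > 0, span, 1.0), 1.0)
    factor = hi_mult - (hi_mult - lo_mult) * frac
    return np.clip(factor, lo_mult, hi_mult)


def fas_filter(
    rates: np.ndarray,
    label: DamageLabel,
    band: Tuple[float, float] = DEFAULT_LOWPASS_BAND,
    rate_range: Tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Apply one FAS damage filter to healthy firing rate(s).

    ``rate_range`` gives the neuron's healthy operating range used by the
    low-pass filter (defaults to normalized [0, 1] units, so a unit rate
    receives the nominal 0.7).  Output is always within ``[0, rate]``.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("firing rates must be non-negative")
    if label is DamageLabel.TRANSMIT:
        return rates.copy()
    if label is DamageLabel.REFLECT:
        return 0.5 * rates
    if label is DamageLabel.ABLATE:
        return np.zeros_like(rates)
    return lowpass_factor(rates, rate_range[0], rate_range[1], band) * rates


def assign_damage(
    n_neurons: int,
    level: float,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> np.ndarray:
    """Select injured neurons and allocate damage types in exact proportions.

    Exactly ``round(level * n_neurons)`` neurons are chosen uniformly at
    random.  Damage-type counts follow the stated proportions via
    largest-remainder rounding (ties broken by damage-type order), then the
    labels are randomly placed among the selected neurons.  Deterministic
    given ``seed``.

    Returns
    -------
    numpy.ndarray
        Integer array of length ``n_neurons``: ``DamageLabel`` values for
        injured neurons, ``-1`` for uninjured ones.
    """
    if n_neurons < 0 or not 0.0 <= level <= 1.0:
        raise ConfigurationError("invalid neuron count or injury level")
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9 or np.any(fractions < 0):
        raise ConfigurationError("damage-type fractions must be non-negative and sum to 1")
    labels = np.full(n_neurons, -1, dtype=int)
    n_injured = int(round(level * n_neurons))
    if n_injured == 0:
        return labels
    rng = np.random.default_rng(seed)
    injured = rng.choice(n_neurons, size=n_injured, replace=False)
    counts = _largest_remainder(fractions * n_injured)
    type_codes = np.repeat(np.arange(fractions.size), counts)
    labels[injured] = rng.permutation(type_codes)
    return labels


def _largest_remainder(quotas: np.ndarray) -> np.ndarray:
    """Round real-valued quotas to integers preserving the total exactly."""
    base = np.floor(quotas).astype(int)
    remainder = int(round(quotas.sum())) - base.sum()
    if remainder > 0:
        # stable: larger fractional part first, ties by lower index
        order = np.lexsort((np.arange(quotas.size), -(quotas - base)))
        base[order[:remainder]] += 1
    return base


def expected_retained_fraction(
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
) -> float:
    """Expected fraction of a FAS-injured neuron's rate that survives.

    The dot product of the damage-type fractions with their nominal
    firing-rate multipliers (low-pass at its nominal 0.7): 0.43 by default.
    """
    fractions = np.asarray(fractions, dtype=float)
    multipliers = np.asarray(multipliers, dtype=float)
    if fractions.shape != multipliers.shape:
        raise ConfigurationError("fractions and multipliers must align")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ConfigurationError("damage-type fractions must sum to 1")
    return float(fractions @ multipliers)


def fas_ablation_ratio(
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
    ndigits: Optional[int] = 2,
) -> float:
    """Equal-loss FAS : ablation level ratio, ``1 / (1 - retained)``.

    Ablating ``n%`` of a large pooled population removes ``n%`` of the summed
    rate; FAS injury to ``m%`` removes ``m * (1 - retained)%``.  The two are
    equal when ``m / n = 1 / (1 - retained)``, ~1.754 at the defaults.  The
    nominal (quoted) rate rounds this to 2 decimals, 1.75, which is also the
    value used in the worked conversions; pass ``ndigits=None`` for the
    exact ratio.
    """
    retained = expected_retained_fraction(fractions, multipliers)
    if retained >= 1.0:
        raise InjuryDomainError("FAS with no expected loss has no ablation equivalent")
    ratio = 1.0 / (1.0 - retained)
    return ratio if ndigits is None else round(ratio, ndigits)


def fas_to_ablation(
    m: float,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
    ndigits: Optional[int] = 2,
) -> float:
    """Ablation level causing the same expected pooled loss as FAS level ``m``."""
    if not 0.0 <= m < 1.0:
        raise InjuryDomainError("FAS level must lie in [0, 1)")
    return m / fas_ablation_ratio(fractions, multipliers, ndigits)


def ablation_to_fas(
    n: float,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
    ndigits: Optional[int] = 2,
) -> float:
    """FAS level causing the same expected pooled loss as ablation level ``n``."""
    if not 0.0 <= n < 1.0:
        raise InjuryDomainError("ablation level must lie in [0, 1)")
    return n * fas_ablation_ratio(fractions, multipliers, ndigits)


# ---------------------------------------------------------------------------
# Application to a network instance
# ---------------------------------------------------------------------------


def apply_injury(instance: "MothInstance", spec: InjurySpec) -> "MothInstance":
    """Dispatch to the site-appropriate injury application."""
    if spec.site == "pn_qn_channel":
        return apply_injury_pn_qn(instance, spec)
    return apply_injury_rn(instance, spec)


def apply_injury_pn_qn(instance: "MothInstance", spec: InjurySpec) -> "MothInstance":
    """Injure the AL -> MB channel: PNs and QNs pooled into one population.

    Every injured neuron's output rate is passed through its FAS filter
    (or zeroed, for ablation) at every subsequent simulation step.  The
    low-pass filters' reference rate ranges (per-neuron 5th/95th percentile
    healthy rates) come from a short noise-free probe puff on the healthy
    instance, so application is deterministic given the spec's seed.
    """
    if spec.site != "pn_qn_channel":
        raise ConfigurationError("spec targets a different site")
    n_al = instance.n_pn_total + instance.n_qn_total
    if spec.kind == "ablation":
        labels = assign_damage(n_al, spec.level, (0.0, 0.0, 1.0, 0.0), spec.seed)
    else:
        labels = assign_damage(n_al, spec.level, spec.fractions, spec.seed)
    static = np.ones(n_al)
    static[labels == DamageLabel.REFLECT.value] = 0.5
    static[labels == DamageLabel.ABLATE.value] = 0.0
    lowpass_mask = labels == DamageLabel.LOWPASS.value
    if lowpass_mask.any():
        rate_lo, rate_hi = _healthy_rate_percentiles(instance)
    else:
        rate_lo = np.zeros(n_al)
        rate_hi = np.ones(n_al)
    state = InjuryState(
        spec=spec,
        labels=labels,
        static_multiplier=static,
        lowpass_mask=lowpass_mask,
        rate_lo=rate_lo,
        rate_hi=rate_hi,
    )
    return replace(instance, injury=state)


def apply_injury_rn(instance: "MothInstance", spec: InjurySpec) -> "MothInstance":
    """Injure the antennae -> AL channel via the pooled-RN treatment.

    For FAS at level ``m``, the ablation-equivalent level is
    ``n = m / ratio`` (ratio ~1.75): every model-RN drive is multiplied by
    ``(1 - n)`` and the RN noise parameter by ``1 / (1 - n)`` (or
    ``1 / sqrt(1 - n)`` under the averaging rule, see the template's
    ``rn_noise_rule``).  The low-pass share of the damage is applied as a
    rate-dependent factor, so the realized attenuation fluctuates slightly
    with odor input.  For ablation at level ``n`` the same pooled formulas
    apply with ``n`` directly and no fluctuation.
    """
    if spec.site != "rn_channel":
        raise ConfigurationError("spec targets a different site")
    if spec.kind == "fas":
        m = spec.level
        n = fas_to_ablation(m, spec.fractions)
        lowpass_share = m * spec.fractions[DamageLabel.LOWPASS.value]
    else:
        m = 0.0
        n = spec.level
        lowpass_share = 0.0
    if n >= 1.0:
        raise InjuryDomainError("pooled RN injury implies total destruction (n >= 1)")
    if instance.template.rn_noise_rule == "inverse_sqrt":
        noise_scale = 1.0 / np.sqrt(1.0 - n)
    else:
        noise_scale = 1.0 / (1.0 - n)
    state = InjuryState(
        spec=spec,
        rn_fas_level=m,
        rn_ablation_level=n,
        rn_noise_scale=float(noise_scale),
        rn_lowpass_share=lowpass_share,
    )
    return replace(instance, injury=state)


def _healthy_rate_percentiles(instance: "MothInstance"):
    """Per-AL-neuron 5th/95th percentile rates from a noise-free probe puff."""
    from .network import simulate  # deferred: network imports this module's types
    from .stimuli import build_schedule, generate_odor, StagePlan

    tpl = instance.template
    odor = generate_odor(
        tpl.n_glomeruli, tpl.n_odor_targets, seed=instance.injury_probe_seed()
    )
    schedule = build_schedule(
        [StagePlan(n_puffs=1, octopamine=False)],
        odors=[odor],
        template=tpl,
        seed=0,
    )
    probe = simulate(
        instance, schedule, record="al", al_noise_factor=0.0
    )
    rates = probe.al  # (n_steps, n_al)
    return (
        np.percentile(rates, 5, axis=0),
        np.percentile(rates, 95, axis=0),
    )
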
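"""Octopamine-gated Hebbian plasticity with weight saturation.

Learning combines two ingredients: octopamine (released on reward) boosts
antennal-lobe firing rates, and Hebbian updates strengthen a plastic synapse
proportionally to the product of its pre- and post-synaptic rates,
``delta_w ~ f_a(t) * f_b(t)``.  Updates apply only to the plastic AL->MB
(PN->KC, QN->KC) and MB->EN connections, only while an octopamine window is
open, and saturate at ``weight_cap_factor`` times each connection's initial
weight.  QN->KC updates grow the inhibitory-weight *magnitude*, mirroring
the excitatory rule.  Learning fails entirely without octopamine: with the
gate closed the instance is returned unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError
from .network import MothInstance, Timecourse, simulate
from .stimuli import StimulusSchedule

__all__ = ["PlasticityConfig", "hebbian_update", "training_pass"]


@dataclass(frozen=True)
class PlasticityConfig:
    """Hebbian rate constant and saturation cap.

    ``hebbian_rate`` is the proportionality constant eta (>= 0; the default
    is calibrated at the template level so five training puffs approach the
    cap); ``weight_cap_factor`` c > 1 bounds every plastic weight at
    ``c * w_init``.  Plasticity is active only while an octopamine window is
    open — the gate is structural, not a flag to toggle here.
    """

    hebbian_rate: float = 1.4
    weight_cap_factor: float = 1.5
    al_mb_rate_ratio: float = 0.007

    def __post_init__(self) -> None:
        if self.hebbian_rate < 0:
            raise ConfigurationError("hebbian_rate must be non-negative")
        if self.weight_cap_factor <= 1.0:
            raise ConfigurationError("weight_cap_factor must exceed 1")

    @classmethod
    def from_template(cls, template) -> "PlasticityConfig":
        return cls(
            hebbian_rate=template.hebbian_rate,
            weight_cap_factor=template.weight_cap_factor,
            al_mb_rate_ratio=template.al_mb_rate_ratio,
        )


def hebbian_update(
    w: float,
    f_pre: float,
    f_post: float,
    config: PlasticityConfig,
    w_init: float,
) -> float:
    """One Hebbian step for a single plastic connection.

    Returns ``min(c * w_init, w + eta * f_pre * f_post)``: the update never
    decreases the weight and the cap is absorbing.  Negative rates violate
    the firing-rate contract.
    """
    if f_pre < 0 or f_post < 0:
        raise ValueError("firing rates must be non-negative")
    return min(
        config.weight_cap_factor * w_init,
        w + config.hebbian_rate * f_pre * f_post,
    )


def training_pass(
    instance: MothInstance,
    schedule: StimulusSchedule,
    config: PlasticityConfig,
) -> MothInstance:
    """Run one training simulation and return the instance with updated weights.

    The schedule's octopamine windows gate the updates: every plastic
    connection receives the :func:`hebbian_update` arithmetic on each step
    inside a window (with the per-step rate ``eta * dt`` scaled by the
    layer's template weight mean, so the growth rate is comparable across
    layers).  A schedule whose octopamine never opens, or a zero learning
    rate, returns the instance unchanged.
    """
    if config.hebbian_rate == 0 or schedule.octopamine_windows.size == 0:
        return instance
    tc = simulate(instance, schedule, plasticity=config)
    assert tc.updated_weights is not None
    return instance.with_weights(*tc.updated_weights)
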
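"""Readout-level statistics for extrinsic-neuron (EN) response sets.

All metrics operate on a :class:`ResponseSet`: the set ``F`` of discrete
per-puff peak EN firing rates recorded during one trial stage, together with
the mean spontaneous (inter-puff) rate ``Sp``.  Response statistics use the
sample standard deviation (``ddof=1``) throughout.

Metrics
-------
fisher_discriminant
    Separability of trained- vs control-odor responses,
    ``(mu_t - mu_c) / (0.5 * (sigma_t + sigma_c))``.
snr
    Signal-to-noise ratio ``mu(F) / sigma(F)``.
ssnr
    Signal-to-spontaneous-noise ratio ``mu(F) / Sp``, the clarity of the odor
    response against background activity.
top_end_preservation
    ``(mu_j + sigma_j) / (mu_h + sigma_h)`` — how much of the top end of the
    response distribution survives injury (1 = untouched, 0 = destroyed).
top_tranche
    The strongest responses, either those above ``mu + sigma`` or the top
    rank quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple

import numpy as np

from .errors import UndefinedMetricError

__all__ = [
    "ResponseSet",
    "fisher_discriminant",
    "snr",
    "ssnr",
    "top_end_preservation",
    "top_tranche",
    "Preservation",
]


@dataclass(frozen=True)
class ResponseSet:
    """Per-puff peak EN responses plus spontaneous rate for one trial stage.

    Parameters
    ----------
    peaks
        ``F = {f_i}``: peak EN firing rate within each odor-puff window.
    spontaneous
        ``Sp``: mean EN rate over the inter-puff baseline windows.
    stage
        Label such as ``"naive"``, ``"post_injury"``, ``"post_training"``.
    """

    peaks: np.ndarray
    spontaneous: float
    stage: str = ""

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float)
        if peaks.ndim != 1 or peaks.size < 1:
            raise ValueError("a ResponseSet needs at least one peak response")
        if np.any(peaks < 0) or self.spontaneous < 0:
            raise ValueError("firing rates must be non-negative")
        object.__setattr__(self, "peaks", peaks)

    @property
    def n(self) -> int:
        return int(self.peaks.size)

    @property
    def mean(self) -> float:
        """mu(F)."""
        return float(np.mean(self.peaks))

    @property
    def std(self) -> float:
        """sigma(F), sample convention (n-1); 0 for a singleton set."""
        if self.peaks.size < 2:
            return 0.0
        return float(np.std(self.peaks, ddof=1))

    def scaled(self, factor: float) -> "ResponseSet":
        """Return a copy with every rate multiplied by ``factor`` (>= 0)."""
        return replace(
            self,
            peaks=self.peaks * factor,
            spontaneous=self.spontaneous * factor,
        )


def fisher_discriminant(f_train: ResponseSet, f_control: ResponseSet) -> float:
    """Fisher linear discriminant between two response sets.

    ``Fd = (mu_train - mu_control) / (0.5 * (sigma_train + sigma_control))``.

    Raises
    ------
    UndefinedMetricError
        If both standard deviations are zero.
    """
    denom = 0.5 * (f_train.std + f_control.std)
    if denom == 0.0:
        raise UndefinedMetricError(
            "Fisher discriminant undefined: both response sets are degenerate"
        )
    return (f_train.mean - f_control.mean) / denom


def snr(responses: ResponseSet) -> float:
    """Signal-to-noise ratio ``mu(F) / sigma(F)``.

    A zero standard deviation (noise-free configuration) yields ``math.inf``
    as an explicit sentinel rather than an exception.
    """
    sigma = responses.std
    if sigma == 0.0:
        return math.inf
    return responses.mean / sigma


def ssnr(responses: ResponseSet) -> float:
    """Signal-to-spontaneous-noise ratio ``mu(F) / Sp``.

    ``Sp == 0`` yields ``math.inf`` as an explicit sentinel.
    """
    if responses.spontaneous == 0.0:
        return math.inf
    return responses.mean / responses.spontaneous


class Preservation(NamedTuple):
    """Raw top-end preservation plus the value clamped to [0, 1] for reporting."""

    raw: float
    reported: float


def top_end_preservation(
    f_healthy: ResponseSet, f_injured: ResponseSet
) -> Preservation:
    """Top-end preservation ``P = (mu_j + sigma_j) / (mu_h + sigma_h)``.

    Measures attenuation of the strongest responses when injury shrinks the
    response distribution: 1 means no attenuation, 0 total attenuation.
    The raw ratio is returned alongside the [0, 1]-clamped reporting value.
    """
    denom = f_healthy.mean + f_healthy.std
    if denom <= 0.0:
        raise UndefinedMetricError("degenerate healthy response set (mu + sigma <= 0)")
    raw = (f_injured.mean + f_injured.std) / denom
    return Preservation(raw=raw, reported=min(max(raw, 0.0), 1.0))


def top_tranche(
    responses: ResponseSet,
    q: float = 0.15,
    rule: Literal["rank", "mu_sigma"] = "rank",
) -> ResponseSet:
    """Extract the top-scoring tranche of a response set.

    Two definitions are supported:

    ``"rank"``
        The top ``ceil(q * n)`` responses by value (default, used by the
        experiment runners).  Ties broken by puff index, earlier first.
    ``"mu_sigma"``
        The set-builder form ``{f_i in F | f_i > mu(F) + sigma(F)}``; may be
        empty (e.g., for a constant response set).
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    peaks = responses.peaks
    if rule == "mu_sigma":
        mask = peaks > responses.mean + responses.std
        subset = peaks[mask]
    elif rule == "rank":
        k = math.ceil(q * peaks.size)
        # stable: sort by (-value, index) so equal peaks keep puff order
        order = np.lexsort((np.arange(peaks.size), -peaks))
        subset = peaks[np.sort(order[:k])]
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown tranche rule: {rule!r}")
    if subset.size == 0:
        # preserve ResponseSet invariants by returning an explicit empty view
        return EmptyResponseSet(spontaneous=responses.spontaneous, stage=responses.stage)
    return replace(responses, peaks=subset)


@dataclass(frozen=True)
class EmptyResponseSet(ResponseSet):
    """Degenerate tranche: no response exceeded the threshold."""

    peaks: np.ndarray = field(default_factory=lambda: np.empty(0))
    spontaneous: float = 0.0

    def __post_init__(self) -> None:  # bypass the n >= 1 contract
        object.__setattr__(self, "peaks", np.empty(0, dtype=float))

    @property
    def mean(self) -> float:
        return 0.0

    @property
    def std(self) -> float:
        return 0.0
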
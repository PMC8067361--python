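"""Synthetic stimulus generation: odors, puff schedules, discrimination pairs.

Odors are non-negative unit-length vectors over antennal-lobe glomeruli,
broadly projected (~25 of 60 glomeruli targeted), scaled by a magnitude
scalar before being fed to the receptor neurons.  A stimulus schedule lays
out odor puffs, inter-puff baseline gaps, and octopamine (reward) windows on
a common time axis; octopamine windows open only during training stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "Odor",
    "StagePlan",
    "StimulusSchedule",
    "generate_odor",
    "noise_stimulus",
    "build_schedule",
    "make_discrimination_pair",
    "DEFAULT_PUFF_DURATION",
    "DEFAULT_PUFF_GAP",
    "DEFAULT_LEAD_IN",
]

#: Odor puff length in seconds.
DEFAULT_PUFF_DURATION = 0.2
#: Baseline gap between puffs in seconds.
DEFAULT_PUFF_GAP = 0.3
#: Settling time before the first puff of a stage, seconds.
DEFAULT_LEAD_IN = 0.5


@dataclass(frozen=True)
class Odor:
    """A unit-length non-negative projection onto the glomeruli.

    ``projection`` has unit Euclidean norm with non-targeted glomeruli
    exactly zero; ``magnitude`` is the scalar concentration factor applied
    before input to the receptor neurons.
    """

    projection: np.ndarray
    magnitude: float = 1.0
    label: str = "odor"

    def __post_init__(self) -> None:
        proj = np.asarray(self.projection, dtype=float)
        if np.any(proj < 0):
            raise ConfigurationError("odor loadings must be non-negative")
        norm = float(np.linalg.norm(proj))
        if norm > 0 and abs(norm - 1.0) > 1e-9:
            raise ConfigurationError("odor projection must have unit norm (or be zero)")
        if self.magnitude < 0:
            raise ConfigurationError("odor magnitude must be non-negative")
        object.__setattr__(self, "projection", proj)

    @property
    def n_glomeruli(self) -> int:
        return int(self.projection.size)

    @property
    def drive(self) -> np.ndarray:
        """Glomerular input vector, ``magnitude * projection``."""
        return self.magnitude * self.projection


@dataclass(frozen=True)
class StagePlan:
    """One trial stage: how many puffs, of which odor, with octopamine or not."""

    n_puffs: int
    odor_index: int = 0
    octopamine: bool = False
    label: str = ""


@dataclass(frozen=True)
class StimulusSchedule:
    """Time-stamped puff and octopamine windows for one simulation run.

    ``puff_windows`` is an ``(n_puffs, 2)`` array of (onset, offset) times,
    ``puff_odor`` the odor index per puff, and ``octopamine_windows`` an
    ``(k, 2)`` array of reward windows (octopamine covers exactly the
    training-stage puffs plus their trailing gap).  ``seed`` drives the
    simulation's noise stream, so identical (instance, schedule) pairs give
    bit-identical results.
    """

    duration: float
    puff_windows: np.ndarray
    puff_odor: np.ndarray
    octopamine_windows: np.ndarray
    odors: Tuple[Odor, ...]
    seed: int = 0
    stage_slices: Tuple[Tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        pw = np.asarray(self.puff_windows, dtype=float).reshape(-1, 2)
        ow = np.asarray(self.octopamine_windows, dtype=float).reshape(-1, 2)
        for win in (pw, ow):
            if win.size and np.any(win[:, 1] <= win[:, 0]):
                raise ConfigurationError("windows must have positive length")
        if pw.size:
            if np.any(np.diff(pw[:, 0]) <= 0) or np.any(pw[:-1, 1] > pw[1:, 0]):
                raise ConfigurationError("puff windows must be ordered and disjoint")
        object.__setattr__(self, "puff_windows", pw)
        object.__setattr__(self, "octopamine_windows", ow)
        object.__setattr__(
            self, "puff_odor", np.asarray(self.puff_odor, dtype=int).reshape(-1)
        )

    @property
    def n_puffs(self) -> int:
        return int(self.puff_windows.shape[0])

    def baseline_windows(self, margin: float = 0.1) -> np.ndarray:
        """Inter-puff windows used for the spontaneous rate, skipping a
        post-puff decay margin."""
        out = []
        pw = self.puff_windows
        for i in range(pw.shape[0]):
            start = pw[i, 1] + margin
            stop = pw[i + 1, 0] if i + 1 < pw.shape[0] else self.duration
            if stop - start > 1e-9:
                out.append((start, stop))
        return np.asarray(out, dtype=float).reshape(-1, 2)


def generate_odor(
    n_glomeruli: int,
    n_targets: int,
    seed: int = 0,
    magnitude: float = 1.0,
    label: str = "odor",
) -> Odor:
    """Generate a random broad odor projection.

    ``n_targets`` glomeruli are chosen uniformly; their loadings are drawn
    from the positive half of a standard Gaussian and the vector normalized
    to unit length.  Deterministic per seed.
    """
    if not 1 <= n_targets <= n_glomeruli:
        raise ConfigurationError("n_targets must lie in [1, n_glomeruli]")
    rng = np.random.default_rng(seed)
    targets = rng.choice(n_glomeruli, size=n_targets, replace=False)
    loadings = np.abs(rng.standard_normal(n_targets))
    loadings[loadings == 0] = 1.0  # measure-zero guard: keep support size exact
    proj = np.zeros(n_glomeruli)
    proj[targets] = loadings / np.linalg.norm(loadings)
    return Odor(projection=proj, magnitude=magnitude, label=label)


def noise_stimulus(
    n_glomeruli: int,
    seed: int = 0,
    magnitude: float = 1.0,
    label: str = "noise",
) -> Odor:
    """A fixed random non-negative unit vector over all glomeruli.

    Used as the structureless control in {odor + noise} vs. noise
    discrimination; held fixed within a trial so discrimination reflects
    stimulus identity (resampling per puff is a schedule-level choice).
    """
    rng = np.random.default_rng(seed)
    loadings = np.abs(rng.standard_normal(n_glomeruli))
    proj = loadings / np.linalg.norm(loadings)
    return Odor(projection=proj, magnitude=magnitude, label=label)


def _mix(odor: Odor, noise: Odor, label: str) -> Odor:
    """Superpose two stimuli; the mixture keeps unit direction with the
    combined magnitude."""
    vec = odor.drive + noise.drive
    mag = float(np.linalg.norm(vec))
    if mag == 0:
        return Odor(projection=np.zeros(odor.n_glomeruli), magnitude=0.0, label=label)
    return Odor(projection=vec / mag, magnitude=mag, label=label)


def make_discrimination_pair(
    mode: str,
    n_glomeruli: int = 60,
    n_targets: int = 25,
    noise_factor: float = 0.6,
    magnitude: float = 1.0,
    seed: int = 0,
) -> Tuple[Odor, Odor]:
    """Build the (trained, control) stimulus pair for discrimination trials.

    ``mode="two_odors"``: two independent broad odors with overlapping
    projections.  ``mode="odor_plus_noise"``: ({odor + noise}, noise), with
    the noise component's magnitude set to ``noise_factor`` (0.2-1.0) times
    the odor magnitude.
    """
    rng = np.random.default_rng(seed)
    s1, s2 = rng.integers(0, 2**31 - 1, size=2)
    if mode == "two_odors":
        return (
            generate_odor(n_glomeruli, n_targets, int(s1), magnitude, "trained"),
            generate_odor(n_glomeruli, n_targets, int(s2), magnitude, "control"),
        )
    if mode == "odor_plus_noise":
        odor = generate_odor(n_glomeruli, n_targets, int(s1), magnitude, "odor")
        noise = noise_stimulus(
            n_glomeruli, int(s2), magnitude * noise_factor, "noise"
        )
        return _mix(odor, noise, "odor+noise"), noise
    raise ConfigurationError(f"unknown discrimination mode: {mode!r}")


def build_schedule(
    stages: Sequence[StagePlan],
    odors: Sequence[Odor],
    template=None,
    seed: int = 0,
    puff_duration: Optional[float] = None,
    puff_gap: Optional[float] = None,
    lead_in: Optional[float] = None,
) -> StimulusSchedule:
    """Realize a stage plan as a concrete schedule.

    Timing defaults come from ``template`` when given (fields
    ``puff_duration``, ``puff_gap``, ``lead_in``), else the module defaults.
    Octopamine windows cover exactly the puffs of octopamine-flagged stages.
    An empty plan yields an empty schedule (baseline-only simulation).
    """
    pd = puff_duration if puff_duration is not None else getattr(
        template, "puff_duration", DEFAULT_PUFF_DURATION
    )
    pg = puff_gap if puff_gap is not None else getattr(
        template, "puff_gap", DEFAULT_PUFF_GAP
    )
    li = lead_in if lead_in is not None else getattr(
        template, "lead_in", DEFAULT_LEAD_IN
    )
    t = li
    puffs: List[Tuple[float, float]] = []
    puff_odor: List[int] = []
    octo: List[Tuple[float, float]] = []
    slices: List[Tuple[str, int, int]] = []
    for stage in stages:
        if stage.n_puffs < 0 or not 0 <= stage.odor_index < max(len(odors), 1):
            raise ConfigurationError("invalid stage plan")
        first = len(puffs)
        stage_start = t
        for _ in range(stage.n_puffs):
            puffs.append((t, t + pd))
            puff_odor.append(stage.odor_index)
            t += pd + pg
        if stage.octopamine and stage.n_puffs > 0:
            octo.append((stage_start, t))
        slices.append((stage.label, first, len(puffs)))
    return StimulusSchedule(
        duration=t,
        puff_windows=np.asarray(puffs, dtype=float).reshape(-1, 2),
        puff_odor=np.asarray(puff_odor, dtype=int),
        octopamine_windows=np.asarray(octo, dtype=float).reshape(-1, 2),
        odors=tuple(odors),
        seed=seed,
        stage_slices=tuple(slices),
    )
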
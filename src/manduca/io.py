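"""Configuration loading, result serialization, and reproducible manifests.

Experiment configurations are YAML (or JSON) with a strict schema: unknown
keys are rejected, template overrides are validated against the modeled
parameter ranges, and defaults are filled from :class:`MothTemplate`.
Results are written as tidy CSV plus a JSON :class:`RunManifest` that
records everything needed to re-run the experiment bit-exactly (experiment
name, full template, grid parameters, seed, package version).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .network import MothTemplate
from .protocols import (
    ExperimentResult,
    experiment_ablation_vs_fas,
    experiment_al_noise,
    experiment_learning_recovery,
    experiment_qn_ratio,
    summarize,
)
from .stimuli import Odor, StimulusSchedule

__all__ = [
    "EXPERIMENTS",
    "RunManifest",
    "load_config",
    "template_from_dict",
    "template_to_dict",
    "run_experiment",
    "write_results",
    "read_manifest",
    "rerun_from_manifest",
    "odor_to_dict",
    "odor_from_dict",
    "schedule_to_dict",
    "schedule_from_dict",
]

EXPERIMENTS = {
    "learning_recovery": experiment_learning_recovery,
    "qn_ratio": experiment_qn_ratio,
    "al_noise": experiment_al_noise,
    "ablation_vs_fas": experiment_ablation_vs_fas,
}

#: extra keyword arguments each experiment accepts in a config file
_EXPERIMENT_PARAMS = {
    "learning_recovery": {"levels", "sites", "mode"},
    "qn_ratio": {"levels", "qn_counts"},
    "al_noise": {"levels", "noise_factors"},
    "ablation_vs_fas": {"levels", "sites"},
}

_TEMPLATE_FIELDS = {f.name for f in dataclasses.fields(MothTemplate)}


def template_to_dict(template: MothTemplate) -> Dict:
    out = dataclasses.asdict(template)
    out["ssnr_acceptance"] = list(template.ssnr_acceptance)
    return out


def template_from_dict(data: Dict) -> MothTemplate:
    """Build a template from a (possibly partial) mapping, strictly validated.

    Unknown keys raise; values outside the modeled study ranges (QNs per
    glomerulus 0-7, AL noise factor 0-1.33) raise as well.
    """
    unknown = set(data) - _TEMPLATE_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown template keys: {sorted(unknown)}")
    data = dict(data)
    if "ssnr_acceptance" in data:
        data["ssnr_acceptance"] = tuple(data["ssnr_acceptance"])
    tpl = MothTemplate(**data)
    if not 0 <= tpl.n_qn_per_glom <= 7:
        raise ConfigurationError(
            f"n_qn_per_glom={tpl.n_qn_per_glom} outside the modeled range 0-7"
        )
    if tpl.al_noise_factor > 1.33 + 1e-9:
        raise ConfigurationError(
            f"al_noise_factor={tpl.al_noise_factor} outside the modeled range 0-1.33"
        )
    return tpl


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated experiment configuration with defaults filled."""

    experiment: str
    template: MothTemplate
    n_instances: int = 30
    seed: int = 0
    params: Dict = field(default_factory=dict)


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML/JSON experiment configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    experiment = raw.pop("experiment", None)
    if experiment not in EXPERIMENTS:
        raise ConfigurationError(
            f"experiment must be one of {sorted(EXPERIMENTS)}, got {experiment!r}"
        )
    template = template_from_dict(raw.pop("template", {}) or {})
    n_instances = int(raw.pop("n_instances", 30))
    if n_instances < 1:
        raise ConfigurationError("n_instances must be positive")
    seed = int(raw.pop("seed", 0))
    allowed = _EXPERIMENT_PARAMS[experiment]
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown config keys for {experiment}: {sorted(unknown)}"
        )
    return ExperimentConfig(
        experiment=experiment,
        template=template,
        n_instances=n_instances,
        seed=seed,
        params=dict(raw),
    )


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Dispatch a validated configuration to its experiment runner."""
    fn = EXPERIMENTS[config.experiment]
    params = dict(config.params)
    for key in ("levels", "sites", "qn_counts", "noise_factors"):
        if key in params:
            params[key] = tuple(params[key])
    return fn(
        config.template,
        n_instances=config.n_instances,
        seed=config.seed,
        **params,
    )


@dataclass
class RunManifest:
    """Everything needed to re-run an experiment bit-exactly."""

    experiment: str
    template: Dict
    n_instances: int
    seed: int
    params: Dict
    version: str
    rejections: Dict[str, int]
    files: Dict[str, str]

    def to_config(self) -> ExperimentConfig:
        return ExperimentConfig(
            experiment=self.experiment,
            template=template_from_dict(self.template),
            n_instances=self.n_instances,
            seed=self.seed,
            params=dict(self.params),
        )


def write_results(
    result: ExperimentResult,
    out_dir,
    config: Optional[ExperimentConfig] = None,
) -> RunManifest:
    """Write tidy metric tables, per-puff responses, summaries and a manifest.

    Existing files are overwritten (idempotent: re-running the same
    experiment into the same directory reproduces the same files).
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    metrics = result.to_frame()
    metrics.to_csv(out / "metrics.csv", index=False)
    summary = summarize(result)
    summary.to_csv(out / "summary.csv", index=False)

    rows = []
    for cond, recs in zip(result.conditions, result.records):
        for rec in recs:
            for key, rs in rec.responses.items():
                for i, peak in enumerate(rs.peaks):
                    rows.append(
                        {
                            **cond,
                            "instance_seed": rec.instance_seed,
                            "stage": key,
                            "puff_index": i,
                            "peak": peak,
                            "spontaneous": rs.spontaneous,
                        }
                    )
    pd.DataFrame(rows).to_csv(out / "responses.csv", index=False)

    rejection_log = {
        json.dumps(cond, sort_keys=True): rej
        for cond, rej in zip(result.conditions, result.rejections)
    }
    manifest = RunManifest(
        experiment=result.name,
        template=template_to_dict(
            config.template if config is not None else MothTemplate()
        ),
        n_instances=result.n_instances,
        seed=result.seed,
        params=dict(config.params) if config is not None else {},
        version=__version__,
        rejections=rejection_log,
        files={
            "metrics": "metrics.csv",
            "summary": "summary.csv",
            "responses": "responses.csv",
        },
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, sort_keys=True)
    return manifest


def read_manifest(out_dir) -> RunManifest:
    with open(Path(out_dir) / "manifest.json") as fh:
        return RunManifest(**json.load(fh))


def rerun_from_manifest(out_dir, target_dir=None) -> ExperimentResult:
    """Re-execute the experiment recorded in ``out_dir``'s manifest.

    When ``target_dir`` is given the regenerated tables are written there,
    allowing byte-level comparison against the originals.
    """
    manifest = read_manifest(out_dir)
    config = manifest.to_config()
    result = run_experiment(config)
    if target_dir is not None:
        write_results(result, target_dir, config)
    return result


# ---------------------------------------------------------------------------
# Stimulus fixtures (JSON, bit-exact round trip)
# ---------------------------------------------------------------------------


def odor_to_dict(odor: Odor) -> Dict:
    return {
        "projection": [float(x) for x in odor.projection],
        "magnitude": float(odor.magnitude),
        "label": odor.label,
    }


def odor_from_dict(data: Dict) -> Odor:
    return Odor(
        projection=np.asarray(data["projection"], dtype=float),
        magnitude=data["magnitude"],
        label=data.get("label", "odor"),
    )


def schedule_to_dict(schedule: StimulusSchedule) -> Dict:
    return {
        "duration": float(schedule.duration),
        "puff_windows": [[float(a), float(b)] for a, b in schedule.puff_windows],
        "puff_odor": [int(i) for i in schedule.puff_odor],
        "octopamine_windows": [
            [float(a), float(b)] for a, b in schedule.octopamine_windows
        ],
        "odors": [odor_to_dict(o) for o in schedule.odors],
        "seed": int(schedule.seed),
        "stage_slices": [list(s) for s in schedule.stage_slices],
    }


def schedule_from_dict(data: Dict) -> StimulusSchedule:
    return StimulusSchedule(
        duration=data["duration"],
        puff_windows=np.asarray(data["puff_windows"], dtype=float).reshape(-1, 2),
        puff_odor=np.asarray(data["puff_odor"], dtype=int),
        octopamine_windows=np.asarray(
            data["octopamine_windows"], dtype=float
        ).reshape(-1, 2),
        odors=tuple(odor_from_dict(o) for o in data["odors"]),
        seed=data["seed"],
        stage_slices=tuple(
            (str(a), int(b), int(c)) for a, b, c in data.get("stage_slices", [])
        ),
    )
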
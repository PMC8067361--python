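#!/usr/bin/env python
"""Is ablation a reliable proxy for FAS-like injury?

Runs paired FAS and ablation ensembles at both injury sites and extracts
the empirical FAS : ablation level ratio that produces equal EN loss.
Expected pattern: for the pooled receptor-neuron channel the ratio matches
the analytic large-population factor (~1.75); for the small PN+QN channel
ablation is relatively less harmful downstream than the theory predicts,
so the empirical ratio is smaller — ablation is an unreliable proxy there.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from manduca import MothTemplate, equal_loss_ratios
from manduca import io as mio
from manduca.plotting import plot_experiment
from manduca.protocols import _mean_loss_curve


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-instances", type=int, default=10)
    parser.add_argument("--n-kc", type=int, default=500)
    parser.add_argument("--levels", default="0,0.2,0.4,0.6")
    parser.add_argument("--seed", type=int, default=404)
    parser.add_argument("--out", type=Path, default=Path("results/05_ablation_vs_fas"))
    args = parser.parse_args()

    cfg = mio.ExperimentConfig(
        experiment="ablation_vs_fas",
        template=MothTemplate(n_kc=args.n_kc),
        n_instances=args.n_instances,
        seed=args.seed,
        params={"levels": [float(x) for x in args.levels.split(",")]},
    )
    result = mio.run_experiment(cfg)
    mio.write_results(result, args.out, cfg)
    plot_experiment(result, args.out)

    ratios = {}
    for site in ("rn_channel", "pn_qn_channel"):
        info = equal_loss_ratios(result, site)
        ratios[site] = info
        lv_f, loss_f = _mean_loss_curve(result, site, "fas")
        lv_a, loss_a = _mean_loss_curve(result, site, "ablation")
        print(f"{site}:")
        print(
            "  mean EN loss, FAS:      "
            + ", ".join(f"{lv:.0%}: {x:.2f}" for lv, x in zip(lv_f, loss_f))
        )
        print(
            "  mean EN loss, ablation: "
            + ", ".join(f"{lv:.0%}: {x:.2f}" for lv, x in zip(lv_a, loss_a))
        )
        print(
            f"  empirical equal-loss FAS:ablation ratio {info['mean_ratio']:.2f} "
            f"(analytic factor {info['analytic_factor']:.2f})"
        )
    with open(args.out / "equal_loss_ratios.json", "w") as fh:
        json.dump(ratios, fh, indent=2, default=float)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
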
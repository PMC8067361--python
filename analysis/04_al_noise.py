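#!/usr/bin/env python
"""Upstream noise as protection for the strongest readout responses.

Sweeps the antennal-lobe noise factor (0-1.33 of the natural level, 0 QNs)
while injuring the receptor-neuron channel with FAS.  Expected pattern:
higher AL noise preserves more of the top-scoring EN responses after a
given injury (noise pushes the strongest responses back over threshold),
the benefit is larger for the top 15% tranche than for average responses,
and the cost is lower naive SNR and SSNR.
"""

import argparse
from pathlib import Path

import numpy as np

from manduca import MothTemplate, snr, ssnr, summarize
from manduca import io as mio
from manduca.plotting import plot_experiment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-instances", type=int, default=10)
    parser.add_argument("--n-kc", type=int, default=500)
    parser.add_argument("--levels", default="0,0.2,0.4,0.6")
    parser.add_argument("--noise-factors", default="0,0.67,1.0,1.33")
    parser.add_argument("--seed", type=int, default=303)
    parser.add_argument("--out", type=Path, default=Path("results/04_al_noise"))
    args = parser.parse_args()

    cfg = mio.ExperimentConfig(
        experiment="al_noise",
        template=MothTemplate(n_kc=args.n_kc),
        n_instances=args.n_instances,
        seed=args.seed,
        params={
            "levels": [float(x) for x in args.levels.split(",")],
            "noise_factors": [float(x) for x in args.noise_factors.split(",")],
        },
    )
    result = mio.run_experiment(cfg)
    mio.write_results(result, args.out, cfg)
    plot_experiment(result, args.out)

    frame = summarize(result)
    for metric, label in (
        ("tranche_preservation", "top-15% tranche preservation"),
        ("normalized_mean", "average-response preservation"),
    ):
        sel = frame[(frame["metric"] == metric) & (frame["stage"] == "post_injury")]
        print(f"{label} (post-injury):")
        for nf, sub in sel.groupby("al_noise_factor"):
            sub = sub.sort_values("level")
            curve = ", ".join(
                f"{lv:.0%}: {m:.2f}" for lv, m in zip(sub["level"], sub["mean"])
            )
            print(f"  noise {nf:g}: {curve}")
    print("naive signal-quality cost of noise:")
    for cond, recs in zip(result.conditions, result.records):
        if cond["level"] != 0.0:
            continue
        snrs = [snr(r.responses["naive"]) for r in recs]
        ssnrs = [ssnr(r.responses["naive"]) for r in recs]
        print(
            f"  noise {cond['al_noise_factor']:g}: "
            f"median SNR {np.median(snrs):.1f}, median SSNR {np.median(ssnrs):.1f}"
        )
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
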
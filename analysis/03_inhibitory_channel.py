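#!/usr/bin/env python
"""Parallel inhibitory channels as an injury-mitigation mechanism.

Sweeps the QN : PN ratio (0-7 inhibitory projection neurons per glomerulus
against the fixed 5 excitatory ones) while injuring the AL->MB channel.
Expected pattern: more QNs mean smaller normalized EN losses at a given FAS
level ("canceling out": injured QNs push the summed MB input up, offsetting
injured PNs), at the cost of a lower signal-to-spontaneous-noise ratio.
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
    parser.add_argument("--qn-counts", default="0,2,4,7")
    parser.add_argument("--seed", type=int, default=202)
    parser.add_argument("--out", type=Path, default=Path("results/03_inhibitory_channel"))
    args = parser.parse_args()

    cfg = mio.ExperimentConfig(
        experiment="qn_ratio",
        template=MothTemplate(n_kc=args.n_kc),
        n_instances=args.n_instances,
        seed=args.seed,
        params={
            "levels": [float(x) for x in args.levels.split(",")],
            "qn_counts": [int(x) for x in args.qn_counts.split(",")],
        },
    )
    result = mio.run_experiment(cfg)
    mio.write_results(result, args.out, cfg)
    plot_experiment(result, args.out)

    frame = summarize(result)
    sel = frame[(frame["metric"] == "normalized_mean") & (frame["stage"] == "post_injury")]
    print("normalized post-injury EN response by QN count:")
    for qn, sub in sel.groupby("qn_per_glom"):
        sub = sub.sort_values("level")
        curve = ", ".join(f"{lv:.0%}: {m:.2f}" for lv, m in zip(sub["level"], sub["mean"]))
        print(f"  QN={qn}: {curve}")
    print("naive SSNR medians (signal clarity cost of inhibition):")
    for cond, recs in zip(result.conditions, result.records):
        if cond["level"] != 0.0:
            continue
        vals = [ssnr(r.responses["naive"]) for r in recs]
        print(f"  QN={cond['qn_per_glom']}: {np.median(vals):.2f}")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
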
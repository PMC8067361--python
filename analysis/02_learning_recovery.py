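#!/usr/bin/env python
"""Hebbian learning as an injury-compensation mechanism.

Sweeps FAS injury over both sites (receptor-neuron channel and PN+QN
channel), with post-injury octopamine training, and reports how far
training restores the normalized EN odor response.  Expected pattern:
responses fall monotonically with injury level, the PN+QN site is hit
harder than the pooled RN site, and training restores responses fully at
low injury levels (the restored level is capped by the synaptic saturation
factor).
"""

import argparse
from pathlib import Path

from manduca import MothTemplate, experiment_learning_recovery, summarize
from manduca import io as mio
from manduca.plotting import plot_experiment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-instances", type=int, default=10)
    parser.add_argument("--n-kc", type=int, default=500)
    parser.add_argument("--levels", default="0,0.2,0.4,0.6")
    parser.add_argument("--seed", type=int, default=101)
    parser.add_argument("--out", type=Path, default=Path("results/02_learning_recovery"))
    args = parser.parse_args()

    levels = tuple(float(x) for x in args.levels.split(","))
    cfg = mio.ExperimentConfig(
        experiment="learning_recovery",
        template=MothTemplate(n_kc=args.n_kc),
        n_instances=args.n_instances,
        seed=args.seed,
        params={"levels": list(levels)},
    )
    result = mio.run_experiment(cfg)
    mio.write_results(result, args.out, cfg)
    plot_experiment(result, args.out)

    frame = summarize(result)
    sel = frame[frame["metric"] == "normalized_mean"]
    for stage in ("post_injury", "post_training"):
        print(f"normalized EN response, {stage}:")
        for site in ("rn_channel", "pn_qn_channel"):
            sub = sel[(sel["stage"] == stage) & (sel["site"] == site)].sort_values("level")
            curve = ", ".join(
                f"{lv:.0%}: {m:.2f}" for lv, m in zip(sub["level"], sub["mean"])
            )
            print(f"  {site:>14}: {curve}")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
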
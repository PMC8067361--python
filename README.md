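# manduca

Injury-mitigation simulations of the *Manduca sexta* (hawkmoth) olfactory
network: a firing-rate model of the cascade from antennal receptor neurons
(RNs) through the antennal lobe (AL) and mushroom body (MB) to a readout
extrinsic neuron (EN), together with a focal-axonal-swelling (FAS) injury
model, octopamine-gated Hebbian plasticity, and ensemble experiment runners.

The package is for computational neuroscientists who want to ask how a
cascaded sensory network keeps its *outputs* useful when its upstream
neurons are damaged. It simulates four mechanisms/questions:

1. **Learning as repair** — reward-triggered octopamine boosts AL firing
   rates and gates Hebbian growth (`Δw ∝ f_pre · f_post`, capped at
   1.5× the initial weight) on the AL→MB and MB→EN synapses; after injury,
   a few rewarded odor exposures restore the EN response.
2. **Parallel inhibition** — inhibitory projection neurons (QNs) running
   alongside the excitatory PNs cancel part of the injury: damaged QNs
   push the summed MB input up while damaged PNs push it down.
3. **Upstream noise** — a broad noise envelope lets the strongest EN
   responses keep crossing downstream thresholds after injury, at the cost
   of signal-to-noise ratio.
4. **Ablation vs FAS** — FAS leaves most injured neurons with reduced but
   non-zero rates (filters ×1, ×0.5, ×0, ×0.7–0.9 in proportions
   0.15/0.35/0.35/0.15, expected retained rate 0.43), so on a large pooled
   population ablating *n*% of neurons equals FAS injury to ≈1.75 *n*%;
   the experiments test where that equivalence breaks.

Readout statistics: per-puff peak EN responses `F` with spontaneous rate
`Sp`, Fisher discriminant `(μ_t − μ_c) / (0.5(σ_t + σ_c))`,
`SNR = μ(F)/σ(F)`, `SSNR = μ(F)/Sp`, and top-end preservation
`P = (μ_j + σ_j)/(μ_h + σ_h)`.

See `docs/methods.md` for the model equations, parameter calibration, and
limitations.

## Worked example

Run one staged trial — naive baseline, 40% FAS to the receptor-neuron
channel, five octopamine training puffs, post-training assessment — on a
full-size instance (2000 Kenyon cells):

```sh
python analysis/01_single_trial_timecourse.py --seed 1 --level 0.4
```

prints

```
rn_channel FAS 40%, seed 1:
           naive: mean peak 0.908 (normalized 1.000), Sp 0.0626
     post_injury: mean peak 0.713 (normalized 0.785), Sp 0.0591
   post_training: mean peak 1.074 (normalized 1.183), Sp 0.0886
```

The healthy odor response sits near 1 (the calibrated unit); 40% FAS
attenuates it to 0.79× naive; five rewarded puffs re-grow the plastic
synapses and lift the response to 1.18× naive — injury fully compensated,
with the overshoot bounded by the ×1.5 synaptic cap. The figure written to
`results/01_timecourse/` shows the corresponding EN trace, including the
very strong responses during the octopamine window.

The ensemble analyses (each ~2–5 min at the reduced default scale of 10
instances per condition, 500 KCs) reproduce the four study patterns:

```sh
python analysis/02_learning_recovery.py    # injury/recovery curves per site
python analysis/03_inhibitory_channel.py   # QN-count protection + SSNR cost
python analysis/04_al_noise.py             # noise protection of top responses
python analysis/05_ablation_vs_fas.py      # equal-loss level ratios per site
```

Representative output (seeds as shipped): normalized post-injury response
at 40% FAS rises from 0.69 (no QNs) to 0.89 (7 QNs per glomerulus) while
the naive SSNR median falls from 10.9 to 3.4; and the empirical equal-loss
FAS:ablation ratio is 1.68 at the pooled RN channel (analytic factor 1.75)
but only 1.33 at the PN+QN channel — ablation is an unreliable proxy for
FAS-like injury where neurons are few and specialized.

The same experiments are available as a CLI
(`manduca run-experiment {learning_recovery,qn_ratio,al_noise,ablation_vs_fas}
--out DIR ...`), which writes tidy CSV tables, a JSON run manifest that
reproduces the run bit-exactly, and the figures.

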
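# Methods

`manduca` simulates how three motifs of the *Manduca sexta* olfactory
network — octopamine-gated Hebbian plasticity, a broad upstream noise
envelope, and parallel inhibitory feed-forward channels — mitigate the
downstream effects of neural injury. This note documents the model, its
parameters and calibration, the injury filters, the trial protocol, the
synthetic stimuli, and the numerical and design choices, including what the
simulations do and do not establish.

## Network model

The olfactory cascade is modeled at the firing-rate level with four stages:

**Receptor neurons (RNs).** Each model RN pools ~500 biological receptors
converging on one antennal-lobe glomerulus (60 glomeruli by default). Its
rate is instantaneous: `r_g = rectify(gain * (odor_g + spont) * a_g + xi)`,
where `odor_g` is the glomerular component of the odor drive, `spont` a
small odorless baseline (0.12), `a_g` the injury attenuation (1 when
healthy) and `xi` Gaussian input noise.

**Antennal lobe (AL).** The AL acts as a pre-amplifier. Glomerular drive
first receives fixed, low-gain, all-to-all subtractive lateral inhibition
(`d_g = rectify(r_g - 0.1 * mean(r))`) and divisive gain control
(`d_g /= 1 + g * mean(r)`, `g = 10`), so a uniform loss of receptor input
is partially renormalized before it reaches the mushroom body. Each
glomerulus houses 5 excitatory projection neurons (PNs) and 0–7 inhibitory
projection neurons (QNs); each projects from exactly one glomerulus. Their
rates follow leaky rectified-linear dynamics integrated with explicit Euler
steps,

```
tau * da = (-a + rectify(octopamine_gain(t) * w_rn * d_g)) * dt
           + sigma_AL * sqrt(dt) * N(0, 1),     a clipped at 0,
```

with `tau = 20 ms` and `dt = 4 ms` (50 steps per 0.2 s odor puff).
Octopamine multiplies the AL input drive by 2.5 during reward windows;
intra-AL connections are not plastic.

**Mushroom body (MB).** Kenyon cells (KCs; 2000 by default, 500 in the
reduced test configuration) are instantaneous. Each KC receives the signed
summed input `u = w+ . p - w- . q` from a random sample of PNs (fan-in 4)
and QNs; both weight families are stored as non-negative magnitudes with
the sign applied in the sum. QN→KC edges are 3x denser than PN→KC edges
with per-edge strength divided by 3, so the mean inhibitory load per KC
matches the excitatory sampling statistics while QN-induced input variance
stays small. Global inhibition sets the KC rates: `kc = rectify(u - theta)`
with

```
theta(t) = 0.5 * theta_cal + 0.5 * quantile(u(t), 1 - mb_sparsity).
```

The per-step quantile term keeps the fraction of active KCs near
`mb_sparsity = 0.10`; the fixed component `theta_cal` is calibrated once
per instance (the KC-input quantile under a noise-free reference odor at
generation time) and is *not* recalibrated after injury or training. The
fixed component is essential: a purely adaptive quantile makes the readout
invariant to mean shifts of the KC input, which removes exactly the
threshold effects the study measures — injured inputs falling below
threshold, noise pushing the strongest responses back over it, and the
inhibitory canceling-out effect. The 50/50 blend was chosen because a pure
fixed threshold over-amplifies losses (a 23% uniform drive loss then wipes
out nearly the whole response), while the blend reproduces the moderate,
monotone loss curves the readout statistics need. Octopamine does not act
on KCs.

**Readout (EN).** A single extrinsic neuron reads the MB:
`en = rectify(w_en . kc)`, instantaneous. The MB→EN weight mean is
parametrized as `w_kc_en_scale / (mb_sparsity * n_kc)` so the calibration
survives changes of the KC count. Units are arbitrary but calibrated so a
healthy instance's peak odor response is ~1 and its odorless response ~0.

## Plasticity

Only AL→MB (PN→KC, QN→KC) and MB→EN connections are plastic, and only
while an octopamine window is open. Each step applies the Hebbian rule
`w <- min(c * w_init, w + eta_layer * f_pre * f_post)` per existing
connection; the cap `c = 1.5` is absorbing and anchored to each
connection's initial weight (per-connection rather than per-neuron-total —
the simplest reading). QN→KC updates grow the inhibitory magnitude.
`eta_layer = hebbian_rate * dt * w_mean_layer` makes the relative growth
rate comparable across layers; `hebbian_rate = 1.4` is calibrated so five
0.2 s training puffs under octopamine bring the MB→EN weights close to the
cap, boosting a healthy EN response to ~1.5x naive. AL→MB growth runs ~140x
slower (`al_mb_rate_ratio = 0.007`): because the readout sits above a
subtractive threshold, input-side weight growth is amplified superlinearly
at the EN, and faster input-side learning drives the post-training response
far beyond the saturation bound the cap is meant to impose.

With the gate closed (no octopamine) or `hebbian_rate = 0`, a training pass
returns the instance unchanged — learning fails without octopamine, by
construction.

## Injury model

Focal axonal swellings (FAS) degrade spike propagation; at the firing-rate
level each injured neuron gets one of four filters: transmit (x1), reflect
(x0.5), ablate (x0), or low-pass (x0.7–0.9, with high rates hit harder).
Damage types are allocated in the fixed proportions
(0.15, 0.35, 0.35, 0.15) by largest-remainder rounding, so the stated
proportions hold exactly at any injury level, and placed randomly among the
neurons selected for injury (exactly `round(level * n)` of them, uniformly
at random). The low-pass factor interpolates linearly from 0.9 at a
neuron's 5th-percentile healthy rate to 0.7 at its 95th percentile
(clamped; a degenerate range collapses to 0.7, the nominal value used in
the analytic correspondence). For the PN+QN site the reference percentiles
come from a short noise-free probe puff on the healthy instance.

**PN+QN channel.** PNs and QNs are modeled one-to-one, so they are pooled
into a single selection population and each injured neuron's output is
passed through its own filter (or zeroed, under ablation) at every step.

**RN channel.** Each model RN stands for ~500 receptors, so injury is
applied as a pooled average: FAS level `m` is converted to the
ablation-equivalent level `n = m / 1.75`, every RN drive is multiplied by
`(1 - n)`, and the RN noise parameter by `1 / (1 - n)` (fewer pooled inputs
average away less noise; the `1/sqrt(1-n)` alternative implied by
independent-averaging arguments is available as `rn_noise_rule =
"inverse_sqrt"`). The low-pass share of the damage is applied as a
rate-dependent deviation around the nominal attenuation, so the realized
attenuation fluctuates slightly with odor input. Ablation at level `n`
uses the same pooled formulas directly.

**Analytic correspondence.** An injured neuron retains on average
`0.15*1 + 0.35*0.5 + 0.35*0 + 0.15*0.7 = 0.43` of its rate, so on a large
pooled population FAS at level `m` removes the same summed rate as ablating
`m * 0.57` of the neurons; the equal-loss ratio is `1/0.57 ~ 1.754`,
quoted and applied at its nominal 2-decimal rounding 1.75 (which is also
the only rounding under which the worked conversion 20% ablation <-> 35%
FAS holds exactly). `ndigits=None` exposes the unrounded ratio.

## Trial protocol and experiments

A trial draws a fresh instance from the template and runs: (optional
pre-training for discrimination trials: 3 puffs with octopamine), naive
assessment (15 puffs, no octopamine), injury, post-injury assessment (15
puffs), training (5 puffs with octopamine and plasticity), post-training
assessment (15 puffs). Puffs last 0.2 s with 0.3 s gaps and a 0.5 s
settling lead-in per stage. The response set `F` holds the peak EN rate in
each puff window (+50 ms margin); the spontaneous rate `Sp` is the mean EN
rate over inter-puff baselines (skipping a 100 ms decay margin). All
reported responses are normalized by the trial's own naive mean.

The post-injury and post-training assessments share one noise seed (common
random numbers), which makes the no-octopamine training control an exact,
not statistical, identity and reduces paired variance; the naive assessment
uses its own stream, so the 0%-injury normalized response scatters slightly
around 1.

Instances whose naive SSNR falls below the acceptance envelope (minimum
2.5, no maximum by default) are discarded and replaced until each condition
has its quota; templates with many QNs or very high AL noise reject more.
The envelope's printed source is ambiguous about direction and value, so it
is a named configuration value; the default minimum sits below the baseline
template's observed naive SSNR (~9–12) and above the failure tail of the
extreme templates (~2–3).

Four ensemble experiments sweep condition grids (30 instances per condition
by default; the shipped analyses and acceptance tests use 10 instances, the
level grid {0, 0.2, 0.4, 0.6}, and 500 KCs so a full run stays within a few
minutes on one CPU): learning recovery (both sites x FAS levels), QN ratio
({0,2,4,5,7} QNs per glomerulus, PN+QN-site FAS), AL noise (factors 0–1.33,
RN-site FAS), and ablation vs FAS (paired kinds at both sites, no training
stage). The equal-loss ratio analysis fits a monotone (PCHIP) curve to the
mean FAS loss-vs-level points and inverts it at each ablation level whose
loss lies inside the fitted range.

## Synthetic stimuli

Odors are non-negative unit vectors over glomeruli with exactly
`n_targets = 25` of 60 glomeruli loaded (loadings drawn from the positive
half of a Gaussian, then normalized — the source is silent on the
distribution), scaled by a magnitude scalar (default 1). The noise
stimulus for {odor+noise} discrimination is a fixed random non-negative
unit vector over all glomeruli, held constant within a trial so
discrimination reflects stimulus identity. All generators are
deterministic per seed and serialize to JSON bit-exactly.

## What the synthetic conditions do and do not show

The generator emulates the study conditions: broad random odors, puff
trains with reward windows, Gaussian upstream noise at 0–1.33x a natural
level, and the stated injury mixtures. It does not emulate real moth data:
odor concentration dynamics, plume structure, narrowly-tuned odors,
receptor adaptation, multiple readouts, or neurogenesis. Passing tests
therefore establish that the implemented mechanisms produce the expected
qualitative orderings under the modeled conditions — not quantitative
agreement with in-vivo firing rates, and not robustness of the orderings
outside the calibrated parameter regime.

## Calibration and numerical choices

The source network's calibrated constants are not binding here; dynamics
and constants are this package's own. Free parameters were calibrated
once, jointly, against the qualitative contract the readout statistics
must support: healthy peak ~1; naive SNR O(10) and SSNR ~10 at natural
noise; moderate, monotone loss curves at both sites with the PN+QN site at
least as damaged as the RN site; a training boost of 1.4–1.6x bounded by
the synaptic cap; and noise/QN protection orderings with usable margins.
The load-bearing results of that calibration are: KC fan-in 4 (small
fan-in gives per-KC input variance large enough that heterogeneous damage
is partially rescued by the competitive threshold — the effect behind the
ablation/FAS discrepancy at the PN site), the 0.5 inhibition-floor blend,
AL gain control 10, RN/AL noise scales 0.08/0.16 (most upstream noise is
AL-state noise, so the RN-injury noise inflation `1/(1-n)` stays a
perturbation rather than dominating high-level ablation), and
`hebbian_rate 1.4` with `al_mb_rate_ratio 0.007`.

Other numerics: sample standard deviation (n-1) everywhere; both
top-tranche definitions (responses above `mu + sigma`, and the top-15%
rank cut) are implemented, with the rank rule used by the experiment
runners; `SNR` and `SSNR` return an infinity sentinel for degenerate
denominators (zero-noise configurations) rather than raising; quantile
tie-breaks use stable neuron-index order; Euler integration requires
`dt <= tau`; non-finite rates abort the simulation with an explicit error.
Timecourse dumps are CSV only.

## Known limitations

- Loss curves are steeper than linear in the retained drive because of the
  threshold readout; absolute loss percentages are not calibrated to the
  source figures, only the orderings and the analytic conversions are.
- With zero upstream noise, repeated puffs are identical up to the initial
  Euler transient (~1e-12 relative), so SNR at noise 0 is effectively
  infinite rather than exactly so.
- Discrimination trials: the intrinsic EN-response asymmetry between two
  random broad odors spans several sigma-units of the Fisher discriminant,
  while the 3-puff pre-training budget shifts it by about +1, so absolute
  pre-trained discriminants rarely reach the nominal target band;
  discrimination effects are therefore reported and tested as within-trial
  shifts.
- The inhibition floor is calibrated against a reference odor, not the
  trial odor, so healthy-odor KC sparsity scatters around (not exactly at)
  `mb_sparsity`.
- A training stage longer than the default five puffs continues to grow
  the slow AL→MB weights toward their own cap and can push the
  post-training boost past the nominal ~1.5x readout bound.
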
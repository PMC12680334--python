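# Methods

## Model and integration

The package implements the two-variable adaptive exponential
integrate-and-fire (AdEx) neuron: a leaky membrane with an exponential
spike-initiation term and a linear adaptation current,

```
C dV/dt = -g_L (V - E_L) + g_L Δ_T exp((V - V_th)/Δ_T) + I(t) - w
τ_w dw/dt = a (V - E_L) - w,
```

with discrete reset `V → V_reset`, `w → w + b` when `V` reaches `V_peak`,
followed by a refractory clamp of both variables for `t_ref`.  Units are
fixed package-wide as mV, ms, pA, nS and pF, so every term of the voltage
equation is a current in pA and no conversion factors appear.

Integration is explicit forward Euler with a default step of `dt = 0.01 ms`.
The scheme is deliberate: the trajectories are smooth except at resets, the
reset itself is an event rule rather than part of the vector field, and the
cost per step is what makes 4096-candidate parameter sweeps affordable.
Details that needed a decision:

- **Exponent guard.**  The argument of the exponential is clamped at +30.
  Any voltage that would exceed the clamp is far above `V_peak`; the guard
  prevents floating-point overflow without affecting spike timing.
- **Initial adaptation.**  `w(0)` defaults to the subthreshold steady state
  `a (V(0) - E_L)`, matching a neuron held at a steady baseline before the
  step; `w0=0` is available as an option.
- **Order at the reset.**  The Euler update of `w` is applied first and `b`
  is added to the updated value.
- **Recorded sample at a spike.**  The sample at the spike step stores
  `V_peak` (so recorded voltages never exceed the peak and threshold
  crossings are guaranteed for downstream spike detection); the integration
  state restarts from `V_reset`.  The following `t_ref/dt` samples hold
  `V_reset` and the post-increment `w` — the adaptation variable does not
  integrate during the clamp.
- **Failure signalling.**  If the state becomes non-finite (possible for
  extreme parameter combinations, e.g. `dt ≫ τ_w` with strong coupling), an
  integration-failure error reports the time of the first bad sample.
  During fitting such candidates receive infinite error so they can never
  enter an ensemble.

**Accuracy.**  With `a = 0` and voltages well below threshold the integrator
tracks the closed-form RC response within 0.1 mV at `dt = 0.01 ms` (checked
at every sample over 600 ms).  Spike timing converges at first order: the
time of the first spike and every interspike interval move by well under
0.5 ms when the step is refined from 0.01 to 0.001 ms.  Absolute spike
times along a long train accumulate phase drift linearly in `dt` — about
0.6 ms by the 24th spike of the strong tonic fixture between `dt = 0.01`
and `0.005 ms` — which is inherent to a first-order method; the test suite
therefore bounds the non-accumulating quantities and separately checks that
the accumulated drift decays when the step is halved.

## Feature extraction

A spike is detected where the trace crosses a user-supplied detection
threshold from below: `v[i] > θ` and `v[i-1] < θ`, both strict, so samples
exactly at threshold never start a spike.  The spike time is the time of the
first supra-threshold sample; no sub-sample interpolation is attempted
(digitised traces do not support it).  Features and presence rules:

- `freq` — spike count / stimulus duration (spikes/s); always present, zero
  without spikes.  The full stimulus window is used even for adapting cells,
  for consistency between data and model.
- `time_to_first/second/third_spike` — from stimulus onset (ms), present
  with ≥1/≥2/≥3 spikes; `time_to_last_spike` only with >3 spikes (with
  exactly three it would duplicate the third).
- `inv_first_ISI`, `inv_last_ISI` — inverse first/last interspike interval,
  converted to 1/s so they share units with `freq`; present with ≥2 / ≥3
  spikes.
- `volt_stimend` — voltage of the sample at or before `stim_end`, included
  on request for strongly adapting traces.

The leak reversal can be derived from a holding point: with no holding
current `E_L` is the holding voltage; otherwise the linear subthreshold
steady state gives `E_L = v_hold - i_hold/(g_L + a)`.

## Fitting

Candidates are drawn from one joint 11-dimensional Sobol sequence
(unscrambled by default, hence bit-reproducible; Owen scrambling available
via a seed).  Sample counts must be powers of two — the sequence is only
balanced at those sizes.  Bounds are closed intervals per parameter with
`lo == hi` pinning a value; `V_peak` and the initial voltage are pinned from
the traces.  The bounds box is validated to lie inside the admissible AdEx
region so every sampled point is a valid model.

Each candidate is simulated under every protocol of the condition and scored
with

```
error = Σ_protocols Σ_j  w_j · |data_j - model_j| / |data_j|
```

over the features the data define.  A feature the model fails to produce
contributes `w_j · 3` (the penalty default; configurable).  Data features
with magnitude below 1e-9 fall back to the absolute difference, since the
relative error is undefined at zero.  All weights default to 1; a heavier
`volt_stimend` weight (e.g. 3) is useful for strongly adapting traces.  The
`n_keep = 16` lowest-error candidates, ties broken by candidate index, form
the condition ensemble.

A consequence of unscrambled Sobol worth knowing: the second sample point is
the centre of the unit cube, so when bounds are centred on a known ground
truth the exact generator is in the candidate pool and recovery fits report
zero error for it.  Recovery quality for off-centre truths is governed by
the 20%-per-feature check in the acceptance suite.

## Phase plane and excitability landscape

Fixed points solve `g_L Δ_T exp((V - V_th)/Δ_T) - (g_L + a)(V - E_L) + I = 0`
over `[E_L - 60 mV, V_peak]`, located by sign-change bracketing on a 0.01 mV
grid and bisection to 1e-10 mV; the search domain width is a package choice
wide enough for any physiological rest.  Stability comes from the analytic
2×2 Jacobian with closed-form eigenvalues; labels are stable/unstable
node/focus, saddle (negative determinant), or nonhyperbolic when a real part
is within 1e-9 /ms of zero.

The local bifurcation that ends the resting state is decided by
`R_a = a/g_L` against `R_τ = τ_m/τ_w = C/(g_L τ_w)`: `a·τ_w > C` gives a
subcritical Hopf onset (Class II), `a·τ_w < C` a saddle-node on invariant
circle (Class I), equality the Bogdanov–Takens point.  Exact equality being
measure-zero in floating point, a relative band of 1e-6 is labelled "BT".
An independent numerical cross-check (`sweep_excitability_class`) sweeps the
current up to the saddle-node value — located by bisection on the existence
of a resting point — and watches the finite-difference-Jacobian eigenvalues
of the lowest fixed point; the sweep grid is densified geometrically toward
the fold because the Hopf destabilisation can occur arbitrarily close to it.
On 200 random parameter sets outside a 10% band around `a·τ_w = C` the
algebraic rule and the sweep agree on ≥ 98% (the acceptance suite measures
this each run).

Ensemble displacement in the landscape is summarised by centroids
(coordinate means); a shift is a *switch* exactly when the two centroid
classes differ, otherwise a *scale*.  A centroid inside the BT band lies on
the boundary and is reported as not having crossed it.  Per-model class
mixtures are available but do not change the label.

## Ensemble statistics

Parameters mix units (pF, nS, mV, ms), so PCA operates on per-parameter
z-scores over the pooled comparison set; zero-variance parameters (pinned
values) are dropped and listed rather than imputed.  Components follow a
sign convention (largest-|loading| entry positive) and report their three
largest-|loading| contributors, ties broken lexicographically.  Cluster
separation uses the silhouette score — per point `(b - a)/max(a, b)` — on
the 2-component projections, Euclidean metric, via scikit-learn; the
choice of PCA space (rather than full parameter space) matches what the
landscape plots show and is switchable by passing any point set.

## Cross-species transfer

Modulation ratios are computed on ensemble means.  The absolute strategy
`|mod/control|` preserves the magnitude of the relative change; the signed
strategy `1 - |mod/control|` preserves its direction and is selected
automatically per parameter when source and target control means disagree in
sign (in practice the subthreshold adaptation `a`, which legitimately takes
either sign).  Both estimates can be emitted side by side, and a convex
interpolation weight λ∈[0,1] covers intermediate scalings.  Ratios are
undefined for near-zero control means (|mean| ≤ 1e-9) and raise rather than
guess.  A transferred parameter set is sanity-gated by simulating it under
the target's protocols and producing its f–I curve for comparison with the
target control.

## Synthetic regimes

Four reference regimes exercise the pipeline: **tonic** (weak adaptation,
first/last inverse ISI within 20%), **adapting** (strong `b`, slow `τ_w`;
firing slows by >1.5×), **initial-burst** (`V_reset` above `V_th`, so spikes
reignite at onset until adaptation accumulates), and **delayed** (slow
membrane firing just above rheobase, first-spike latency >50 ms).  Each
regime ships three steps at 0.8×, 1.05× and 1.6× its closed-form rheobase
`(g_L+a)(V_th - E_L + Δ_T ln((g_L+a)/g_L) - Δ_T)`; the sub-rheobase step is
additionally capped by the transient (`a = 0`) rheobase so slowly adapting
regimes stay silent below threshold.  Steps run 100–600 ms of a 700 ms
record from the leak reversal, with a fixed detection threshold of -20 mV
(above every reset, below every peak).

Trace noise is additive, zero-mean Gaussian on the voltage samples only —
observation noise emulating digitisation error, not process noise.  What the
synthetic tests therefore do **not** show: robustness to channel noise or
trial-to-trial variability in the dynamics, to non-uniform sampling or
monotonic-time violations from plot digitisation, to unknown holding
currents, or to liquid-junction-potential offsets in real recordings.  They
do establish that the estimator recovers known generators under the stated
noise, and that the landscape/ensemble statistics separate genuinely
different regimes while not separating re-fits of the same one.

## Problem sizes and runtime choices

The default analyses use 4096 Sobol candidates × 3 protocols per condition
(~12k simulations of 70k Euler steps each, a handful of seconds with the
compiled kernel per thousand candidates), 200 parameter sets for the
classifier cross-check, and ensembles of 16.  These sizes reproduce the
stated checks comfortably on a single CPU; they scale linearly for users
with more traces or wider bounds.

## Known limitations

- Forward Euler is first-order: absolute spike times accumulate phase drift
  along long trains (see Accuracy above); halve `dt` for timing-critical
  work.
- The excitability classification is local (resting-state bifurcation); no
  limit-cycle continuation is attempted, so phenomena such as bistability
  windows are out of scope.
- `fit_condition` is exhaustive sampling, not optimisation; very wide bounds
  in 11 dimensions need correspondingly larger sample counts.
- The transfer machinery asserts nothing about biological validity; it
  propagates ensemble means only, with source sds reported for context.
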
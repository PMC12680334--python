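# adexscape

Tools for asking how a neuromodulator (acetylcholine, dopamine,
norepinephrine, serotonin, histamine, ...) reshapes the excitability of a
neuron, using the adaptive exponential integrate-and-fire (AdEx) model as a
common language.  Electrophysiologists usually have a handful of voltage
traces per cell and condition; `adexscape` turns each condition into an
*ensemble* of AdEx parameter sets that reproduce the traces' spike-train
features, then interprets the control → modulated change through parameter
statistics, phase-plane geometry and a two-ratio "excitability landscape".

## The model

The AdEx neuron couples membrane voltage `V` (mV) and adaptation current `w`
(pA):

```
C dV/dt = -g_L (V - E_L) + g_L Δ_T exp((V - V_th)/Δ_T) + I(t) - w
τ_w dw/dt = a (V - E_L) - w
```

When `V` reaches `V_peak`: a spike is recorded, `V → V_reset`, `w → w + b`,
and both are clamped for a refractory period `t_ref`.  Eleven parameters
(`C, g_L, E_L, Δ_T, V_th, a, b, τ_w, V_reset, V_peak, t_ref`) define a model;
units are fixed package-wide as mV / ms / pA / nS / pF.

The workflow:

1. **simulate** — forward Euler at `dt = 0.01 ms` with spike reset and
   refractory clamp (`adexscape.model`);
2. **extract features** — firing frequency, times to first/second/third/last
   spike, inverse first/last interspike interval, optional end-of-stimulus
   voltage (`adexscape.features`);
3. **fit** — a base-2 Sobol sweep of parameter space scored by a weighted
   sum of relative feature errors (missing features cost a fixed +3
   penalty); the best 16 models form the condition ensemble
   (`adexscape.fitting`);
4. **interpret** — per-parameter means/sds, PCA with silhouette separation
   (`adexscape.ensembles`), fixed points and stability from nullcline
   intersections, Class I/II excitability from the ratios `R_a = a/g_L` vs
   `R_τ = τ_m/τ_w` (boundary `a·τ_w = C`, the Bogdanov–Takens line), f–I
   curves, and "switch vs scale" centroid shifts (`adexscape.dynamics`);
5. **transfer** — map a modulator's per-parameter ratios measured in one
   species onto another species' control means (`adexscape.transfer`).

A `synthetic` module generates ground-truth regimes (tonic, adapting,
initial-burst, delayed) and noisy traces so the whole pipeline is testable
without external recordings.

## Worked example

```python
from adexscape import (FitConfig, FitTarget, ParameterBounds, Trace,
                       excitability_point, extract_features, fit_condition,
                       make_reference_condition, simulate, synthesize_trace)

rc = make_reference_condition("tonic")       # known ground truth + 3 steps
proto = rc.protocols[2]                      # the strong (1.6x rheobase) step
sim = simulate(rc.parameters, proto)
feats = extract_features(Trace(sim.times, sim.voltages), proto,
                         rc.detection_threshold)
print(feats.to_dict())
print(excitability_point(rc.parameters))

targets = [FitTarget(synthesize_trace(rc.parameters, p), p,
                     rc.detection_threshold) for p in rc.protocols]
ranked = fit_condition(targets, ParameterBounds.around(rc.parameters),
                       FitConfig(n_samples=256), condition="tonic")
print(ranked.errors[:4])
```

prints (rounded):

```
{'freq': 48.0, 'time_to_first_spike': 23.27, 'time_to_second_spike': 41.19,
 'time_to_third_spike': 59.87, 'time_to_last_spike': 484.82,
 'inv_first_ISI': 55.8, 'inv_last_ISI': 49.07}
ExcitabilityPoint(R_a=0.2, R_tau=0.5, excitability_class='Class I')
[0.    1.487 2.237 2.467]
```

The 48 spikes/s rate and near-equal first/last inverse interspike intervals
(55.8 vs 49.1 s⁻¹) are the tonic phenotype; `a·τ_w = 80 < C = 200` places the
model below the Bogdanov–Takens line (Class I: firing can start at
arbitrarily low rates through a saddle-node-on-invariant-circle onset).  The
zero-error ensemble member is the generator itself — with unscrambled Sobol
sampling and truth-centred bounds, the second sample point is the centre of
the box.

The same pipeline is scriptable from a shell:

```sh
adexscape simulate --params params.json --step 352.6 --out trace.csv
adexscape features --trace trace.csv --metadata meta.json --out features.json
adexscape fit --manifest control.json --bounds bounds.json --out control_models.json
adexscape pca control_models.json modulated_models.json --out report.json
adexscape landscape control_models.json modulated_models.json --out landscape.json
adexscape estimate --source-control rc.json --source-modulated rm.json \
    --target-control hc.json --out estimate.json
```

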
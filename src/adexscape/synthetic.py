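"""Ground-truth AdEx regimes and synthetic trace generation.

Four reference firing regimes — tonic, adapting, initial-burst and delayed —
cover the qualitative behaviours the fitting pipeline must recover: regular
firing, spike-frequency adaptation, a high after-spike reset that reignites
spikes at stimulus onset, and long first-spike latency near rheobase.  Each
regime ships a known parameter set and three current-step protocols
(sub-rheobase, near-rheobase, strong) whose step amplitudes are derived from
the closed-form rheobase of the parameter set.

Synthetic traces add zero-mean Gaussian observation noise on the voltage
only; the underlying dynamics are noiseless.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import rheobase_current
from .features import Trace
from .model import AdExParameters, StimulusProtocol, simulate

__all__ = [
    "REGIMES",
    "DETECTION_THRESHOLD",
    "ReferenceCondition",
    "make_reference_condition",
    "synthesize_trace",
]

#: Spike-detection threshold (mV) used for all reference conditions; it lies
#: above every regime's reset voltage and below every peak voltage, so each
#: model spike produces exactly one upward crossing.
DETECTION_THRESHOLD = -20.0

# step amplitude as a multiple of the closed-form rheobase
_STEP_FACTORS = {"sub": 0.8, "near": 1.05, "strong": 1.6}

_REGIME_PARAMS = {
    # Regular firing, weak adaptation: first and last interspike intervals
    # agree within 20% at the strong step.
    "tonic": AdExParameters(
        C=200.0, g_L=10.0, E_L=-70.0, Delta_T=2.0, V_th=-50.0,
        a=2.0, b=3.0, tau_w=40.0, V_reset=-58.0, V_peak=20.0, t_ref=2.0,
    ),
    # Strong spike-triggered adaptation: the firing slows visibly during the
    # step (inv_first_ISI > 1.5 * inv_last_ISI).
    "adapting": AdExParameters(
        C=150.0, g_L=12.0, E_L=-68.0, Delta_T=2.5, V_th=-52.0,
        a=4.0, b=90.0, tau_w=250.0, V_reset=-60.0, V_peak=15.0, t_ref=2.0,
    ),
    # Reset above threshold: spikes reignite immediately at stimulus onset
    # until the accumulated adaptation slows them down.
    "initial-burst": AdExParameters(
        C=180.0, g_L=9.0, E_L=-72.0, Delta_T=2.0, V_th=-50.0,
        a=1.5, b=60.0, tau_w=180.0, V_reset=-45.0, V_peak=25.0, t_ref=1.5,
    ),
    # Slow membrane (tau_m > 30 ms) firing just above rheobase: long latency
    # to the first spike at the near-rheobase step.
    "delayed": AdExParameters(
        C=250.0, g_L=8.0, E_L=-65.0, Delta_T=1.5, V_th=-48.0,
        a=1.0, b=20.0, tau_w=150.0, V_reset=-55.0, V_peak=20.0, t_ref=2.0,
    ),
}

REGIMES = tuple(_REGIME_PARAMS)

_EXPECTED = {
    "tonic": "inv_first_ISI / inv_last_ISI within [1/1.2, 1.2] at the strong step",
    "adapting": "inv_first_ISI > 1.5 * inv_last_ISI at the strong step",
    "initial-burst": "inv_first_ISI > 2 * inv_last_ISI at the strong step",
    "delayed": "time_to_first_spike > 50 ms at the near-rheobase step",
}


@dataclass(frozen=True)
class ReferenceCondition:
    """A named ground-truth regime with its step protocols."""

    regime: str
    parameters: AdExParameters
    protocols: tuple  # (sub-rheobase, near-rheobase, strong)
    detection_threshold: float
    expected: str  # qualitative relation the regime satisfies


def make_reference_condition(regime: str) -> ReferenceCondition:
    """Deterministic parameter set and three step protocols for a regime.

    Step amplitudes are 0.8x, 1.05x and 1.6x the closed-form rheobase of the
    regime's parameters; each protocol holds the neuron at its leak reversal,
    with the step from 100 to 600 ms of a 700 ms record.
    """
    if regime not in _REGIME_PARAMS:
        raise ValueError(
            f"unknown regime {regime!r}; choose one of {sorted(_REGIME_PARAMS)}"
        )
    params = _REGIME_PARAMS[regime]
    i_rh = rheobase_current(params)
    # The sub-rheobase step must stay below the *transient* rheobase as well:
    # before the adaptation current reaches its steady state the membrane
    # alone (a = 0) sets the spiking limit.
    i_inst = params.g_L * (params.V_th - params.E_L - params.Delta_T)
    i_sub_base = min(i_rh, i_inst)
    protocols = tuple(
        StimulusProtocol(
            step_amplitude=round(
                factor * (i_sub_base if name == "sub" else i_rh), 1
            ),
            stim_delay=100.0,
            stim_end=600.0,
            duration=700.0,
            initial_voltage=params.E_L,
            holding_current=0.0,
        )
        for name, factor in _STEP_FACTORS.items()
    )
    return ReferenceCondition(
        regime=regime,
        parameters=params,
        protocols=protocols,
        detection_threshold=DETECTION_THRESHOLD,
        expected=_EXPECTED[regime],
    )


def synthesize_trace(
    params: AdExParameters,
    protocol: StimulusProtocol,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 0.01,
) -> Trace:
    """Simulated voltage trace plus Gaussian observation noise.

    ``noise_sd`` is the sample-wise standard deviation in mV (0 reproduces
    the simulation exactly); the trace is deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    sim = simulate(params, protocol, dt=dt)
    voltages = sim.voltages
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        voltages = voltages + rng.normal(0.0, noise_sd, size=voltages.shape)
    return Trace(times=sim.times, voltages=voltages)
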
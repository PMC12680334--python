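"""Adaptive exponential integrate-and-fire (AdEx) model and its integration.

The AdEx neuron couples a membrane voltage ``V`` (mV) with an adaptation
current ``w`` (pA)::

    C dV/dt = -g_L (V - E_L) + g_L * Delta_T * exp((V - V_th)/Delta_T) + I(t) - w
    tau_w dw/dt = a (V - E_L) - w

When ``V`` reaches the peak voltage ``V_peak`` a spike is recorded, ``V`` is
reset to ``V_reset``, ``w`` is incremented by ``b``, and both variables are
clamped for a refractory period ``t_ref``.

Units are fixed package-wide: mV, ms, pA, nS, pF.  With these choices both
``C dV/dt`` and conductance-times-voltage terms are expressed in pA, so the
equations above can be evaluated without conversion factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

from ._integrator import adex_euler

__all__ = [
    "PARAM_NAMES",
    "EXP_ARG_MAX",
    "AdExParameters",
    "StimulusProtocol",
    "SimulationResult",
    "IntegrationError",
    "simulate",
    "v_nullcline",
    "w_nullcline",
]

#: Canonical ordering of the AdEx parameter vector used throughout the package.
PARAM_NAMES = (
    "C",
    "g_L",
    "E_L",
    "Delta_T",
    "V_th",
    "a",
    "b",
    "tau_w",
    "V_reset",
    "V_peak",
    "t_ref",
)

#: Upper clamp on the argument of the exponential term.  Any voltage whose
#: exponent would exceed this is already far above ``V_peak`` in practice, so
#: the clamp prevents floating-point overflow without changing spike timing.
EXP_ARG_MAX = 30.0


class IntegrationError(RuntimeError):
    """Raised when the forward-Euler state becomes non-finite.

    Attributes
    ----------
    time_ms : float
        Simulation time (ms) at which the first non-finite sample appeared.
    """

    def __init__(self, time_ms: float):
        self.time_ms = float(time_ms)
        super().__init__(
            f"integration failure: non-finite state at t = {time_ms:g} ms"
        )


@dataclass(frozen=True)
class AdExParameters:
    """The 11-value AdEx parameter vector.

    Parameters
    ----------
    C : float
        Membrane capacitance (pF).
    g_L : float
        Leak conductance (nS).
    E_L : float
        Leak reversal potential (mV).
    Delta_T : float
        Exponential slope factor (mV).
    V_th : float
        Effective threshold potential of the exponential term (mV).
    a : float
        Subthreshold adaptation conductance (nS); may be negative.
    b : float
        Spike-triggered adaptation increment (pA).
    tau_w : float
        Adaptation time constant (ms).
    V_reset : float
        After-spike reset potential (mV).
    V_peak : float
        Spike detection / peak voltage (mV).
    t_ref : float
        Refractory period (ms) during which V and w are clamped.
    """

    C: float
    g_L: float
    E_L: float
    Delta_T: float
    V_th: float
    a: float
    b: float
    tau_w: float
    V_reset: float
    V_peak: float
    t_ref: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.g_L <= 0:
            raise ValueError(f"g_L must be positive, got {self.g_L}")
        if self.Delta_T <= 0:
            raise ValueError(f"Delta_T must be positive, got {self.Delta_T}")
        if self.tau_w <= 0:
            raise ValueError(f"tau_w must be positive, got {self.tau_w}")
        if self.t_ref < 0:
            raise ValueError(f"t_ref must be non-negative, got {self.t_ref}")
        if not self.V_reset < self.V_peak:
            raise ValueError("V_reset must lie below V_peak")
        if not self.V_th < self.V_peak:
            raise ValueError("V_th must lie below V_peak")

    def as_array(self) -> np.ndarray:
        """Return the parameters as a float vector in ``PARAM_NAMES`` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "AdExParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(
                f"expected {len(PARAM_NAMES)} values, got shape {values.shape}"
            )
        return cls(**dict(zip(PARAM_NAMES, values.tolist())))

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "AdExParameters":
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})

    def replace(self, **changes) -> "AdExParameters":
        return replace(self, **changes)

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_L (ms)."""
        return self.C / self.g_L


@dataclass(frozen=True)
class StimulusProtocol:
    """A holding current plus a rectangular current step.

    ``I(t) = holding_current + step_amplitude * [stim_delay <= t < stim_end]``

    All times in ms, currents in pA, voltages in mV.  ``initial_voltage`` is
    the holding voltage the recording starts from.
    """

    step_amplitude: float
    stim_delay: float
    stim_end: float
    duration: float
    initial_voltage: float
    holding_current: float = 0.0

    def __post_init__(self):
        if not (0 <= self.stim_delay < self.stim_end <= self.duration):
            raise ValueError(
                "protocol requires 0 <= stim_delay < stim_end <= duration, got "
                f"delay={self.stim_delay}, end={self.stim_end}, "
                f"duration={self.duration}"
            )

    @property
    def stim_duration(self) -> float:
        return self.stim_end - self.stim_delay

    def current_at(self, t: float) -> float:
        step = self.step_amplitude if self.stim_delay <= t < self.stim_end else 0.0
        return self.holding_current + step

    def to_dict(self) -> dict:
        return {
            "step_amplitude": self.step_amplitude,
            "stim_delay": self.stim_delay,
            "stim_end": self.stim_end,
            "duration": self.duration,
            "initial_voltage": self.initial_voltage,
            "holding_current": self.holding_current,
        }


@dataclass
class SimulationResult:
    """Sampled state of one AdEx simulation.

    ``times`` is a uniform ms grid; ``voltages`` (mV) and ``adaptation`` (pA)
    have the same length.  ``spike_times`` are the grid times at which the
    voltage reached ``V_peak``.
    """

    times: np.ndarray
    voltages: np.ndarray
    adaptation: np.ndarray
    spike_times: np.ndarray

    @property
    def n_spikes(self) -> int:
        return int(len(self.spike_times))

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def simulate(
    params: AdExParameters,
    protocol: StimulusProtocol,
    dt: float = 0.01,
    w0: float | None = None,
) -> SimulationResult:
    """Integrate the AdEx equations with explicit forward Euler.

    Parameters
    ----------
    params, protocol
        Model and stimulus definitions.
    dt : float
        Time step in ms (default 0.01).  Must satisfy ``dt <= t_ref`` whenever
        ``t_ref > 0`` so the refractory clamp is representable on the grid.
    w0 : float, optional
        Initial adaptation current (pA).  By default the subthreshold steady
        state ``a * (V(0) - E_L)`` is used, matching a neuron held at a steady
        baseline before the step.

    Returns
    -------
    SimulationResult

    Raises
    ------
    ValueError
        On an invalid time step.
    IntegrationError
        If the state becomes non-finite despite the exponent guard.
    """
    if not (dt > 0) or not math.isfinite(dt):
        raise ValueError(f"dt must be a positive finite number, got {dt!r}")
    if params.t_ref > 0 and dt > params.t_ref:
        raise ValueError(
            f"dt={dt} must not exceed t_ref={params.t_ref} (refractory clamp "
            "would not be representable)"
        )

    n = int(round(protocol.duration / dt)) + 1
    v0 = float(protocol.initial_voltage)
    if w0 is None:
        w0 = params.a * (v0 - params.E_L)
    ref_steps = int(round(params.t_ref / dt))

    voltages, adaptation, spike_idx, fail_idx = adex_euler(
        params.C,
        params.g_L,
        params.E_L,
        params.Delta_T,
        params.V_th,
        params.a,
        params.b,
        params.tau_w,
        params.V_reset,
        params.V_peak,
        ref_steps,
        protocol.holding_current,
        protocol.step_amplitude,
        protocol.stim_delay,
        protocol.stim_end,
        v0,
        float(w0),
        dt,
        n,
    )
    if fail_idx >= 0:
        raise IntegrationError(fail_idx * dt)

    times = np.arange(n) * dt
    return SimulationResult(
        times=times,
        voltages=voltages,
        adaptation=adaptation,
        spike_times=times[spike_idx],
    )


def _guarded_exp(arg):
    return np.exp(np.minimum(arg, EXP_ARG_MAX))


def v_nullcline(params: AdExParameters, I: float, V):
    """Adaptation current w on the V-nullcline (dV/dt = 0) at voltage(s) V.

    Returns ``-g_L (V - E_L) + g_L * Delta_T * exp((V - V_th)/Delta_T) + I``
    in pA.  Accepts scalars or arrays.
    """
    V = np.asarray(V, dtype=float)
    w = (
        -params.g_L * (V - params.E_L)
        + params.g_L * params.Delta_T * _guarded_exp((V - params.V_th) / params.Delta_T)
        + I
    )
    return w if w.ndim else float(w)


def w_nullcline(params: AdExParameters, V):
    """Adaptation current w on the w-nullcline (dw/dt = 0): ``a (V - E_L)``."""
    V = np.asarray(V, dtype=float)
    w = params.a * (V - params.E_L)
    return w if w.ndim else float(w)
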
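"""Spike detection and scalar feature extraction from voltage traces.

The feature set deliberately ignores spike shape: it summarises a current-step
response by spike timing and rate quantities plus, optionally, the membrane
potential at the end of the stimulus (informative for strongly adapting
cells).  Which features exist depends on how many spikes were detected:

========================  =========================================
spike count               features present
========================  =========================================
any                       freq
>= 1                      time_to_first_spike
>= 2                      time_to_second_spike, inv_first_ISI
>= 3                      time_to_third_spike, inv_last_ISI
>  3                      time_to_last_spike
========================  =========================================

Times are reported in ms relative to stimulus onset; rates (freq, inverse
interspike intervals) in 1/s; voltages in mV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import StimulusProtocol

__all__ = [
    "FEATURE_NAMES",
    "Trace",
    "FeatureSet",
    "detect_spikes",
    "extract_features",
    "derive_leak_reversal",
]

FEATURE_NAMES = (
    "freq",
    "time_to_first_spike",
    "time_to_second_spike",
    "time_to_third_spike",
    "time_to_last_spike",
    "inv_first_ISI",
    "inv_last_ISI",
    "volt_stimend",
)


@dataclass(frozen=True)
class Trace:
    """A sampled voltage trace: times in ms (strictly increasing), mV values."""

    times: np.ndarray
    voltages: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "voltages", v)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("times and voltages must be 1-D and equally long")
        if len(t) < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("trace contains non-finite values")
        if not np.all(np.diff(t) > 0):
            raise ValueError("trace times must be strictly increasing")


@dataclass(frozen=True)
class FeatureSet:
    """Scalar features of one trace; absent features are ``None``.

    ``freq`` (spikes/s) is always defined, zero when no spike was detected.
    """

    freq: float
    time_to_first_spike: float | None = None
    time_to_second_spike: float | None = None
    time_to_third_spike: float | None = None
    time_to_last_spike: float | None = None
    inv_first_ISI: float | None = None
    inv_last_ISI: float | None = None
    volt_stimend: float | None = None

    def __post_init__(self):
        if self.freq < 0:
            raise ValueError("freq must be non-negative")
        if self.time_to_second_spike is not None:
            if self.time_to_first_spike is None:
                raise ValueError("time_to_second_spike requires time_to_first_spike")
            if not self.time_to_second_spike > self.time_to_first_spike:
                raise ValueError("time_to_second_spike must exceed time_to_first_spike")
        for name in ("inv_first_ISI", "inv_last_ISI"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive when present")

    def get(self, name: str):
        if name not in FEATURE_NAMES:
            raise KeyError(f"unknown feature {name!r}")
        return getattr(self, name)

    def present(self) -> tuple:
        """Names of the features that are defined on this trace."""
        return tuple(n for n in FEATURE_NAMES if getattr(self, n) is not None)

    def to_dict(self) -> dict:
        """Present features only, keyed by their canonical names."""
        return {n: float(getattr(self, n)) for n in self.present()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        unknown = set(d) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature keys: {sorted(unknown)}")
        if "freq" not in d:
            raise ValueError("a FeatureSet requires 'freq'")
        return cls(**{k: float(v) for k, v in d.items()})


def detect_spikes(trace: Trace, V_th: float) -> np.ndarray:
    """Times (ms) at which the trace crosses ``V_th`` from below.

    A spike is recorded at sample ``i >= 1`` whenever
    ``voltages[i] > V_th and voltages[i-1] < V_th`` — both inequalities
    strict, so samples exactly at threshold never start a spike.
    """
    v = trace.voltages
    crossing = (v[1:] > V_th) & (v[:-1] < V_th)
    return trace.times[1:][crossing]


def extract_features(
    trace: Trace,
    protocol: StimulusProtocol,
    V_th: float,
    include_volt_stimend: bool = False,
) -> FeatureSet:
    """Compute the feature set of a trace under a current-step protocol.

    ``freq`` is the spike count divided by the stimulus duration, in spikes/s;
    timing features are measured from stimulus onset; inverse interspike
    intervals are converted to 1/s so they share units with ``freq``.
    ``volt_stimend`` (when requested) is the voltage of the sample nearest to
    — at or before — ``stim_end``.
    """
    t = trace.times
    if protocol.stim_delay < t[0] or protocol.stim_end > t[-1]:
        raise ValueError(
            "protocol window "
            f"[{protocol.stim_delay}, {protocol.stim_end}] ms lies outside the "
            f"trace extent [{t[0]}, {t[-1]}] ms"
        )

    spikes = detect_spikes(trace, V_th)
    n = len(spikes)
    values: dict = {
        # count / ms -> spikes/s
        "freq": 1000.0 * n / protocol.stim_duration
    }
    onset = protocol.stim_delay
    if n >= 1:
        values["time_to_first_spike"] = spikes[0] - onset
    if n >= 2:
        values["time_to_second_spike"] = spikes[1] - onset
        values["inv_first_ISI"] = 1000.0 / (spikes[1] - spikes[0])
    if n >= 3:
        values["time_to_third_spike"] = spikes[2] - onset
        values["inv_last_ISI"] = 1000.0 / (spikes[-1] - spikes[-2])
    if n > 3:
        values["time_to_last_spike"] = spikes[-1] - onset
    if include_volt_stimend:
        idx = int(np.searchsorted(t, protocol.stim_end, side="right")) - 1
        values["volt_stimend"] = float(trace.voltages[idx])
    return FeatureSet(**values)


def derive_leak_reversal(v_hold: float, i_hold: float, g_L: float, a: float) -> float:
    """Leak reversal E_L consistent with a holding point (v_hold, i_hold).

    With no injected current the holding voltage is the leak reversal itself.
    Under a nonzero holding current the linear subthreshold steady state gives
    ``E_L = v_hold - i_hold / (g_L + a)``.
    """
    g_total = g_L + a
    if abs(g_total) < 1e-12:
        raise ValueError(
            "degenerate total conductance g_L + a = 0; E_L cannot be derived"
        )
    if i_hold == 0:
        return float(v_hold)
    return float(v_hold - i_hold / g_total)
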
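"""Quasi-random exploration of AdEx parameter space and ensemble ranking.

Candidates are drawn from a base-2 Sobol sequence (unscrambled by default, so
runs are exactly reproducible), simulated under every available protocol, and
scored with a weighted sum of per-feature relative errors against the
data-derived features.  The lowest-error candidates form the condition's
model ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .features import FEATURE_NAMES, FeatureSet, Trace, extract_features
from .model import PARAM_NAMES, AdExParameters, IntegrationError, StimulusProtocol, simulate

__all__ = [
    "ParameterBounds",
    "FitConfig",
    "FitTarget",
    "RankedModels",
    "DEFAULT_PENALTY",
    "sample_parameters",
    "feature_error",
    "feature_error_terms",
    "fit_condition",
]

#: Added to the total error, once per weighted feature, when the data define a
#: feature that the model failed to produce (e.g. it did not spike enough).
DEFAULT_PENALTY = 3.0

_VOLTAGE_PARAMS = ("E_L", "V_th", "V_reset")


@dataclass(frozen=True)
class ParameterBounds:
    """Closed interval per AdEx parameter; lo == hi pins a parameter.

    The box must lie inside the valid AdEx region (positive capacitances,
    conductances and time constants; reset and threshold below the lowest
    admissible peak), so that every sampled vertex is a valid parameter set.
    """

    bounds: dict

    def __post_init__(self):
        missing = set(PARAM_NAMES) - set(self.bounds)
        if missing:
            raise ValueError(f"bounds missing parameters: {sorted(missing)}")
        unknown = set(self.bounds) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters in bounds: {sorted(unknown)}")
        clean = {}
        for name in PARAM_NAMES:
            lo, hi = (float(x) for x in self.bounds[name])
            if not lo <= hi:
                raise ValueError(f"bounds for {name} have lo > hi: ({lo}, {hi})")
            clean[name] = (lo, hi)
        object.__setattr__(self, "bounds", clean)
        for name in ("C", "g_L", "Delta_T", "tau_w"):
            if clean[name][0] <= 0:
                raise ValueError(f"lower bound of {name} must be positive")
        if clean["t_ref"][0] < 0:
            raise ValueError("lower bound of t_ref must be non-negative")
        v_peak_lo = clean["V_peak"][0]
        for name in ("V_reset", "V_th"):
            if clean[name][1] >= v_peak_lo:
                raise ValueError(
                    f"upper bound of {name} must lie below the lower bound of V_peak"
                )

    def lo_hi_arrays(self):
        lo = np.array([self.bounds[n][0] for n in PARAM_NAMES])
        hi = np.array([self.bounds[n][1] for n in PARAM_NAMES])
        return lo, hi

    def is_fixed(self, name: str) -> bool:
        lo, hi = self.bounds[name]
        return lo == hi

    @classmethod
    def around(
        cls,
        params: AdExParameters,
        rel: float = 0.5,
        volt_delta: float = 10.0,
        fixed: tuple = ("V_peak",),
    ) -> "ParameterBounds":
        """Box around a parameter set: ±``rel`` multiplicative on magnitudes
        (C, g_L, Delta_T, a, b, tau_w, t_ref), ±``volt_delta`` mV on voltage
        parameters (E_L, V_th, V_reset).  Parameters named in ``fixed`` are
        pinned to their current value; V_peak is pinned by default since it is
        read off the traces.
        """
        b: dict = {}
        for name in PARAM_NAMES:
            v = getattr(params, name)
            if name in fixed:
                b[name] = (v, v)
            elif name in _VOLTAGE_PARAMS:
                b[name] = (v - volt_delta, v + volt_delta)
            else:
                half = abs(v) * rel
                b[name] = (v - half, v + half)
        return cls(b)

    def to_dict(self) -> dict:
        return {n: list(self.bounds[n]) for n in PARAM_NAMES}


@dataclass(frozen=True)
class FitConfig:
    """Search configuration.

    ``n_samples`` must be a power of two (the Sobol sequence is balanced in
    base 2); ``n_keep`` models with the lowest error are retained.  Weights
    multiply individual feature error terms; missing entries default to 1.
    """

    n_samples: int = 4096
    n_keep: int = 16
    weights: dict = field(default_factory=dict)
    penalty: float = DEFAULT_PENALTY
    dt: float = 0.01
    scramble_seed: int | None = None

    def __post_init__(self):
        _check_power_of_two(self.n_samples)
        if not 1 <= self.n_keep <= self.n_samples:
            raise ValueError("n_keep must be in [1, n_samples]")
        if self.penalty < 0:
            raise ValueError("penalty must be non-negative")
        unknown = set(self.weights) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"weights for unknown features: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")

    def weight(self, feature: str) -> float:
        return float(self.weights.get(feature, 1.0))

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_keep": self.n_keep,
            "weights": dict(self.weights),
            "penalty": self.penalty,
            "dt": self.dt,
            "scramble_seed": self.scramble_seed,
        }


@dataclass(frozen=True)
class FitTarget:
    """One data trace with its protocol and spike-detection threshold."""

    trace: Trace
    protocol: StimulusProtocol
    detection_threshold: float
    include_volt_stimend: bool = False


@dataclass
class RankedModels:
    """Error-ordered ensemble of fitted parameter sets for one condition."""

    condition: str
    models: list  # list of (AdExParameters, total_error), ascending error
    config: FitConfig | None = None

    def __post_init__(self):
        errors = [e for _, e in self.models]
        if any(e2 < e1 for e1, e2 in zip(errors, errors[1:])):
            raise ValueError("model errors must be ascending")

    @property
    def parameters(self) -> list:
        return [p for p, _ in self.models]

    @property
    def errors(self) -> np.ndarray:
        return np.array([e for _, e in self.models])

    def __len__(self):
        return len(self.models)


def _check_power_of_two(n: int):
    if n < 1 or (n & (n - 1)) != 0:
        raise ValueError(
            f"the number of Sobol samples must be a power of 2, got {n}"
        )


def sample_parameters(
    bounds: ParameterBounds,
    n: int,
    scramble_seed: int | None = None,
) -> list:
    """Draw ``n`` AdEx parameter vectors from a joint 11-dimensional Sobol
    sequence mapped affinely into the bounds box.

    Unscrambled by default, hence bit-reproducible across calls; pass
    ``scramble_seed`` for an Owen-scrambled sequence.
    """
    _check_power_of_two(n)
    d = len(PARAM_NAMES)
    if scramble_seed is None:
        engine = qmc.Sobol(d=d, scramble=False)
    else:
        engine = qmc.Sobol(d=d, scramble=True, seed=scramble_seed)
    unit = engine.random_base2(int(np.log2(n)))
    lo, hi = bounds.lo_hi_arrays()
    points = lo + unit * (hi - lo)
    return [AdExParameters.from_array(row) for row in points]


def feature_error(
    data: FeatureSet,
    model: FeatureSet,
    weights: dict | None = None,
    penalty: float = DEFAULT_PENALTY,
) -> float:
    """Weighted sum of relative feature errors between data and model.

    For each feature the data define, the term is
    ``weight * |data - model| / |data|``; if the model failed to produce the
    feature the term is ``weight * penalty``.  Features absent from the data
    are ignored.  Data features with magnitude below 1e-9 fall back to the
    absolute difference (the relative error is undefined at zero).
    """
    return sum(t for _, t, _ in feature_error_terms(data, model, weights, penalty))


def feature_error_terms(
    data: FeatureSet,
    model: FeatureSet,
    weights: dict | None = None,
    penalty: float = DEFAULT_PENALTY,
) -> list:
    """Per-feature breakdown of :func:`feature_error`.

    Returns a list of ``(feature_name, weighted_term, flag)`` where flag is
    ``"penalty"`` for a model-absent feature, ``"absolute"`` where the
    near-zero fallback applied, and ``""`` otherwise.
    """
    weights = weights or {}
    terms = []
    for name in data.present():
        w = float(weights.get(name, 1.0))
        d = data.get(name)
        m = model.get(name)
        if m is None:
            terms.append((name, w * penalty, "penalty"))
        elif abs(d) < 1e-9:
            terms.append((name, w * abs(d - m), "absolute"))
        else:
            terms.append((name, w * abs(d - m) / abs(d), ""))
    return terms


def fit_condition(
    targets: list,
    bounds: ParameterBounds,
    config: FitConfig | None = None,
    condition: str = "",
    initial_candidates: list | None = None,
) -> RankedModels:
    """Fit an AdEx ensemble to one condition's traces.

    Every Sobol candidate (optionally preceded by user-supplied
    ``initial_candidates``) is simulated under each target's protocol; its
    total error is the sum of :func:`feature_error` across targets.
    Candidates whose simulation diverges receive infinite error.  The
    ``config.n_keep`` lowest-error candidates are returned in ascending order,
    ties broken by candidate index.

    ``targets`` may contain :class:`FitTarget` objects or
    ``(trace, protocol, detection_threshold)`` tuples.
    """
    if config is None:
        config = FitConfig()
    norm_targets = []
    for t in targets:
        if isinstance(t, FitTarget):
            norm_targets.append(t)
        else:
            trace, protocol, thr = t
            norm_targets.append(FitTarget(trace, protocol, thr))
    if not norm_targets:
        raise ValueError("at least one target trace is required")

    data_features = [
        extract_features(
            t.trace, t.protocol, t.detection_threshold, t.include_volt_stimend
        )
        for t in norm_targets
    ]

    candidates = list(initial_candidates or []) + sample_parameters(
        bounds, config.n_samples, config.scramble_seed
    )
    errors = np.empty(len(candidates))
    for i, cand in enumerate(candidates):
        total = 0.0
        for target, data in zip(norm_targets, data_features):
            try:
                sim = simulate(cand, target.protocol, dt=config.dt)
            except (IntegrationError, ValueError):
                total = np.inf
                break
            model_trace = Trace(sim.times, sim.voltages)
            model_features = extract_features(
                model_trace,
                target.protocol,
                target.detection_threshold,
                target.include_volt_stimend,
            )
            total += feature_error(
                data, model_features, config.weights, config.penalty
            )
        errors[i] = total

    if not np.any(np.isfinite(errors)):
        raise RuntimeError(
            "every candidate failed to integrate; widen or recenter the bounds"
        )
    order = np.argsort(errors, kind="stable")[: config.n_keep]
    models = [(candidates[i], float(errors[i])) for i in order]
    return RankedModels(condition=condition, models=models, config=config)
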
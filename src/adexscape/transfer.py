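"""Cross-species transfer of neuromodulator-induced parameter changes.

When a modulator's effect has been measured in a source species (e.g. rodent)
but not in the target species (e.g. human), and the control excitability of
the two is comparable, the per-parameter change can be transferred as a
*modulation ratio* applied to the target's control means.  Two strategies
exist for each parameter ``i``:

- absolute:  ``ratio_i = |mod_i / control_i|`` — preserves the magnitude of
  the relative change;
- signed:    ``ratio_i = 1 - |mod_i / control_i|`` — preserves the direction
  of change when the source and target control means have opposite signs
  (relevant in practice for the subthreshold adaptation ``a``).

The estimated target value is ``target_control_i * ratio_i`` in both cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import PARAM_NAMES, AdExParameters

__all__ = [
    "TransferRecipe",
    "modulation_ratio",
    "build_recipe",
    "estimate_modulated_parameters",
    "interpolate_estimates",
]

_STRATEGIES = ("absolute", "signed")


def modulation_ratio(control_mean: float, modulated_mean: float, strategy: str) -> float:
    """Modulation ratio of one parameter under either strategy."""
    if strategy not in _STRATEGIES:
        raise ValueError(f"strategy must be one of {_STRATEGIES}, got {strategy!r}")
    if abs(control_mean) <= 1e-9:
        raise ValueError(
            f"control mean {control_mean!r} is too close to zero; the "
            "modulation ratio is undefined"
        )
    mag = abs(modulated_mean / control_mean)
    return mag if strategy == "absolute" else 1.0 - mag


@dataclass(frozen=True)
class TransferRecipe:
    """Per-parameter ratios and the strategy each was computed with."""

    ratios: dict  # name -> float
    strategies: dict  # name -> "absolute" | "signed"
    source_control: str = ""
    source_modulated: str = ""

    def __post_init__(self):
        for name, r in self.ratios.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r} in recipe")
            if not (r == r and abs(r) != float("inf")):
                raise ValueError(f"ratio for {name} must be finite")
        for name, s in self.strategies.items():
            if s not in _STRATEGIES:
                raise ValueError(f"invalid strategy {s!r} for {name}")

    def to_dict(self) -> dict:
        return {
            "ratios": dict(self.ratios),
            "strategies": dict(self.strategies),
            "source_control": self.source_control,
            "source_modulated": self.source_modulated,
        }


def build_recipe(
    source_control_means: dict,
    source_modulated_means: dict,
    target_control_means: dict | None = None,
    strategy_overrides: dict | None = None,
    source_control: str = "",
    source_modulated: str = "",
) -> TransferRecipe:
    """Recipe from source control/modulated ensemble means.

    The absolute strategy is the default per parameter; the signed strategy is
    selected automatically wherever the source and target control means
    disagree in sign (it then preserves the direction of the source change).
    ``strategy_overrides`` forces a strategy per parameter.
    """
    overrides = strategy_overrides or {}
    ratios, strategies = {}, {}
    for name in source_control_means:
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
        c = source_control_means[name]
        m = source_modulated_means[name]
        strategy = overrides.get(name)
        if strategy is None:
            strategy = "absolute"
            if target_control_means is not None and name in target_control_means:
                if c * target_control_means[name] < 0:
                    strategy = "signed"
        ratios[name] = modulation_ratio(c, m, strategy)
        strategies[name] = strategy
    return TransferRecipe(
        ratios=ratios,
        strategies=strategies,
        source_control=source_control,
        source_modulated=source_modulated,
    )


def estimate_modulated_parameters(
    target_control_means: dict, recipe: TransferRecipe
) -> AdExParameters:
    """Estimated modulated parameter set: target mean times ratio, per
    parameter.  Parameters missing from the recipe raise; to pass a parameter
    through unchanged give it ratio 1."""
    values = {}
    for name in PARAM_NAMES:
        if name not in target_control_means:
            raise ValueError(f"target control means missing parameter {name!r}")
        if name not in recipe.ratios:
            raise ValueError(f"recipe has no ratio for free parameter {name!r}")
        values[name] = target_control_means[name] * recipe.ratios[name]
    return AdExParameters(**values)


def interpolate_estimates(
    absolute: AdExParameters, signed: AdExParameters, lam: float
) -> AdExParameters:
    """Convex blend of the two strategies' estimates.

    ``lam = 0`` returns the absolute-strategy estimate, ``lam = 1`` the signed
    one; intermediate weights cover alternative scalings of sign-flipping
    parameters that land between the two endpoints.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    values = {
        n: (1.0 - lam) * getattr(absolute, n) + lam * getattr(signed, n)
        for n in PARAM_NAMES
    }
    return AdExParameters(**values)
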
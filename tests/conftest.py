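"""Shared fixtures.

The heavy session fixtures (full 4096-candidate Sobol fits) are shared
between the recovery and ensemble-separation tests so each condition is
fitted exactly once per test run.
"""

import numpy as np
import pytest

from adexscape import (
    FitConfig,
    FitTarget,
    ParameterBounds,
    REGIMES,
    fit_condition,
    make_reference_condition,
    synthesize_trace,
)

RECOVERY_N_SAMPLES = 4096


def fit_reference_condition(regime, noise_sd=0.0, seed=0, label=None,
                            n_samples=RECOVERY_N_SAMPLES):
    """Fit a reference regime to its own (optionally noisy) traces with
    bounds centred on the ground truth (+-50% magnitudes, +-10 mV voltages)."""
    rc = make_reference_condition(regime)
    targets = [
        FitTarget(
            synthesize_trace(rc.parameters, proto, noise_sd=noise_sd, seed=seed + j),
            proto,
            rc.detection_threshold,
        )
        for j, proto in enumerate(rc.protocols)
    ]
    bounds = ParameterBounds.around(rc.parameters)
    ranked = fit_condition(
        targets, bounds, FitConfig(n_samples=n_samples), condition=label or regime
    )
    return rc, ranked


@pytest.fixture(scope="session")
def recovery_fits():
    """Noiseless round-trip fits: {regime: (ReferenceCondition, RankedModels)}."""
    return {regime: fit_reference_condition(regime) for regime in REGIMES}


@pytest.fixture(scope="session")
def same_source_fits():
    """Three ensembles fitted independently to three noisy renderings of the
    same tonic ground truth — the non-independence consistency check."""
    return [
        fit_reference_condition(
            "tonic", noise_sd=0.5, seed=100 + 10 * i, label=f"tonic-trace-{i}"
        )[1]
        for i in range(3)
    ]
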
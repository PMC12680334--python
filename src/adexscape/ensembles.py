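"""Ensemble statistics: parameter summaries, PCA, cluster separation.

Each fitted condition yields an ensemble of parameter sets (typically 16).
Because the parameters mix units (pF, nS, mV, ms), every parameter is
z-scored over the pooled comparison set before PCA; parameters with zero
pooled variance (e.g. values pinned by the traces) are dropped and listed in
the result rather than silently imputed.  Cluster separation between
conditions is quantified with the silhouette score, computed on the
2-component PCA projections by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .model import PARAM_NAMES, AdExParameters

__all__ = [
    "ConditionEnsemble",
    "PCAResult",
    "summarize_parameters",
    "pca_project",
    "silhouette",
]


@dataclass(frozen=True)
class ConditionEnsemble:
    """A labelled list of AdEx parameter sets with optional provenance."""

    condition: str
    parameters: list  # list[AdExParameters]
    provenance: tuple = ()

    def __post_init__(self):
        if not self.parameters:
            raise ValueError("ensemble must be nonempty")
        for p in self.parameters:
            if not isinstance(p, AdExParameters):
                raise TypeError("ensemble entries must be AdExParameters")

    def matrix(self) -> np.ndarray:
        """(n_models, n_params) array in canonical parameter order."""
        return np.stack([p.as_array() for p in self.parameters])

    def __len__(self):
        return len(self.parameters)


@dataclass
class PCAResult:
    """Projection of pooled ensembles onto principal components."""

    projections: np.ndarray  # (n_models, k)
    labels: list  # condition label per row
    loadings: np.ndarray  # (n_params_kept, k), unit-norm columns
    parameter_names: tuple  # names of the kept (varying) parameters
    dropped_parameters: tuple  # zero-variance parameters excluded from PCA
    explained_variance: np.ndarray  # fractions, nonincreasing
    top_contributors: list  # per component: 3 parameter names, |loading| desc


def summarize_parameters(ensemble: ConditionEnsemble) -> dict:
    """Per-parameter (mean, population sd) over the ensemble."""
    X = ensemble.matrix()
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population sd
    return {n: (float(m), float(s)) for n, m, s in zip(PARAM_NAMES, means, sds)}


def pca_project(ensembles: list, k: int = 2) -> PCAResult:
    """PCA of the pooled, z-scored model parameters of several ensembles.

    Sign convention: each component is flipped so its largest-|loading| entry
    is positive.  Top contributors are the three largest-|loading| parameters
    per component (ties broken lexicographically by parameter name).
    """
    if not ensembles:
        raise ValueError("at least one ensemble is required")
    X = np.vstack([e.matrix() for e in ensembles])
    labels = [e.condition for e in ensembles for _ in range(len(e))]
    if X.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} pooled models for k={k}")

    sd = X.std(axis=0)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("all parameters are constant across the pooled models")
    kept_names = tuple(n for n, m in zip(PARAM_NAMES, keep) if m)
    dropped = tuple(n for n, m in zip(PARAM_NAMES, keep) if not m)
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    k_eff = min(k, Z.shape[1])
    pca = PCA(n_components=k_eff)
    proj = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()  # (n_params_kept, k)

    for j in range(k_eff):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1.0
            proj[:, j] *= -1.0

    top = []
    for j in range(k_eff):
        # sort by descending |loading|, lexicographic name on ties
        order = sorted(
            range(len(kept_names)),
            key=lambda i: (-abs(loadings[i, j]), kept_names[i]),
        )
        top.append([kept_names[i] for i in order[:3]])

    return PCAResult(
        projections=proj,
        labels=labels,
        loadings=loadings,
        parameter_names=kept_names,
        dropped_parameters=dropped,
        explained_variance=pca.explained_variance_ratio_,
        top_contributors=top,
    )


def silhouette(points, labels) -> float:
    """Mean silhouette score of labelled points, Euclidean distance.

    Per point: ``(b - a) / max(a, b)`` with ``a`` the mean intra-cluster
    distance and ``b`` the smallest mean distance to another cluster;
    singleton clusters score 0.  Requires at least two distinct labels.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two distinct labels")
    if len(X) != len(labels):
        raise ValueError("points and labels must have equal length")
    return float(silhouette_score(X, labels, metric="euclidean"))
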
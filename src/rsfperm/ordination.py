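"""PCA ordination of standardized habitat attributes.

Produces oriented loadings, per-component variance fractions, record
scores, and group centroids for used locations (by behavior) versus
control sites.  The decomposition is an eigen-analysis of the correlation
structure of the z-scored attribute matrix, computed by singular value
decomposition of the centered data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from rsfperm.dataset_io import AnalysisDataset


@dataclass(frozen=True)
class OrdinationResult:
    loadings: pd.DataFrame           # attribute x component weights (orthonormal columns)
    variance_fractions: np.ndarray   # non-increasing, sums to 1 over all components
    scores: pd.DataFrame             # record x component coordinates (centered)
    n_dropped_incomplete: int

    @property
    def components(self) -> list[str]:
        return list(self.loadings.columns)


def fit_pca(
    dataset: AnalysisDataset,
    attributes: list[str],
    include: pd.Series | None = None,
) -> OrdinationResult:
    """Fit a PCA on z-scored attributes over the included records.

    ``include`` is an optional boolean mask aligned with ``dataset.frame``
    (e.g. all used locations except a rare behavior, plus all controls).
    Records missing any attribute are dropped with a count recorded.
    Components are ordered by decreasing variance; signs are as returned
    by the decomposition until :func:`orient_components` is applied.
    """
    frame = dataset.frame if include is None else dataset.frame[np.asarray(include, dtype=bool)]
    data = frame[["record_id", *attributes]].dropna()
    n, p = len(data), len(attributes)
    if n <= p:
        raise ValueError(f"need more records ({n}) than attributes ({p}) for a stable ordination")

    X = data[attributes].to_numpy(dtype=float)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [a for a, s in zip(attributes, sds) if s == 0]
        raise ValueError(f"constant attribute(s) in ordination: {bad}")

    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    fractions = var / var.sum()
    comp_names = [f"PC{i + 1}" for i in range(p)]

    loadings = pd.DataFrame(Vt.T, index=attributes, columns=comp_names)
    scores = pd.DataFrame(U * s, index=pd.Index(data["record_id"], name="record_id"), columns=comp_names)
    return OrdinationResult(
        loadings=loadings,
        variance_fractions=fractions,
        scores=scores,
        n_dropped_incomplete=len(frame) - n,
    )


def orient_components(
    result: OrdinationResult,
    anchors: dict[str, str] | None = None,
) -> OrdinationResult:
    """Resolve the arbitrary sign of each component.

    Each component is flipped, scores included, so that its anchor
    attribute's loading is non-negative.  The default anchor for a
    component (also the fallback when a requested anchor loads exactly 0)
    is the attribute with the largest absolute loading on it.
    """
    anchors = anchors or {}
    loadings = result.loadings.copy()
    scores = result.scores.copy()
    for comp in loadings.columns:
        anchor = anchors.get(comp)
        value = loadings.loc[anchor, comp] if anchor is not None else 0.0
        if anchor is None or value == 0.0:
            anchor = loadings[comp].abs().idxmax()
            value = loadings.loc[anchor, comp]
        if value < 0:
            loadings[comp] = -loadings[comp]
            scores[comp] = -scores[comp]
    return replace(result, loadings=loadings, scores=scores)


def group_centroids(
    result: OrdinationResult,
    labels: pd.Series,
    n_components: int = 2,
) -> pd.DataFrame:
    """Mean score per group on the first ``n_components`` components.

    ``labels`` maps record_id to a group (behavior type or "control").
    Groups without scored records are omitted with a warning.
    """
    comps = result.components[:n_components]
    scored = result.scores[comps].join(labels.rename("group"), how="left")
    if scored["group"].isna().any():
        raise ValueError("every scored record must be labeled")
    empty = set(labels.unique()) - set(scored["group"].unique())
    if empty:
        warnings.warn(f"groups with no scored records omitted: {sorted(empty)}", stacklevel=2)
    return scored.groupby("group")[comps].mean()
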
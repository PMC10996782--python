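"""Latent factor scores via correlation-matrix PCA with varimax rotation.

Future orientation is summarized as the first principal component of the
standardized questionnaire indicators (CFC total, ZTPI future mean, PFE
ratio — or the two-questionnaire variant without PFE); dispositional
negativity is built identically from BDI, STAI and ATQ-NA scores.

Indicators are standardized to mean 0, SD 1 before the singular value
decomposition (the indicators live on incommensurate scales, so a
covariance-matrix PCA would be dominated by the widest one).  Varimax
rotation is applied when more than one component is retained and is the
identity for a single component.  Loadings are reported as
indicator-component correlations; a component's variance proportion is its
(rotated) variance divided by the number of indicators.  Factor scores are
the projections onto the first component, scaled to unit sample variance
and signed so the anchor indicator (first column by default) loads
positively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal varimax rotation matrix for a p x m loading matrix."""
    p, m = loadings.shape
    rot = np.eye(m)
    var_old = 0.0
    for _ in range(max_iter):
        L = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / p)
        )
        rot = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return rot


@dataclass
class FactorModel:
    """Fitted principal-component factor model."""

    indicator_names: list
    loadings: pd.DataFrame           # indicators x components, rotated
    variance_explained: np.ndarray   # proportion per component (of p)
    scores: np.ndarray               # first-component scores, unit variance
    mean_: np.ndarray
    std_: np.ndarray
    weights_: np.ndarray             # projection weights for the first component
    score_scale_: float

    @property
    def first_component_variance(self) -> float:
        return float(self.variance_explained[0])


def fit_pca_factor(
    score_matrix,
    n_components: int = 1,
    anchor: int | str = 0,
) -> FactorModel:
    """Fit an SVD-based PCA with varimax rotation and extract factor scores.

    ``score_matrix`` is participants x indicators (DataFrame or array),
    complete (exclusions happen upstream) with at least 3 rows and no
    constant column.  ``anchor`` names the indicator whose loading fixes
    the first component's sign (the future-orientation factor is oriented
    CFC-positive).
    """
    if isinstance(score_matrix, pd.DataFrame):
        names = list(score_matrix.columns)
        X = score_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(score_matrix, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 participants")
    if np.isnan(X).any():
        raise ValueError("missing values in the indicator matrix; exclude upstream")
    if not 1 <= n_components <= p:
        raise ValueError("n_components must be in [1, n_indicators]")

    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    if np.any(std == 0):
        bad = [names[i] for i in np.where(std == 0)[0]]
        raise ValueError(f"constant indicator(s): {bad}")
    Z = (X - mean) / std

    # eigen-decomposition of the correlation matrix through the SVD of Z
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (n - 1)
    V = vt.T[:, :n_components]
    lam = eigvals[:n_components]
    loadings = V * np.sqrt(lam)  # indicator-component correlations

    if n_components > 1:
        rot = _varimax(loadings)
        loadings = loadings @ rot
        # reorder rotated components by explained variance
        comp_var = (loadings**2).sum(axis=0)
        order = np.argsort(comp_var)[::-1]
        loadings = loadings[:, order]

    comp_var = (loadings**2).sum(axis=0)
    var_prop = comp_var / p

    if isinstance(anchor, str):
        anchor_idx = names.index(anchor)
    else:
        anchor_idx = int(anchor)
    for j in range(loadings.shape[1]):
        ref = loadings[anchor_idx, j]
        if ref == 0:
            ref = loadings[np.argmax(np.abs(loadings[:, j])), j]
        if ref < 0:
            loadings[:, j] = -loadings[:, j]

    # first-component scores: project standardized data onto the loading
    # direction, then scale to unit sample variance
    w = loadings[:, 0]
    raw = Z @ w
    scale = raw.std(ddof=1)
    if scale == 0:
        raise ValueError("degenerate component: zero score variance")
    scores = raw / scale

    return FactorModel(
        indicator_names=names,
        loadings=pd.DataFrame(
            loadings, index=names,
            columns=[f"PC{j + 1}" for j in range(loadings.shape[1])],
        ),
        variance_explained=var_prop,
        scores=scores,
        mean_=mean,
        std_=std,
        weights_=w,
        score_scale_=float(scale),
    )


def factor_scores(model: FactorModel, score_matrix) -> np.ndarray:
    """Score new data on a fitted model's first component.

    Standardization uses the fitting sample's mean/SD, so scores for the
    fitting matrix itself have mean 0 and SD 1 exactly.
    """
    if isinstance(score_matrix, pd.DataFrame):
        if list(score_matrix.columns) != model.indicator_names:
            raise ValueError(
                f"indicator mismatch: expected {model.indicator_names}, "
                f"got {list(score_matrix.columns)}"
            )
        X = score_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(score_matrix, dtype=float)
        if X.shape[1] != len(model.indicator_names):
            raise ValueError("indicator count mismatch")
    Z = (X - model.mean_) / model.std_
    return (Z @ model.weights_) / model.score_scale_
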
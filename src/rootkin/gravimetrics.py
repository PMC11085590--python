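"""Gravitropism curve summaries and trait-to-bending correlation analysis.

Tip-angle time courses (241 samples, every 2 min for 8 h after a 90-degree
rotation) are reduced to principal-component scores and to a maximum swing
rate (the peak rate of change of tip angle).  Kinematic traits are related
to the curve summaries by pairwise Pearson correlation and by canonical
correlation analysis (CCA) on z-scored blocks, with an empirical
permutation null for the first canonical correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.decomposition import PCA

from .types import CCASolution, PCSummary

SAMPLE_INTERVAL_H = 2.0 / 60.0  # 2-min sampling


def pca_curves(curves: np.ndarray | pd.DataFrame, n_components: int = 5) -> PCSummary:
    """PCA of a RIL x time curve matrix (column-centered, unscaled).

    Angles share units across time points, so columns are centered but not
    standardized.  Component sign is fixed so each loading vector has a
    positive sum; scores have zero column means.
    """
    X = np.asarray(curves, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 curves")
    if not np.all(np.isfinite(X)):
        raise ValueError("curves contain non-finite values; interpolate upstream")
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds matrix rank bound {min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    components = pca.components_.copy()
    flip = components.sum(axis=1) < 0
    components[flip] *= -1.0
    scores[:, flip] *= -1.0
    total_var = np.var(X - X.mean(axis=0), axis=0, ddof=1).sum()
    share = pca.explained_variance_ / total_var if total_var > 0 else np.zeros(n_components)
    return PCSummary(
        scores=scores,
        variance_share=share,
        mean_curve=pca.mean_,
        components=components,
    )


def max_swing_rate(
    angles: np.ndarray,
    window: int = 5,
    sample_interval_h: float = SAMPLE_INTERVAL_H,
) -> float:
    """Peak rate of change of tip angle, in degrees per hour.

    The rate at each time is the slope of a least-squares line over
    ``window`` consecutive samples; the maximum over the curve is returned.
    """
    angles = np.asarray(angles, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if angles.size < window:
        raise ValueError(f"curve shorter than window ({angles.size} < {window})")
    c = np.arange(window) - (window - 1) / 2.0
    # OLS slope over a uniform grid: sum(c * theta) / (sum(c^2) * dt)
    slopes = np.convolve(angles, c[::-1], mode="valid") / (c @ c * sample_interval_h)
    return float(slopes.max())


def pearson_matrix(table: pd.DataFrame, min_periods: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of a trait table.

    Zero-variance columns yield NaN entries and a warning.
    """
    table = table.astype(float)
    degenerate = [c for c in table.columns if table[c].dropna().nunique() <= 1]
    if degenerate:
        warnings.warn(
            f"zero-variance columns produce undefined correlations: {degenerate}",
            stacklevel=2,
        )
    return table.corr(method="pearson", min_periods=min_periods)


def _inv_sqrt(S: np.ndarray, names: list[str], label: str) -> np.ndarray:
    vals, vecs = linalg.eigh(S)
    tol = max(S.shape[0], 1) * np.finfo(float).eps * max(vals.max(), 0.0)
    if vals.min() <= tol:
        raise ValueError(
            f"{label} block is rank-deficient (collinear columns among {names})"
        )
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def cca(
    x_block: pd.DataFrame | np.ndarray,
    y_block: pd.DataFrame | np.ndarray,
    sign_column: int = 0,
) -> CCASolution:
    """First canonical correlation between two z-scored blocks.

    Both blocks are z-scored column-wise (sample SD); the first canonical
    pair comes from the SVD of the whitened cross-covariance
    Sxx^{-1/2} Sxy Syy^{-1/2}.  Weights are scaled so the canonical
    variates have unit sample variance; the overall sign is fixed so the
    x-weight in ``sign_column`` is nonnegative (falling back to a positive
    weight sum if that entry is zero).
    """
    x_names = list(x_block.columns) if isinstance(x_block, pd.DataFrame) else None
    y_names = list(y_block.columns) if isinstance(y_block, pd.DataFrame) else None
    X = np.asarray(x_block, dtype=float)
    Y = np.asarray(y_block, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("blocks must have the same number of rows")
    n, p = X.shape
    q = Y.shape[1]
    if n <= p + q:
        raise ValueError(f"need more rows than total columns ({n} <= {p + q})")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("CCA requires complete rows; drop missing values first")

    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    Yz = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
    Sxx = Xz.T @ Xz / (n - 1)
    Syy = Yz.T @ Yz / (n - 1)
    Sxy = Xz.T @ Yz / (n - 1)
    Wx = _inv_sqrt(Sxx, x_names or [f"x{i}" for i in range(p)], "x")
    Wy = _inv_sqrt(Syy, y_names or [f"y{i}" for i in range(q)], "y")
    U, s, Vt = linalg.svd(Wx @ Sxy @ Wy)
    a = Wx @ U[:, 0]
    b = Wy @ Vt[0, :]
    corr = float(min(s[0], 1.0))
    # sign convention
    ref = a[sign_column] if a[sign_column] != 0 else a.sum()
    if ref < 0:
        a, b = -a, -b
    return CCASolution(
        x_weights=a,
        y_weights=b,
        x_scores=Xz @ a,
        y_scores=Yz @ b,
        correlation=corr,
    )


def cca_permutation_threshold(
    x_block: pd.DataFrame | np.ndarray,
    y_block: pd.DataFrame | np.ndarray,
    n_perm: int = 1000,
    quantile: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation null quantile for the first canonical correlation.

    Rows of the y block are shuffled against the x block ``n_perm`` times
    (breaking the pairing while preserving within-block structure); the
    empirical ``quantile`` of the resulting correlations is returned.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Y = np.asarray(y_block, dtype=float)
    vals = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(Y.shape[0])
        vals[i] = cca(x_block, Y[perm]).correlation
    return float(np.quantile(vals, quantile))
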
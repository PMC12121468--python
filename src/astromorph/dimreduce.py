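"""Feature scaling, correlation-matrix PCA, and component retention.

Components are retained by the conjunction of Kaiser's criterion
(eigenvalue > 1 on the correlation matrix) and Horn's parallel analysis
(eigenvalue above the per-rank 95th percentile of eigenvalues from
equally-sized standard-normal null data).  Retention is a leading prefix:
component k is kept only if every earlier component is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ScaledMatrix:
    """Column-wise z-scored data with the statistics for the inverse map."""

    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    columns: list[str] | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def inverse(self, scaled: np.ndarray | None = None) -> np.ndarray:
        """Map z-scores back to the original feature scale."""
        z = self.values if scaled is None else scaled
        return z * self.column_sds + self.column_means


@dataclass
class PCARetention:
    """Eigenstructure of the correlation-matrix PCA plus retention counts."""

    eigenvalues: np.ndarray
    loadings: np.ndarray  # features x components
    scores: np.ndarray  # cells x components
    kaiser_k: int = 0
    horn_k: int = 0
    retained_k: int = 0
    horn_thresholds: np.ndarray | None = None

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.retained_k]


def zscale(
    table: pd.DataFrame | np.ndarray,
    log10_features: list[str] | None = None,
    log10p_features: list[str] | None = None,
) -> ScaledMatrix:
    """Column-wise z-scores (n-1 standard deviation).

    ``log10_features`` names columns to log10-transform before scaling
    (for strictly positive right-skewed features); ``log10p_features``
    applies log10(1 + x) instead, for skewed counts that may be zero.
    Transforms require a DataFrame input.
    """
    if isinstance(table, pd.DataFrame):
        columns = list(table.columns)
        X = table.to_numpy(dtype=float).copy()
        for name in log10_features or []:
            j = columns.index(name)
            if (X[:, j] <= 0).any():
                raise ValueError(
                    f"log10 transform of {name!r}: non-positive values"
                )
            X[:, j] = np.log10(X[:, j])
        for name in log10p_features or []:
            j = columns.index(name)
            if (X[:, j] < 0).any():
                raise ValueError(
                    f"log10(1+x) transform of {name!r}: negative values"
                )
            X[:, j] = np.log10(1.0 + X[:, j])
    else:
        if log10_features or log10p_features:
            raise ValueError("feature transforms require a DataFrame input")
        columns = None
        X = np.asarray(table, dtype=float).copy()
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in feature table")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if len(bad):
        name = columns[bad[0]] if columns else f"column {bad[0]}"
        raise ValueError(f"constant feature cannot be scaled: {name}")
    return ScaledMatrix(
        values=(X - means) / sds,
        column_means=means,
        column_sds=sds,
        columns=columns,
    )


def _corr_eigh(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted (descending) eigenvalues/vectors of the correlation matrix."""
    n = Z.shape[0]
    corr = (Z.T @ Z) / (n - 1)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


def pca(scaled: ScaledMatrix) -> PCARetention:
    """PCA on the correlation matrix (eigendecomposition of corr(Z)).

    Component signs are fixed so that the largest-magnitude entry of each
    loading column is positive.  Scores are Z @ loadings.
    """
    Z = scaled.values
    if not np.isfinite(Z).all():
        raise ValueError("non-finite values")
    n, p = Z.shape
    if n <= p:
        logger.warning("PCA with n (%d) <= p (%d): unstable eigenvalues", n, p)
    eigenvalues, loadings = _corr_eigh(Z)
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    return PCARetention(
        eigenvalues=np.clip(eigenvalues, 0.0, None),
        loadings=loadings,
        scores=Z @ loadings,
    )


def kaiser(eigenvalues: np.ndarray) -> int:
    """Number of leading correlation-matrix eigenvalues strictly above 1."""
    above = np.asarray(eigenvalues) > 1.0
    if above.all():
        return len(above)
    return int(np.argmin(above))


def horn_parallel(
    scaled: ScaledMatrix,
    n_iter: int = 1000,
    quantile: float = 0.95,
    seed: int | np.random.Generator | None = None,
    method: str = "quantile",
) -> tuple[int, np.ndarray]:
    """Horn's parallel analysis for correlation-matrix PCA.

    Simulates ``n_iter`` datasets of the same shape with independent
    standard-normal entries and takes the per-rank ``quantile`` (or mean,
    with ``method='mean'``) of their sorted eigenvalues as thresholds.
    Returns the length of the leading run of observed eigenvalues exceeding
    both their rank's threshold and 1, together with the thresholds.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    rng = np.random.default_rng(seed)
    n, p = scaled.shape
    sim = np.empty((n_iter, p))
    for it in range(n_iter):
        Znull = rng.standard_normal((n, p))
        Znull = (Znull - Znull.mean(axis=0)) / Znull.std(axis=0, ddof=1)
        sim[it] = _corr_eigh(Znull)[0]
    if method == "quantile":
        thresholds = np.quantile(sim, quantile, axis=0)
    elif method == "mean":
        thresholds = sim.mean(axis=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    observed = _corr_eigh(scaled.values)[0]
    passing = (observed > thresholds) & (observed > 1.0)
    k = len(passing) if passing.all() else int(np.argmin(passing))
    return k, thresholds


def retain(
    pca_out: PCARetention,
    kaiser_k: int,
    horn_k: int,
    min_components: int | None = None,
) -> PCARetention:
    """Fix the retained component count as the Kaiser AND Horn leading prefix.

    Both criteria are leading-run counts, so their conjunction is their
    minimum.  A result of zero raises unless ``min_components`` supplies a
    floor (2 is the usual choice for downstream clustering).
    """
    k = min(int(kaiser_k), int(horn_k))
    if k == 0:
        if min_components is None:
            raise ValueError(
                "no component passes both Kaiser and Horn; set "
                "min_components (e.g. 2) to impose a floor"
            )
        logger.warning("retention floor applied: 0 -> %d", min_components)
        k = min_components
    if min_components is not None:
        k = max(k, min_components)
    k = min(k, pca_out.scores.shape[1])
    pca_out.kaiser_k = int(kaiser_k)
    pca_out.horn_k = int(horn_k)
    pca_out.retained_k = int(k)
    return pca_out


def fit_retained_pca(
    table: pd.DataFrame | np.ndarray,
    n_iter: int = 1000,
    quantile: float = 0.95,
    seed: int | np.random.Generator | None = None,
    min_components: int | None = 2,
    log10_features: list[str] | None = None,
    log10p_features: list[str] | None = None,
) -> tuple[ScaledMatrix, PCARetention]:
    """Scale, run PCA and apply Kaiser + Horn retention in one call."""
    scaled = zscale(
        table, log10_features=log10_features, log10p_features=log10p_features
    )
    out = pca(scaled)
    k_kaiser = kaiser(out.eigenvalues)
    k_horn, thresholds = horn_parallel(
        scaled, n_iter=n_iter, quantile=quantile, seed=seed
    )
    out.horn_thresholds = thresholds
    out = retain(out, k_kaiser, k_horn, min_components=min_components)
    logger.info(
        "PCA retention: kaiser=%d horn=%d retained=%d (eigenvalues %s)",
        k_kaiser,
        k_horn,
        out.retained_k,
        np.round(out.eigenvalues, 3),
    )
    return scaled, out
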
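"""Discriminant analysis of principal components (DAPC).

A multi-class linear discriminant analysis fitted on retained PC scores
with cluster labels from the clustering stage: the between/within scatter
eigenproblem yields at most k - 1 discriminant axes, and per-cell posterior
cluster memberships follow from a shared-covariance Gaussian model in
discriminant space (uniform priors).  Reassigning each cell to its
maximum-posterior cluster refines the initial partition; a variable
contribution filter then keeps only features that both separate the
clusters strongly (|within-cluster mean z-score| > 0.7 somewhere) and
differ significantly between clusters (Kruskal-Wallis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class DAPCModel:
    """Fitted discriminant model in retained-PC space."""

    n_pcs_retained: int
    classes: np.ndarray  # cluster ids, ascending
    discriminant_axes: np.ndarray  # PCs x (k-1), within-class metric normalised
    axis_eigenvalues: np.ndarray
    class_means_da: np.ndarray  # class centroids in discriminant space
    posteriors: np.ndarray  # cells x k, rows sum to 1
    reassigned_labels: np.ndarray
    variable_contributions: pd.DataFrame | None = None

    def transform(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, float) @ self.discriminant_axes

    def posterior(self, scores: np.ndarray) -> np.ndarray:
        """Posterior cluster membership for new points (uniform priors)."""
        z = self.transform(scores)
        d2 = ((z[:, None, :] - self.class_means_da[None, :, :]) ** 2).sum(axis=2)
        log_post = -0.5 * d2
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        return post / post.sum(axis=1, keepdims=True)


def fit_dapc(
    scores: np.ndarray, labels: np.ndarray, ridge: float = 1e-8
) -> DAPCModel:
    """Fit multi-class LDA on PC scores with the given cluster labels.

    Solves the generalized eigenproblem S_b a = lambda S_w a with the pooled
    within-class covariance S_w (ridge-regularised if singular); eigenvectors
    are normalised in the within-class metric (a' S_w a = 1), so the shared
    within-class covariance in discriminant space is the identity and
    posteriors reduce to softmax of minus half the squared distance to class
    centroids.
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    classes = np.unique(labels)
    k = len(classes)
    if k < 2:
        raise ValueError("need >= 2 clusters")
    grand = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        sub = X[labels == c]
        mu = sub.mean(axis=0)
        diff = sub - mu
        Sw += diff.T @ diff
        Sb += len(sub) * np.outer(mu - grand, mu - grand)
    Sw /= n - k
    Sb /= n - 1 if n > 1 else 1
    try:
        w, v = sla.eigh(Sb, Sw)
    except (np.linalg.LinAlgError, sla.LinAlgError):
        logger.warning("within-class scatter singular; ridge %g added", ridge)
        w, v = sla.eigh(Sb, Sw + ridge * np.eye(d))
    order = np.argsort(w)[::-1][: k - 1]
    axes = v[:, order]
    eigvals = np.clip(w[order], 0.0, None)
    # scipy normalises v' Sw v = I already; fix signs for determinism
    flip = np.sign(axes[np.abs(axes).argmax(axis=0), np.arange(axes.shape[1])])
    flip[flip == 0] = 1.0
    axes = axes * flip

    z = X @ axes
    means_da = np.vstack([z[labels == c].mean(axis=0) for c in classes])
    model = DAPCModel(
        n_pcs_retained=d,
        classes=classes,
        discriminant_axes=axes,
        axis_eigenvalues=eigvals,
        class_means_da=means_da,
        posteriors=np.empty((0, k)),
        reassigned_labels=labels.copy(),
    )
    model.posteriors = model.posterior(X)
    model.reassigned_labels = classes[np.argmax(model.posteriors, axis=1)]
    return model


def refine_partition(
    model: DAPCModel, labels: np.ndarray
) -> np.ndarray:
    """One round of maximum-posterior reassignment of cells to clusters.

    A cluster emptied by reassignment keeps its single highest-posterior
    cell (with a warning) so that every cluster stays non-empty.  The moved
    fraction is logged.
    """
    labels = np.asarray(labels)
    refined = model.reassigned_labels.copy()
    for j, c in enumerate(model.classes):
        if (refined == c).sum() == 0:
            keep = int(np.argmax(model.posteriors[:, j]))
            logger.warning(
                "cluster %s emptied by DAPC reassignment; keeping cell %d",
                c, keep,
            )
            refined[keep] = c
    moved = float((refined != labels).mean())
    logger.info("DAPC refinement moved %.1f%% of cells", 100 * moved)
    return refined


def variable_contribution_filter(
    feature_table_z: pd.DataFrame,
    labels: np.ndarray,
    threshold: float = 0.7,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Filter features for cluster characterisation.

    The contribution of a feature to a cluster is the absolute mean of its
    z-scores within that cluster.  A feature is retained iff its maximum
    contribution over clusters exceeds ``threshold`` and a Kruskal-Wallis
    test across clusters is significant at ``alpha``.  Returns the retained
    feature names and a per-feature report (contributions per cluster, max,
    KW p-value, retained flag).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 clusters")
    rows = []
    for feat in feature_table_z.columns:
        col = feature_table_z[feat].to_numpy(dtype=float)
        contrib = {
            f"contribution_c{c}": abs(float(np.nanmean(col[labels == c])))
            for c in classes
        }
        groups = [col[labels == c] for c in classes]
        groups = [g[np.isfinite(g)] for g in groups]
        if all(len(g) for g in groups) and np.ptp(np.concatenate(groups)) > 0:
            _, p = sps.kruskal(*groups)
        else:
            p = 1.0  # degenerate: constant feature or empty group
        max_contrib = max(contrib.values())
        rows.append(
            {
                "feature": feat,
                **contrib,
                "max_contribution": max_contrib,
                "kw_p": float(p),
                "retained": bool(max_contrib > threshold and p < alpha),
            }
        )
    report = pd.DataFrame(rows).set_index("feature")
    retained = report.index[report["retained"]].tolist()
    dropped = report.index[~report["retained"]].tolist()
    if dropped:
        logger.info("variable filter dropped: %s", dropped)
    return retained, report
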
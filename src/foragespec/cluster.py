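"""Ward clustering of individual × stage foraging profiles.

Profiles are standardized (z-scores; circular mean heading enters as a
cos/sin pair), agglomerated with Euclidean distance and Ward's criterion, and
the cluster count is chosen at the largest relative jump in merge heights —
a height-gap surrogate for inertia-based cluster-count selection.  Merge
heights are expressed as the increase in within-cluster sum of squares
(Ward.D2 convention: delta_SS = d**2 / 2 for the pairwise Euclidean linkage
distance d).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .errors import InsufficientDataError
from .varcomp import loglik_ml

logger = logging.getLogger(__name__)

DEFAULT_FEATURES = [
    "mean_total_distance_km", "mean_max_distance_km", "mean_duration_h",
    "cv_total_distance", "sd_heading", "consistency_index",
]


def standardize(features: pd.DataFrame,
                heading_col: str = "mean_heading_deg") -> pd.DataFrame:
    """Z-score feature columns; encode the circular heading as (cos, sin).

    Zero-variance columns are dropped with a warning.  Uses the n-1 sample SD.
    """
    if len(features) < 2:
        raise InsufficientDataError("standardization needs at least two rows")
    out = features.copy()
    if heading_col in out.columns:
        rad = np.radians(out.pop(heading_col).to_numpy(float))
        out["heading_cos"] = np.cos(rad)
        out["heading_sin"] = np.sin(rad)
    for col in list(out.columns):
        x = out[col].to_numpy(float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            logger.warning("dropping zero-variance feature column %r", col)
            out = out.drop(columns=[col])
        else:
            out[col] = (x - x.mean()) / sd
    return out


@dataclass
class ClusterSolution:
    """Dendrogram, chosen cluster count and row labels."""

    linkage: np.ndarray          # scipy linkage matrix (Euclidean-Ward heights)
    heights_ss: np.ndarray       # within-cluster SS increase per merge
    k: int
    labels: np.ndarray           # cluster ids 1..k, in row order

    @property
    def merge_history(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h))
                for (a, b), h in zip(self.linkage[:, :2], self.heights_ss)]


def ward_cluster(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ward agglomeration; returns (scipy linkage matrix, delta-SS heights).

    Heights in the returned second array are the increase in within-cluster
    sum of squares at each merge; they are non-decreasing and sum to the total
    within-SS of the one-cluster solution.
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2 or len(X) < 3:
        raise InsufficientDataError("Ward clustering needs at least three rows")
    Z = hierarchy.linkage(X, method="ward")
    heights_ss = Z[:, 2] ** 2 / 2.0
    return Z, heights_ss


def choose_k(heights_ss: np.ndarray, k_max: int = 8) -> int:
    """Cluster count at the largest relative jump between successive merge heights.

    For candidate k, the score is the height of the merge that collapses k
    clusters into k-1, relative to the preceding merge; the k with the
    largest score (smallest k on ties) is returned, searched over
    2..min(k_max, n_rows - 1).
    """
    h = np.asarray(heights_ss, float)
    n = len(h) + 1
    best_k, best_score = 2, -np.inf
    for k in range(2, min(k_max, n - 1) + 1):
        top = h[n - k]          # merge reducing k -> k-1 clusters
        prev = h[n - k - 1]     # merge reducing k+1 -> k
        score = top / prev if prev > 0 else (np.inf if top > 0 else 1.0)
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def cut_labels(Z: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster ids 1..k, renumbered by first appearance in row order."""
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    mapping: dict[int, int] = {}
    labels = np.empty(len(raw), int)
    for i, r in enumerate(raw):
        mapping.setdefault(r, len(mapping) + 1)
        labels[i] = mapping[r]
    return labels


def cluster_profiles(features: pd.DataFrame, k: int | None = None,
                     k_max: int = 8) -> ClusterSolution:
    """Standardize, agglomerate and cut: the full strategy-clustering step."""
    M = standardize(features)
    Z, heights = ward_cluster(M)
    if k is None:
        k = choose_k(heights, k_max=k_max)
    return ClusterSolution(linkage=Z, heights_ss=heights, k=k, labels=cut_labels(Z, k))


def compare_clusters(labels, response, individual) -> dict:
    """Does cluster membership explain a response beyond individual identity?

    Likelihood-ratio comparison (ML) of random-intercept models with and
    without the cluster factor, plus descriptive pairwise Welch t-tests
    between clusters with >= 2 rows (singletons excluded with a warning).
    """
    labels = np.asarray(labels)
    y = np.asarray(response, float)
    individual = np.asarray(individual)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise InsufficientDataError("need at least two clusters")
    X0 = np.ones((len(y), 1))
    dummies = pd.get_dummies(pd.Categorical(labels), drop_first=True).to_numpy(float)
    X1 = np.column_stack([X0, dummies])
    ll0 = loglik_ml(y, X0, individual)
    ll1 = loglik_ml(y, X1, individual)
    lr = max(0.0, 2.0 * (ll1 - ll0))
    df = len(uniq) - 1
    p = float(stats.chi2.sf(lr, df))
    F, p_F = stats.f_oneway(*(y[labels == u] for u in uniq))

    pairwise = []
    sizes = {u: int((labels == u).sum()) for u in uniq}
    for u in uniq:
        if sizes[u] < 2:
            logger.warning("cluster %s is a singleton; excluded from pairwise tests", u)
    multi = [u for u in uniq if sizes[u] >= 2]
    for i, a in enumerate(multi):
        for b in multi[i + 1:]:
            ya, yb = y[labels == a], y[labels == b]
            t, pw = stats.ttest_ind(ya, yb, equal_var=False)
            pairwise.append({"a": a, "b": b,
                             "diff": float(ya.mean() - yb.mean()),
                             "t": float(t), "p": float(pw)})
    return {"lr": lr, "df": df, "p": p,
            "F": float(F), "p_F": float(p_F), "pairwise": pairwise}
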
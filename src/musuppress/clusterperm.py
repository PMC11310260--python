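"""Cluster-based sign-flip permutation testing of paired MSI contrasts.

Per-vertex paired t-tests are thresholded at a two-sided critical value,
supra-threshold vertices are grouped into connected same-sign clusters on
the mesh adjacency, and each observed cluster's signed t-sum is compared
against a permutation distribution of the extreme (largest-|sum|, sign
kept) cluster sum obtained by flipping the sign of each subject's
difference map — the exchangeability-preserving relabeling for a paired
before/after design.  Clusters below the 2.5th or above the 97.5th
percentile of that distribution are flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .core import InvalidGraphError, InvalidInputError, PairingError
from .msi import MSITable


@dataclass
class Cluster:
    vertices: tuple[int, ...]
    sum_t: float
    p: float = np.nan
    significant: bool = False

    @property
    def size(self) -> int:
        return len(self.vertices)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    threshold_t: float
    null_distribution: np.ndarray
    n_permutations: int
    seed: int | None = None
    percentiles: tuple[float, float] = (np.nan, np.nan)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cluster": i, "size": c.size, "sum_t": c.sum_t, "p": c.p,
             "significant": c.significant,
             "vertices": " ".join(map(str, c.vertices))}
            for i, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(
            rows, columns=["cluster", "size", "sum_t", "p", "significant",
                           "vertices"],
        )


def paired_differences(msi_a: MSITable, msi_b: MSITable) -> np.ndarray:
    """Per-subject per-vertex MSI differences (B - A), aligned on
    subject and location labels."""
    pa = msi_a.table.pivot_table(index="subject", columns="location",
                                 values="msi", sort=True)
    pb = msi_b.table.pivot_table(index="subject", columns="location",
                                 values="msi", sort=True)
    if not pa.index.equals(pb.index) or not pa.columns.equals(pb.columns):
        raise PairingError("subject or vertex sets differ between sessions")
    if pa.isna().any().any() or pb.isna().any().any():
        raise PairingError("missing cells in paired MSI tables")
    return (pb - pa).to_numpy(dtype=float)


def t_from_differences(diffs: np.ndarray) -> np.ndarray:
    """One-sample t per column of a (subjects x vertices) difference array.

    Zero-variance columns get t = 0 (documented rule; keeps null
    simulations well-defined).
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    if n < 2:
        raise InvalidInputError("need >= 2 subjects")
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    return t


def paired_t_map(msi_a, msi_b) -> np.ndarray:
    """Per-vertex paired t (session B minus session A), df = n - 1."""
    if isinstance(msi_a, MSITable):
        diffs = paired_differences(msi_a, msi_b)
    else:
        a = np.asarray(msi_a, dtype=float)
        b = np.asarray(msi_b, dtype=float)
        if a.shape != b.shape:
            raise PairingError("paired arrays must have identical shape")
        diffs = b - a
    return t_from_differences(diffs)


def _check_adjacency(adjacency: np.ndarray) -> sparse.csr_matrix:
    adj = np.asarray(adjacency)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise InvalidGraphError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise InvalidGraphError("adjacency must be symmetric")
    adj = adj.copy()
    np.fill_diagonal(adj, 0)
    return sparse.csr_matrix(adj != 0)


def _clusters_from_t(
    t_map: np.ndarray, adj: sparse.csr_matrix, threshold_t: float
) -> list[Cluster]:
    """Maximal connected same-sign components of supra-threshold vertices."""
    clusters: list[Cluster] = []
    for sign in (1.0, -1.0):
        mask = sign * t_map > threshold_t
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        sub = adj[np.ix_(idx, idx)]
        n_comp, labels = connected_components(sub, directed=False)
        for k in range(n_comp):
            members = idx[labels == k]
            clusters.append(Cluster(tuple(int(v) for v in members),
                                    float(t_map[members].sum())))
    clusters.sort(key=lambda c: -abs(c.sum_t))
    return clusters


def form_clusters(
    t_map: np.ndarray,
    adjacency: np.ndarray,
    alpha: float = 0.05,
    df: int | None = None,
    threshold_t: float | None = None,
) -> tuple[list[Cluster], float]:
    """Threshold a t-map two-sidedly and form adjacency clusters.

    The cluster-forming threshold is the two-tailed t critical value at
    alpha with the given df unless threshold_t is supplied directly.
    Returns (clusters, threshold_t); cluster statistic = signed sum of
    member t values.
    """
    if threshold_t is None:
        if df is None or df < 1:
            raise InvalidInputError("df >= 1 required to derive the threshold")
        threshold_t = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    adj = _check_adjacency(adjacency)
    return _clusters_from_t(np.asarray(t_map, dtype=float), adj, threshold_t), threshold_t


def _extreme_sum(clusters: list[Cluster]) -> float:
    if not clusters:
        return 0.0
    return max((c.sum_t for c in clusters), key=abs)


def permutation_test(
    differences: np.ndarray,
    adjacency: np.ndarray,
    n_perm: int = 1000,
    alpha_cluster: float = 0.05,
    seed: int | None = 0,
) -> ClusterResult:
    """Sign-flip cluster permutation test of per-subject difference maps.

    Each repetition flips every subject's difference map by an independent
    +/-1, recomputes the t-map and clusters, and records the signed
    extreme cluster sum (0 when no cluster forms).  An observed cluster
    is significant when its sum lies below the 2.5th or above the 97.5th
    percentile of that null; per-cluster p is the two-sided exceedance
    proportion with the observed statistic included (+1 correction), so
    p >= 1/(n_perm + 1) always.
    """
    diffs = np.asarray(differences, dtype=float)
    if diffs.ndim != 2:
        raise InvalidInputError("differences must be (subjects x vertices)")
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    n = diffs.shape[0]
    adj = _check_adjacency(adjacency)
    threshold_t = float(stats.t.ppf(1.0 - alpha_cluster / 2.0, n - 1))

    t_obs = t_from_differences(diffs)
    clusters = _clusters_from_t(t_obs, adj, threshold_t)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for r in range(n_perm):
        signs = rng.choice((-1.0, 1.0), size=n)
        t_perm = t_from_differences(signs[:, None] * diffs)
        null[r] = _extreme_sum(_clusters_from_t(t_perm, adj, threshold_t))

    lo, hi = np.quantile(null, [alpha_cluster / 2.0, 1.0 - alpha_cluster / 2.0])
    for c in clusters:
        c.p = float((1 + np.sum(np.abs(null) >= abs(c.sum_t))) / (n_perm + 1))
        c.significant = bool(c.sum_t < lo or c.sum_t > hi)
    return ClusterResult(
        clusters=clusters, t_map=t_obs, threshold_t=threshold_t,
        null_distribution=null, n_permutations=n_perm, seed=seed,
        percentiles=(float(lo), float(hi)),
    )
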
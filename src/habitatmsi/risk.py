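"""Unsupervised risk stratification from MSI feature profiles.

Patients are compared by the Spearman rank correlation of their MSI
feature profiles (distance 1 - rho), clustered with PAM-style k-medoids,
and stabilized by consensus clustering over repeated subsamples for
k = 2..5.  The number of risk groups is chosen by the silhouette
coefficient (Calinski-Harabasz as tiebreak) computed in consensus-
distance space, and at k = 2 the cluster with the higher observed event
fraction is labeled high risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances, silhouette_score


def spearman_distance(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise 1 - Spearman-rho between patient feature profiles (rows)."""
    X = np.asarray(table, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    ranks = np.apply_along_axis(rankdata, 1, X)
    sd = ranks.std(axis=1)
    if np.any(sd == 0):
        bad = np.nonzero(sd == 0)[0]
        ids = (
            list(np.asarray(table.index)[bad])
            if isinstance(table, pd.DataFrame)
            else bad.tolist()
        )
        raise ValueError(f"constant feature profile for patient(s) {ids}")
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    corr = (centered @ centered.T) / np.outer(sd, sd) / X.shape[1]
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(0.5 * (d + d.T), 0.0, 2.0)


def feature_distance(table: pd.DataFrame | np.ndarray, metric: str) -> np.ndarray:
    """Patient-by-patient distance matrix under a named metric."""
    if metric == "spearman":
        return spearman_distance(table)
    if metric in ("euclidean", "manhattan"):
        X = np.asarray(table, dtype=float)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        Xs = (X - mu) / np.where(sd == 0, 1.0, sd)
        return pairwise_distances(Xs, metric=metric)
    raise ValueError(f"unknown metric {metric!r}")


def _pam_cost(dist: np.ndarray, medoids: list[int]) -> float:
    return float(dist[:, medoids].min(axis=1).sum())


def kmedoids_cluster(dist: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """PAM k-medoids: greedy build phase, then swap until no improvement.

    Fully deterministic (the greedy build needs no randomness; ties break
    toward the lower index).  Returns 0-based labels.
    """
    n = dist.shape[0]
    if not (1 <= k < n) and k != n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    # build
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    while len(medoids) < k:
        cur = dist[:, medoids].min(axis=1)
        # gain of adding each candidate
        gains = np.minimum(dist, cur[None, :]).sum(axis=0)
        gains[medoids] = np.inf
        medoids.append(int(np.argmin(gains)))
    # swap
    improved = True
    while improved:
        improved = False
        cost = _pam_cost(dist, medoids)
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            d_excl = (
                dist[:, others].min(axis=1)
                if others
                else np.full(n, np.inf)
            )
            # cost for every candidate replacement h at once
            cand_cost = np.minimum(d_excl[:, None], dist).sum(axis=0)
            cand_cost[medoids] = np.inf
            h = int(np.argmin(cand_cost))
            delta = cand_cost[h] - cost
            if delta < best[0] - 1e-12:
                best = (float(delta), mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            improved = True
    medoids = sorted(medoids)
    labels = np.argmin(dist[:, medoids], axis=1)
    return labels.astype(np.int32)


def _classical_mds(dist: np.ndarray, n_components: int = 10) -> np.ndarray:
    """Classical MDS coordinates of a distance matrix (for running
    k-means under non-Euclidean metrics)."""
    n = dist.shape[0]
    d2 = dist**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    keep = min(n_components, int((w > 1e-10).sum()))
    keep = max(keep, 1)
    return v[:, :keep] * np.sqrt(np.maximum(w[:keep], 0.0))


def _cluster_submatrix(
    dist_sub: np.ndarray,
    coords_sub: np.ndarray | None,
    k: int,
    algorithm: str,
    seed: int,
) -> np.ndarray:
    if algorithm == "kmedoids":
        return kmedoids_cluster(dist_sub, k, seed=seed)
    if algorithm == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(coords_sub)
        return km.labels_.astype(np.int32)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def ch_from_distances(dist: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index computed from pairwise distances alone,
    treating them as Euclidean: within-cluster SS via the pairwise-
    squared-distance identity."""
    n = len(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2 or k >= n:
        raise ValueError("need 2 <= k < n clusters")
    d2 = dist**2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for c in uniq:
        idx = np.nonzero(labels == c)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_between = max(ss_total - ss_within, 0.0)
    if ss_within <= 0:
        return np.inf
    return float((ss_between / (k - 1)) / (ss_within / (n - k)))


@dataclass
class ConsensusResult:
    consensus: dict[int, np.ndarray]  # k -> n x n matrix
    labels: dict[int, np.ndarray]  # k -> final labels (0-based)
    metrics: pd.DataFrame  # columns k, silhouette, ch_score
    chosen_k: int | None
    subsample_fraction: float
    n_repeats: int
    seed: int
    metric: str = "spearman"
    algorithm: str = "kmedoids"


def consensus_cluster(
    table: pd.DataFrame | np.ndarray,
    k_range: tuple[int, ...] = (2, 3, 4, 5),
    n_repeats: int = 100,
    fraction: float = 0.8,
    seed: int = 0,
    metric: str = "spearman",
    algorithm: str = "kmedoids",
) -> ConsensusResult:
    """Consensus clustering over repeated patient subsamples.

    For each k, ``n_repeats`` subsamples of ``ceil(fraction * n)``
    patients are clustered; consensus(i, j) is the fraction of
    co-sampled repeats in which i and j landed in the same cluster.
    Final labels per k come from k-medoids on (1 - consensus), and the
    per-k silhouette / CH metrics are computed in that same consensus-
    distance space.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(table, dtype=float)
    n = X.shape[0]
    dist = feature_distance(table, metric)
    coords = _classical_mds(dist) if algorithm == "kmeans" else None
    m = int(np.ceil(fraction * n))
    rng = np.random.default_rng(seed)
    consensus: dict[int, np.ndarray] = {}
    final_labels: dict[int, np.ndarray] = {}
    rows = []
    for k in k_range:
        together = np.zeros((n, n))
        sampled = np.zeros((n, n))
        for _ in range(n_repeats):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            sub = dist[np.ix_(idx, idx)]
            lab = _cluster_submatrix(
                sub,
                coords[idx] if coords is not None else None,
                k,
                algorithm,
                seed,
            )
            sampled[np.ix_(idx, idx)] += 1
            same = lab[:, None] == lab[None, :]
            together[np.ix_(idx, idx)] += same
        never = (sampled == 0) & ~np.eye(n, dtype=bool)
        if never.any():
            warnings.warn(
                f"{int(never.sum() // 2)} patient pairs were never "
                "co-sampled; their consensus entries are 0",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore"):
            cons = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = 0.5 * (cons + cons.T)
        cdist = 1.0 - cons
        np.fill_diagonal(cdist, 0.0)
        lab = kmedoids_cluster(cdist, k, seed=seed)
        if len(np.unique(lab)) < 2:
            sil = -1.0
            ch = 0.0
        else:
            sil = float(silhouette_score(cdist, lab, metric="precomputed"))
            ch = ch_from_distances(cdist, lab)
        consensus[k] = cons
        final_labels[k] = lab
        rows.append({"k": k, "silhouette": sil, "ch_score": ch})
    return ConsensusResult(
        consensus=consensus,
        labels=final_labels,
        metrics=pd.DataFrame(rows),
        chosen_k=None,
        subsample_fraction=fraction,
        n_repeats=n_repeats,
        seed=seed,
        metric=metric,
        algorithm=algorithm,
    )


def select_k(result: ConsensusResult | pd.DataFrame) -> int:
    """argmax silhouette over k; exact ties resolved by the larger CH."""
    metrics = result.metrics if isinstance(result, ConsensusResult) else result
    t = metrics.sort_values(
        ["silhouette", "ch_score"], ascending=False, kind="stable"
    )
    chosen = int(t.iloc[0]["k"])
    if isinstance(result, ConsensusResult):
        result.chosen_k = chosen
    return chosen


@dataclass
class RiskAssignment:
    groups: pd.Series  # patient -> "high" / "low"
    rule: dict = field(default_factory=dict)


def label_risk_groups(
    labels: np.ndarray,
    records: pd.DataFrame,
) -> RiskAssignment:
    """Map the two clusters to high/low risk.

    The cluster with the higher observed event fraction is "high"; exact
    ties go to the cluster with the shorter median observed time.
    ``records`` needs columns time_months and event aligned with labels.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"expected 2 clusters, found {len(uniq)}")
    stats = {}
    for c in uniq:
        sel = labels == c
        if sel.sum() == 0:
            raise ValueError(f"cluster {c} is empty")
        stats[c] = (
            float(records.loc[sel, "event"].mean()),
            float(records.loc[sel, "time_months"].median()),
        )
    a, b = uniq
    if stats[a][0] != stats[b][0]:
        high = a if stats[a][0] > stats[b][0] else b
    else:
        high = a if stats[a][1] <= stats[b][1] else b
    groups = pd.Series(
        np.where(labels == high, "high", "low"),
        index=records.index,
        name="risk_group",
    )
    rule = {
        "rule": "higher event fraction = high risk; tie -> shorter median time",
        "event_fraction": {int(c): stats[c][0] for c in uniq},
        "median_time": {int(c): stats[c][1] for c in uniq},
        "high_cluster": int(high),
    }
    return RiskAssignment(groups=groups, rule=rule)
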
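"""Clustering of well-scored decoys and score-RMSD evaluation.

Scoring functions alone are imperfect discriminators of near-native poses;
clustering the best-scored decoys by mutual ligand RMSD and examining the
biggest clusters is markedly more robust.  The greedy scheme used here
repeatedly extracts the row of the RMSD matrix with the most neighbors
below a cutoff (default 5 A over the 100 best-scored decoys, with a
relaxed 10 A / 200-decoy fallback when nothing clusters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ClusterResult",
    "ThresholdStats",
    "EvaluationReport",
    "cluster_decoys",
    "relaxed_clustering_fallback",
    "cluster_with_fallback",
    "correlation_report",
    "rank_native",
]


@dataclass
class ClusterResult:
    clusters: list[list]          # decoy ids, largest cluster first
    representatives: list         # per-cluster id of the lowest-energy member
    cutoff: float
    top_n: int
    relaxed: bool = False

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def biggest(self, n: int = 3) -> list[list]:
        """The n biggest clusters (candidates for native-like groups)."""
        return self.clusters[:n]


def _validate_matrix(mat: np.ndarray) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("RMSD matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("RMSD matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0, atol=1e-8):
        raise ValueError("RMSD matrix must have a zero diagonal")


def cluster_decoys(
    decoy_ids: list,
    scores: np.ndarray,
    rmsd_matrix: np.ndarray,
    top_n: int = 100,
    cutoff: float = 5.0,
    relaxed: bool = False,
) -> ClusterResult:
    """Greedy RMSD clustering of the best-scored decoys.

    The ``top_n`` lowest-energy decoys are retained; then, repeatedly, the
    row with the largest number of off-diagonal RMSD entries below
    ``cutoff`` (ties broken toward the earlier input position) seeds a
    cluster of itself plus those neighbors, which are removed.  Iteration
    stops when no remaining row has a neighbor within the cutoff.  Clusters
    are reported largest first (size ties by representative score), each
    with its lowest-energy member as representative.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(decoy_ids)
    if n != len(scores) or rmsd_matrix.shape != (n, n):
        raise ValueError("decoy_ids, scores and rmsd_matrix sizes disagree")
    if n < 2:
        raise ValueError("clustering needs at least 2 decoys")
    _validate_matrix(np.asarray(rmsd_matrix, dtype=float))
    if top_n > n:
        warnings.warn(f"top_n={top_n} exceeds {n} decoys; using all", stacklevel=2)
        top_n = n

    order = np.argsort(scores, kind="stable")[:top_n]
    selected = np.sort(order)  # keep original input order within the selection
    sub = np.asarray(rmsd_matrix, dtype=float)[np.ix_(selected, selected)]
    active = list(range(len(selected)))
    clusters_idx: list[list[int]] = []
    while active:
        best_row, best_count = None, 0
        for row in active:
            count = sum(1 for col in active if col != row and sub[row, col] < cutoff)
            if count > best_count:
                best_row, best_count = row, count
        if best_row is None:
            break
        members = [best_row] + [
            col for col in active if col != best_row and sub[best_row, col] < cutoff
        ]
        clusters_idx.append(sorted(members))
        active = [a for a in active if a not in set(members)]

    def rep(members: list[int]) -> int:
        return min(members, key=lambda m: (scores[selected[m]], m))

    clusters_idx.sort(key=lambda ms: (-len(ms), scores[selected[rep(ms)]]))
    clusters = [[decoy_ids[selected[m]] for m in ms] for ms in clusters_idx]
    representatives = [decoy_ids[selected[rep(ms)]] for ms in clusters_idx]
    return ClusterResult(clusters, representatives, cutoff, top_n, relaxed)


def relaxed_clustering_fallback(
    primary: ClusterResult,
    decoy_ids: list,
    scores: np.ndarray,
    rmsd_matrix: np.ndarray,
    top_n: int = 200,
    cutoff: float = 10.0,
) -> ClusterResult:
    """Re-cluster with relaxed settings after an empty primary result.

    Used when the default (100 best decoys, 5 A) finds no clusters; the
    relaxed pass widens to the 200 best decoys and a 10 A threshold and the
    result is flagged accordingly.
    """
    if primary.n_clusters > 0:
        raise ValueError("fallback applies only after an empty primary clustering")
    return cluster_decoys(decoy_ids, scores, rmsd_matrix, top_n, cutoff, relaxed=True)


def cluster_with_fallback(
    decoy_ids: list, scores: np.ndarray, rmsd_matrix: np.ndarray,
    top_n: int = 100, cutoff: float = 5.0,
) -> ClusterResult:
    primary = cluster_decoys(decoy_ids, scores, rmsd_matrix, top_n, cutoff)
    if primary.n_clusters > 0:
        return primary
    return relaxed_clustering_fallback(primary, decoy_ids, scores, rmsd_matrix)


@dataclass
class ThresholdStats:
    threshold: float
    n_below: int
    pearson_r: float | None      # None when undefined (n < 3 or zero variance)
    std_error: float | None


@dataclass
class EvaluationReport:
    per_threshold: dict[float, ThresholdStats] = field(default_factory=dict)
    native_rank: int | None = None


def correlation_report(
    scores: np.ndarray,
    rmsds: np.ndarray,
    thresholds: tuple[float, ...] = (5.0, 10.0, 20.0),
    native_rank: int | None = None,
) -> EvaluationReport:
    """Pearson correlation between score and ligand RMSD per RMSD range.

    For each threshold, decoys with RMSD strictly below it are pooled; a
    positive correlation means better (lower) scores go with more
    native-like poses.  With fewer than three decoys, or zero variance in
    either vector, the coefficient is reported as undefined.  The standard
    error is sqrt((1 - r^2) / (n - 2)).
    """
    scores = np.asarray(scores, dtype=float)
    rmsds = np.asarray(rmsds, dtype=float)
    if scores.shape != rmsds.shape:
        raise ValueError("scores and rmsds must be paired vectors of equal length")
    report = EvaluationReport(native_rank=native_rank)
    for thr in thresholds:
        mask = rmsds < thr
        n = int(mask.sum())
        if n < 3:
            report.per_threshold[thr] = ThresholdStats(thr, n, None, None)
            continue
        s, r = scores[mask], rmsds[mask]
        if np.ptp(s) == 0 or np.ptp(r) == 0:
            report.per_threshold[thr] = ThresholdStats(thr, n, None, None)
            continue
        pr = float(stats.pearsonr(s, r).statistic)
        se = float(np.sqrt(max(0.0, 1.0 - pr * pr) / (n - 2)))
        report.per_threshold[thr] = ThresholdStats(thr, n, pr, se)
    return report


def rank_native(native_score: float, decoy_scores: np.ndarray) -> int:
    """1-based rank of the native among decoys; strictly lower scores beat it."""
    decoy_scores = np.asarray(decoy_scores, dtype=float)
    return 1 + int(np.count_nonzero(decoy_scores < native_score))
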
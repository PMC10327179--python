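"""Clustering of folded motif profiles into nucleosome-binding modes.

Per-TF motif profiles restricted to +/-60 bp around the dyad are folded
(the two symmetrical nucleosomal halves summed, exploiting the two-fold
symmetry of the nucleosome), min-max normalized, embedded in 2-D with
t-SNE and partitioned with k-medoids (PAM, k = 6 by default).  Cluster
members with silhouette width <= 0.25 are flagged as outliers.  Profiles
enter clustering only if they pass quality filters: at least 500 motif
base pairs on nucleosome regions and a symmetry correlation >= 0.4
between the two halves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_samples

from .profiles import MotifProfile, minmax_normalize

__all__ = [
    "ProfileQC",
    "FoldedProfile",
    "ClusterResult",
    "filter_profiles",
    "fold_profile",
    "embed_2d",
    "kmedoids_cluster",
    "cluster_report",
    "silhouette_scan",
]


@dataclass
class ProfileQC:
    """A motif profile with the quality metrics the filters act on."""

    profile: MotifProfile
    nr_motif_bp: int
    symmetry_pcc: float | None


@dataclass
class FoldedProfile:
    """Half-profile with mirrored offsets summed, min-max normalized."""

    tf_name: str
    values: np.ndarray  # offsets 0..half_width
    half_width: int
    cell_line: str = ""

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.half_width + 1)


@dataclass
class ClusterResult:
    labels: np.ndarray          # cluster id 1..k per profile
    medoid_indices: np.ndarray  # index into the input array, one per cluster
    silhouette: np.ndarray      # silhouette width per profile
    outlier: np.ndarray         # True where width <= threshold
    points: np.ndarray          # the coordinates that were clustered

    @property
    def k(self) -> int:
        return len(self.medoid_indices)


def filter_profiles(
    qcs: Sequence[ProfileQC],
    min_nr_motif_bp: int = 500,
    min_symmetry_pcc: float = 0.4,
) -> list[ProfileQC]:
    """Drop under-sampled profiles (< 500 motif bp on NRs) and profiles
    whose two halves correlate below 0.4 (or not at all)."""
    return [
        qc
        for qc in qcs
        if qc.nr_motif_bp >= min_nr_motif_bp
        and qc.symmetry_pcc is not None
        and qc.symmetry_pcc >= min_symmetry_pcc
    ]


def fold_profile(
    motif_profile: MotifProfile, half_width: int = 60
) -> FoldedProfile | None:
    """Sum the two mirrored halves and min-max normalize.

    ``value[o] = counts[+o] + counts[-o]`` for o >= 1 and ``counts[0]``
    at the dyad.  Returns None for a constant folded profile, whose
    normalization is undefined.
    """
    hw = motif_profile.half_width
    if hw < half_width:
        raise ValueError("profile too narrow to fold")
    c = motif_profile.counts.astype(float)
    folded = np.empty(half_width + 1)
    folded[0] = c[hw]
    for o in range(1, half_width + 1):
        folded[o] = c[hw + o] + c[hw - o]
    if np.ptp(folded) == 0:
        return None
    return FoldedProfile(
        motif_profile.tf_name,
        minmax_normalize(folded),
        half_width,
        cell_line=motif_profile.cell_line,
    )


def embed_2d(
    folded_profiles: Sequence[FoldedProfile],
    seed: int = 0,
    perplexity: float = 10.0,
    n_iter: int = 1000,
) -> np.ndarray:
    """t-SNE projection of folded profiles onto two dimensions."""
    n = len(folded_profiles)
    if n < 3 * perplexity:
        raise ValueError(
            f"need >= {int(3 * perplexity)} profiles for perplexity "
            f"{perplexity}; got {n} — consider clustering the profiles "
            "directly (embed=False)"
        )
    X = np.vstack([fp.values for fp in folded_profiles])
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=n_iter,
        init="pca",
        random_state=seed,
    )
    return tsne.fit_transform(X)


def _pam(dist: np.ndarray, k: int) -> np.ndarray:
    """Partitioning-around-medoids on a precomputed distance matrix.

    Deterministic: greedy BUILD initialization followed by best-improvement
    SWAP passes until no swap lowers the total within-cluster cost.
    """
    n = dist.shape[0]
    # BUILD: first medoid minimizes total distance, then greedy gain
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        nearest = dist[:, medoids].min(axis=1)
        gains = np.maximum(nearest[None, :] - dist, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids_arr = np.array(sorted(medoids))

    def cost(meds: np.ndarray) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    current = cost(medoids_arr)
    improved = True
    while improved:
        improved = False
        best = (current, medoids_arr)
        for mi in range(k):
            for h in range(n):
                if h in medoids_arr:
                    continue
                cand = medoids_arr.copy()
                cand[mi] = h
                c = cost(cand)
                if c < best[0] - 1e-12:
                    best = (c, np.sort(cand))
        if best[0] < current - 1e-12:
            current, medoids_arr = best
            improved = True
    return medoids_arr


def kmedoids_cluster(
    points: np.ndarray,
    k: int = 6,
    seed: int = 0,
    silhouette_outlier_max: float = 0.25,
) -> ClusterResult:
    """k-medoids (PAM) on Euclidean distances with silhouette widths.

    Silhouette widths are computed on the same distances that were
    clustered; members with width <= ``silhouette_outlier_max`` are
    flagged as outliers.  The PAM search is deterministic; ``seed`` is
    accepted for interface symmetry with the embedding step.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    medoids = _pam(dist, k)
    labels = np.argmin(dist[:, medoids], axis=1) + 1
    if len(np.unique(labels)) > 1:
        widths = silhouette_samples(dist, labels, metric="precomputed")
    else:
        widths = np.zeros(n)
    return ClusterResult(
        labels=labels,
        medoid_indices=medoids,
        silhouette=widths,
        outlier=widths <= silhouette_outlier_max,
        points=points,
    )


def cluster_report(
    result: ClusterResult, profiles: Sequence[FoldedProfile]
) -> tuple[dict[int, np.ndarray], pd.DataFrame]:
    """Per-cluster mean folded profile (outliers excluded) and a
    membership table (tf, cell_line, cluster, silhouette, outlier)."""
    values = np.vstack([fp.values for fp in profiles])
    means: dict[int, np.ndarray] = {}
    for cid in range(1, result.k + 1):
        mask = (result.labels == cid) & ~result.outlier
        if mask.any():
            means[cid] = values[mask].mean(axis=0)
        else:
            means[cid] = np.full(values.shape[1], np.nan)
    table = pd.DataFrame(
        {
            "tf_name": [fp.tf_name for fp in profiles],
            "cell_line": [fp.cell_line for fp in profiles],
            "cluster": result.labels,
            "silhouette": result.silhouette,
            "outlier": result.outlier,
        }
    )
    return means, table


def silhouette_scan(
    points: np.ndarray, k_values: Sequence[int] = range(2, 11), seed: int = 0
) -> pd.DataFrame:
    """Average silhouette width per candidate k, to support choosing k."""
    rows = []
    for k in k_values:
        if k >= len(points):
            break
        res = kmedoids_cluster(points, k=k, seed=seed)
        rows.append({"k": k, "mean_silhouette": float(res.silhouette.mean())})
    return pd.DataFrame(rows)
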
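"""PCA, PAM (k-medoids) clustering and model-selection diagnostics.

The trait pipeline reduces fatty-acid profiles to their first two
principal components, selects the number of clusters with the gap
statistic, partitions with PAM (BUILD + SWAP) and diagnoses the result
with silhouette widths — all deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

from .data_model import DistanceMatrix, Partition, QuantitativeMatrix
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "PcaResult",
    "pca",
    "PamResult",
    "pam",
    "GapCurve",
    "gap_statistic",
    "SilhouetteReport",
    "silhouette",
]


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    sample_ids: list[str]
    variables: list[str]
    scores: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray

    def scores_frame(self, n: int | None = None) -> pd.DataFrame:
        n = n or self.scores.shape[1]
        return pd.DataFrame(
            self.scores[:, :n],
            index=self.sample_ids,
            columns=[f"PC{i + 1}" for i in range(n)],
        )


def pca(q: QuantitativeMatrix, scale: bool = True) -> PcaResult:
    """Principal component analysis of a trait table.

    Columns are centred and, with ``scale=True`` (the default, sensible
    for fatty-acid percentages spanning 0.01-80%), divided by their
    sample standard deviation.  Components are ordered by decreasing
    variance; each loading vector is flipped so its largest-magnitude
    entry is positive (deterministic sign).  Missing values are refused
    rather than imputed.
    """
    x = q.values().copy()
    n, p = x.shape
    if n < 2 or p < 2:
        raise DegenerateInputError("PCA needs at least 2 samples and 2 variables")
    if np.isnan(x).any():
        bad = q.sample_ids[int(np.flatnonzero(np.isnan(x).any(axis=1))[0])]
        raise ValidationError(f"missing values (e.g. sample {bad!r}); impute upstream")
    x -= x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if len(zero):
            raise ValidationError(
                f"zero-variance column {q.variables[int(zero[0])]!r} cannot be scaled"
            )
        x /= sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    var = s**2
    return PcaResult(
        sample_ids=list(q.sample_ids),
        variables=list(q.variables),
        scores=u * s,
        loadings=vt.T,
        variance_fractions=var / var.sum(),
    )


# ---------------------------------------------------------------------------
# PAM (k-medoids), BUILD + SWAP


@dataclass
class PamResult:
    medoids: list[int]
    partition: Partition
    objective: float


def _as_distance(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, DistanceMatrix):
        return data.values, list(data.ids)
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValidationError("points must be a 2-D array or a DistanceMatrix")
    return squareform(pdist(x)), [f"S{i + 1}" for i in range(x.shape[0])]


def _pam_build(d: np.ndarray, k: int, first: int) -> list[int]:
    """Greedy BUILD from a given first medoid."""
    medoids = [first]
    dist_to_med = d[first].copy()
    while len(medoids) < k:
        gains = np.maximum(dist_to_med[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        cand = int(np.argmax(gains))
        medoids.append(cand)
        dist_to_med = np.minimum(dist_to_med, d[cand])
    return medoids


def _pam_swap(d: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Best-improvement SWAP until no swap lowers the objective."""
    n = d.shape[0]

    def objective(meds: list[int]) -> float:
        return float(d[meds].min(axis=0).sum())

    best = objective(medoids)
    improved = True
    while improved:
        improved = False
        best_swap: tuple[int, int] | None = None
        best_obj = best
        meds = sorted(medoids)
        for mi, m in enumerate(meds):
            for h in range(n):
                if h in meds:
                    continue
                trial = meds[:mi] + meds[mi + 1 :] + [h]
                obj = objective(trial)
                if obj < best_obj - 1e-12:
                    best_obj = obj
                    best_swap = (m, h)
        if best_swap is not None:
            medoids = sorted(set(medoids) - {best_swap[0]} | {best_swap[1]})
            best = best_obj
            improved = True
    return sorted(medoids), best


_PAM_MULTISTART_N = 25


def pam(data, k: int, ids: list[str] | None = None) -> PamResult:
    """Partitioning Around Medoids: greedy BUILD then best-improvement SWAP.

    The objective (total dissimilarity of samples to their nearest
    medoid) never increases across swaps; ties break to the lowest
    sample index so the result is deterministic.  BUILD + SWAP is a
    local search, so on instances small enough to afford it (n <= 25)
    the search restarts from every sample as the BUILD seed and keeps
    the best solution — in practice this returns the exhaustive optimum
    on such instances.  ``data`` is either a DistanceMatrix or an
    (n, p) point array (Euclidean).  k = 1 is allowed (single medoid
    minimising total dissimilarity) so the same clusterer can serve the
    gap statistic's null curve.
    """
    d, default_ids = _as_distance(data)
    ids = ids or default_ids
    n = d.shape[0]
    if not 1 <= k < n:
        raise ValidationError(f"k={k} out of range 1..{n - 1}")

    starts = range(n) if n <= _PAM_MULTISTART_N else [int(np.argmin(d.sum(axis=0)))]
    best_medoids: list[int] | None = None
    best = np.inf
    for first in starts:
        meds, obj = _pam_swap(d, _pam_build(d, k, first))
        if obj < best - 1e-12 or (abs(obj - best) <= 1e-12 and meds < best_medoids):
            best_medoids, best = meds, obj
    labels = np.argmin(d[best_medoids], axis=0)
    return PamResult(best_medoids, Partition(list(ids), labels), best)


# ---------------------------------------------------------------------------
# Gap statistic


@dataclass
class GapCurve:
    k_values: list[int]
    gap: np.ndarray
    s_k: np.ndarray
    log_w: np.ndarray
    chosen_k: int
    b: int
    seed: int | None


def _log_wk(x: np.ndarray, labels: np.ndarray) -> float:
    """log of pooled within-cluster dispersion W_k (squared Euclidean)."""
    total = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        if len(pts) > 1:
            total += float((pdist(pts) ** 2).sum()) / (2.0 * len(pts))
    return float(np.log(max(total, 1e-300)))


def gap_statistic(
    points: np.ndarray,
    k_max: int,
    b: int = 50,
    seed: int | None = None,
) -> GapCurve:
    """Gap statistic over k = 1..k_max with PAM as the clusterer.

    gap(k) = mean_b log W*_kb - log W_k, with B reference datasets drawn
    uniformly over each observed feature range; s_k carries the
    sqrt(1 + 1/B) simulation-error inflation.  The number of clusters
    is chosen by the first-SE-max rule: the smallest k with
    gap(k) >= gap(k+1) - s_{k+1}.
    """
    x = np.asarray(points, dtype=float)
    n = x.shape[0]
    if k_max >= n:
        raise ValidationError(f"k_max={k_max} must be < n={n}")
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    rng = np.random.default_rng(seed)
    ks = list(range(1, k_max + 1))
    log_w = np.array([_log_wk(x, pam(x, k).partition.labels) for k in ks])
    lo, hi = x.min(axis=0), x.max(axis=0)
    ref = np.empty((b, len(ks)))
    for bi in range(b):
        xb = rng.uniform(lo, hi, size=x.shape)
        ref[bi] = [_log_wk(xb, pam(xb, k).partition.labels) for k in ks]
    gap = ref.mean(axis=0) - log_w
    s_k = ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / b)
    chosen = ks[-1]
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s_k[i + 1]:
            chosen = ks[i]
            break
    return GapCurve(ks, gap, s_k, log_w, chosen, b, seed)


# ---------------------------------------------------------------------------
# Silhouette


@dataclass
class SilhouetteReport:
    sample_ids: list[str]
    widths: np.ndarray
    cluster_means: dict[int, float]
    mean_width: float


def silhouette(p: Partition, d: DistanceMatrix) -> SilhouetteReport:
    """Silhouette widths s(i) = (b - a) / max(a, b) from a distance matrix.

    a = mean distance to own cluster (excluding self); b = smallest mean
    distance to another cluster; singleton clusters get width 0.
    Invariant to rescaling the distances by a positive constant.
    """
    if set(p.ids) != set(d.ids):
        raise ValidationError("partition and distance matrix cover different samples")
    if p.n_clusters < 2:
        raise DegenerateInputError("silhouette needs at least 2 clusters")
    pos = {s: i for i, s in enumerate(d.ids)}
    labels = np.empty(len(d.ids), dtype=np.int64)
    for s, lab in zip(p.ids, p.labels):
        labels[pos[s]] = lab
    widths = silhouette_samples(d.values, labels, metric="precomputed")
    cluster_means = {
        int(lab): float(widths[labels == lab].mean()) for lab in np.unique(labels)
    }
    return SilhouetteReport(list(d.ids), widths, cluster_means, float(widths.mean()))
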
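"""Dice-Sorensen genetic distance, Ward dendrograms, Evanno delta-K and ARI.

The genetic similarity between two trees is the Dice-Sorensen index on
their binary allele-presence vectors, computed over mutually typed
loci; the distance is sqrt(1 - s) by default (Euclidean-embeddable,
suitable for Ward linkage) with plain 1 - s available by flag.
Model-based admixture inference itself is out of scope: this module
only consumes externally produced Q-matrices and per-K log-likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hierarchy
from sklearn.metrics import adjusted_rand_score

from .data_model import DistanceMatrix, MergeTree, Partition
from .errors import DegenerateInputError, ValidationError
from .popgen_stats import AlleleMatrix

__all__ = [
    "dice_similarity",
    "genetic_distance_matrix",
    "ward_tree",
    "cut_tree",
    "adjusted_rand_index",
    "QMatrix",
    "read_q_matrix",
    "hard_assignment",
    "DeltaKTable",
    "evanno_delta_k",
]


def dice_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Dice-Sorensen similarity 2a11 / (|a| + |b|) over mutually typed columns.

    Rows come from an :class:`AlleleMatrix`; NaN marks untyped loci and
    the comparison is restricted to columns typed in both samples
    (pairwise-complete), so heavily missing samples remain placeable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.any():
        raise DegenerateInputError("no mutually typed locus between the two samples")
    aa, bb = a[ok], b[ok]
    denom = aa.sum() + bb.sum()
    if denom == 0:
        raise DegenerateInputError("both samples carry no alleles on shared loci")
    return float(2.0 * np.sum((aa == 1) & (bb == 1)) / denom)


def genetic_distance_matrix(m: AlleleMatrix, sqrt: bool = True) -> DistanceMatrix:
    """Pairwise genetic distances d = sqrt(1 - s) (or 1 - s with sqrt=False)."""
    n = len(m.sample_ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = dice_similarity(m.values[i], m.values[j])
            d = 1.0 - s
            out[i, j] = out[j, i] = np.sqrt(max(d, 0.0)) if sqrt else max(d, 0.0)
    return DistanceMatrix(list(m.sample_ids), out, "dice_sorensen")


def ward_tree(d: DistanceMatrix) -> MergeTree:
    """Agglomerate by Ward linkage (Ward.D2 Lance-Williams update).

    Deterministic given the input order; ties fall to the earliest pair
    in condensed order.  Heights are monotone non-decreasing on metric
    input.
    """
    if len(d) < 2:
        raise ValidationError("need at least 2 samples to build a dendrogram")
    Z = _hierarchy.linkage(d.condensed(), method="ward")
    return MergeTree(list(d.ids), Z)


def cut_tree(tree: MergeTree, k: int) -> Partition:
    """Cut the dendrogram into exactly k clusters."""
    return tree.cut(k)


def adjusted_rand_index(p1: Partition, p2: Partition) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    1 iff identical up to relabelling; expectation approximately 0 for
    independent random labellings.  The two partitions must cover the
    same sample set (order-insensitive).
    """
    if set(p1.ids) != set(p2.ids):
        raise ValidationError("partitions cover different sample sets")
    order = {s: i for i, s in enumerate(p1.ids)}
    lab2 = np.empty(len(p2.ids), dtype=np.int64)
    for s, lab in zip(p2.ids, p2.labels):
        lab2[order[s]] = lab
    return float(adjusted_rand_score(p1.labels, lab2))


# ---------------------------------------------------------------------------
# Admixture (Q-matrix) post-processing


@dataclass
class QMatrix:
    """Per-sample admixture proportions over K ancestral clusters."""

    sample_ids: list[str]
    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.sample_ids):
            raise ValidationError("Q-matrix must be samples x K")
        if ((self.q < -1e-9) | (self.q > 1 + 1e-9)).any():
            raise ValidationError("admixture proportions must lie in [0, 1]")
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("each Q-matrix row must sum to 1")

    @property
    def k(self) -> int:
        return self.q.shape[1]


def read_q_matrix(path, sample_ids: list[str] | None = None) -> QMatrix:
    """Read a plain numeric table of admixture proportions.

    Accepts whitespace- or comma-separated rows, one per sample, K
    numeric columns; an optional leading non-numeric column is taken as
    the sample ID.
    """
    rows: list[list[float]] = []
    ids: list[str] = []
    from pathlib import Path as _P

    for ln, line in enumerate(_P(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        toks = line.replace(",", " ").split()
        start = 0
        try:
            float(toks[0])
        except ValueError:
            ids.append(toks[0])
            start = 1
        try:
            rows.append([float(t) for t in toks[start:]])
        except ValueError as exc:
            raise ValidationError(f"malformed Q-matrix row {ln + 1}: {exc}") from exc
    if sample_ids is None:
        sample_ids = ids if len(ids) == len(rows) else [f"S{i + 1}" for i in range(len(rows))]
    return QMatrix(sample_ids, np.array(rows))


def hard_assignment(q: QMatrix) -> Partition:
    """Assign each sample to its argmax admixture cluster.

    Ties go to the lowest cluster index, with a warning.
    """
    labels = np.argmax(q.q, axis=1)
    ties = (q.q == q.q.max(axis=1, keepdims=True)).sum(axis=1) > 1
    for i in np.flatnonzero(ties):
        warnings.warn(
            f"sample {q.sample_ids[i]!r} has tied admixture maxima; "
            "assigned to the lowest cluster index",
            stacklevel=2,
        )
    return Partition(list(q.sample_ids), labels)


# ---------------------------------------------------------------------------
# Evanno delta-K


@dataclass
class DeltaKTable:
    """Second-difference diagnostics of log-likelihood across K."""

    k_values: list[int]
    mean_l: np.ndarray
    sd_l: np.ndarray
    delta_k: dict[int, float]

    @property
    def best_k(self) -> int:
        return max(self.delta_k, key=lambda k: self.delta_k[k])


def evanno_delta_k(runs: dict[int, list[float]]) -> DeltaKTable:
    """Evanno delta-K from replicate log-likelihoods per K.

    delta-K(K) = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)), defined for
    interior K only; a K whose replicate runs are constant (sd = 0) is
    excluded with a warning.
    """
    ks = sorted(runs)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValidationError("need at least 3 consecutive K values")
    if any(len(runs[k]) < 2 for k in ks):
        raise ValidationError("need at least 2 runs per K")
    mean_l = np.array([np.mean(runs[k]) for k in ks])
    sd_l = np.array([np.std(runs[k], ddof=1) for k in ks])
    delta: dict[int, float] = {}
    for i in range(1, len(ks) - 1):
        second = abs(mean_l[i + 1] - 2 * mean_l[i] + mean_l[i - 1])
        if sd_l[i] == 0:
            warnings.warn(
                f"K={ks[i]}: zero run-to-run sd, delta-K undefined (excluded)",
                stacklevel=2,
            )
            continue
        delta[ks[i]] = float(second / sd_l[i])
    return DeltaKTable(ks, mean_l, sd_l, delta)
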
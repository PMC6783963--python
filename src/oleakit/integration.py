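"""Macro-descriptor distance matrices and Mantel permutation inference.

Each macro-descriptor of a germplasm collection — geographic position,
morphometrics, fatty-acid profile, SSR genotype — yields one pairwise
distance matrix over the same samples; the Mantel test quantifies how
strongly two such matrices co-vary, with significance from random
relabelling of one matrix's samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_model import DistanceMatrix, QuantitativeMatrix
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "euclidean_matrix",
    "canberra_matrix",
    "MantelResult",
    "mantel_test",
    "DescriptorSet",
    "descriptor_correlations",
]


def _matrix_input(q) -> tuple[np.ndarray, list[str]]:
    if isinstance(q, QuantitativeMatrix):
        return q.values(), list(q.sample_ids)
    x = np.asarray(q, dtype=float)
    return x, [f"S{i + 1}" for i in range(x.shape[0])]


def euclidean_matrix(q, ids: list[str] | None = None, scale: bool = False) -> DistanceMatrix:
    """Pairwise Euclidean (L2) distances between sample rows.

    ``scale=True`` z-scores each variable first — useful when units are
    heterogeneous (g, cm, cm^2); the default works on raw units.
    """
    x, default_ids = _matrix_input(q)
    ids = ids or default_ids
    if np.isnan(x).any():
        bad = ids[int(np.flatnonzero(np.isnan(x).any(axis=1))[0])]
        raise ValidationError(f"missing value in sample {bad!r}")
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    return DistanceMatrix(ids, squareform(pdist(x, metric="euclidean")), "euclidean")


def canberra_matrix(q, ids: list[str] | None = None) -> DistanceMatrix:
    """Pairwise Canberra distances d = sum |x - y| / (|x| + |y|).

    Terms with x = y = 0 contribute 0.  Because each term is normalised
    by the pair's own magnitude, an acid present at trace level in one
    sample and absent in the other contributes a full unit — the
    behaviour wanted for biomarker-like compositional variables.
    Negative abundances are rejected.
    """
    x, default_ids = _matrix_input(q)
    ids = ids or default_ids
    if np.isnan(x).any():
        bad = ids[int(np.flatnonzero(np.isnan(x).any(axis=1))[0])]
        raise ValidationError(f"missing value in sample {bad!r}")
    if (x < 0).any():
        raise ValidationError("Canberra distance requires non-negative values")
    return DistanceMatrix(ids, squareform(pdist(x, metric="canberra")), "canberra")


# ---------------------------------------------------------------------------
# Mantel test


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    seed: int | None
    pair: tuple[str, str] = ("d1", "d2")


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 100_000,
    seed: int | None = None,
    pair: tuple[str, str] = ("d1", "d2"),
) -> MantelResult:
    """One-tailed Mantel test for positive association of two distance matrices.

    r is the Pearson correlation of the n(n-1)/2 upper-triangle entries;
    p = (1 + #{joint row/column permutations of d2 with r* >= r}) /
    (n_perm + 1).  Bit-reproducible given the seed.
    """
    if d1.ids != d2.ids:
        if set(d1.ids) == set(d2.ids):
            d2 = d2.subset(d1.ids)
        else:
            raise ValidationError("distance matrices cover different samples")
    n = len(d1)
    if n < 4:
        raise DegenerateInputError("Mantel test needs n >= 4")
    row, col = np.triu_indices(n, k=1)
    v1 = d1.values[row, col]
    if np.ptp(v1) == 0 or np.ptp(d2.values[row, col]) == 0:
        raise DegenerateInputError("constant distance matrix: r undefined")
    v1 = v1 - v1.mean()
    v1 /= np.linalg.norm(v1)

    def corr(perm: np.ndarray) -> float:
        # condensed vector of the jointly permuted d2, gathered directly
        v2 = d2.values[perm[row], perm[col]]
        v2 = v2 - v2.mean()
        return float(v1 @ (v2 / np.linalg.norm(v2)))

    r_obs = corr(np.arange(n))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if corr(rng.permutation(n)) >= r_obs - 1e-12:
            hits += 1
    return MantelResult(r_obs, (1 + hits) / (n_perm + 1), n_perm, seed, pair)


# ---------------------------------------------------------------------------
# Descriptor set and the all-pairs correlation table


@dataclass
class DescriptorSet:
    """Named distance matrices over one aligned sample set.

    Canonical members: geographic (euclidean), morphometric (euclidean),
    fatty_acids (canberra), ssr (dice_sorensen).
    """

    matrices: dict[str, DistanceMatrix]

    def __post_init__(self) -> None:
        if len(self.matrices) < 2:
            raise ValidationError("need at least two descriptors")
        names = list(self.matrices)
        ref = self.matrices[names[0]].ids
        for name in names[1:]:
            m = self.matrices[name]
            if m.ids != ref:
                if set(m.ids) != set(ref):
                    missing = sorted(set(ref) ^ set(m.ids))
                    raise ValidationError(
                        f"descriptor {name!r} misaligned; offending samples: {missing[:5]}"
                    )
                self.matrices[name] = m.subset(list(ref))

    @property
    def ids(self) -> list[str]:
        return list(next(iter(self.matrices.values())).ids)

    def subset(self, sample_ids: list[str]) -> "DescriptorSet":
        return DescriptorSet({k: v.subset(sample_ids) for k, v in self.matrices.items()})


def descriptor_correlations(
    ds: DescriptorSet,
    n_perm: int = 100_000,
    seed: int | None = None,
    subset_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Mantel r and p for every unordered descriptor pair.

    ``subset_ids`` restricts the analysis (e.g. to samples belonging to
    well-replicated genets).  Returns a tidy frame with one row per
    pair; fully reproducible from the seed.
    """
    if subset_ids is not None:
        ds = ds.subset(list(subset_ids))
    names = list(ds.matrices)
    rows = []
    for i, (a, b) in enumerate(combinations(names, 2)):
        res = mantel_test(
            ds.matrices[a],
            ds.matrices[b],
            n_perm=n_perm,
            seed=None if seed is None else seed + i,
            pair=(a, b),
        )
        rows.append({"d1": a, "d2": b, "r": res.r, "p_value": res.p_value, "n_perm": n_perm})
    return pd.DataFrame(rows)
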
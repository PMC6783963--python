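"""Per-locus SSR diversity statistics, HWE inference and clone detection.

Implements the classic codominant-marker summary for a diploid
genotype table: allele frequencies, observed/expected/unbiased
heterozygosity, effective allele number, the Brookfield null-allele
estimator, a Monte-Carlo exact Hardy-Weinberg test, the probability of
genetic identity (Pgen) of a multilocus genotype, the binary
allele-presence matrix that feeds genetic distances, and
multilocus-genotype (clone) grouping.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data_model import GenotypeTable, Partition, SampleTable
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "LocusSummary",
    "AlleleMatrix",
    "GenotypeProbability",
    "allele_frequencies",
    "expected_heterozygosity",
    "unbiased_heterozygosity",
    "effective_alleles",
    "heterozygosities",
    "brookfield_null",
    "hwe_exact_mc",
    "pgen",
    "allele_matrix",
    "find_clones",
    "summary_report",
    "write_summary_report",
]


def allele_frequencies(g: GenotypeTable, locus: str) -> tuple[dict[int, float], int]:
    """Allele frequency map and the number N of typed samples at a locus.

    Frequencies are counted over the 2N allele draws of the non-missing
    samples and sum to 1.
    """
    pairs, typed = g.calls(locus)
    n = int(typed.sum())
    if n == 0:
        raise DegenerateInputError(f"locus {locus!r} has no typed samples")
    sizes, counts = np.unique(pairs[typed].ravel(), return_counts=True)
    total = 2 * n
    return {int(a): c / total for a, c in zip(sizes, counts)}, n


def expected_heterozygosity(freqs: dict[int, float]) -> float:
    """He = 1 - sum f^2 (the uncorrected estimator)."""
    f = np.asarray(list(freqs.values()), dtype=float)
    return float(1.0 - np.sum(f**2))


def unbiased_heterozygosity(he: float, n: int) -> float:
    """uHe = (2N / (2N - 1)) * He, the small-sample correction."""
    if n < 1:
        raise DegenerateInputError("need at least one typed sample")
    return float(2 * n / (2 * n - 1) * he)


def effective_alleles(freqs: dict[int, float]) -> float:
    """Ne = 1 / sum f^2; equals the allele count for equifrequent alleles."""
    if not freqs:
        raise DegenerateInputError("empty frequency map")
    f = np.asarray(list(freqs.values()), dtype=float)
    return float(1.0 / np.sum(f**2))


def heterozygosities(g: GenotypeTable, locus: str) -> tuple[float, float, float]:
    """(Ho, He, uHe) for one locus.

    Ho is the fraction of typed samples whose two alleles differ; He and
    uHe come from the estimated allele frequencies.
    """
    freqs, n = allele_frequencies(g, locus)
    pairs, typed = g.calls(locus)
    ho = float(np.mean(pairs[typed, 0] != pairs[typed, 1]))
    he = expected_heterozygosity(freqs)
    return ho, he, unbiased_heterozygosity(he, n)


def brookfield_null(he: float, ho: float) -> float:
    """Brookfield (estimator 1) null-allele frequency r = (He - Ho) / (1 + He).

    Negative estimates (Ho >= He) are clamped to 0; the estimator
    assumes no distinct null-homozygote class was scored.
    """
    if not (0 <= ho <= 1 and 0 <= he <= 1):
        raise ValueError("Ho and He must lie in [0, 1]")
    return max((he - ho) / (1.0 + he), 0.0)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test, Monte-Carlo


def _pairing_stat(pairs: np.ndarray) -> np.ndarray:
    """Variable part of log P(genotype array | allele counts).

    ``pairs``: (..., N, 2) sorted allele codes.  Under fixed allele
    counts only the heterozygote count h and the genotype multiplicities
    vary across pairings:  stat = h*log 2 - sum_g log(n_g!).
    The j-th occurrence of a genotype contributes log j to the sum, so
    the factorials reduce to a positionwise log over occurrence indices.
    """
    het = (pairs[..., 0] != pairs[..., 1]).sum(axis=-1)
    codes = pairs[..., 0].astype(np.int64) * 100003 + pairs[..., 1]
    s = np.sort(codes, axis=-1)
    m, n = s.shape
    eq = s[:, 1:] == s[:, :-1]
    pos = np.arange(1, n)
    starts = np.where(eq, 0, pos)
    runstart = np.maximum.accumulate(
        np.concatenate([np.zeros((m, 1), dtype=np.int64), starts], axis=1), axis=1
    )
    occ = np.arange(n) - runstart  # 0-based occurrence index within its run
    logfact = np.log(occ + 1.0).sum(axis=1)
    return het * np.log(2.0) - logfact


def hwe_exact_mc(
    g: GenotypeTable,
    locus: str,
    n_perm: int = 100_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo exact Hardy-Weinberg test for one locus.

    The test statistic is the conditional probability of the observed
    genotype array given the allele counts; the null distribution is
    simulated by re-pairing the 2N-allele vector uniformly at random.
    p = (1 + #{pairings with probability <= observed}) / (n_perm + 1).
    """
    pairs, typed = g.calls(locus)
    pairs = np.sort(pairs[typed], axis=1)
    n = pairs.shape[0]
    if n < 2:
        raise DegenerateInputError(f"locus {locus!r}: need at least 2 typed samples")
    flat = pairs.ravel()
    if len(np.unique(flat)) < 2:
        warnings.warn(f"locus {locus!r} is monomorphic; HWE p = 1", stacklevel=2)
        return 1.0
    obs = float(_pairing_stat(pairs[None, ...])[0])
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(n_perm, 4_000_000 // (2 * n)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        mat = rng.permuted(np.broadcast_to(flat, (m, 2 * n)).copy(), axis=1)
        perm_pairs = np.sort(mat.reshape(m, n, 2), axis=2)
        stats = _pairing_stat(perm_pairs)
        hits += int((stats <= obs + 1e-9).sum())
        done += m
    return (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Pgen


@dataclass
class GenotypeProbability:
    """Probability of a multilocus genotype under random mating."""

    sample_id: str
    pgen: float
    factors: dict[str, float]
    missing_loci: list[str] = field(default_factory=list)


def pgen(
    g: GenotypeTable,
    sample_id: str,
    freqs: dict[str, dict[int, float]] | None = None,
) -> GenotypeProbability:
    """Pgen = product over typed loci of f^2 (homozygote) or 2 f f' (heterozygote).

    By default allele frequencies are pooled over the whole table;
    pass ``freqs`` (locus -> allele -> frequency), e.g. computed on one
    collection site, to change the reference pool.
    """
    i = g.sample_ids.index(sample_id)
    if freqs is None:
        freqs = {locus: allele_frequencies(g, locus)[0] for locus in g.loci}
    factors: dict[str, float] = {}
    missing: list[str] = []
    for j, locus in enumerate(g.loci):
        if g.missing[i, j]:
            missing.append(locus)
            continue
        a1, a2 = int(g.alleles[i, j, 0]), int(g.alleles[i, j, 1])
        fmap = freqs[locus]
        try:
            f1, f2 = fmap[a1], fmap[a2]
        except KeyError as exc:
            raise ValidationError(
                f"allele {exc.args[0]} at {locus!r} absent from frequency map"
            ) from exc
        factors[locus] = f1 * f2 if a1 == a2 else 2.0 * f1 * f2
    total = float(np.prod(list(factors.values()))) if factors else 1.0
    return GenotypeProbability(sample_id, total, factors, missing)


def pgen_by_site(
    g: GenotypeTable, samples: SampleTable
) -> dict[str, GenotypeProbability]:
    """Pgen for every sample using its own site's allele frequencies."""
    out: dict[str, GenotypeProbability] = {}
    for site in samples.site_labels:
        members = [s for s, lab in zip(samples.sample_ids, samples.sites) if lab == site]
        sub = g.subset(members)
        site_freqs = {locus: allele_frequencies(sub, locus)[0] for locus in sub.loci}
        for sid in members:
            out[sid] = pgen(sub, sid, freqs=site_freqs)
    return out


# ---------------------------------------------------------------------------
# Binary allele matrix


@dataclass
class AlleleMatrix:
    """Binary presence/absence of each (locus, allele) per sample.

    ``values`` is (n_samples, n_columns) with 1.0 = present, 0.0 =
    absent and NaN where the sample's locus is untyped (masked, never
    silently 0).
    """

    sample_ids: list[str]
    columns: list[tuple[str, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.columns)):
            raise ValidationError("allele matrix shape mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.columns, names=["locus", "allele"])
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)


def allele_matrix(g: GenotypeTable) -> AlleleMatrix:
    """One binary column per distinct (locus, allele) across the table.

    A homozygote sets exactly one column at its locus, a heterozygote
    two; a fully typed sample therefore has row sum 2L - #homozygous
    loci.
    """
    columns: list[tuple[str, int]] = []
    for locus in g.loci:
        try:
            freqs, _ = allele_frequencies(g, locus)
        except DegenerateInputError:
            continue
        columns.extend((locus, a) for a in sorted(freqs))
    col_pos = {c: k for k, c in enumerate(columns)}
    values = np.zeros((g.n_samples, len(columns)))
    for j, locus in enumerate(g.loci):
        span = [k for (loc, _), k in col_pos.items() if loc == locus]
        for i in range(g.n_samples):
            if g.missing[i, j]:
                values[i, span] = np.nan
            else:
                for a in g.alleles[i, j]:
                    values[i, col_pos[(locus, int(a))]] = 1.0
    return AlleleMatrix(list(g.sample_ids), columns, values)


# ---------------------------------------------------------------------------
# Clone (multilocus genotype) detection


def _genotype_match(a: np.ndarray, b: np.ndarray, tol: int) -> bool:
    # both (2,) sorted allele pairs
    return abs(int(a[0]) - int(b[0])) <= tol and abs(int(a[1]) - int(b[1])) <= tol


def find_clones(
    g: GenotypeTable,
    max_mismatch_loci: int = 0,
    allele_tolerance_bp: int = 0,
) -> Partition:
    """Group samples into multilocus genotypes (putative clones).

    Two samples match when, over loci typed in both, at most
    ``max_mismatch_loci`` loci differ; a locus agrees when both sorted
    alleles are within ``allele_tolerance_bp`` base pairs (somatic
    variants of a vegetatively propagated genet typically differ by 2-3
    bp).  Matching is closed transitively (single-linkage), so a chain
    of tolerated variants forms one genet.  Samples typed at no locus
    become singletons with a warning.
    """
    n = g.n_samples
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    all_missing = g.missing.all(axis=1)
    for i in np.flatnonzero(all_missing):
        warnings.warn(
            f"sample {g.sample_ids[i]!r} is untyped at every locus; kept as singleton",
            stacklevel=2,
        )
    for i in range(n):
        if all_missing[i]:
            continue
        for j in range(i + 1, n):
            if all_missing[j]:
                continue
            shared = ~(g.missing[i] | g.missing[j])
            if not shared.any():
                continue
            mismatches = sum(
                not _genotype_match(g.alleles[i, L], g.alleles[j, L], allele_tolerance_bp)
                for L in np.flatnonzero(shared)
            )
            if mismatches <= max_mismatch_loci:
                union(i, j)
    roots = [find(i) for i in range(n)]
    return Partition(list(g.sample_ids), np.array(roots)).relabel()


# ---------------------------------------------------------------------------
# Per-locus summary report


@dataclass
class LocusSummary:
    """GenAlEx-style per-locus diversity summary."""

    locus: str
    freqs: dict[int, float]
    n: int
    na: int
    ne: float
    ho: float
    he: float
    uhe: float
    r_null: float
    hwe_p: float | None = None


def locus_summary(
    g: GenotypeTable,
    locus: str,
    n_perm: int | None = None,
    seed: int | None = None,
) -> LocusSummary:
    freqs, n = allele_frequencies(g, locus)
    ho, he, uhe = heterozygosities(g, locus)
    p = hwe_exact_mc(g, locus, n_perm=n_perm, seed=seed) if n_perm else None
    return LocusSummary(
        locus=locus,
        freqs=freqs,
        n=n,
        na=len(freqs),
        ne=effective_alleles(freqs),
        ho=ho,
        he=he,
        uhe=uhe,
        r_null=brookfield_null(he, ho),
        hwe_p=p,
    )


def summary_report(
    g: GenotypeTable,
    n_perm: int | None = None,
    seed: int | None = None,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Loci x indices table (N, Na, Ne, Ho, He, uHe, r, HWE p and flag).

    HWE p-values are raw Monte-Carlo p; the flag marks p < alpha
    (default 0.001), with no multiplicity correction.
    """
    rows = []
    for k, locus in enumerate(g.loci):
        s = locus_summary(g, locus, n_perm=n_perm, seed=None if seed is None else seed + k)
        rows.append(
            {
                "locus": s.locus,
                "N": s.n,
                "Na": s.na,
                "Ne": s.ne,
                "Ho": s.ho,
                "He": s.he,
                "uHe": s.uhe,
                "r": s.r_null,
                "hwe_p": s.hwe_p,
                "hwe_significant": None if s.hwe_p is None else bool(s.hwe_p < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("locus")


def write_summary_report(report: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(report.reset_index().to_dict(orient="records"), indent=1))
    else:
        report.to_csv(path, sep="\t")
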
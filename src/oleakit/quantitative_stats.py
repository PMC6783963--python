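"""Nonparametric group comparisons for morphometric and fatty-acid traits.

Gate checks (Shapiro-Wilk normality, Levene homoscedasticity) justify
the nonparametric route; the Kruskal-Wallis rank test replaces one-way
ANOVA and the Siegel-Castellan multiple-comparison procedure provides
the pairwise site grid.  The MUFA/PUFA ratio summarises oil quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import QuantitativeMatrix
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "GroupTestResult",
    "PosthocTable",
    "shapiro_wilk",
    "levene",
    "kruskal_wallis",
    "kw_posthoc_siegel_castellan",
    "spearman_test",
    "DEFAULT_FATTY_ACID_CLASSES",
    "mufa_pufa_ratio",
]


@dataclass
class GroupTestResult:
    variable: str
    test: str
    statistic: float
    df: int
    p_value: float
    group_n: dict[str, int]


@dataclass
class PosthocTable:
    """Pairwise rank-mean comparison grid (Siegel-Castellan)."""

    variable: str
    alpha: float
    pairs: list[tuple[str, str]]
    rank_mean_diff: dict[tuple[str, str], float]
    critical_diff: dict[tuple[str, str], float]
    significant: dict[tuple[str, str], bool]

    def lookup(self, a: str, b: str) -> bool:
        key = (a, b) if (a, b) in self.significant else (b, a)
        return self.significant[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pair": f"{a}-{b}",
                "rank_mean_diff": self.rank_mean_diff[(a, b)],
                "critical_diff": self.critical_diff[(a, b)],
                "significant": self.significant[(a, b)],
            }
            for a, b in self.pairs
        ]
        return pd.DataFrame(rows).set_index("pair")


def _as_groups(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValidationError("values and group labels must align")
    out: dict[str, np.ndarray] = {}
    for gname in pd.unique(groups):
        sel = values[groups == gname]
        out[str(gname)] = sel[~np.isnan(sel)]
    return out


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (Royston approximation, 3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if not 3 <= len(x) <= 5000:
        raise DegenerateInputError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant vector: normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def levene(groups, center: str = "mean") -> tuple[float, float]:
    """Levene homoscedasticity test on mean-centred absolute deviations.

    ``center='median'`` gives the Brown-Forsythe variant.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise DegenerateInputError("Levene needs >= 2 groups with n >= 2 each")
    if center not in {"mean", "median"}:
        raise ValueError("center must be 'mean' or 'median'")
    f, p = sps.levene(*arrays, center=center)
    return float(f), float(p)


def kruskal_wallis(values, groups, variable: str = "") -> GroupTestResult:
    """Kruskal-Wallis rank test with tie correction; p from chi2 (k-1 df)."""
    by_group = _as_groups(values, groups)
    arrays = list(by_group.values())
    if len(arrays) < 2:
        raise DegenerateInputError("need >= 2 groups")
    total = sum(len(a) for a in arrays)
    if total < 3:
        raise DegenerateInputError("need total n >= 3")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        warnings.warn("all observations tied: H = 0, p = 1", stacklevel=2)
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    return GroupTestResult(
        variable=variable,
        test="kruskal_wallis",
        statistic=float(h),
        df=len(arrays) - 1,
        p_value=float(p),
        group_n={k: len(v) for k, v in by_group.items()},
    )


def siegel_castellan_critical(
    n_total: int, n_i: int, n_j: int, k: int, alpha: float
) -> float:
    """Critical rank-mean difference z(alpha / (k(k-1))) * SE for one pair."""
    z = sps.norm.ppf(1.0 - alpha / (k * (k - 1)))
    se = np.sqrt(n_total * (n_total + 1) / 12.0 * (1.0 / n_i + 1.0 / n_j))
    return float(z * se)


def kw_posthoc_siegel_castellan(
    values, groups, alpha: float = 0.05, variable: str = ""
) -> PosthocTable:
    """Siegel-Castellan nonparametric multiple comparisons after Kruskal-Wallis.

    Pair (i, j) is significant when the absolute difference of mean
    ranks exceeds z(alpha/(k(k-1))) * sqrt(N(N+1)/12 * (1/ni + 1/nj)).
    The grid is symmetric in pair order.
    """
    by_group = _as_groups(values, groups)
    names = list(by_group)
    k = len(names)
    if k < 2:
        raise DegenerateInputError("need >= 2 groups")
    pooled = np.concatenate([by_group[g] for g in names])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for g in names:
        n_g = len(by_group[g])
        mean_ranks[g] = float(ranks[start : start + n_g].mean()) if n_g else np.nan
        start += n_g
    diffs, crits, sig = {}, {}, {}
    pairs = list(combinations(names, 2))
    for a, b in pairs:
        d = abs(mean_ranks[a] - mean_ranks[b])
        c = siegel_castellan_critical(n_total, len(by_group[a]), len(by_group[b]), k, alpha)
        diffs[(a, b)] = d
        crits[(a, b)] = c
        sig[(a, b)] = bool(d >= c)
    return PosthocTable(variable, alpha, pairs, diffs, crits, sig)


def spearman_test(
    x, y, method: str = "asymptotic", n_perm: int = 10_000, seed: int | None = None
) -> tuple[float, float]:
    """Tie-corrected Spearman correlation with t-approximation p.

    ``method='permutation'`` replaces the analytic p with a seeded
    two-sided permutation p on |rho|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise DegenerateInputError("need paired finite data with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            r_perm, _ = sps.spearmanr(x, rng.permutation(y))
            if abs(r_perm) >= abs(rho) - 1e-12:
                hits += 1
        p = (1 + hits) / (n_perm + 1)
    return float(rho), float(p)


# Chemical classification of the ten assayed fatty acids.  Saturated
# acids (palmitic, eicosanoic, behenic) belong to neither class.
DEFAULT_FATTY_ACID_CLASSES: dict[str, str] = {
    "C16:0 (Palmitic)": "other",
    "C16:1 (Palmitoleic)": "MUFA",
    "C17:1 (Heptadecenoic)": "MUFA",
    "C18:1 (Oleic)": "MUFA",
    "C18:1t (t-Octadecenoic)": "MUFA",
    "C18:2 (Linoleic)": "PUFA",
    "C18:3 (Linolenic)": "PUFA",
    "C20:0 (Eicosanoic)": "other",
    "C20:1 (Eicosenoic)": "MUFA",
    "C22:0 (Behenic)": "other",
}


def _classify(name: str, classes: dict[str, str]) -> str:
    if name in classes:
        return classes[name]
    key = name.split()[0]
    for full, cls in classes.items():
        if full.split()[0] == key:
            return cls
    return "other"


def mufa_pufa_ratio(
    q: QuantitativeMatrix, classes: dict[str, str] | None = None
) -> pd.Series:
    """Per-sample ratio of summed MUFA % to summed PUFA %.

    Samples with zero PUFA are flagged with +inf and a warning; exclude
    them from summaries.  Column names match on the ``Cxx:y`` prefix so
    both bare ("C18:1") and annotated ("C18:1 (Oleic)") headers work.
    """
    classes = classes or DEFAULT_FATTY_ACID_CLASSES
    cls = {v: _classify(v, classes) for v in q.variables}
    mufa_cols = [v for v, c in cls.items() if c == "MUFA"]
    pufa_cols = [v for v, c in cls.items() if c == "PUFA"]
    if not mufa_cols or not pufa_cols:
        raise ValidationError("classification found no MUFA or no PUFA columns")
    mufa = q.data[mufa_cols].sum(axis=1)
    pufa = q.data[pufa_cols].sum(axis=1)
    if (pufa == 0).any():
        warnings.warn(
            f"{int((pufa == 0).sum())} sample(s) with zero PUFA: ratio set to inf",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        ratio = mufa / pufa
    ratio.name = "MUFA/PUFA"
    return ratio
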
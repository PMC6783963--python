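import math

import numpy as np
import pytest

from oleakit.data_model import GenotypeTable
from oleakit.errors import DegenerateInputError
from oleakit.popgen_stats import (
    allele_frequencies,
    allele_matrix,
    brookfield_null,
    effective_alleles,
    expected_heterozygosity,
    find_clones,
    heterozygosities,
    hwe_exact_mc,
    pgen,
    summary_report,
    unbiased_heterozygosity,
)


def single_locus(pairs, missing=None):
    n = len(pairs)
    alleles = np.array(pairs).reshape(n, 1, 2)
    miss = np.zeros((n, 1), dtype=bool)
    if missing:
        for i in missing:
            miss[i, 0] = True
            alleles[i] = 0
    return GenotypeTable([f"S{i}" for i in range(n)], ["L"], alleles, miss)


class TestFrequencies:
    def test_hand_counts(self):
        g = single_locus([(140, 144), (140, 140)])
        freqs, n = allele_frequencies(g, "L")
        assert n == 2
        assert freqs == {140: 0.75, 144: 0.25}

    def test_monomorphic(self):
        g = single_locus([(100, 100), (100, 100)])
        freqs, _ = allele_frequencies(g, "L")
        assert freqs == {100: 1.0}

    def test_all_missing_errors(self):
        g = single_locus([(100, 100)], missing=[0])
        with pytest.raises(DegenerateInputError):
            allele_frequencies(g, "L")

    def test_missing_excluded_from_denominator(self):
        g = single_locus([(140, 144), (140, 140), (144, 144)], missing=[2])
        freqs, n = allele_frequencies(g, "L")
        assert n == 2
        assert sum(freqs.values()) == pytest.approx(1.0)


class TestHeterozygosity:
    def test_all_homozygous(self):
        g = single_locus([(100, 100), (100, 100)])
        ho, he, _ = heterozygosities(g, "L")
        assert ho == 0.0
        assert he == 0.0

    def test_identity_he_equals_one_minus_sum_squares(self):
        rng = np.random.default_rng(3)
        pairs = rng.choice([140, 142, 144, 148], size=(30, 2)).tolist()
        g = single_locus(pairs)
        freqs, n = allele_frequencies(g, "L")
        _, he, uhe = heterozygosities(g, "L")
        assert he == pytest.approx(1 - sum(f**2 for f in freqs.values()), abs=1e-12)
        assert uhe == pytest.approx(2 * n / (2 * n - 1) * he, abs=1e-12)
        assert uhe >= he

    def test_unbiased_correction_factor(self):
        assert unbiased_heterozygosity(0.817, 152) == pytest.approx(0.817 * 304 / 303)


class TestEffectiveAlleles:
    def test_equifrequent(self):
        k = 5
        assert effective_alleles({i: 1 / k for i in range(k)}) == pytest.approx(k)

    def test_hand_value(self):
        assert effective_alleles({1: 0.5, 2: 0.25, 3: 0.25}) == pytest.approx(8 / 3)

    def test_bounded_by_allele_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            f = rng.dirichlet(np.ones(rng.integers(2, 10)))
            freqs = {i: v for i, v in enumerate(f)}
            assert 1.0 <= effective_alleles(freqs) <= len(freqs) + 1e-9


class TestBrookfield:
    def test_equal_ho_he_gives_zero(self):
        assert brookfield_null(0.7, 0.7) == 0.0

    def test_closed_form(self):
        assert brookfield_null(0.5, 0.25) == pytest.approx(1 / 6)

    def test_clamped_at_zero(self):
        assert brookfield_null(0.3, 0.9) == 0.0

    def test_monotonicity(self):
        grid = np.linspace(0, 1, 11)
        for he in grid:
            vals = [brookfield_null(he, ho) for ho in grid]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))  # decreasing in Ho
        for ho in grid:
            vals = [brookfield_null(he, ho) for he in grid]
            # increasing in He wherever the estimator is positive
            positive = [(v, h) for v, h in zip(vals, grid) if v > 0]
            assert all(a[0] <= b[0] + 1e-12 for a, b in zip(positive, positive[1:]))


def _matchings(items):
    """All perfect matchings of an even-length list of positions."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for i, partner in enumerate(rest):
        for rest_match in _matchings(rest[:i] + rest[i + 1 :]):
            yield [(first, partner)] + rest_match


def _exact_hwe_p(allele_vector):
    """Enumerate all pairings of the allele vector (uniform over matchings)."""
    from oleakit.popgen_stats import _pairing_stat

    vec = list(range(len(allele_vector)))
    arr = np.asarray(allele_vector)

    def stat_of(match):
        pairs = np.sort(arr[np.array(match)], axis=1)[None, ...]
        return float(_pairing_stat(pairs)[0])

    obs = stat_of([(2 * i, 2 * i + 1) for i in range(len(arr) // 2)])
    stats = [stat_of(m) for m in _matchings(vec)]
    return sum(s <= obs + 1e-9 for s in stats) / len(stats)


class TestHWE:
    def test_monomorphic_warns_p_one(self):
        g = single_locus([(100, 100), (100, 100), (100, 100)])
        with pytest.warns(UserWarning, match="monomorphic"):
            assert hwe_exact_mc(g, "L", n_perm=10, seed=0) == 1.0

    def test_same_seed_bit_reproducible(self):
        g = single_locus([(1, 2), (1, 1), (2, 2), (1, 2), (2, 2), (1, 1)])
        p1 = hwe_exact_mc(g, "L", n_perm=2000, seed=42)
        p2 = hwe_exact_mc(g, "L", n_perm=2000, seed=42)
        assert p1 == p2

    @pytest.mark.parametrize(
        "pairs",
        [
            [(1, 2), (1, 1), (2, 2), (1, 2)],
            [(1, 1), (1, 1), (2, 2), (2, 2)],
            [(1, 2), (1, 3), (2, 3), (1, 1), (3, 3), (2, 2)],
        ],
    )
    def test_matches_exhaustive_enumeration(self, pairs):
        g = single_locus(pairs)
        vec = [a for p in pairs for a in p]
        exact = _exact_hwe_p(vec)
        n_perm = 40_000
        p_mc = hwe_exact_mc(g, "L", n_perm=n_perm, seed=7)
        # MC p converges to (1 + n_perm * exact) / (n_perm + 1)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert p_mc == pytest.approx((1 + n_perm * exact) / (n_perm + 1), abs=4 * se + 1e-9)

    def test_seed_spread_consistent_with_binomial(self):
        g = single_locus([(1, 2), (1, 1), (2, 2), (1, 2), (2, 2), (1, 1), (1, 2), (1, 2)])
        ps = [hwe_exact_mc(g, "L", n_perm=500, seed=s) for s in range(30)]
        p_hat = np.mean(ps)
        se = math.sqrt(p_hat * (1 - p_hat) / 500)
        assert np.std(ps) < 3 * se + 1e-9


class TestPgen:
    def test_hand_product(self):
        alleles = np.array([[[1, 2], [5, 5]]])
        g = GenotypeTable(["S1"], ["L1", "L2"], alleles, np.zeros((1, 2), dtype=bool))
        freqs = {"L1": {1: 0.3, 2: 0.2}, "L2": {5: 0.5}}
        res = pgen(g, "S1", freqs=freqs)
        assert res.factors["L1"] == pytest.approx(0.12)
        assert res.factors["L2"] == pytest.approx(0.25)
        assert res.pgen == pytest.approx(0.03)

    def test_monomorphic_homozygous_is_one(self):
        alleles = np.array([[[5, 5], [7, 7]]])
        g = GenotypeTable(["S1"], ["L1", "L2"], alleles, np.zeros((1, 2), dtype=bool))
        assert pgen(g, "S1").pgen == pytest.approx(1.0)

    def test_missing_locus_listed_and_factors_multiply(self, toy_genotypes):
        res = pgen(toy_genotypes, "S3")
        assert res.missing_loci == ["L2"]
        assert 0 < res.pgen <= 1
        assert res.pgen == pytest.approx(np.prod(list(res.factors.values())))


class TestAlleleMatrix:
    def test_heterozygote_row_sum(self):
        g = single_locus([(140, 144), (140, 140)])
        m = allele_matrix(g)
        assert m.values[0].sum() == 2  # het: two columns set
        assert m.values[1].sum() == 1  # hom: one column set

    def test_missing_locus_masked_not_zero(self, toy_genotypes):
        m = allele_matrix(toy_genotypes)
        row = m.row("S3")
        l2_cols = [k for k, (locus, _) in enumerate(m.columns) if locus == "L2"]
        assert np.isnan(row[l2_cols]).all()
        # unmasked part: S3 is homozygous at L1 -> row sum 1
        l1_cols = [k for k, (locus, _) in enumerate(m.columns) if locus == "L1"]
        assert np.nansum(row[l1_cols]) == 1

    def test_fully_typed_row_sums(self, toy_genotypes):
        m = allele_matrix(toy_genotypes)
        L = toy_genotypes.n_loci
        for i, sid in enumerate(toy_genotypes.sample_ids):
            if toy_genotypes.missing[i].any():
                continue
            hom = sum(
                toy_genotypes.alleles[i, j, 0] == toy_genotypes.alleles[i, j, 1]
                for j in range(L)
            )
            assert np.nansum(m.values[i]) == 2 * L - hom


class TestFindClones:
    def test_identical_profiles_grouped(self):
        g = single_locus([(140, 144), (140, 144)])
        part = find_clones(g)
        assert part.n_clusters == 1

    def test_tolerance_controls_matching(self):
        pairs = [(140, 144), (142, 144)]
        g = single_locus(pairs)
        assert find_clones(g, allele_tolerance_bp=0).n_clusters == 2
        assert find_clones(g, allele_tolerance_bp=2).n_clusters == 1

    def test_planted_duplicates(self):
        rng = np.random.default_rng(11)
        base = [tuple(sorted(rng.choice([140, 150, 160, 170], 2))) for _ in range(7)]
        pairs = base + [base[0], base[1], base[2]]  # 3 planted duplicates
        g = single_locus(pairs)
        found = find_clones(g).n_clusters
        unique_planted = len(set(base))
        assert found == unique_planted

    def test_all_missing_sample_is_singleton_with_warning(self):
        g = single_locus([(140, 144), (140, 144), (1, 1)], missing=[2])
        with pytest.warns(UserWarning, match="untyped"):
            part = find_clones(g)
        assert part.n_clusters == 2


class TestSummaryReport:
    def test_shape_and_invariants(self, toy_genotypes):
        rep = summary_report(toy_genotypes, n_perm=200, seed=0)
        assert list(rep.index) == ["L1", "L2"]
        assert (rep["Ne"] <= rep["Na"] + 1e-9).all()
        assert rep[["Ho", "He", "uHe"]].apply(lambda c: c.between(0, 1)).all().all()
        assert (rep["r"] >= 0).all()
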
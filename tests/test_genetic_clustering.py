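import numpy as np
import pytest

from oleakit.data_model import DistanceMatrix, Partition
from oleakit.errors import DegenerateInputError, ValidationError
from oleakit.genetic_clustering import (
    adjusted_rand_index,
    cut_tree,
    dice_similarity,
    evanno_delta_k,
    genetic_distance_matrix,
    hard_assignment,
    read_q_matrix,
    ward_tree,
)
from oleakit.popgen_stats import AlleleMatrix, allele_matrix
from oleakit.synthetic_data import default_config, generate


class TestDice:
    def test_identical_profiles(self):
        a = np.array([1.0, 0, 1, 0])
        assert dice_similarity(a, a) == 1.0

    def test_hand_value(self):
        # 8 present alleles each, 6 shared -> 12/16
        a = np.zeros(12)
        b = np.zeros(12)
        a[:8] = 1
        b[2:10] = 1
        assert dice_similarity(a, b) == pytest.approx(0.75)

    def test_disjoint(self):
        a = np.array([1.0, 1, 0, 0])
        b = np.array([0.0, 0, 1, 1])
        assert dice_similarity(a, b) == 0.0

    def test_symmetric_and_masked(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 20).astype(float)
        b = rng.integers(0, 2, 20).astype(float)
        a[3] = np.nan
        b[7] = np.nan
        assert dice_similarity(a, b) == dice_similarity(b, a)

    def test_no_shared_locus_errors(self):
        a = np.array([1.0, np.nan])
        b = np.array([np.nan, 1.0])
        with pytest.raises(DegenerateInputError):
            dice_similarity(a, b)


class TestGeneticDistance:
    def test_transforms(self):
        m = AlleleMatrix(
            ["a", "b"],
            [("L", 1), ("L", 2), ("L", 3), ("L", 4)],
            np.array([[1.0, 1, 0, 0], [1.0, 0, 1, 0]]),
        )
        d_sqrt = genetic_distance_matrix(m, sqrt=True)
        d_lin = genetic_distance_matrix(m, sqrt=False)
        s = 0.5
        assert d_lin.values[0, 1] == pytest.approx(1 - s)
        assert d_sqrt.values[0, 1] == pytest.approx(np.sqrt(1 - s))
        assert d_sqrt.metric == "dice_sorensen"

    def test_identical_samples_distance_zero(self):
        m = AlleleMatrix(["a", "b"], [("L", 1)], np.array([[1.0], [1.0]]))
        assert genetic_distance_matrix(m).values[0, 1] == 0.0


def _ward_d2_oracle(d: np.ndarray):
    """Naive Lance-Williams Ward.D2 agglomeration, O(n^3)."""
    n = d.shape[0]
    active = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(active) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        ni, nj = len(active[i]), len(active[j])
        merges.append((sorted((i, j)), h))
        members = active.pop(i) + active.pop(j)
        new = {}
        for k in active:
            nk = len(active[k])
            dki = dist[tuple(sorted((k, i)))]
            dkj = dist[tuple(sorted((k, j)))]
            dij = h
            val = np.sqrt(
                ((ni + nk) * dki**2 + (nj + nk) * dkj**2 - nk * dij**2) / (ni + nj + nk)
            )
            new[k] = val
        dist = {kv: v for kv, v in dist.items() if i not in kv and j not in kv}
        for k, v in new.items():
            dist[tuple(sorted((k, nxt)))] = v
        active[nxt] = members
        nxt += 1
    return merges


class TestWard:
    def test_two_samples(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]]))
        t = ward_tree(d)
        assert t.heights[0] == pytest.approx(0.4)

    def test_matches_lance_williams_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=(4, 3))
            from scipy.spatial.distance import pdist, squareform

            dm = squareform(pdist(x))
            d = DistanceMatrix(list("abcd"), dm)
            t = ward_tree(d)
            oracle = _ward_d2_oracle(dm)
            for row, (pair, h) in zip(t.linkage, oracle):
                assert sorted(row[:2].astype(int).tolist()) == pair
                assert row[2] == pytest.approx(h)

    def test_heights_monotone(self):
        rng = np.random.default_rng(9)
        from scipy.spatial.distance import pdist, squareform

        x = rng.normal(size=(15, 2))
        d = DistanceMatrix([f"s{i}" for i in range(15)], squareform(pdist(x)))
        t = ward_tree(d)
        assert (np.diff(t.heights) >= -1e-12).all()

    def test_planted_clusters_recovered(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix([f"s{i}" for i in range(20)], squareform(pdist(x)))
        part = cut_tree(ward_tree(d), 2)
        truth = Partition([f"s{i}" for i in range(20)], np.repeat([0, 1], 10))
        assert adjusted_rand_index(part, truth) == 1.0

    def test_clones_merge_first_at_height_zero(self):
        cfg = default_config()
        _, g, _, _ = generate(cfg, seed=3)
        m = allele_matrix(g)
        d = genetic_distance_matrix(m)
        t = ward_tree(d)
        # identical profiles exist (clones); first merge is at height 0
        assert t.heights[0] == pytest.approx(0.0, abs=1e-12)


class TestCutTree:
    def setup_method(self):
        from scipy.cluster.hierarchy import linkage

        rng = np.random.default_rng(4)
        self.ids = [f"s{i}" for i in range(8)]
        self.tree = ward_tree(
            DistanceMatrix(
                self.ids,
                _squareform_of(rng.normal(size=(8, 2))),
            )
        )

    def test_extremes(self):
        assert self.tree.cut(8).n_clusters == 8
        assert self.tree.cut(1).n_clusters == 1

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            self.tree.cut(0)
        with pytest.raises(ValueError):
            self.tree.cut(9)

    def test_nested_cuts_are_refinements(self):
        for k in range(1, 7):
            coarse = self.tree.cut(k).labels
            fine = self.tree.cut(k + 1).labels
            # every fine cluster maps into exactly one coarse cluster
            for lab in np.unique(fine):
                assert len(np.unique(coarse[fine == lab])) == 1


def _squareform_of(x):
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(x))


class TestARI:
    def test_identical_partitions(self):
        p = Partition(list("abcdef"), np.array([0, 0, 0, 1, 1, 1]))
        assert adjusted_rand_index(p, p) == 1.0

    def test_hand_example(self):
        # {123|456} vs {12|3456} -> (4 - 2.8) / (6.5 - 2.8)
        p1 = Partition(list("abcdef"), np.array([0, 0, 0, 1, 1, 1]))
        p2 = Partition(list("abcdef"), np.array([0, 0, 1, 1, 1, 1]))
        assert adjusted_rand_index(p1, p2) == pytest.approx(1.2 / 3.7, abs=1e-4)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(8)
        ids = [f"s{i}" for i in range(30)]
        l1 = rng.integers(0, 4, 30)
        l2 = rng.integers(0, 3, 30)
        base = adjusted_rand_index(Partition(ids, l1), Partition(ids, l2))
        perm = rng.permutation(4)
        assert adjusted_rand_index(Partition(ids, perm[l1]), Partition(ids, l2)) == pytest.approx(base)

    def test_order_insensitive_alignment(self):
        ids = list("abcd")
        p1 = Partition(ids, np.array([0, 0, 1, 1]))
        p2 = Partition(list(reversed(ids)), np.array([1, 1, 0, 0]))
        assert adjusted_rand_index(p1, p2) == 1.0

    def test_mismatched_sample_sets_error(self):
        p1 = Partition(list("abc"), np.zeros(3, dtype=int))
        p2 = Partition(list("abd"), np.zeros(3, dtype=int))
        with pytest.raises(ValidationError):
            adjusted_rand_index(p1, p2)

    def test_random_labelings_mean_near_zero(self):
        rng = np.random.default_rng(12)
        ids = [f"s{i}" for i in range(40)]
        vals = []
        for _ in range(1000):
            p1 = Partition(ids, rng.integers(0, 3, 40))
            p2 = Partition(ids, rng.integers(0, 3, 40))
            vals.append(adjusted_rand_index(p1, p2))
        assert abs(np.mean(vals)) < 0.02


class TestQMatrix:
    def test_argmax_assignment(self, tmp_path):
        p = tmp_path / "q.txt"
        p.write_text("0.9 0.1\n0.2 0.8\n")
        q = read_q_matrix(p)
        part = hard_assignment(q)
        np.testing.assert_array_equal(part.labels, [0, 1])

    def test_tie_warns_lowest_index(self, tmp_path):
        p = tmp_path / "q.txt"
        p.write_text("0.5 0.5\n0.2 0.8\n")
        q = read_q_matrix(p)
        with pytest.warns(UserWarning, match="tied"):
            part = hard_assignment(q)
        assert part.labels[0] == 0

    def test_three_column_fixture_sizes(self, tmp_path):
        p = tmp_path / "q.csv"
        rows = ["0.8,0.1,0.1"] * 3 + ["0.1,0.7,0.2"] * 4 + ["0.0,0.2,0.8"] * 2
        p.write_text("\n".join(rows) + "\n")
        part = hard_assignment(read_q_matrix(p))
        assert part.sizes() == {0: 3, 1: 4, 2: 2}

    def test_malformed_row_errors(self, tmp_path):
        p = tmp_path / "q.txt"
        p.write_text("0.9 x1\n")
        with pytest.raises(ValidationError):
            read_q_matrix(p)

    def test_bad_row_sum_rejected(self, tmp_path):
        p = tmp_path / "q.txt"
        p.write_text("0.9 0.3\n")
        with pytest.raises(ValidationError, match="sum"):
            read_q_matrix(p)


class TestEvanno:
    def test_hand_second_differences(self):
        runs = {
            1: [-100.5, -99.5],
            2: [-80.5, -79.5],
            3: [-75.5, -74.5],
            4: [-74.5, -73.5],
        }
        # sd = std([x-0.5, x+0.5], ddof=1) = 0.7071
        sd = np.std([-0.5, 0.5], ddof=1)
        table = evanno_delta_k(runs)
        assert table.delta_k[2] == pytest.approx(15 / sd)
        assert table.delta_k[3] == pytest.approx(4 / sd)
        assert table.best_k == 2

    def test_linear_likelihood_gives_zero(self):
        runs = {k: [-100.0 + 10 * k + e for e in (-1, 0, 1)] for k in range(1, 6)}
        table = evanno_delta_k(runs)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in table.delta_k.values())

    def test_constant_runs_excluded_with_warning(self):
        runs = {1: [-100.0, -99.0], 2: [-80.0, -80.0], 3: [-75.0, -74.0]}
        with pytest.warns(UserWarning, match="zero run-to-run sd"):
            table = evanno_delta_k(runs)
        assert 2 not in table.delta_k

    def test_requires_consecutive_ks_and_replicates(self):
        with pytest.raises(ValidationError):
            evanno_delta_k({1: [-1.0, -2.0], 3: [-1.0, -2.0], 4: [-1.0, -2.0]})
        with pytest.raises(ValidationError):
            evanno_delta_k({1: [-1.0], 2: [-1.0], 3: [-1.0]})
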
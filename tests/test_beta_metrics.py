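import math

import numpy as np
import pandas as pd
import pytest

from contribdiv import ValidationError, pairwise_matrix
from contribdiv.beta_metrics import (
    BUILTIN_BETA_METRICS,
    DistanceMatrix,
    bray_curtis,
    get_beta_metric,
    jaccard_binary,
    jensen_shannon,
    register_beta_metric,
    unweighted_unifrac,
    weighted_unifrac,
)
from contribdiv.fixtures import random_tree
from contribdiv.phylo import parse_newick
from contribdiv.tables_io import TaxonAbundanceTable

from ._oracles import (
    BETA_ORACLES,
    o_unweighted_unifrac,
    o_weighted_unifrac,
)
from .conftest import random_abundance_vectors


class TestNamedValues:
    @pytest.mark.parametrize(
        "x,y,expected",
        [((1, 2, 3), (1, 2, 3), 0.0), ((2, 0), (0, 2), 1.0), ((1, 1), (3, 1), 1 / 3)],
    )
    def test_bray_curtis(self, x, y, expected):
        assert bray_curtis(x, y) == pytest.approx(expected, abs=1e-12)

    def test_bray_curtis_both_zero_is_nan(self):
        assert math.isnan(bray_curtis([0.0], [0.0]))

    def test_bray_curtis_one_zero_is_one(self):
        assert bray_curtis([1.0, 2.0], [0.0, 0.0]) == 1.0

    @pytest.mark.parametrize(
        "x,y,expected",
        [((1, 1, 0), (0, 1, 1), 2 / 3), ((1, 2), (3, 4), 0.0), ((1, 0), (0, 1), 1.0)],
    )
    def test_jaccard_binary(self, x, y, expected):
        assert jaccard_binary(x, y) == pytest.approx(expected, abs=1e-12)

    def test_jensen_shannon_identical_is_zero(self):
        assert jensen_shannon([0.2, 0.8], [0.2, 0.8]) == pytest.approx(0.0, abs=1e-12)

    def test_jensen_shannon_disjoint_point_masses_is_ln2(self):
        assert jensen_shannon([1, 0], [0, 1]) == pytest.approx(math.log(2), abs=1e-12)

    def test_jensen_shannon_matches_direct_kl(self):
        got = jensen_shannon([0.5, 0.5], [1.0, 0.0])
        want = BETA_ORACLES["jensen_shannon"]([0.5, 0.5], [1.0, 0.0])
        assert got == pytest.approx(want, abs=1e-12)

    def test_mismatched_labels_rejected(self):
        x = pd.Series([1.0], index=["A"])
        y = pd.Series([1.0], index=["B"])
        with pytest.raises(ValidationError, match="label"):
            bray_curtis(x, y)


class TestUniFrac:
    tree = parse_newick("((A:1,B:1):1,C:2);")

    def _s(self, values):
        return pd.Series(values, index=list("ABC"), dtype=float)

    def test_unweighted_identical_presence_is_zero(self):
        x = self._s([1, 0, 1])
        assert unweighted_unifrac(x, 2 * x, self.tree) == 0.0

    def test_unweighted_star_disjoint_is_one(self):
        star = parse_newick("(A:1,B:1);")
        x = pd.Series([1.0, 0.0], index=["A", "B"])
        y = pd.Series([0.0, 1.0], index=["A", "B"])
        assert unweighted_unifrac(x, y, star) == 1.0

    def test_unweighted_worked_example(self):
        # x present {A,C}, y present {B,C}: A and B branches unshared (2)
        # over observed total 5
        x = self._s([5, 0, 2])
        y = self._s([0, 3, 1])
        assert unweighted_unifrac(x, y, self.tree) == pytest.approx(0.4, abs=1e-12)

    def test_unweighted_nothing_present_is_nan(self):
        z = self._s([0, 0, 0])
        assert math.isnan(unweighted_unifrac(z, z, self.tree))

    def test_weighted_identical_composition_is_zero(self):
        x = self._s([1, 2, 3])
        assert weighted_unifrac(x, 5 * x, self.tree) == pytest.approx(0.0, abs=1e-12)

    def test_weighted_star_disjoint_normalized_is_one(self):
        star = parse_newick("(A:1,B:1);")
        x = pd.Series([1.0, 0.0], index=["A", "B"])
        y = pd.Series([0.0, 1.0], index=["A", "B"])
        assert weighted_unifrac(x, y, star) == pytest.approx(1.0, abs=1e-12)

    def test_weighted_matches_branch_oracle(self):
        x = self._s([1, 0, 1])
        y = self._s([0, 1, 1])
        for normalized in (True, False):
            got = weighted_unifrac(x, y, self.tree, normalized=normalized)
            want = o_weighted_unifrac(
                dict(zip("ABC", x)), dict(zip("ABC", y)), self.tree, normalized
            )
            assert got == pytest.approx(want, abs=1e-12)

    def test_weighted_zero_sum_vector_is_nan(self):
        assert math.isnan(weighted_unifrac(self._s([0, 0, 0]), self._s([1, 0, 0]), self.tree))

    @pytest.mark.parametrize("seed", range(6))
    def test_random_trees_match_oracles_and_pruning(self, seed):
        """Mask-based UniFrac equals brute-force branch enumeration and the
        same computation on the tree pruned to present tips."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 17))
        tree = random_tree([f"T{i}" for i in range(n)], rng)
        names = [t.name for t in tree.tips()]
        x = pd.Series(np.where(rng.random(n) < 0.4, 0.0, rng.lognormal(0, 1, n)), index=names)
        y = pd.Series(np.where(rng.random(n) < 0.4, 0.0, rng.lognormal(0, 1, n)), index=names)
        if x.sum() == 0 or y.sum() == 0:
            pytest.skip("degenerate draw")
        xp = [t for t, v in x.items() if v > 0]
        yp = [t for t, v in y.items() if v > 0]
        assert unweighted_unifrac(x, y, tree) == pytest.approx(
            o_unweighted_unifrac(xp, yp, tree), abs=1e-9
        )
        assert weighted_unifrac(x, y, tree) == pytest.approx(
            o_weighted_unifrac(dict(x), dict(y), tree), abs=1e-9
        )
        # pruned-tree equivalence (same root retained by shear)
        pruned = tree.shear(sorted(set(xp) | set(yp)))
        xs = x[x > 0].reindex(sorted(set(xp) | set(yp)), fill_value=0.0)
        ys = y[y > 0].reindex(sorted(set(xp) | set(yp)), fill_value=0.0)
        assert unweighted_unifrac(x, y, tree) == pytest.approx(
            unweighted_unifrac(xs, ys, pruned), abs=1e-9
        )
        assert weighted_unifrac(x, y, tree) == pytest.approx(
            weighted_unifrac(xs, ys, pruned), abs=1e-9
        )


class TestStarTreeReductions:
    @pytest.mark.parametrize("seed", range(5))
    def test_unifrac_collapses_to_set_and_abundance_metrics(self, seed):
        """On a unit-branch star tree, unweighted UniFrac is binary Jaccard
        and normalized weighted UniFrac is Bray-Curtis of relative
        abundances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 10))
        names = [f"T{i}" for i in range(n)]
        star = parse_newick("(" + ",".join(f"{t}:1" for t in names) + ");")
        x = pd.Series(np.where(rng.random(n) < 0.35, 0.0, rng.lognormal(0, 1, n)), index=names)
        y = pd.Series(np.where(rng.random(n) < 0.35, 0.0, rng.lognormal(0, 1, n)), index=names)
        if x.sum() == 0 or y.sum() == 0:
            pytest.skip("degenerate draw")
        assert unweighted_unifrac(x, y, star) == pytest.approx(
            jaccard_binary(x, y), abs=1e-12
        )
        rel_x = x / x.sum()
        rel_y = y / y.sum()
        assert weighted_unifrac(x, y, star, normalized=True) == pytest.approx(
            bray_curtis(rel_x, rel_y), abs=1e-12
        )


class TestFormulaOracles:
    @pytest.mark.parametrize("name", sorted(BETA_ORACLES))
    def test_non_unifrac_metrics_match_naive(self, name, rng):
        metric = get_beta_metric(name).func
        oracle = BETA_ORACLES[name]
        vectors = random_abundance_vectors(rng, n=60)
        for i in range(0, len(vectors) - 1, 2):
            x, y = vectors[i], vectors[i + 1]
            if len(x) != len(y):
                y = np.resize(y, len(x))
            got = metric(x, y)
            want = oracle(list(x), list(y))
            assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(
                want, abs=1e-12
            ), f"{name} on {x} vs {y}"

    def test_symmetry_and_identity(self, rng):
        vectors = random_abundance_vectors(rng, n=20)
        for name in BETA_ORACLES:
            metric = get_beta_metric(name).func
            for i in range(0, 18, 2):
                x = vectors[i]
                y = np.resize(vectors[i + 1], len(x))
                d_xy, d_yx = metric(x, y), metric(y, x)
                assert (math.isnan(d_xy) and math.isnan(d_yx)) or d_xy == pytest.approx(
                    d_yx, abs=1e-12
                )
                if x.sum() > 0:
                    assert metric(x, x) == pytest.approx(0.0, abs=1e-12)


class TestPairwiseMatrix:
    def _table(self, arr, samples):
        taxa = [f"T{i}" for i in range(arr.shape[0])]
        return TaxonAbundanceTable(pd.DataFrame(arr, index=taxa, columns=samples))

    def test_identical_samples_all_zero_distance(self):
        t = self._table(np.array([[1.0, 1.0], [2.0, 2.0]]), ["s1", "s2"])
        dm = pairwise_matrix(t, "bray_curtis")
        assert dm.values.tolist() == [[0.0, 0.0], [0.0, 0.0]]

    def test_matches_double_loop(self, rng):
        arr = rng.lognormal(0, 1, size=(5, 4))
        arr[rng.random(arr.shape) < 0.3] = 0.0
        t = self._table(arr, [f"s{i}" for i in range(4)])
        dm = pairwise_matrix(t, "bray_curtis")
        for i in range(4):
            for j in range(4):
                want = BETA_ORACLES["bray_curtis"](list(arr[:, i]), list(arr[:, j]))
                assert dm.values[i, j] == pytest.approx(want, abs=1e-12)

    def test_euclidean_three_four_five(self):
        t = self._table(np.array([[0.0, 3.0], [0.0, 4.0]]), ["s1", "s2"])
        dm = pairwise_matrix(t, "euclidean")
        assert dm["s1", "s2"] == pytest.approx(5.0, abs=1e-12)

    def test_unknown_metric_lists_names(self):
        t = self._table(np.ones((2, 2)), ["s1", "s2"])
        with pytest.raises(ValidationError, match="bray_curtis"):
            pairwise_matrix(t, "nope")

    def test_single_sample_rejected(self):
        t = self._table(np.ones((2, 1)), ["s1"])
        with pytest.raises(ValidationError, match="2 samples"):
            pairwise_matrix(t, "bray_curtis")

    def test_nan_pairs_propagate_symmetrically(self):
        arr = np.array([[1.0, 0.0, 2.0], [1.0, 0.0, 0.0]])
        t = self._table(arr, ["s1", "s2", "s3"])
        dm = pairwise_matrix(t, "bray_curtis")
        # a single all-zero partner follows the formula (distance 1);
        # only the all-zero self-pair is undefined
        assert dm["s1", "s2"] == 1.0 and dm["s2", "s1"] == 1.0
        assert math.isnan(dm["s2", "s2"])
        assert dm["s1", "s3"] == dm["s3", "s1"]

    def test_tree_metric_matrix_matches_pair_calls(self, rng):
        tree = random_tree([f"T{i}" for i in range(5)], rng)
        names = [t.name for t in tree.tips()]
        arr = rng.lognormal(0, 1, size=(5, 3))
        arr[rng.random(arr.shape) < 0.3] = 0.0
        table = TaxonAbundanceTable(
            pd.DataFrame(arr, index=names, columns=["s1", "s2", "s3"])
        )
        dm = pairwise_matrix(table, "weighted_unifrac", tree=tree)
        for i, si in enumerate(["s1", "s2", "s3"]):
            for j, sj in enumerate(["s1", "s2", "s3"]):
                want = weighted_unifrac(
                    table.data[si], table.data[sj], tree
                )
                got = dm[si, sj]
                assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(
                    want, abs=1e-12
                )

    def test_write_square_and_condensed(self, tmp_path):
        t = self._table(np.array([[1.0, 2.0, 3.0]] * 2), ["a", "b", "c"])
        dm = pairwise_matrix(t, "manhattan")
        dm.to_tsv(tmp_path / "sq.tsv")
        back = pd.read_csv(tmp_path / "sq.tsv", sep="\t", index_col=0)
        assert np.allclose(back.to_numpy(), dm.values)
        dm.to_tsv(tmp_path / "lt.tsv", condensed=True)
        lt = pd.read_csv(tmp_path / "lt.tsv", sep="\t")
        assert len(lt) == 3

    def test_custom_beta_metric_registry(self):
        register_beta_metric("always_half", lambda x, y: 0.5 if (np.any(np.asarray(x) != np.asarray(y))) else 0.0)
        try:
            t = self._table(np.array([[1.0, 2.0]]), ["s1", "s2"])
            dm = pairwise_matrix(t, "always_half")
            assert dm["s1", "s2"] == 0.5
            with pytest.raises(ValidationError, match="already registered"):
                register_beta_metric("always_half", lambda x, y: 0.0)
        finally:
            from contribdiv.beta_metrics import _BETA_REGISTRY

            _BETA_REGISTRY.pop("always_half", None)

    def test_asymmetric_frame_rejected(self):
        df = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="symmetric"):
            DistanceMatrix(df)
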
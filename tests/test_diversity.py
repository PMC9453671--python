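"""Alpha/beta diversity statistics against hand computations and oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ecoassembly import (
    CommunityTable,
    ValidationError,
    bray_curtis,
    faith_pd,
    group_compare,
    kruskal_wallis_by_taxon,
    pcoa,
    percent_change,
    shannon,
    sobs,
)
from ecoassembly.diversity import compact_letters, significance_stars
from ecoassembly.simulate import simulate_tree

from .conftest import random_table


class TestSobs:
    @pytest.mark.parametrize("vec,expected", [([5, 0, 2], 2), ([0, 0], 0), ([], 0)])
    def test_examples(self, vec, expected):
        assert sobs(vec) == expected

    def test_counting_oracle(self):
        rng = np.random.default_rng(0)
        v = rng.poisson(0.8, 200) * rng.integers(0, 2, 200)
        assert sobs(v) == sum(1 for x in v if x > 0)


class TestShannon:
    def test_uniform_maximum(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(math.log(4), abs=1e-12)

    def test_single_taxon_zero(self):
        assert shannon([0, 7, 0]) == 0.0

    def test_direct_sum_oracle(self):
        # independent 10-digit direct summation for [1,2,3,4]
        p = [1 / 10, 2 / 10, 3 / 10, 4 / 10]
        expected = -sum(x * math.log(x) for x in p)  # 1.2798542258...
        assert shannon([1, 2, 3, 4]) == pytest.approx(expected, abs=1e-10)
        assert shannon([1, 2, 3, 4]) == pytest.approx(1.2798542258, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounded_by_log_richness(self, vec):
        h = shannon(vec)
        assert -1e-9 <= h <= math.log(sobs(vec)) + 1e-9

    def test_log2_base(self):
        assert shannon([1, 1], base=2) == pytest.approx(1.0)


class TestFaithPD:
    def test_star_tree(self):
        from skbio import TreeNode
        import io as _io

        star = TreeNode.read(_io.StringIO("(A:1,B:1,C:1,D:1);"))
        assert faith_pd([1, 1, 1, 0], ["A", "B", "C", "D"], star) == pytest.approx(3.0)

    def test_saturation_equals_total_branch_length(self, small_tree):
        total = sum(n.length or 0 for n in small_tree.traverse(include_self=False))
        assert faith_pd([1, 1, 1], ["A", "B", "C"], small_tree) == pytest.approx(total)

    def test_missing_taxon_named(self, small_tree):
        with pytest.raises(ValidationError, match="Z"):
            faith_pd([1], ["Z"], small_tree)

    def test_matches_reference_implementation(self):
        from skbio.diversity.alpha import faith_pd as skbio_faith_pd

        tree = simulate_tree(25, seed=9)
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(4)
        vec = (rng.random(25) < 0.4).astype(int)
        vec[0] = 1
        assert faith_pd(vec, tips, tree) == pytest.approx(
            float(skbio_faith_pd(vec, tips, tree)), abs=1e-9
        )

    def test_edge_union_oracle_and_monotonicity(self):
        tree = simulate_tree(30, seed=5)
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(1)

        def oracle(present):
            edges = {}
            for tip in tree.tips():
                if tip.name not in present:
                    continue
                node = tip
                while node.parent is not None:
                    edges[id(node)] = node.length
                    node = node.parent
            return sum(edges.values())

        prev = 0.0
        present: set = set()
        for tip in rng.permutation(tips):
            present.add(tip)
            vec = [1 if t in present else 0 for t in tips]
            pd_val = faith_pd(vec, tips, tree)
            assert pd_val == pytest.approx(oracle(present), abs=1e-9)
            assert pd_val >= prev - 1e-12  # adding taxa never decreases PD
            prev = pd_val


class TestPercentChange:
    @pytest.mark.parametrize(
        "treatment,control,expected",
        [
            (1529.25, 1130.38, 35.29),  # richness gain, mixed forest vs control
            (153.49, 122.51, 25.29),
            (1415.00, 1130.38, 25.18),
            (55.70, 79.01, -29.50),  # fungal PD loss, broadleaf vs control
            (7.0, 7.0, 0.00),
        ],
    )
    def test_reported_rounding(self, treatment, control, expected):
        assert percent_change(treatment, control) == expected

    def test_zero_control_rejected(self):
        with pytest.raises(ValidationError):
            percent_change(1.0, 0.0)

    def test_antisymmetry_identity(self):
        # percent_change(a,b) = -percent_change(b,a) * b/a, up to rounding
        a, b = 153.49, 122.51
        lhs = 100 * (a - b) / b
        rhs = -(100 * (b - a) / a) * (a / b)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestGroupCompare:
    def test_identical_groups_share_letter(self):
        out = group_compare({"g1": [5, 5, 5.1], "g2": [5, 5.1, 5]})
        assert out.loc["g1", "letters"] == out.loc["g2", "letters"] == "a"

    def test_separated_groups_differ(self):
        out = group_compare({"lo": [0, 0, 0.01], "hi": [100, 100, 100.01]})
        assert out.loc["lo", "letters"] != out.loc["hi", "letters"]
        assert out.attrs["anova_p"] < 0.001

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            group_compare({"a": [1], "b": [1, 2]})

    def test_letters_match_all_pairs_oracle(self):
        rng = np.random.default_rng(21)
        groups = {f"g{i}": rng.normal(loc=(3.0 if i == 2 else 0.0), size=8) for i in range(5)}
        out = group_compare(groups, alpha=0.05)

        # oracle: LSD p-matrix computed independently; two groups must share
        # a letter iff their pairwise test is non-significant
        arrays = {g: np.asarray(v) for g, v in groups.items()}
        n_tot = sum(len(v) for v in arrays.values())
        df_err = n_tot - len(arrays)
        mse = sum((len(v) - 1) * np.var(v, ddof=1) for v in arrays.values()) / df_err
        for g1, g2 in itertools.combinations(arrays, 2):
            se = math.sqrt(mse * (1 / len(arrays[g1]) + 1 / len(arrays[g2])))
            t = (arrays[g1].mean() - arrays[g2].mean()) / se
            p = 2 * stats.t.sf(abs(t), df_err)
            shared = set(out.loc[g1, "letters"]) & set(out.loc[g2, "letters"])
            assert bool(shared) == (p >= 0.05)

    def test_compact_letters_contract_on_synthetic_pmatrix(self):
        # a non-transitive significance pattern needs overlapping letters
        p = pd.DataFrame(1.0, index=list("abc"), columns=list("abc"))
        p.loc["a", "c"] = p.loc["c", "a"] = 0.001  # only a vs c differs
        letters = compact_letters(p, ["a", "b", "c"])
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])


class TestBrayCurtis:
    def test_hand_values(self):
        table = CommunityTable(
            pd.DataFrame({"x": [1, 1], "y": [1, 0], "z": [1, 1]}, index=["A", "B"]),
            pd.Series({"x": "g", "y": "g", "z": "g"}),
        )
        d = bray_curtis(table)
        assert d.loc["x", "y"] == pytest.approx(1 / 3)
        assert d.loc["x", "z"] == 0.0

    def test_disjoint_supports(self):
        table = CommunityTable(
            pd.DataFrame({"x": [3, 0], "y": [0, 5]}, index=["A", "B"]),
            pd.Series({"x": "g", "y": "g"}),
        )
        assert bray_curtis(table).loc["x", "y"] == 1.0

    def test_invariant_to_taxon_order_and_zero_padding(self):
        rng = np.random.default_rng(3)
        table = random_table(rng, 15, 6)
        d1 = bray_curtis(table)
        perm = rng.permutation(table.taxon_ids)
        shuffled = CommunityTable(table.counts.loc[perm], table.groups)
        padded = CommunityTable(
            pd.concat([table.counts, pd.DataFrame(0.0, index=["zzz"], columns=table.sample_ids)]),
            table.groups,
        )
        np.testing.assert_allclose(d1.values, bray_curtis(shuffled).values, atol=1e-12)
        np.testing.assert_allclose(d1.values, bray_curtis(padded).values, atol=1e-12)

    def test_brute_force_formula(self):
        rng = np.random.default_rng(8)
        table = random_table(rng, 20, 5)
        d = bray_curtis(table)
        x, y = table.counts["s1"].values, table.counts["s2"].values
        expected = 1 - 2 * np.minimum(x, y).sum() / (x + y).sum()
        assert d.loc["s1", "s2"] == pytest.approx(expected, abs=1e-12)


class TestPcoa:
    def test_two_samples(self):
        d = pd.DataFrame([[0, 4], [4, 0]], index=["a", "b"], columns=["a", "b"], dtype=float)
        res = pcoa(d)
        coords = res["coordinates"]["PC1"].values
        np.testing.assert_allclose(sorted(coords), [-2, 2], atol=1e-9)
        assert res["proportion_explained"]["PC1"] == pytest.approx(1.0)

    def test_three_equidistant(self):
        d = pd.DataFrame(1 - np.eye(3), index=list("abc"), columns=list("abc"))
        res = pcoa(d)
        np.testing.assert_allclose(res["proportion_explained"].values, [0.5, 0.5], atol=1e-9)

    def test_planted_points_reconstruction(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(pd.DataFrame(d))
        coords = res["coordinates"].values[:, :2]
        recon = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(recon, d, atol=1e-8)

    def test_matches_reference_implementation(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(12)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        mine = pcoa(pd.DataFrame(d))
        theirs = skbio_pcoa(DistanceMatrix(d), method="eigh")
        np.testing.assert_allclose(
            mine["proportion_explained"].values[:3],
            theirs.proportion_explained.values[:3],
            atol=1e-8,
        )

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValidationError):
            pcoa(d)


class TestKruskalWallis:
    def _table(self, rows, groups):
        counts = pd.DataFrame(rows, index=[f"t{i}" for i in range(len(rows))])
        counts.columns = [f"s{i}" for i in range(counts.shape[1])]
        return CommunityTable(counts, pd.Series(dict(zip(counts.columns, groups))))

    def test_identical_distributions(self):
        table = self._table([[3, 3, 3, 3]], ["a", "a", "b", "b"])
        out = kruskal_wallis_by_taxon(table)
        assert out.loc["t0", "H"] == 0.0
        assert out.loc["t0", "p"] == 1.0

    @pytest.mark.parametrize(
        "p,stars", [(0.004, "**"), (0.03, "*"), (0.0004, "***"), (0.2, "")]
    )
    def test_star_mapping(self, p, stars):
        assert significance_stars(p) == stars

    def test_exact_p_matches_enumeration_oracle(self):
        table = self._table([[1.0, 2.5, 7.0, 3.0, 9.0, 4.0]], ["a", "a", "b", "b", "c", "c"])
        out = kruskal_wallis_by_taxon(table, method="exact")

        # oracle: enumerate every assignment of the 6 values to groups of 2
        values = np.array([1.0, 2.5, 7.0, 3.0, 9.0, 4.0])

        def h_stat(groups):
            pooled = np.concatenate(groups)
            ranks = stats.rankdata(pooled)
            n = len(pooled)
            start, h = 0, 0.0
            for g in groups:
                h += ranks[start : start + len(g)].sum() ** 2 / len(g)
                start += len(g)
            return 12 / (n * (n + 1)) * h - 3 * (n + 1)

        h_obs = h_stat([values[:2], values[2:4], values[4:]])
        count = total = 0
        for perm in itertools.permutations(range(6)):
            v = values[list(perm)]
            total += 1
            if h_stat([v[:2], v[2:4], v[4:]]) >= h_obs - 1e-12:
                count += 1
        assert out.loc["t0", "p"] == pytest.approx(count / total, abs=1e-12)

    def test_absent_taxon_skipped_with_warning(self):
        table = self._table([[0, 0, 0, 0], [1, 2, 3, 4]], ["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="absent"):
            out = kruskal_wallis_by_taxon(table)
        assert "t0" not in out.index

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(2)
        table = random_table(rng, 12, 10, groups=["a"] * 5 + ["b"] * 5)
        out = kruskal_wallis_by_taxon(table, adjust=True)
        assert (out["p_adj"].values >= out["p"].values - 1e-12).all()
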
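"""MNTD/betaMNTD hand oracles, NTI sign conventions, betaNTI machinery."""

import numpy as np
import pytest

from mycoassembly import simulate
from mycoassembly.assembly import bmntd, bnti, mean_nti_test, mntd, nti, summarize_assembly
from mycoassembly.core import OtuTable
from mycoassembly.errors import DegenerateInputError, MissingTaxonError


def brute_force_mntd(abund, d, weighted):
    """Independent O(S^2) nearest-taxon oracle."""
    present = [i for i, a in enumerate(abund) if a > 0]
    nearest = {}
    for i in present:
        nearest[i] = min(d[i][j] for j in present if j != i)
    if weighted:
        total = sum(abund[i] for i in present)
        return sum(abund[i] / total * nearest[i] for i in present)
    return sum(nearest.values()) / len(present)


def brute_force_bmntd(ak, al, d, weighted):
    ik = [i for i, a in enumerate(ak) if a > 0]
    il = [j for j, a in enumerate(al) if a > 0]
    nk = {i: min(d[i][j] for j in il) for i in ik}
    nl = {j: min(d[i][j] for i in ik) for j in il}
    if weighted:
        tk, tl = sum(ak[i] for i in ik), sum(al[j] for j in il)
        return 0.5 * (
            sum(ak[i] / tk * nk[i] for i in ik) + sum(al[j] / tl * nl[j] for j in il)
        )
    return 0.5 * (np.mean(list(nk.values())) + np.mean(list(nl.values())))


class TestMntd:
    def test_pair_in_one_clade(self, small_tree):
        d = small_tree.cophenetic().filter(["A", "B", "C"]).data
        assert mntd([1, 1, 0], d) == pytest.approx(2.0)

    def test_weights_irrelevant_when_distances_equal(self, small_tree):
        d = small_tree.cophenetic().filter(["A", "B", "C"]).data
        assert mntd([3, 1, 0], d) == pytest.approx(2.0)

    def test_single_taxon_undefined(self, small_tree):
        d = small_tree.cophenetic().filter(["A", "B", "C"]).data
        with pytest.raises(DegenerateInputError):
            mntd([1, 0, 0], d)


class TestBmntd:
    def test_hand_examples(self, small_tree):
        d = small_tree.cophenetic().filter(["A", "B", "C"]).data
        assert bmntd([1, 0, 0], [0, 0, 1], d) == pytest.approx(4.0)
        assert bmntd([1, 0, 0], [1, 1, 0], d) == pytest.approx(0.5)
        assert bmntd([1, 1, 0], [1, 1, 0], d) == pytest.approx(0.0)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_on_random_instances(self, weighted):
        for s in range(30):
            rng = np.random.default_rng(s)
            n_tips = int(rng.integers(4, 15))
            tree = simulate.gen_tree(n_tips, seed=s)
            d = tree.cophenetic().filter(tree.tip_labels).data
            a = rng.integers(0, 4, n_tips)
            b = rng.integers(0, 4, n_tips)
            for v in (a, b):
                if (v > 0).sum() < 2:
                    v[:2] = 1
            assert bmntd(a, b, d, weighted) == pytest.approx(
                brute_force_bmntd(a, b, d, weighted), abs=1e-10
            )
            assert mntd(a, d, weighted) == pytest.approx(
                brute_force_mntd(a, d, weighted), abs=1e-10
            )


class TestNti:
    def test_clade_restricted_community_is_clustered(self):
        tree = simulate.gen_tree(40, seed=2)
        clades = simulate._two_deep_clades(tree)
        idx = {o: i for i, o in enumerate(tree.tip_labels)}
        counts = np.zeros((1, 40), int)
        for o in clades[0][:12]:
            counts[0, idx[o]] = 5
        tab = OtuTable(counts, ["clade"], tree.tip_labels)
        res = nti(tab, tree, n_null=199, seed=0)
        assert res.loc["clade", "nti"] > 0

    def test_full_community_has_zero_ses(self):
        tree = simulate.gen_tree(25, seed=3)
        tab = OtuTable(np.ones((1, 25), int), ["all"], tree.tip_labels)
        res = nti(tab, tree, n_null=199, seed=0)
        assert res.loc["all", "nti"] == 0.0
        assert res.loc["all", "p_value"] == pytest.approx(1.0)
        assert not res.loc["all", "defined"]

    def test_deterministic_and_column_order_invariant(self):
        tree = simulate.gen_tree(20, seed=4)
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 3, size=(4, 20))
        counts[:, 0] = 1
        counts[:, 1] = 1
        tab = OtuTable(counts, otu_ids=tree.tip_labels)
        a = nti(tab, tree, n_null=99, seed=11)["nti"]
        b = nti(tab, tree, n_null=99, seed=11)["nti"]
        assert (a == b).all()
        perm = list(np.random.default_rng(0).permutation(tree.tip_labels))
        c = nti(tab.select_otus(perm), tree, n_null=99, seed=11)["nti"]
        np.testing.assert_allclose(a.to_numpy(), c.to_numpy(), atol=1e-9)

    def test_missing_taxon_rejected(self, small_tree):
        tab = OtuTable([[1, 1]], ["s"], ["A", "Z"])
        with pytest.raises(MissingTaxonError):
            nti(tab, small_tree, n_null=99, seed=0)


class TestBnti:
    def test_pair_table_shape_and_bins(self):
        tree = simulate.gen_tree(30, seed=6)
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 5, size=(6, 30))
        counts[:, :2] = 1
        tab = OtuTable(counts, otu_ids=tree.tip_labels)
        res = bnti(tab, tree, n_null=99, seed=0)
        assert len(res.pairs) == 6 * 5 // 2
        s = res.summary
        total = s.frac_bnti_above_2 + s.frac_bnti_within + s.frac_bnti_below_minus2
        assert total == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        tree = simulate.gen_tree(20, seed=8)
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 4, size=(4, 20))
        counts[:, :2] = 1
        tab = OtuTable(counts, otu_ids=tree.tip_labels)
        a = bnti(tab, tree, n_null=99, seed=1).bnti_values()
        b = bnti(tab, tree, n_null=99, seed=1).bnti_values()
        np.testing.assert_array_equal(a, b)

    def test_matrix_form_matches_pairwise_calls(self):
        tree = simulate.gen_tree(15, seed=10)
        d = tree.cophenetic().filter(tree.tip_labels).data
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 4, size=(5, 15))
        counts[:, :2] = 1
        tab = OtuTable(counts, otu_ids=tree.tip_labels)
        res = bnti(tab, tree, n_null=99, seed=0)
        for _, row in res.pairs.iterrows():
            i = tab.sample_ids.index(row.sample_1)
            j = tab.sample_ids.index(row.sample_2)
            direct = bmntd(counts[i], counts[j], d)
            assert row.bmntd_obs == pytest.approx(direct, abs=1e-10)


class TestMeanNtiTest:
    def test_symmetric_values_not_significant(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(0, 1, 200)
        _, p = mean_nti_test(vals - vals.mean())
        assert p > 0.9

    def test_shifted_values_significant(self):
        rng = np.random.default_rng(13)
        t, p = mean_nti_test(3 + 0.01 * rng.normal(size=30))
        assert t > 0 and p < 1e-3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            mean_nti_test([1.0])
        with pytest.raises(DegenerateInputError):
            mean_nti_test([2.0, 2.0, 2.0])


def test_summarize_assembly_combines_both_statistics():
    tree = simulate.gen_tree(30, seed=14)
    rng = np.random.default_rng(15)
    counts = rng.integers(0, 5, size=(6, 30))
    counts[:, :3] = 1
    tab = OtuTable(counts, otu_ids=tree.tip_labels)
    nti_tab = nti(tab, tree, n_null=99, seed=0)
    bres = bnti(tab, tree, n_null=99, seed=1)
    summ = summarize_assembly(nti_tab, bres)
    assert summ.mean_nti is not None and np.isfinite(summ.nti_t_pvalue)
    assert summ.n_pairs == len(bres.pairs[bres.pairs.defined])
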
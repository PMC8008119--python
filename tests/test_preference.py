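"""Interaction matrices, d' specialization, 2DP randomization inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mycoassembly import simulate
from mycoassembly.core import OtuTable
from mycoassembly.errors import DegenerateInputError
from mycoassembly.preference import (
    InteractionMatrix,
    _patefield_draws,
    build_interaction_matrix,
    dprime,
    fdr_adjust,
    filter_abundant,
    standardized_preference,
)


def make_im(counts, caps=None):
    counts = np.asarray(counts)
    df = pd.DataFrame(
        counts,
        index=[f"o{i}" for i in range(counts.shape[0])],
        columns=[f"p{j}" for j in range(counts.shape[1])],
    )
    if caps is None:
        caps = pd.Series(counts.max(axis=0) + 2, index=df.columns)
    return InteractionMatrix(df, caps)


class TestBuildInteractionMatrix:
    @pytest.fixture
    def site_data(self):
        counts = np.array(
            [
                [5, 0, 2],  # plant A samples
                [3, 0, 1],
                [4, 1, 0],
                [0, 6, 0],  # plant B samples
                [0, 4, 2],
                [9, 9, 9],  # other site
            ]
        )
        table = OtuTable(counts, [f"s{i}" for i in range(6)], ["o1", "o2", "o3"])
        from mycoassembly.core import SampleMetadata

        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "host_species": ["A", "A", "A", "B", "B", "A"],
                    "site": ["x", "x", "x", "x", "x", "y"],
                },
                index=table.sample_ids,
            )
        )
        return table, meta

    def test_presence_counts(self, site_data):
        table, meta = site_data
        im = build_interaction_matrix(table, meta, "x")
        assert im.counts.loc["o1", "A"] == 3
        assert im.counts.loc["o2", "B"] == 2
        # capacities bound every cell
        assert (im.counts.le(im.samples_per_plant, axis=1)).all().all()

    def test_absent_site_rejected(self, site_data):
        table, meta = site_data
        with pytest.raises(KeyError):
            build_interaction_matrix(table, meta, "nowhere")

    def test_single_host_site_rejected(self, site_data):
        table, meta = site_data
        with pytest.raises(DegenerateInputError):
            build_interaction_matrix(table, meta, "y")


class TestFilterAbundant:
    def test_identity_at_one(self):
        im = make_im([[2, 0], [0, 1]])
        out = filter_abundant(im, 1)
        assert out.otu_ids == im.otu_ids

    def test_threshold_matches_brute_force(self):
        counts = np.array([[3, 1], [1, 0], [0, 4], [1, 1]])
        im = make_im(counts)
        out = filter_abundant(im, 3)
        expected = [f"o{i}" for i in range(4) if counts[i].sum() >= 3]
        assert out.otu_ids == expected

    def test_empty_result_rejected(self):
        with pytest.raises(DegenerateInputError):
            filter_abundant(make_im([[1, 0]]), 5)


class TestDprime:
    def test_exclusive_otus_fully_specialized(self):
        # 3 OTUs each exclusive to one plant, equal totals: d' = ln3/ln3 = 1
        im = make_im(10 * np.eye(3, dtype=int))
        np.testing.assert_allclose(dprime(im).to_numpy(), 1.0)

    def test_marginal_proportional_row_is_zero(self):
        im = make_im([[4, 2, 2], [4, 2, 2], [8, 4, 4]])
        assert dprime(im).iloc[0] == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(arrays(np.int64, (5, 3), elements=st.integers(0, 10)))
    def test_bounded_zero_one(self, counts):
        counts[counts.sum(axis=1) == 0, 0] = 1
        if counts.sum(axis=0).min() == 0:
            counts[0] += 1
        vals = dprime(make_im(counts)).to_numpy()
        assert np.all(vals >= 0) and np.all(vals <= 1)


class TestRandomization:
    def test_patefield_preserves_margins_on_every_draw(self):
        im = make_im(np.random.default_rng(0).integers(0, 6, size=(8, 4)) + 0)
        draws = _patefield_draws(im, 50, np.random.default_rng(1))
        a = im.counts.to_numpy()
        for d in draws:
            np.testing.assert_array_equal(d.sum(axis=1), a.sum(axis=1))
            np.testing.assert_array_equal(d.sum(axis=0), a.sum(axis=0))

    def test_block_diagonal_preference_detected(self):
        counts = np.zeros((9, 3), int)
        for i in range(9):
            counts[i, i % 3] = 10
        im = make_im(counts, caps=pd.Series([12, 12, 12], index=["p0", "p1", "p2"]))
        res = standardized_preference(im, n_rand=999, seed=0)
        assert (res.otu_table.p_fdr < 0.05).all()
        matched = res.pair_table[res.pair_table.observed > 0]
        assert matched.strong.all()
        assert (matched.two_dp > 1.6).all()

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 8, size=(6, 3))
        counts[counts.sum(axis=1) == 0, 0] = 1
        im = make_im(counts)
        res = standardized_preference(im, n_rand=199, seed=5)
        # permute OTU rows: 2DP matrix permutes identically
        order = list(np.random.default_rng(1).permutation(im.otu_ids))
        im2 = InteractionMatrix(im.counts.loc[order], im.samples_per_plant)
        res2 = standardized_preference(im2, n_rand=199, seed=5)
        got = res2.two_dp.loc[im.otu_ids]
        # same null family: values agree in distribution; check SES closeness
        np.testing.assert_allclose(
            got.to_numpy(), res.two_dp.to_numpy(), atol=0.6
        )

    def test_shuffle_null_alternative(self):
        im = make_im([[4, 0, 0], [0, 4, 0], [0, 0, 4]], caps=pd.Series([5, 5, 5], index=["p0", "p1", "p2"]))
        res = standardized_preference(im, n_rand=199, seed=0, null_model="shuffle")
        assert res.null_model == "shuffle"
        assert (res.pair_table[res.pair_table.observed > 0].two_dp > 0).all()


class TestFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([1.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_at_least_raw_and_monotone(self, ps):
        adj = fdr_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)
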
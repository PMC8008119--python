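"""PCoA/PCNM geometry and the distance-based permutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova

from mycoassembly.errors import DegenerateInputError
from mycoassembly.ordination import pcnm, pcnm_truncation_distance, pcoa
from mycoassembly.permtests import (
    envfit_vectors,
    mantel,
    partial_mantel,
    permanova,
    permdisp,
)


def euclidean_dm(points: np.ndarray) -> DistanceMatrix:
    return DistanceMatrix(
        squareform(pdist(points)), ids=[f"i{k}" for k in range(len(points))]
    )


class TestPcoa:
    def test_two_points_on_a_line(self):
        res = pcoa(euclidean_dm(np.array([[0.0], [3.0]])))
        np.testing.assert_allclose(
            np.abs(res.coordinates.to_numpy()[:, 0]), [1.5, 1.5], atol=1e-10
        )

    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        dm = euclidean_dm(pts)
        res = pcoa(dm)
        back = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(back, dm.data, atol=1e-8)
        assert res.n_negative_eigenvalues == 0

    def test_equilateral_distances_give_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-10)

    def test_axes_ordered_by_eigenvalue(self):
        rng = np.random.default_rng(1)
        res = pcoa(euclidean_dm(rng.normal(size=(10, 4))))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_single_item_rejected(self):
        with pytest.raises(DegenerateInputError):
            pcoa(DistanceMatrix(np.zeros((1, 1)), ids=["a"]))


class TestPcnm:
    @pytest.fixture
    def transect(self):
        # 10 equidistant collinear sites, 55.6 km apart
        x = np.arange(10.0)[:, None] * 55.6
        return euclidean_dm(x)

    def test_eigenvalues_positive_and_orthogonal(self, transect):
        res = pcnm(transect)
        assert (res.eigenvalues > 0).all()
        c = res.coordinates.to_numpy()
        gram = c.T @ c
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_matches_brute_force_eigendecomposition(self, transect):
        res = pcnm(transect)
        t = pcnm_truncation_distance(transect)
        d = transect.data.copy()
        d[d > t] = 4 * t
        np.fill_diagonal(d, 0)
        a = -0.5 * d**2
        centred = a - a.mean(0) - a.mean(1)[:, None] + a.mean()
        w, v = np.linalg.eigh(centred)
        w, v = w[::-1], v[:, ::-1]
        keep = w > 1e-8 * w[0]
        np.testing.assert_allclose(res.eigenvalues, w[keep], rtol=1e-8)
        expect = v[:, keep] * np.sqrt(w[keep])
        np.testing.assert_allclose(
            np.abs(res.coordinates.to_numpy()), np.abs(expect), atol=1e-8
        )

    def test_first_axis_single_wave_along_transect(self, transect):
        v1 = pcnm(transect).coordinates.iloc[:, 0].to_numpy()
        assert (np.diff(np.sign(v1)) != 0).sum() == 1  # one sign change

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            pcnm(DistanceMatrix(np.zeros((4, 4)), ids=list("abcd")))


class TestPermanova:
    def test_equals_classical_anova_univariate(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=24)
        groups = np.repeat(list("abc"), 8)
        dm = euclidean_dm(vals[:, None])
        res = permanova(dm, groups, n_perm=99, seed=0)
        f = stats.f_oneway(vals[:8], vals[8:16], vals[16:]).statistic
        assert res.statistic == pytest.approx(f, abs=1e-8)

    def test_agrees_with_skbio(self):
        rng = np.random.default_rng(4)
        dm = euclidean_dm(rng.normal(size=(18, 3)))
        groups = np.repeat(list("ab"), 9)
        ours = permanova(dm, groups, n_perm=99, seed=0)
        ref = skbio_permanova(dm, list(groups), permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"], abs=1e-8)

    def test_seed_reproducible_and_p_bounds(self):
        rng = np.random.default_rng(5)
        dm = euclidean_dm(rng.normal(size=(12, 2)))
        groups = np.repeat(list("ab"), 6)
        a = permanova(dm, groups, n_perm=199, seed=7)
        b = permanova(dm, groups, n_perm=199, seed=7)
        assert a.p_value == b.p_value
        assert 1 / 200 <= a.p_value <= 1.0

    def test_single_group_rejected(self):
        dm = euclidean_dm(np.zeros((4, 1)))
        with pytest.raises(ValueError):
            permanova(dm, ["a"] * 4, n_perm=99, seed=0)


class TestPermdisp:
    def test_mirror_groups_not_significant(self):
        hits = 0
        runs = 10
        for s in range(runs):
            rng = np.random.default_rng(s)
            a = rng.normal(0, 1, (15, 3))
            pts = np.vstack([a, -a + 10.0])  # identical dispersion
            dm = euclidean_dm(pts)
            res = permdisp(dm, np.repeat(list("ab"), 15), n_perm=199, seed=s)
            hits += res.p_value <= 0.05
        assert hits <= 1  # non-significant in >= 90% of runs

    def test_scaled_group_detected(self):
        hits = 0
        runs = 10
        for s in range(runs):
            rng = np.random.default_rng(100 + s)
            pts = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(0, 3, (20, 3))])
            dm = euclidean_dm(pts)
            res = permdisp(dm, np.repeat(list("ab"), 20), n_perm=199, seed=s)
            hits += res.p_value <= 0.05
        assert hits >= 9

    def test_centroid_option_and_singleton_exclusion(self, caplog):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(13, 2))
        groups = np.array(["a"] * 6 + ["b"] * 6 + ["c"])
        with caplog.at_level("WARNING"):
            res = permdisp(euclidean_dm(pts), groups, center="centroid", n_perm=99, seed=0)
        assert "singleton" in caplog.text
        assert np.isfinite(res.statistic)


class TestMantel:
    def test_identity_and_affine_give_r_one(self):
        rng = np.random.default_rng(8)
        dm = euclidean_dm(rng.normal(size=(10, 2)))
        affine = DistanceMatrix(2 * dm.data + 1 - np.eye(10), ids=list(dm.ids))
        assert mantel(dm, dm, n_perm=99, seed=0).statistic == pytest.approx(1.0)
        assert mantel(dm, affine, n_perm=99, seed=0).statistic == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_agrees_with_skbio(self, method):
        rng = np.random.default_rng(9)
        d1 = euclidean_dm(rng.normal(size=(12, 2)))
        d2 = euclidean_dm(rng.normal(size=(12, 2)))
        ours = mantel(d1, d2, n_perm=99, seed=0, method=method)
        ref_r, _, _ = skbio_mantel(d1, d2, method=method, permutations=0)
        assert ours.statistic == pytest.approx(ref_r, abs=1e-10)

    def test_constant_matrix_rejected(self):
        d = DistanceMatrix(np.ones((5, 5)) - np.eye(5), ids=list("abcde"))
        with pytest.raises(DegenerateInputError):
            mantel(d, d, n_perm=99, seed=0)


class TestPartialMantel:
    def test_zero_when_conditioning_on_self(self):
        rng = np.random.default_rng(10)
        d1 = euclidean_dm(rng.normal(size=(10, 2)))
        d2 = euclidean_dm(rng.normal(size=(10, 2)))
        res = partial_mantel(d1, d2, d1, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_independent_conditioner_leaves_r_unchanged(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(25, 2))
        d1 = euclidean_dm(base)
        d2 = euclidean_dm(base + rng.normal(0, 0.5, size=(25, 2)))
        d3 = euclidean_dm(rng.normal(size=(25, 2)))
        simple = mantel(d1, d2, n_perm=99, seed=0).statistic
        partial = partial_mantel(d1, d2, d3, n_perm=99, seed=0).statistic
        assert partial == pytest.approx(simple, abs=0.1)
        assert partial > 0.3  # signal recovered

    def test_detects_shared_structure(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(20, 2))
        d1 = euclidean_dm(base)
        d2 = euclidean_dm(base + rng.normal(0, 0.3, size=(20, 2)))
        d3 = euclidean_dm(rng.normal(size=(20, 2)))
        res = partial_mantel(d1, d2, d3, n_perm=199, seed=0)
        assert res.statistic > 0.5 and res.p_value <= 0.05


class TestEnvfit:
    def test_axis_aligned_variable_r2_one(self):
        rng = np.random.default_rng(13)
        dm = euclidean_dm(rng.normal(size=(15, 3)))
        ord_res = pcoa(dm)
        variables = pd.DataFrame(
            {"v": ord_res.coordinates.iloc[:, 0].to_numpy()},
            index=list(ord_res.coordinates.index),
        )
        fit = envfit_vectors(ord_res, variables, n_perm=99, seed=0)
        assert fit.loc["v", "r2"] == pytest.approx(1.0, abs=1e-10)
        norm = np.hypot(fit.loc["v", "direction_1"], fit.loc["v", "direction_2"])
        assert norm == pytest.approx(1.0, abs=1e-10)

    def test_noise_variable_p_calibrated(self):
        rng = np.random.default_rng(14)
        dm = euclidean_dm(rng.normal(size=(20, 3)))
        ord_res = pcoa(dm)
        ps = []
        for s in range(60):
            v = pd.DataFrame(
                {"noise": np.random.default_rng(s).normal(size=20)},
                index=list(ord_res.coordinates.index),
            )
            ps.append(envfit_vectors(ord_res, v, n_perm=99, seed=s).loc["noise", "p_value"])
        ps = np.array(ps)
        assert 0.3 <= ps.mean() <= 0.7  # roughly uniform
        assert (ps <= 0.05).mean() <= 0.12

    def test_constant_variable_rejected(self):
        rng = np.random.default_rng(15)
        ord_res = pcoa(euclidean_dm(rng.normal(size=(8, 2))))
        v = pd.DataFrame({"c": np.ones(8)}, index=list(ord_res.coordinates.index))
        with pytest.raises(DegenerateInputError):
            envfit_vectors(ord_res, v, n_perm=99, seed=0)
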
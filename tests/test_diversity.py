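import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes as scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity.alpha import chao1 as skbio_chao1, pielou_e as skbio_pielou
from skbio.stats.distance import permanova as skbio_permanova

from fluvidiv.diversity import (
    Ordination,
    bray_curtis,
    beta_dispersion,
    chao1,
    envfit_vector,
    kruskal_stress,
    nmds,
    permanova,
    pielou_evenness,
    procrustes_test,
)
from fluvidiv.otu_io import OTUTable


class TestAlpha:
    def test_hand_derived_values(self):
        assert chao1([5, 5, 5]) == 3.0
        assert chao1([1, 1, 2, 3]) == pytest.approx(4.5)
        assert chao1([1, 2]) == pytest.approx(2.0)
        assert pielou_evenness([10, 10, 10, 10]) == pytest.approx(1.0)
        assert pielou_evenness([9, 1]) == pytest.approx(0.4690, abs=1e-4)

    def test_degenerate_inputs(self):
        for bad in ([], [0, 0], [1.5, 2], [-1, 3]):
            with pytest.raises(ValueError):
                chao1(bad)
        with pytest.raises(ValueError):
            pielou_evenness([1, 0, 0])

    @pytest.mark.parametrize("seed", range(20))
    def test_chao1_dominates_observed_richness(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.integers(0, 6, size=30)
        if v.sum() == 0:
            v[0] = 1
        s_obs = int((v > 0).sum())
        est = chao1(v)
        assert est >= s_obs
        f1 = int((v == 1).sum())
        assert (est == s_obs) == (f1 <= 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_reference_implementation(self, seed):
        rng = np.random.default_rng(100 + seed)
        v = rng.integers(0, 20, size=50)
        v[:3] = [1, 1, 2]  # guarantee singletons/doubletons and >= 2 taxa
        assert chao1(v) == pytest.approx(float(skbio_chao1(v, bias_corrected=True)))
        assert pielou_evenness(v) == pytest.approx(float(skbio_pielou(v)))


class TestBrayCurtis:
    def test_hand_derived(self):
        t = OTUTable(
            pd.DataFrame([[2, 0, 4], [1, 1, 0]], index=["a", "b"], columns=["x", "y", "z"])
        )
        assert bray_curtis(t).data[0, 1] == pytest.approx(0.75)

    def test_identical_and_disjoint(self):
        t = OTUTable(
            pd.DataFrame(
                [[3, 1, 0, 0], [3, 1, 0, 0], [0, 0, 2, 2]],
                index=["a", "b", "c"],
                columns=list("wxyz"),
            )
        )
        d = bray_curtis(t)
        assert d["a", "b"] == 0.0
        assert d["a", "c"] == 1.0

    def test_shared_zero_taxa_irrelevant(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 10, size=(4, 8))
        t1 = OTUTable(pd.DataFrame(base, index=list("abcd")))
        padded = np.hstack([base, np.zeros((4, 3), dtype=int)])
        t2 = OTUTable(pd.DataFrame(padded, index=list("abcd")))
        np.testing.assert_allclose(bray_curtis(t1).data, bray_curtis(t2).data)

    def test_zero_total_sample_rejected(self):
        t = OTUTable(pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"]))
        with pytest.raises(ValueError, match="b"):
            bray_curtis(t)


def _pava(y: np.ndarray) -> np.ndarray:
    """Independent pool-adjacent-violators oracle (block-merging form)."""
    blocks = [[v, 1] for v in y]  # [mean, weight]
    out: list[list[float]] = []
    for b in blocks:
        out.append(b)
        while len(out) > 1 and out[-2][0] > out[-1][0]:
            m2, w2 = out.pop()
            m1, w1 = out.pop()
            out.append([(m1 * w1 + m2 * w2) / (w1 + w2), w1 + w2])
    return np.concatenate([[m] * int(w) for m, w in out])


class TestNMDS:
    def test_stress_matches_hand_pava_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(9, 2))
        noise = rng.normal(scale=0.3, size=(9, 3))
        dm = DistanceMatrix(squareform(pdist(noise + np.pad(x, ((0, 0), (0, 1))))),
                            ids=[str(i) for i in range(9)])
        d = pdist(x)
        delta = dm.condensed_form()
        order = np.lexsort((d, delta))
        dhat = np.empty_like(d)
        dhat[order] = _pava(d[order])
        expected = np.sqrt(((d - dhat) ** 2).sum() / (d**2).sum())
        assert kruskal_stress(x, dm) == pytest.approx(expected, abs=1e-12)

    def test_planar_points_recovered(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(size=(12, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(12)])
        ord_ = nmds(dm, k=2, n_restarts=8, seed=0)
        assert ord_.stress < 0.01

    def test_reported_stress_is_self_consistent(self):
        rng = np.random.default_rng(3)
        t = OTUTable(
            pd.DataFrame(
                rng.integers(0, 40, size=(10, 25)), index=[f"s{i}" for i in range(10)]
            )
        )
        dm = bray_curtis(t)
        ord_ = nmds(dm, k=2, n_restarts=5, seed=4)
        assert ord_.stress == pytest.approx(kruskal_stress(ord_.scores, dm), abs=1e-10)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 4))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(8)])
        a = nmds(dm, k=2, n_restarts=3, seed=5)
        b = nmds(dm, k=2, n_restarts=3, seed=5)
        np.testing.assert_array_equal(a.scores, b.scores)
        assert a.stress == b.stress

    def test_bad_k_rejected(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            nmds(dm, k=2)


class TestEnvfit:
    def _ordination(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return Ordination(
            ids=tuple(str(i) for i in range(n)),
            scores=rng.normal(size=(n, 2)),
            stress=0.1,
            k=2,
        )

    def test_perfect_alignment(self):
        ord_ = self._ordination()
        res = envfit_vector(ord_, ord_.scores[:, 0], n_perm=99, seed=1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_r2_matches_normal_equations_oracle(self):
        ord_ = self._ordination(n=5, seed=2)
        rng = np.random.default_rng(3)
        env = rng.normal(size=5)
        x = np.column_stack([np.ones(5), ord_.scores])
        beta = np.linalg.solve(x.T @ x, x.T @ env)
        resid = env - x @ beta
        r2_expected = 1 - (resid @ resid) / ((env - env.mean()) @ (env - env.mean()))
        res = envfit_vector(ord_, env, n_perm=9, seed=0)
        assert res.statistic == pytest.approx(r2_expected, abs=1e-12)

    def test_missing_values_dropped_pairwise(self):
        ord_ = self._ordination(n=12, seed=4)
        env = pd.Series(
            np.arange(12, dtype=float), index=[str(i) for i in range(12)]
        )
        env.iloc[3] = np.nan
        res = envfit_vector(ord_, env, n_perm=9, seed=0)
        assert res.extras["n_used"] == 11
        assert np.linalg.norm(res.extras["direction"]) == pytest.approx(1.0)


def _cluster_dm(n_per=5, sep=0.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_per, 3))
    b = rng.normal(size=(n_per, 3)) + sep
    pts = np.vstack([a, b])
    ids = [f"g{i}" for i in range(2 * n_per)]
    labels = np.array(["A"] * n_per + ["B"] * n_per)
    return DistanceMatrix(squareform(pdist(pts)), ids=ids), labels


class TestPermanova:
    def test_statistic_matches_reference_implementation(self):
        dm, labels = _cluster_dm(n_per=6, sep=1.0, seed=2)
        ours = permanova(dm, labels, n_perm=99, seed=0)
        ref = skbio_permanova(dm, grouping=list(labels), permutations=99)
        assert ours.statistic == pytest.approx(float(ref["test statistic"]), rel=1e-10)

    def test_separated_clusters_r2_near_one(self):
        dm, labels = _cluster_dm(n_per=5, sep=50.0, seed=1)
        res = permanova(dm, labels, n_perm=999, seed=0)
        assert res.extras["r2"] > 0.95
        # only 126 distinct 5+5 splits exist, so the attainable p floor is ~1/126
        assert res.p_value <= 0.02

    def test_degenerate_groupings_rejected(self):
        dm, labels = _cluster_dm()
        with pytest.raises(ValueError):
            permanova(dm, np.array(["A"] * len(labels)), n_perm=99)
        labels2 = labels.copy()
        labels2[0] = "C"
        with pytest.raises(ValueError, match="C"):
            permanova(dm, labels2, n_perm=99)


class TestProcrustes:
    def test_similarity_transform_recovered_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(7, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        y = 3.2 * x @ rot + np.array([5.0, -2.0])
        res = procrustes_test(x, y, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.extras["m2"] == pytest.approx(0.0, abs=1e-12)
        assert res.p_value <= 0.05

    def test_m2_matches_scipy_disparity(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
        res = procrustes_test(x, y, n_perm=9, seed=0)
        _, _, disparity = scipy_procrustes(x, y)
        assert res.extras["m2"] == pytest.approx(disparity, rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_r_bounded(self, seed):
        rng = np.random.default_rng(seed)
        res = procrustes_test(
            rng.normal(size=(6, 2)), rng.normal(size=(6, 2)), n_perm=19, seed=0
        )
        assert 0.0 <= res.statistic <= 1.0

    def test_mismatched_samples_rejected(self):
        x = pd.DataFrame(np.eye(3), index=["a", "b", "c"])
        y = pd.DataFrame(np.eye(3), index=["a", "b", "z"])
        with pytest.raises(ValueError, match="z"):
            procrustes_test(x, y, n_perm=9)


class TestBetaDispersion:
    def test_inflated_group_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3)) * 3.0  # same centroid, inflated spread
        pts = np.vstack([a, b])
        dm = DistanceMatrix(
            squareform(pdist(pts)), ids=[str(i) for i in range(20)]
        )
        labels = np.array(["A"] * 10 + ["B"] * 10)
        res, dists = beta_dispersion(dm, labels, n_perm=999, seed=0)
        assert (dists >= 0).all()
        means = res.extras["group_mean_distances"]
        assert means["B"] > means["A"]
        assert res.p_value < 0.05
        assert res.extras["mean_ratio"] >= 1.0

    def test_semimetric_distances_handled(self):
        # Bray-Curtis typically has negative PCoA eigenvalues
        rng = np.random.default_rng(2)
        t = OTUTable(
            pd.DataFrame(
                rng.integers(0, 30, size=(12, 20)), index=[f"s{i}" for i in range(12)]
            )
        )
        dm = bray_curtis(t)
        labels = np.array(["A"] * 6 + ["B"] * 6)
        res, dists = beta_dispersion(dm, labels, n_perm=99, seed=0)
        assert np.isfinite(res.statistic)
        assert (dists.to_numpy() >= 0).all()
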
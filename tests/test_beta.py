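import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from riverneutral import (
    DistanceMatrix,
    OtuTable,
    RiverNetwork,
    anosim,
    bray_curtis,
    distance_decay,
    geo_distances,
    mantel_test,
    partial_mantel,
    pcoa,
)


def _dm_from_points(points: np.ndarray, labels=None) -> DistanceMatrix:
    labels = labels or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), labels, "euclid")


@pytest.fixture
def point_dms():
    rng = np.random.default_rng(0)
    pts1 = rng.normal(size=(12, 2))
    pts2 = rng.normal(size=(12, 2))
    return _dm_from_points(pts1), _dm_from_points(pts2)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = OtuTable(
            pd.DataFrame(
                [[3, 1, 0], [3, 1, 0], [0, 0, 7]],
                index=["a", "b", "c"],
                columns=["x", "y", "z"],
            )
        )
        d = bray_curtis(t)
        assert d.values[0, 1] == pytest.approx(0.0)  # identical -> sim 1
        assert d.values[0, 2] == pytest.approx(1.0)  # disjoint -> sim 0
        s = bray_curtis(t, as_similarity=True)
        np.testing.assert_allclose(s.values, 1 - d.values, atol=1e-12)

    def test_hand_value(self):
        t = OtuTable(
            pd.DataFrame([[6, 2], [2, 2]], index=["a", "b"], columns=["x", "y"])
        )
        assert bray_curtis(t).values[0, 1] == pytest.approx(1 / 3)

    def test_range_and_symmetry(self, random_table):
        d = bray_curtis(random_table)
        assert ((d.values >= 0) & (d.values <= 1)).all()
        np.testing.assert_allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)


class TestGeoDistances:
    def test_same_point_zero(self):
        meta = pd.DataFrame(
            {"longitude": [116.0, 116.0], "latitude": [25.0, 25.0]}, index=["a", "b"]
        )
        assert geo_distances(meta).values[0, 1] == 0.0

    def test_one_degree_longitude_at_equator(self):
        meta = pd.DataFrame(
            {"longitude": [0.0, 1.0], "latitude": [0.0, 0.0]}, index=["a", "b"]
        )
        assert geo_distances(meta).values[0, 1] == pytest.approx(111.19, abs=0.1)

    def test_dendritic_y_network(self, y_network):
        meta = y_network.nodes
        dm = geo_distances(meta, network=y_network)
        i = list(meta.index).index("tipA")
        j = list(meta.index).index("tipB")
        assert dm.values[i, j] == pytest.approx(7.0)  # 3 km + 4 km via confluence
        assert dm.metric == "dendritic-km"

    def test_missing_site_errors(self, y_network):
        meta = pd.DataFrame(
            {"longitude": [116.0], "latitude": [25.0]}, index=["elsewhere"]
        )
        with pytest.raises(ValueError, match="elsewhere"):
            geo_distances(meta, network=y_network)


class TestMantel:
    def test_self_correlation(self, point_dms):
        dm1, _ = point_dms
        res = mantel_test(dm1, dm1, permutations=99, seed=0)
        assert res["r"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1 / 100)

    def test_rank_reversal_spearman(self, point_dms):
        dm1, _ = point_dms
        v = dm1.condensed()
        # build a matrix whose pair ranks are exactly reversed
        rev = squareform(v.max() + v.min() - v)
        dm_rev = DistanceMatrix(rev, dm1.labels, "reversed")
        res = mantel_test(dm1, dm_rev, method="spearman", permutations=99, seed=0)
        assert res["r"] == pytest.approx(-1.0)

    def test_agrees_with_skbio(self, point_dms):
        """Independent cross-check of r against scikit-bio's Mantel."""
        import skbio
        from skbio.stats.distance import mantel as sk_mantel

        dm1, dm2 = point_dms
        for method in ("pearson", "spearman"):
            ours = mantel_test(dm1, dm2, method=method, permutations=99, seed=0)
            r_sk, p_sk, _ = sk_mantel(
                skbio.DistanceMatrix(dm1.values, dm1.labels),
                skbio.DistanceMatrix(dm2.values, dm2.labels),
                method=method,
                permutations=999,
                alternative="greater",
                seed=0,
            )
            assert ours["r"] == pytest.approx(r_sk, abs=1e-12)

    def test_label_mismatch_errors(self, point_dms):
        dm1, dm2 = point_dms
        dm2b = DistanceMatrix(dm2.values, [f"x{i}" for i in range(dm2.n)], "euclid")
        with pytest.raises(ValueError, match="labels"):
            mantel_test(dm1, dm2b)

    def test_determinism(self, point_dms):
        dm1, dm2 = point_dms
        a = mantel_test(dm1, dm2, permutations=199, seed=3)
        b = mantel_test(dm1, dm2, permutations=199, seed=3)
        assert a == b


class TestPartialMantel:
    def test_unrelated_control_matches_plain(self):
        rng = np.random.default_rng(1)
        rs_plain, rs_partial = [], []
        for rep in range(15):
            pts = rng.normal(size=(14, 2))
            dm1 = _dm_from_points(pts)
            dm2 = _dm_from_points(pts + rng.normal(0, 0.4, size=pts.shape))
            dm3 = _dm_from_points(rng.normal(size=(14, 2)))
            rs_plain.append(mantel_test(dm1, dm2, permutations=99, seed=rep)["r"])
            rs_partial.append(
                partial_mantel(dm1, dm2, dm3, permutations=99, seed=rep)["r"]
            )
        assert np.mean(np.abs(np.array(rs_plain) - np.array(rs_partial))) < 0.08

    def test_confounder_fully_explains(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(14, 2))
        dm1 = _dm_from_points(pts)
        dm3 = _dm_from_points(pts)  # dm3 == geometry behind dm2
        dm2 = DistanceMatrix(2.0 * dm3.values + 0.5 * (dm3.values > 0), dm3.labels, "scaled")
        res = partial_mantel(dm1, dm2, dm3, method="pearson", permutations=99, seed=0)
        assert abs(res["r"]) < 0.35  # association mostly removed

    def test_self_control_degenerate(self, point_dms):
        dm1, _ = point_dms
        with pytest.warns(UserWarning, match="degenerate"):
            res = partial_mantel(dm1, dm1, dm1, permutations=99, seed=0)
        assert res["r"] == 0.0 and res["degenerate"]


class TestAnosim:
    def test_complete_separation(self):
        # two tight, well-separated clusters: all between > all within
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 0.05, (5, 2)), rng.normal(10, 0.05, (5, 2))])
        dm = _dm_from_points(pts)
        res = anosim(dm, ["g1"] * 5 + ["g2"] * 5, permutations=199, seed=0)
        assert res["R"] == pytest.approx(1.0)
        assert res["p"] < 0.05

    def test_random_labels_center_zero(self):
        rng = np.random.default_rng(4)
        rs = []
        for rep in range(30):
            pts = rng.normal(size=(12, 2))
            dm = _dm_from_points(pts)
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            rs.append(anosim(dm, labels, permutations=99, seed=rep)["R"])
        assert abs(np.mean(rs)) < 0.1

    def test_singleton_group_errors(self, point_dms):
        dm1, _ = point_dms
        with pytest.raises(ValueError, match="singleton|Singleton"):
            anosim(dm1, ["a"] + ["b"] * (dm1.n - 1))


class TestPcoa:
    def test_euclidean_recovery(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 2))
        dm = _dm_from_points(pts)
        res = pcoa(dm)
        coords = res["coordinates"].to_numpy()[:, :2]
        recon = squareform(pdist(coords))
        np.testing.assert_allclose(recon, dm.values, atol=1e-8)

    def test_axis_ordering(self, random_table):
        res = pcoa(bray_curtis(random_table))
        ev = res["eigenvalues"]
        assert np.all(np.diff(ev) <= 1e-12)
        pe = res["proportion_explained"]
        assert pe[0] >= pe[1]


class TestDistanceDecay:
    def test_pair_count_for_30_sites(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(30, 2))
        dm = _dm_from_points(pts)
        sim = DistanceMatrix(np.exp(-dm.values), dm.labels, "sim")
        res = distance_decay(sim, dm, permutations=99, seed=0)
        assert res["n_pairs"] == 435

    def test_linear_construction_slope(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 2))
        dm = _dm_from_points(pts)
        dmax = dm.values.max()
        sim = DistanceMatrix(1 - dm.values / dmax, dm.labels, "sim")
        res = distance_decay(sim, dm, permutations=99, seed=0)
        assert res["slope"] == pytest.approx(-1 / dmax, rel=1e-9)
        assert res["intercept"] == pytest.approx(1.0, abs=1e-9)
        assert res["p"] < 0.05
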
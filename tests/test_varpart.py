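import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from riverneutral import (
    DistanceMatrix,
    forward_select,
    rda_adjusted_r2,
    varpart2,
    varpart_mantel,
    vif_filter,
)
from riverneutral.varpart import ezekiel_adjust, _r2


class TestRdaR2:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 3))
        y = x @ rng.normal(size=(3, 5))
        assert rda_adjusted_r2(y, x) == pytest.approx(1.0, abs=1e-10)

    def test_intercept_only_is_zero(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(15, 4))
        x = np.empty((15, 0))
        assert rda_adjusted_r2(y, x) == 0.0

    def test_noise_adjusted_r2_unbiased(self):
        # pure-noise predictors: adjusted R² averages ~0 (raw R² would not)
        rng = np.random.default_rng(2)
        vals = [
            rda_adjusted_r2(rng.normal(size=(30, 6)), rng.normal(size=(30, 3)))
            for _ in range(300)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"])
        x["dup_of_a"] = x["a"]
        y = rng.normal(size=(12, 3))
        with pytest.raises(ValueError, match="dup_of_a"):
            rda_adjusted_r2(y, x)

    def test_saturated_design_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="n > p"):
            rda_adjusted_r2(rng.normal(size=(5, 2)), rng.normal(size=(5, 4)))


class TestVifFilter:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        x["c"] = x["a"]
        reduced, removed = vif_filter(x)
        assert len(removed) == 1
        assert removed[0] in {"a", "c"}
        assert reduced.shape[1] == 2

    def test_orthonormal_columns_untouched(self):
        q, _ = np.linalg.qr(np.random.default_rng(6).normal(size=(20, 4)))
        reduced, removed = vif_filter(pd.DataFrame(q, columns=list("abcd")))
        assert removed == []
        assert reduced.shape[1] == 4

    def test_known_correlation_vif_values(self):
        """Three equicorrelated columns (rho = 0.9): each VIF is
        1/(1 - R²) with R² from the analytic regression of one column on the
        other two, checked against an explicit least-squares oracle."""
        rng = np.random.default_rng(7)
        n = 40_000
        rho = 0.9
        cov = np.full((3, 3), rho) + np.diag([1 - rho] * 3)
        x = rng.multivariate_normal(np.zeros(3), cov, size=n)
        # analytic: R²_j = 2*rho² / (1 + rho) for equicorrelated triples
        r2_expected = 2 * rho**2 / (1 + rho)
        r2_hand = _r2(x[:, :1], x[:, 1:])
        assert r2_hand == pytest.approx(r2_expected, abs=0.01)
        vif_expected = 1 / (1 - r2_expected)  # ~ 6.8 -> below threshold 20
        reduced, removed = vif_filter(pd.DataFrame(x, columns=list("abc")))
        assert removed == []
        reduced2, removed2 = vif_filter(
            pd.DataFrame(x, columns=list("abc")), threshold=vif_expected * 0.8
        )
        assert len(removed2) >= 1

    def test_single_column_returned_unchanged(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        reduced, removed = vif_filter(x)
        assert removed == [] and reduced.shape[1] == 1


class TestForwardSelect:
    def test_all_noise_usually_empty(self):
        rng = np.random.default_rng(8)
        empties = 0
        runs = 30
        for rep in range(runs):
            y = rng.normal(size=(25, 4))
            x = pd.DataFrame(
                rng.normal(size=(25, 5)), columns=[f"v{j}" for j in range(5)]
            )
            sel = forward_select(y, x, permutations=99, seed=rep)
            empties += not sel
        assert empties >= 0.9 * runs * 0.9  # >= ~81% empty at alpha 0.05

    def test_true_predictor_found_first(self):
        rng = np.random.default_rng(9)
        hits = 0
        runs = 15
        for rep in range(runs):
            x = pd.DataFrame(
                rng.normal(size=(30, 5)), columns=[f"v{j}" for j in range(5)]
            )
            y = np.outer(x["v2"], rng.normal(size=4)) + 0.3 * rng.normal(size=(30, 4))
            sel = forward_select(y, x, permutations=99, seed=rep)
            hits += bool(sel) and sel[0] == "v2"
        assert hits >= 0.9 * runs

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        x = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        y = np.outer(x["b"], [1.0, -1.0]) + 0.5 * rng.normal(size=(25, 2))
        s1 = forward_select(y, x, permutations=199, seed=3)
        s2 = forward_select(y, x, permutations=199, seed=3)
        assert s1 == s2


class TestVarpart2:
    def test_fraction_identity_random_designs(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            y = rng.normal(size=(25, 6))
            xe = rng.normal(size=(25, 3))
            xs = rng.normal(size=(25, 2))
            res = varpart2(y, xe, xs)
            total = sum(res.fractions.values())
            assert total == pytest.approx(1.0, abs=1e-10)
            assert res.fractions["pure_env"] + res.fractions["shared"] == pytest.approx(
                res.details["adj_env"], abs=1e-10
            )
            assert res.fractions["pure_spatial"] + res.fractions[
                "shared"
            ] == pytest.approx(res.details["adj_spatial"], abs=1e-10)

    def test_identical_sets_have_no_pure_fractions(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=(20, 4))
        x = rng.normal(size=(20, 3))
        res = varpart2(y, x, x.copy())
        assert res.fractions["pure_env"] == pytest.approx(0.0, abs=1e-10)
        assert res.fractions["pure_spatial"] == pytest.approx(0.0, abs=1e-10)
        assert res.fractions["shared"] == pytest.approx(
            rda_adjusted_r2(y, x), abs=1e-10
        )

    def test_orthogonal_design_small_shared(self):
        rng = np.random.default_rng(13)
        n = 40
        q, _ = np.linalg.qr(rng.normal(size=(n, 4)))
        xe, xs = q[:, :2], q[:, 2:]
        y = xe @ rng.normal(size=(2, 5)) + 0.2 * rng.normal(size=(n, 5))
        res = varpart2(y, xe, xs)
        assert abs(res.fractions["shared"]) < 0.05
        assert res.fractions["pure_env"] > 0.5

    def test_empty_set_degenerate_report(self):
        rng = np.random.default_rng(14)
        y = rng.normal(size=(15, 3))
        with pytest.warns(UserWarning, match="empty"):
            res = varpart2(y, np.empty((15, 0)), rng.normal(size=(15, 2)))
        assert res.fractions["pure_env"] == 0.0
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-10)


class TestVarpartMantel:
    @staticmethod
    def _dm(points):
        return DistanceMatrix(
            squareform(pdist(points)), [f"s{i}" for i in range(len(points))], "d"
        )

    def test_identical_explanatory_no_pure(self):
        rng = np.random.default_rng(15)
        comm = self._dm(rng.normal(size=(12, 2)))
        env = self._dm(rng.normal(size=(12, 2)))
        res = varpart_mantel(comm, env, env, permutations=99, seed=0)
        assert res.fractions["pure_env"] == pytest.approx(0.0, abs=1e-9)
        assert res.fractions["pure_spatial"] == pytest.approx(0.0, abs=1e-9)

    def test_env_built_community_dominated_by_env(self):
        rng = np.random.default_rng(16)
        env_pts = rng.normal(size=(14, 2))
        env = self._dm(env_pts)
        comm = DistanceMatrix(env.values * 1.7, env.labels, "comm")
        spa = self._dm(rng.normal(size=(14, 2)))
        res = varpart_mantel(comm, env, spa, method="pearson", permutations=99, seed=0)
        assert res.fractions["pure_env"] > 0.8
        assert abs(res.fractions["pure_spatial"]) < 0.1

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(17)
        fracs = []
        for rep in range(10):
            comm = self._dm(rng.normal(size=(12, 2)))
            env = self._dm(rng.normal(size=(12, 2)))
            spa = self._dm(rng.normal(size=(12, 2)))
            res = varpart_mantel(comm, env, spa, permutations=99, seed=rep)
            fracs.append(res.fractions["pure_env"] + res.fractions["pure_spatial"])
        assert np.mean(fracs) < 0.15


def test_ezekiel_formula_spot_value():
    # n=30, p=3, R²=0.5 -> 1 - 0.5 * 29/26
    assert ezekiel_adjust(0.5, 30, 3) == pytest.approx(1 - 0.5 * 29 / 26)
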
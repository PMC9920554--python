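import itertools
import math

import numpy as np
import pytest
from sklearn.ensemble import RandomForestRegressor

from grapespec.interpretability import (
    ImportanceProfile,
    gini_importance,
    mean_rank,
    mutual_information_profile,
    sage_values,
    top_wavelengths,
    vip_scores,
)
from grapespec.model_zoo import fit


class TestMutualInformation:
    def test_independent_band_near_zero(self):
        rng = np.random.default_rng(0)
        vals = []
        for s in range(50):
            X = rng.normal(size=(100, 1))
            y = rng.normal(size=100)
            vals.append(mutual_information_profile(X, y, seed=s).scores[0])
        assert np.mean(vals) <= 0.05

    def test_deterministic_dependency_is_argmax(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 10))
        y = np.exp(X[:, 4])  # monotone function of band 4
        prof = mutual_information_profile(X, y, seed=0)
        assert int(np.argmax(prof.scores)) == 4

    def test_gaussian_closed_form(self):
        rho = 0.9
        rng = np.random.default_rng(2)
        x = rng.normal(size=2000)
        y = rho * x + math.sqrt(1 - rho**2) * rng.normal(size=2000)
        mi = mutual_information_profile(x[:, None], y, seed=0).scores[0]
        assert mi == pytest.approx(-0.5 * math.log(1 - rho**2), abs=0.1)

    def test_monotone_invariance_of_target(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2000, 1))
        y = 0.9 * x[:, 0] + 0.45 * rng.normal(size=2000)
        m1 = mutual_information_profile(x, y, seed=0).scores[0]
        m2 = mutual_information_profile(x, np.exp(y), seed=0).scores[0]
        assert m2 == pytest.approx(m1, rel=0.15)

    def test_constant_band_flagged_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 3))
        X[:, 1] = 2.0
        prof = mutual_information_profile(X, rng.normal(size=50), seed=0)
        assert prof.scores[1] == 0.0
        assert prof.diagnostics["constant_bands"] == [1]


def reference_vip(pls):
    """Textbook VIP with explicit loops (independent of the implementation)."""
    W, T, Q = pls.x_weights_, pls.x_scores_, pls.y_loadings_
    p, A = W.shape
    ss = [Q[0, a] ** 2 * float(T[:, a] @ T[:, a]) for a in range(A)]
    out = np.zeros(p)
    for j in range(p):
        num = sum(ss[a] * (W[j, a] ** 2 / float(W[:, a] @ W[:, a])) for a in range(A))
        out[j] = math.sqrt(p * num / sum(ss))
    return out


class TestVip:
    def _fitted(self, seed=0, n=60, p=12, ncomp=4):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = X[:, 0] - 2 * X[:, 5] + 0.2 * rng.normal(size=n)
        return fit("PLS", {"n_components": ncomp}, X, y)

    def test_mean_squared_vip_is_one(self):
        for seed in range(3):
            vip = vip_scores(self._fitted(seed)).scores
            assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-9)

    def test_single_feature_vip_is_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 1))
        y = 2 * X[:, 0] + 0.1 * rng.normal(size=30)
        vip = vip_scores(fit("PLS", {"n_components": 1}, X, y)).scores
        assert np.allclose(vip, [1.0])

    def test_matches_textbook_formula(self):
        m = self._fitted(seed=7)
        pls = m.model.named_steps["pls"]
        assert np.allclose(vip_scores(m).scores, reference_vip(pls), atol=1e-10)

    def test_informative_features_rank_highest(self):
        vip = vip_scores(self._fitted()).scores
        assert set(np.argsort(-vip)[:2]) == {0, 5}

    def test_non_pls_model_rejected(self):
        rng = np.random.default_rng(6)
        m = fit("RF", {"n_estimators": 50, "max_features": "sqrt"},
                rng.normal(size=(30, 4)), rng.normal(size=30))
        with pytest.raises(TypeError):
            vip_scores(m)


class TestGini:
    def test_scores_sum_to_one_and_nonnegative(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 6))
        y = X[:, 2] + 0.3 * rng.normal(size=80)
        g = gini_importance(fit("RF", {"n_estimators": 50, "max_features": "max"}, X, y, 0))
        assert g.scores.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(g.scores >= 0)

    def test_feature_never_split_scores_zero(self):
        rng = np.random.default_rng(8)
        X = np.column_stack([rng.normal(size=100), np.full(100, 5.0)])
        y = X[:, 0]
        g = gini_importance(fit("RF", {"n_estimators": 50, "max_features": "max"}, X, y, 0))
        assert g.scores[1] == 0.0

    def test_depth_one_single_informative_feature(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(100, 3))
        y = (X[:, 1] > 0).astype(float)
        rf = RandomForestRegressor(n_estimators=20, max_depth=1, random_state=0).fit(X, y)
        assert gini_importance(rf).scores[1] == pytest.approx(1.0)


def exhaustive_sage(w, b, Xb, Xe, ye):
    """Exact Shapley values for a linear model with marginal (background)
    imputation, by enumerating all coalitions."""
    d = len(w)

    def value(S):
        # E[f | x_S] = w_S . x_S + w_notS . mean(background)
        mask = np.zeros(d, bool)
        mask[list(S)] = True
        f = Xe[:, mask] @ w[mask] + Xb.mean(axis=0)[~mask] @ w[~mask] + b
        return -np.mean((ye - f) ** 2)

    phi = np.zeros(d)
    for j in range(d):
        others = [k for k in range(d) if k != j]
        for r in range(d):
            for S in itertools.combinations(others, r):
                weight = math.factorial(r) * math.factorial(d - r - 1) / math.factorial(d)
                phi[j] += weight * (value(S + (j,)) - value(S))
    return phi


class TestSage:
    def _setup(self, seed=0, d=3, n=200):
        rng = np.random.default_rng(seed)
        w = np.array([2.0, -1.0, 0.0][:d])
        Xb = rng.normal(size=(32, d))
        Xe = rng.normal(size=(40, d))
        ye = Xe @ w + 1.0 + 0.1 * rng.normal(size=40)
        predict = lambda X: X @ w + 1.0
        return w, Xb, Xe, ye, predict

    def test_null_player_scores_zero_within_error(self):
        w, Xb, Xe, ye, predict = self._setup()
        prof = sage_values(predict, Xb, Xe, ye, n_permutations=64, seed=0)
        assert abs(prof.scores[2]) <= 3 * prof.stderr[2] + 1e-9

    def test_matches_exhaustive_shapley_enumeration(self):
        w, Xb, Xe, ye, predict = self._setup()
        prof = sage_values(predict, Xb, Xe, ye, n_permutations=128, seed=1)
        exact = exhaustive_sage(w, 1.0, Xb, Xe, ye)
        for j in range(3):
            assert abs(prof.scores[j] - exact[j]) <= 3 * prof.stderr[j] + 1e-9

    def test_efficiency_scores_sum_to_loss_reduction(self):
        w, Xb, Xe, ye, predict = self._setup()
        prof = sage_values(predict, Xb, Xe, ye, n_permutations=16, seed=2)
        d = prof.diagnostics
        assert prof.scores.sum() == pytest.approx(d["base_loss"] - d["full_model_loss"],
                                                  abs=1e-9)

    def test_stderr_shrinks_with_permutation_budget(self):
        w, Xb, Xe, ye, predict = self._setup()
        ses = [sage_values(predict, Xb, Xe, ye, n_permutations=nb, seed=3).stderr.mean()
               for nb in (8, 32, 128)]
        assert ses[0] > ses[1] > ses[2]
        # 1/sqrt(n): 16x the budget should shrink stderr about 4x
        assert ses[0] / ses[2] == pytest.approx(4.0, rel=0.5)

    def test_grouped_bands_preserve_efficiency(self):
        rng = np.random.default_rng(20)
        w = np.array([2.0, -1.0, 0.0, 0.5, 0.0, 0.0])
        Xb = rng.normal(size=(24, 6))
        Xe = rng.normal(size=(30, 6))
        ye = Xe @ w + 0.1 * rng.normal(size=30)
        predict = lambda X: X @ w
        prof = sage_values(predict, Xb, Xe, ye, n_permutations=16, seed=4,
                           group_size=2)
        d = prof.diagnostics
        assert d["n_groups"] == 3
        assert prof.scores.sum() == pytest.approx(
            d["base_loss"] - d["full_model_loss"], abs=1e-9)
        # bands of one group share the (split) group credit
        assert prof.scores[4] == prof.scores[5]

    def test_invalid_budget_rejected(self):
        w, Xb, Xe, ye, predict = self._setup()
        with pytest.raises(ValueError):
            sage_values(predict, Xb, Xe, ye, n_permutations=0, seed=0)


class TestMeanRank:
    def _profile(self, scores, method="MI", wl=None):
        return ImportanceProfile(method, np.asarray(scores, float),
                                 wavelengths=wl, fold="1")

    def test_identical_profiles_unchanged(self):
        profs = [self._profile([1.0, 2.0, 3.0]) for _ in range(5)]
        assert np.allclose(mean_rank(profs).scores, [1, 2, 3])

    def test_symmetric_two_fold_average(self):
        out = mean_rank([self._profile([1.0, 0.0]), self._profile([0.0, 1.0])])
        assert np.allclose(out.scores, [0.5, 0.5])
        assert np.allclose(out.diagnostics["mean_ranks"], [1.5, 1.5])

    def test_random_profiles_elementwise_average(self):
        rng = np.random.default_rng(10)
        mats = rng.uniform(size=(5, 7))
        out = mean_rank([self._profile(m) for m in mats])
        assert np.allclose(out.scores, mats.mean(axis=0))
        assert out.fold == "mean"

    def test_mismatched_grids_rejected(self):
        a = self._profile([1.0, 2.0], wl=np.array([400.0, 500.0]))
        b = self._profile([1.0, 2.0], wl=np.array([400.0, 600.0]))
        with pytest.raises(ValueError):
            mean_rank([a, b])

    def test_averaging_never_shrinks_support(self):
        rng = np.random.default_rng(11)
        profs = []
        for _ in range(5):
            s = np.zeros(10)
            s[rng.choice(10, 3, replace=False)] = rng.uniform(size=3)
            profs.append(self._profile(s))
        merged = mean_rank(profs)
        assert np.count_nonzero(merged.scores) >= max(
            np.count_nonzero(p.scores) for p in profs)


def test_top_wavelengths_orders_by_score():
    prof = ImportanceProfile("MI", np.array([0.1, 0.9, 0.5]),
                             wavelengths=np.array([400.0, 500.0, 600.0]))
    assert list(top_wavelengths(prof, 2)) == [500.0, 600.0]
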
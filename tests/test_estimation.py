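import numpy as np
import pytest

import t2gwg as tg
from t2gwg import estimation as est
from t2gwg.families import get_family


class _IdealUniform:
    """Uniform(0,1)-cdf stand-in to probe objectives at chosen u-values."""

    def cdf(self, x):
        return np.clip(np.asarray(x, dtype=float), 0.0, 1.0)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where((x > 0) & (x < 1), 0.0, -np.inf)


class TestObjectiveValues:
    def test_nll_single_observation(self, t2gwe_111):
        # -log pdf(log 2) = 1 - log 2
        val = est.nll(t2gwe_111, [np.log(2.0)])
        assert val == pytest.approx(1.0 - np.log(2.0), rel=1e-12)

    def test_score_vanishes_componentwise_at_stationary_point(self, t2gwe_111):
        # d l / d alpha = 1/alpha - (H/Hbar)^(-beta) = 0 at x = log 2
        s = est.score(t2gwe_111, [np.log(2.0)])
        assert s[0] == pytest.approx(0.0, abs=1e-12)

    def test_ls_zero_at_perfect_plotting_positions(self):
        n = 7
        u = np.arange(1, n + 1) / (n + 1)
        assert est.ls_objective(_IdealUniform(), u) == pytest.approx(0.0, abs=1e-16)

    def test_ls_and_wls_single_point(self):
        # n=1, F=0.75: LS = (0.75-0.5)^2; WLS weight (n+1)^2(n+2)/[i(n-i+1)] = 12
        assert est.ls_objective(_IdealUniform(), [0.75]) == pytest.approx(0.0625)
        assert est.wls_objective(_IdealUniform(), [0.75]) == pytest.approx(0.75)

    def test_cvm_constant_at_centered_positions(self):
        n = 5
        u = (2 * np.arange(1, n + 1) - 1) / (2 * n)
        assert est.cvm_objective(_IdealUniform(), u) == pytest.approx(1.0 / 300.0)

    def test_cvm_single_point(self):
        # 1/(12 n^2) + (1/n)(0.75 - (2i-1)/(2n))^2 at i = n = 1
        assert est.cvm_objective(_IdealUniform(), [0.75]) == pytest.approx(
            1.0 / 12.0 + 0.0625)

    def test_cvm_invariant_to_tie_relabeling(self, t2gwe_table):
        d = t2gwe_table.rvs(40, seed=0)
        d[5] = d[11]
        shuffled = np.random.default_rng(1).permutation(d)
        assert est.cvm_objective(t2gwe_table, d) == pytest.approx(
            est.cvm_objective(t2gwe_table, shuffled), rel=1e-14)

    def test_ad_single_point(self):
        # -1 - (log u + log(1-u)) at u = 0.5
        assert est.ad_objective(_IdealUniform(), [0.5]) == pytest.approx(
            -1.0 - 2.0 * np.log(0.5))

    def test_ad_matches_naive_two_loop_reference(self, t2gwe_table, rng):
        for _ in range(5):
            d = t2gwe_table.rvs(23, seed=int(rng.integers(1 << 30)))
            x = np.sort(d)
            u = t2gwe_table.cdf(x)
            n = len(x)
            ref = -n
            for i in range(1, n + 1):
                ref -= (2 * i - 1) / n * (np.log(u[i - 1]) + np.log(1 - u[n - i]))
            assert est.ad_objective(t2gwe_table, d) == pytest.approx(ref, rel=1e-12)

    def test_mps_equal_spacings(self):
        # n=2 with F values (1/3, 2/3): three equal spacings of 1/3
        assert est.mps_objective(_IdealUniform(), [1 / 3, 2 / 3]) == pytest.approx(
            -np.log(1 / 3))

    def test_mps_spacings_sum_to_one(self, t2gwe_table):
        d = np.sort(t2gwe_table.rvs(50, seed=3))
        ss = est.SpacingSet.from_model(t2gwe_table, d)
        assert np.sum(ss.spacings) == pytest.approx(1.0, abs=1e-12)
        assert np.all(ss.spacings >= 0)

    def test_mps_optimum_is_equal_spacing(self):
        # AM-GM: mean log spacing is maximal at equal spacings (grid search, n=2)
        best = -np.inf
        arg = None
        for u1 in np.linspace(0.01, 0.98, 98):
            for u2 in np.linspace(u1 + 0.01, 0.99, 99):
                w = (np.log(u1) + np.log(u2 - u1) + np.log(1 - u2)) / 3
                if w > best:
                    best, arg = w, (u1, u2)
        assert best <= np.log(1 / 3) + 1e-12
        assert arg == pytest.approx((1 / 3, 2 / 3), abs=0.02)
        # the analytic optimum dominates every grid point
        assert -est.mps_objective(_IdealUniform(), [1 / 3, 2 / 3]) >= best

    def test_mps_handles_exact_ties(self, t2gwe_table):
        d = t2gwe_table.rvs(30, seed=4)
        d[7] = d[3]
        val = est.mps_objective(t2gwe_table, d)
        assert np.isfinite(val)


FAMILIES_WITH_GRADS = ["t2gwe", "t2gwu", "t2gwp"]
GRAD_METHODS = ["mle", "ls", "wls", "mps", "cvm", "ad"]


class TestGradients:
    @pytest.mark.parametrize("method", GRAD_METHODS)
    @pytest.mark.parametrize("family", FAMILIES_WITH_GRADS)
    def test_analytic_gradient_matches_finite_differences(self, family, method,
                                                          fd_grad, rng):
        fam = get_family(family)
        truth = {"t2gwe": [2.5, 0.8, 1.3], "t2gwu": [0.7, 0.9, 3.0],
                 "t2gwp": [1.4, 1.1, 0.8, 2.2]}[family]
        data = np.sort(fam.make(np.array(truth)).rvs(60, seed=9))

        def value_at(params):
            model = fam.make(params)
            out = est._objective_value_grad(method, model, data, False)
            return out[0] if isinstance(out, tuple) else out

        for _ in range(10):
            params = np.array(truth) * rng.uniform(0.8, 1.25, size=len(truth))
            if family == "t2gwu":
                params[2] = max(params[2], data.max() * 1.02)
            if family == "t2gwp":
                params[2] = min(params[2], data.min() * 0.98)
            model = fam.make(params)
            _, g = est._objective_value_grad(method, model, data, True)
            fd = fd_grad(value_at, params)
            assert np.allclose(g, fd, rtol=1e-5, atol=1e-6 * max(1, np.max(np.abs(fd))))


class TestFit:
    def test_mle_recovers_truth_at_n1000(self):
        truth = np.array([2.5, 0.8, 1.3])
        data = tg.t2gwe(*truth).rvs(1000, seed=17)
        r = tg.fit(data, family="t2gwe", method="mle", seed=0)
        assert r.converged
        # published table root-MSEs at n=1000: 0.34, 0.06, 0.16
        assert np.all(np.abs(r.estimates - truth) < 3 * np.array([0.34, 0.06, 0.16]))
        # first-order condition at the optimum
        fam = get_family("t2gwe")
        s = est.score(fam.make(r.estimates), np.sort(data))
        assert np.max(np.abs(s)) < 1e-3

    def test_objective_value_is_reproducible_from_estimates(self):
        data = tg.t2gwe(2.5, 0.8, 1.3).rvs(200, seed=21)
        for method in GRAD_METHODS:
            r = tg.fit(data, family="t2gwe", method=method, seed=0)
            fam = get_family("t2gwe")
            model = fam.make(r.estimates)
            out = est._objective_value_grad(method, model, np.sort(data), False)
            val = out[0] if isinstance(out, tuple) else out
            assert val == pytest.approx(r.objective, abs=1e-8)

    @pytest.mark.parametrize("method", GRAD_METHODS)
    def test_fitted_objective_not_worse_than_truth(self, method):
        truth = np.array([2.5, 0.8, 1.3])
        data = tg.t2gwe(*truth).rvs(400, seed=33)
        r = tg.fit(data, family="t2gwe", method=method, seed=0)
        model = get_family("t2gwe").make(truth)
        out = est._objective_value_grad(method, model, np.sort(data), False)
        at_truth = out[0] if isinstance(out, tuple) else out
        assert r.objective <= at_truth + 1e-9

    def test_mle_scale_equivariance(self):
        data = tg.t2gwe(2.5, 0.8, 1.3).rvs(500, seed=5)
        c = 3.7
        r1 = tg.fit(data, family="t2gwe", method="mle", seed=0, compute_se=False)
        r2 = tg.fit(data * c, family="t2gwe", method="mle", seed=0, compute_se=False)
        assert r2.params["alpha"] == pytest.approx(r1.params["alpha"], rel=1e-5)
        assert r2.params["beta"] == pytest.approx(r1.params["beta"], rel=1e-5)
        assert r2.params["gamma"] == pytest.approx(r1.params["gamma"] / c, rel=1e-5)

    def test_standard_errors_only_for_mle(self):
        data = tg.t2gwe(2.5, 0.8, 1.3).rvs(300, seed=8)
        r_mle = tg.fit(data, family="t2gwe", method="mle", seed=0)
        r_ls = tg.fit(data, family="t2gwe", method="ls", seed=0)
        assert r_mle.se is not None and np.all(r_mle.se > 0)
        assert r_ls.se is None

    def test_degenerate_constant_data_does_not_crash(self):
        r = tg.fit(np.full(20, 3.0), family="t2gwe", method="mle", seed=0,
                   compute_se=False)
        assert isinstance(r, est.FitResult)

    def test_gradient_free_family_fit(self):
        data = np.random.default_rng(10).weibull(1.5, size=400) * 2.0
        r = tg.fit(data, family="weibull", method="mle", seed=0, compute_se=False)
        assert r.converged
        assert r.params["k"] == pytest.approx(1.5, abs=0.25)
        assert r.params["lam"] == pytest.approx(2.0, abs=0.3)

    def test_result_serializes_to_json(self):
        data = tg.t2gwe(2.5, 0.8, 1.3).rvs(100, seed=12)
        r = tg.fit(data, family="t2gwe", method="mle", seed=3)
        import json
        blob = json.loads(r.to_json())
        assert blob["method"] == "mle" and blob["family"] == "t2gwe"
        assert set(blob["estimates"]) == {"alpha", "beta", "gamma"}

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            tg.fit([1.0, 2.0], family="t2gwe", method="nope")
        with pytest.raises(ValueError):
            tg.fit([], family="t2gwe")
        with pytest.raises(ValueError):
            tg.fit([1.0], family="t2gwe", method="mps")
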
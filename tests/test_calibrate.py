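"""WSSRES objective, screening, least-squares fitting and inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chokinet as ck
from chokinet.calibrate import (ObservationError, ObservationSet,
                                _se_from_jacobian, wssres_by_variable)


def _obs_from_rows(rows):
    return ObservationSet(pd.DataFrame(
        rows, columns=["time_h", "variable", "replicate", "value"]))


class TestObservationSet:
    def test_missing_column_rejected(self):
        df = pd.DataFrame({"time_h": [0.0], "variable": ["GLC"],
                           "value": [30.0]})
        with pytest.raises(ObservationError, match="replicate"):
            ObservationSet(df)

    def test_unmapped_variable_rejected(self):
        with pytest.raises(ObservationError, match="unmapped"):
            _obs_from_rows([(0.0, "NOPE", 1, 1.0)])

    def test_pooled_variance_from_duplicates(self):
        obs = _obs_from_rows([(0.0, "GLC", 1, 29.0), (0.0, "GLC", 2, 31.0),
                              (24.0, "GLC", 1, 25.0), (24.0, "GLC", 2, 27.0)])
        # per-time variances are 2.0 and 2.0 -> pooled 2.0
        assert obs.variance["GLC"] == pytest.approx(2.0)

    def test_variance_floor_when_replicates_coincide(self):
        obs = _obs_from_rows([(0.0, "GLC", 1, 30.0), (0.0, "GLC", 2, 30.0)])
        assert obs.variance["GLC"] > 0


class TestWssres:
    def test_exact_match_is_zero(self, parental_truth, net):
        obs, traj = parental_truth
        assert ck.wssres(obs, traj) == pytest.approx(0.0, abs=1e-12)

    def test_single_residual_arithmetic(self, net, parental_params):
        """One variable, one time, residual 2, variance 4 -> 2^2/4 = 1."""
        traj = ck.simulate_batch(net, parental_params)
        sim = traj.value("GLC", [24.0])[0]
        obs = ObservationSet(pd.DataFrame(
            [(24.0, "GLC", 1, sim - 2.0)],
            columns=["time_h", "variable", "replicate", "value"]),
            variance={"GLC": 4.0})
        assert ck.wssres(obs, traj) == pytest.approx(1.0, rel=1e-12)

    def test_matches_brute_force_double_loop(self, parental_noisy, net,
                                             parental_params):
        """The vectorized objective equals an explicit double loop over
        variables and times to 1e-12 relative."""
        obs, _ = parental_noisy
        traj = ck.simulate_batch(net, parental_params)
        means = obs.records.groupby(["variable", "time_h"])["value"].mean()
        total = 0.0
        for (m, t), mea in means.items():
            sim = np.interp(t, traj.times, traj.value(m))
            total += (sim - mea) ** 2 / obs.variance[m]
        assert ck.wssres(obs, traj) == pytest.approx(total, rel=1e-12)

    def test_record_order_invariance(self, parental_noisy, net,
                                     parental_params):
        obs, _ = parental_noisy
        traj = ck.simulate_batch(net, parental_params)
        shuffled = ObservationSet(
            obs.records.sample(frac=1.0, random_state=0),
            variance=dict(obs.variance))
        assert ck.wssres(shuffled, traj) == pytest.approx(
            ck.wssres(obs, traj), rel=1e-12)

    def test_additive_over_variables(self, parental_noisy, net,
                                     parental_params):
        obs, _ = parental_noisy
        traj = ck.simulate_batch(net, parental_params)
        per_var = wssres_by_variable(obs, traj)
        assert ck.wssres(obs, traj) == pytest.approx(sum(per_var.values()),
                                                     rel=1e-12)
        v0 = obs.variables[0]
        assert ck.wssres(obs, traj, variables=[v0]) == pytest.approx(
            per_var[v0], rel=1e-12)

    def test_unknown_restriction_rejected(self, parental_noisy, net,
                                          parental_params):
        obs, _ = parental_noisy
        traj = ck.simulate_batch(net, parental_params)
        with pytest.raises(ObservationError):
            ck.wssres(obs, traj, variables=["ARG"])


class TestScreening:
    def test_zero_influence_parameter_frozen_and_last(self, parental_noisy,
                                                      net, parental_params):
        """A maximum rate already at zero has exactly zero influence under
        multiplicative perturbation: ranked last and frozen."""
        obs, _ = parental_noisy
        p = parental_params.with_updates({"vmax.CK_f": 0.0})
        res = ck.screen_parameters(
            obs, net, p, parameters=["vmax.HK", "vmax.CK_f"],
            grid=(-0.5, 0.5))
        assert res.sensitive == ["vmax.HK"]
        assert res.frozen == ["vmax.CK_f"]
        assert res.table.index[-1] == "vmax.CK_f"

    def test_zero_threshold_keeps_everything(self, parental_noisy, net,
                                             parental_params):
        obs, _ = parental_noisy
        res = ck.screen_parameters(obs, net, parental_params,
                                   parameters=["vmax.HK", "vmax.PDH"],
                                   grid=(-0.5, 0.5), threshold=0.0)
        assert set(res.sensitive) == {"vmax.HK", "vmax.PDH"}

    def test_deterministic_across_reruns(self, parental_noisy, net,
                                         parental_params):
        obs, _ = parental_noisy
        kw = dict(parameters=["vmax.HK", "vmax.resp"], grid=(-0.25, 0.25))
        a = ck.screen_parameters(obs, net, parental_params, **kw)
        b = ck.screen_parameters(obs, net, parental_params, **kw)
        assert a.sensitive == b.sensitive and a.frozen == b.frozen
        assert np.array_equal(a.table.to_numpy(), b.table.to_numpy())


class TestFitting:
    def test_noiseless_no_free_parameters_is_exact(self, parental_truth,
                                                   net, parental_params):
        obs, _ = parental_truth
        fit = ck.fit_parameters(obs, net, parental_params, [])
        # residual floor set by integrator tolerance only
        assert fit.wssres == pytest.approx(0.0, abs=1e-6)
        assert fit.converged

    def test_objective_never_increases(self, parental_noisy, net,
                                       parental_params):
        obs, _ = parental_noisy
        fit = ck.fit_parameters(obs, net, parental_params, ["vmax.HK"],
                                xtol=1e-6, ftol=1e-6, gtol=1e-6)
        assert fit.wssres <= fit.wssres_initial

    def test_unknown_free_parameter_rejected(self, parental_noisy, net,
                                             parental_params):
        obs, _ = parental_noisy
        with pytest.raises(KeyError):
            ck.fit_parameters(obs, net, parental_params, ["vmax.NOPE"])

    def test_screened_out_free_parameter_warns(self, parental_truth, net,
                                               parental_params):
        obs, _ = parental_truth
        with pytest.warns(UserWarning, match="screened out"):
            ck.fit_parameters(obs, net, parental_params, ["vmax.HK"],
                              screened_out=["vmax.HK"], max_nfev=1)


class TestConfidenceIntervals:
    def test_se_matches_closed_form_linear_regression(self):
        """For weighted linear regression y = theta*x + e the standard
        error is s/sqrt(sum (x/sd)^2); the Jacobian-based computation must
        reproduce it to 1e-10."""
        rng = np.random.default_rng(0)
        x = np.linspace(1.0, 10.0, 25)
        sd = 0.5
        theta = 2.0
        y = theta * x + rng.normal(0, sd, x.size)
        # weighted residuals r = (theta*x - y)/sd, J = dr/dtheta = x/sd
        theta_hat = (x @ y) / (x @ x)
        r = (theta_hat * x - y) / sd
        J = (x / sd)[:, None]
        dof = x.size - 1
        wss = float(r @ r)
        se = _se_from_jacobian(J, wss, dof)[0]
        s2 = wss / dof
        closed = np.sqrt(s2 / np.sum((x / sd) ** 2))
        assert se == pytest.approx(closed, rel=1e-10)

    def test_zero_residual_fit_has_tight_ci(self, parental_truth, net,
                                            parental_params):
        obs, _ = parental_truth
        fit = ck.fit_parameters(obs, net, parental_params, ["vmax.HK"],
                                xtol=1e-8, ftol=1e-8)
        lo, hi = fit.ci95["vmax.HK"]
        assert (hi - lo) / fit.theta[0] < 1e-3

    def test_ci_invariant_under_common_variance_rescaling(
            self, parental_noisy, net, parental_params):
        """With the residual variance estimated from the fit (the
        nlparci-style convention), rescaling every per-variable variance by
        a common factor leaves the parameter intervals unchanged: the MSE
        estimate absorbs the scale."""
        obs, _ = parental_noisy
        fit1 = ck.fit_parameters(obs, net, parental_params, ["vmax.HK"],
                                 xtol=1e-6, ftol=1e-6)
        obs2 = ObservationSet(obs.records.copy(),
                              variance={k: 2 * v
                                        for k, v in obs.variance.items()})
        fit2 = ck.fit_parameters(obs2, net, parental_params, ["vmax.HK"],
                                 xtol=1e-6, ftol=1e-6)
        w1 = np.log10(fit1.ci95["vmax.HK"][1] / fit1.ci95["vmax.HK"][0])
        w2 = np.log10(fit2.ci95["vmax.HK"][1] / fit2.ci95["vmax.HK"][0])
        assert w2 == pytest.approx(w1, rel=1e-2)
        # the objective itself does scale: halved by doubled variances
        assert fit2.wssres == pytest.approx(fit1.wssres / 2, rel=1e-2)

    def test_rank_deficient_jacobian_reports_infinite_ci(self):
        J = np.zeros((10, 2))
        J[:, 0] = np.linspace(1, 2, 10)      # second column identically 0
        with pytest.warns(UserWarning, match="unidentifiable"):
            se = _se_from_jacobian(J, 1.0, 8)
        assert np.isfinite(se[0]) and np.isinf(se[1])

    def test_prediction_envelope_contains_prediction(self, parental_noisy,
                                                     net, parental_params):
        obs, _ = parental_noisy
        fit = ck.fit_parameters(obs, net, parental_params, ["vmax.HK"],
                                xtol=1e-6, ftol=1e-6)
        param_ci, pred = ck.confidence_intervals(fit)
        assert param_ci.keys() == fit.ci95.keys()
        assert np.all(pred["ci_low"] <= pred["prediction"] + 1e-12)
        assert np.all(pred["prediction"] <= pred["ci_high"] + 1e-12)


def _dummy_fit(log_theta, se_log, names=("a", "b")):
    from chokinet.calibrate import FitResult
    n = len(names)
    return FitResult(
        estimates=None, free_names=list(names),
        theta=10.0 ** np.asarray(log_theta, float),
        log_theta=np.asarray(log_theta, float),
        se_log=np.asarray(se_log, float),
        ci95={}, wssres=0.0, wssres_initial=0.0, dof=10,
        jacobian=np.zeros((10, n)), residuals=np.zeros(10), obs=None)


class TestCompareParameterSets:
    def test_identical_estimates_give_p_one(self):
        a = _dummy_fit([0.0, 1.0], [0.1, 0.1])
        b = _dummy_fit([0.0, 1.0], [0.1, 0.1])
        tab = ck.compare_parameter_sets(a, b)
        assert np.allclose(tab["p_value"], 1.0)
        assert not tab["significant"].any()

    def test_z_of_196_gives_p_005(self):
        se = 0.1
        delta = 1.959963984540054 * np.sqrt(2) * se
        a = _dummy_fit([0.0], [se], names=("a",))
        b = _dummy_fit([delta], [se], names=("a",))
        tab = ck.compare_parameter_sets(a, b)
        assert tab["p_value"].iloc[0] == pytest.approx(0.05, rel=1e-6)

    def test_mismatched_parameter_lists_rejected(self):
        a = _dummy_fit([0.0], [0.1], names=("a",))
        b = _dummy_fit([0.0], [0.1], names=("b",))
        with pytest.raises(ValueError):
            ck.compare_parameter_sets(a, b)

    def test_normal_quantile_consistency(self):
        a = _dummy_fit([0.0], [0.1], names=("a",))
        b = _dummy_fit([0.3], [0.1], names=("a",))
        tab = ck.compare_parameter_sets(a, b)
        z = 0.3 / (0.1 * np.sqrt(2))
        assert tab["p_value"].iloc[0] == pytest.approx(
            2 * stats.norm.sf(z), rel=1e-12)
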
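"""Benchmark-dose engine: fitting, lack of fit, BMC, profile bounds, pooling."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from nanorisk import bmd
from nanorisk.bmd import (
    BMDEstimate,
    DoseGroup,
    DoseResponseDataset,
    ModelFit,
    NoReliableModelsError,
)
from nanorisk.synthetic import (
    SyntheticDoseResponseSpec,
    generate_dose_response,
    recovery_spec,
)


def _dataset(doses, means, sds, n=10, direction=None):
    if direction is None:
        direction = DoseResponseDataset.infer_direction(doses, means)
    groups = tuple(DoseGroup(d, n, m, s) for d, m, s in zip(doses, means, sds))
    return DoseResponseDataset("study", "endpoint", groups, direction)


def _linear_dataset(gamma=1.0, beta=2.0, doses=(0.0, 0.5, 1.0, 2.0), sd=1e-6, n=10):
    d = np.asarray(doses)
    return _dataset(d, gamma + beta * d, [sd] * len(d), n=n)


class TestDatasetValidation:
    def test_requires_control_group(self):
        with pytest.raises(ValueError, match="control"):
            _dataset([0.5, 1.0, 2.0], [1, 2, 3], [0.1] * 3)

    def test_requires_increasing_doses(self):
        with pytest.raises(ValueError, match="increasing"):
            _dataset([0.0, 1.0, 0.5], [1, 2, 3], [0.1] * 3)

    def test_requires_three_groups(self):
        with pytest.raises(ValueError, match="3 dose groups"):
            _dataset([0.0, 1.0], [1, 2], [0.1, 0.1])

    def test_group_size_floor(self):
        with pytest.raises(ValueError, match="group size"):
            DoseGroup(0.0, 1, 1.0, 0.1)


class TestFitModel:
    def test_noiseless_linear_recovery(self):
        ds = _linear_dataset(gamma=1.0, beta=2.0)
        fit = bmd.fit_model(ds, "linear")
        assert fit.converged
        assert fit.params["gamma"] == pytest.approx(1.0, rel=1e-6)
        assert fit.params["beta"] == pytest.approx(2.0, rel=1e-6)

    def test_noiseless_recovery_all_families(self):
        # each family must reproduce its own noiseless curve
        for model in bmd.MODEL_NAMES:
            spec = recovery_spec(model)
            noiseless = SyntheticDoseResponseSpec(
                **{**spec.__dict__, "response_sd": 0.0})
            ds0 = generate_dose_response(noiseless)
            groups = tuple(DoseGroup(g.dose, g.n, g.mean, 1e-7) for g in ds0.groups)
            ds = DoseResponseDataset(ds0.study_id, ds0.endpoint, groups, ds0.direction)
            fit = bmd.fit_model(ds, model)
            mu = bmd.model_mean(model, ds.doses, fit.params, ds.direction)
            np.testing.assert_allclose(mu, ds.means, rtol=1e-4)

    def test_hill_parameter_recovery_over_replicates(self):
        # estimates across replicates center on the truth (within 3 SEM)
        truth = {"gamma": 1.0, "v": 4.0, "k": 0.3, "eta": 2.0}
        est = {p: [] for p in truth}
        for i in range(200):
            spec = SyntheticDoseResponseSpec(
                true_model="hill", params=truth,
                doses=(0.0, 0.1, 0.3, 1.0, 2.0), n_per_group=10,
                response_sd=0.5, seed=5000 + i)
            fit = bmd.fit_model(generate_dose_response(spec), "hill")
            for p in truth:
                est[p].append(fit.params[p])
        for p, vals in est.items():
            vals = np.array(vals)
            sem = vals.std(ddof=1) / math.sqrt(len(vals))
            assert abs(vals.mean() - truth[p]) < 3 * sem, p

    def test_saturated_loglik_dominates(self):
        ds = generate_dose_response(recovery_spec("hill", seed=2))
        ll_sat = bmd.saturated_loglik(ds)
        for model in bmd.MODEL_NAMES:
            assert bmd.fit_model(ds, model).loglik <= ll_sat + 1e-8

    def test_aic_definition(self):
        ds = _linear_dataset(sd=0.3)
        fit = bmd.fit_model(ds, "linear")
        # k = 2 mean parameters + 1 variance
        assert fit.aic == pytest.approx(2 * 3 - 2 * fit.loglik)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            bmd.fit_model(_linear_dataset(), "weibull")


class TestGoodnessOfFit:
    def test_pvalues_calibrated_under_truth(self):
        # fitting the generating model at large n: p-values ~ Uniform(0,1)
        pvals = []
        for i in range(500):
            spec = SyntheticDoseResponseSpec(
                true_model="linear", params={"gamma": 1.0, "beta": 2.0},
                doses=(0.0, 0.4, 0.8, 1.2, 2.0), n_per_group=50,
                response_sd=0.5, seed=9000 + i)
            fit = bmd.fit_model(generate_dose_response(spec), "linear")
            pvals.append(fit.gof_p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_detects_gross_misspecification(self):
        # a straight line cannot fit a steep sigmoid measured precisely
        spec = SyntheticDoseResponseSpec(
            true_model="hill", params={"gamma": 1.0, "v": 4.0, "k": 0.3, "eta": 6.0},
            doses=(0.0, 0.1, 0.3, 1.0, 2.0), n_per_group=50,
            response_sd=0.4, seed=4)
        fit = bmd.fit_model(generate_dose_response(spec), "linear")
        assert fit.gof_p < 0.001

    def test_saturated_fit_has_p_one(self):
        ds = generate_dose_response(recovery_spec("linear", seed=1))
        sat = ModelFit(model="linear", params={"gamma": 0, "beta": 0},
                       loglik=bmd.saturated_loglik(ds), n_mean_params=2,
                       converged=True, direction="increasing")
        assert bmd.goodness_of_fit(sat, ds) == pytest.approx(1.0)

    def test_undefined_when_no_residual_df(self):
        ds = _dataset([0.0, 0.5, 1.0], [1.0, 2.0, 2.5], [0.2] * 3)
        fit = bmd.fit_model(ds, "polynomial2")  # 3 params, 3 groups
        assert math.isnan(fit.gof_p)


class TestBMC:
    def test_linear_closed_form(self):
        ds = _linear_dataset(gamma=10.0, beta=2.0, sd=4.0)
        fit = bmd.fit_model(ds, "linear")
        assert bmd.bmc_from_fit(fit, ds, bmr_sd=4.0) == pytest.approx(2.0, rel=1e-9)

    def test_hill_half_maximal_identity(self):
        # when |v| equals twice the anchor, the BMC sits at k exactly
        sd_ctrl = 1.0
        params = {"gamma": 0.5, "v": 2 * sd_ctrl, "k": 0.4, "eta": 3.0}
        doses = np.array([0.0, 0.2, 0.4, 0.8, 1.6])
        means = bmd.model_mean("hill", doses, params)
        ds = _dataset(doses, means, [sd_ctrl] * len(doses))
        fit = ModelFit(model="hill", params=params, loglik=0.0, n_mean_params=4,
                       converged=True, direction="increasing")
        assert bmd.bmc_from_fit(fit, ds, bmr_sd=sd_ctrl) == pytest.approx(0.4, rel=1e-9)

    def test_root_agrees_with_dense_grid(self):
        ds = generate_dose_response(recovery_spec("power", seed=6))
        fit = bmd.fit_model(ds, "power")
        delta = 0.35
        b = bmd.bmc_from_fit(fit, ds, bmr_sd=delta)
        grid = np.linspace(1e-9, ds.doses.max() * 10, 2_000_001)
        inc = bmd.model_mean("power", grid, fit.params) - bmd.model_mean("power", [0.0], fit.params)[0]
        b_grid = grid[np.argmax(inc >= delta)]
        assert b == pytest.approx(b_grid, abs=grid[1] - grid[0])

    def test_flat_curve_has_no_bmc(self):
        ds = _dataset([0.0, 1.0, 2.0, 3.0], [1.0, 1.0, 1.0, 1.0], [0.5] * 4,
                      direction="increasing")
        fit = ModelFit(model="linear", params={"gamma": 1.0, "beta": 0.0},
                       loglik=0.0, n_mean_params=2, converged=True,
                       direction="increasing")
        assert math.isnan(bmd.bmc_from_fit(fit, ds, bmr_sd=0.5))

    def test_affine_response_rescaling_invariance(self):
        # endpoint units cancel through the anchor: y -> a*y + b keeps the BMC
        spec = recovery_spec("linear", seed=8)
        ds = generate_dose_response(spec)
        fit = bmd.fit_model(ds, "linear")
        b1 = bmd.bmc_from_fit(fit, ds)
        groups = tuple(DoseGroup(g.dose, g.n, 3.0 * g.mean + 5.0, 3.0 * g.sd)
                       for g in ds.groups)
        ds2 = DoseResponseDataset(ds.study_id, ds.endpoint, groups, ds.direction)
        fit2 = bmd.fit_model(ds2, "linear")
        assert bmd.bmc_from_fit(fit2, ds2) == pytest.approx(b1, rel=1e-6)

    def test_decreasing_direction(self):
        d = np.array([0.0, 0.5, 1.0, 2.0])
        ds = _dataset(d, 10.0 - 2.0 * d, [1e-6] * 4, direction="decreasing")
        fit = bmd.fit_model(ds, "linear")
        assert fit.params["beta"] == pytest.approx(-2.0, rel=1e-6)
        assert bmd.bmc_from_fit(fit, ds, bmr_sd=4.0) == pytest.approx(2.0, rel=1e-6)


class TestProfileBounds:
    def test_interval_shrinks_with_information(self):
        # near-noiseless, large n: bounds collapse onto the BMC
        spec = SyntheticDoseResponseSpec(
            true_model="linear", params={"gamma": 1.0, "beta": 2.0},
            doses=(0.0, 0.5, 1.0, 2.0), n_per_group=1000,
            response_sd=0.05, seed=0)
        ds = generate_dose_response(spec)
        fit = bmd.fit_model(ds, "linear")
        bmc = bmd.bmc_from_fit(fit, ds)
        bmcl, bmcu, warns = bmd.profile_bounds(fit, ds, bmc=bmc)
        assert not warns
        # half-width scales as ~1.645/sqrt(2N); N = 4000 here
        assert bmcl == pytest.approx(bmc, rel=0.03)
        assert bmcu == pytest.approx(bmc, rel=0.03)

    def test_matches_delta_method_for_linear(self):
        # asymptotic equivalence at n=50/group, moderate noise
        spec = SyntheticDoseResponseSpec(
            true_model="linear", params={"gamma": 1.0, "beta": 2.0},
            doses=(0.0, 0.5, 1.0, 1.5, 2.0), n_per_group=50,
            response_sd=0.5, seed=21)
        ds = generate_dose_response(spec)
        fit = bmd.fit_model(ds, "linear")
        bmc = bmd.bmc_from_fit(fit, ds)
        bmcl, bmcu, warns = bmd.profile_bounds(fit, ds, bmc=bmc)
        assert not warns
        # delta method on ln(bmc) = ln(sigma) - ln(beta):
        # var(ln sigma) = 1/(2N); var(ln beta) = sigma^2 / (beta^2 Sxx)
        N = ds.ns.sum()
        mu = bmd.model_mean("linear", ds.doses, fit.params)
        sigma2 = (((ds.ns - 1) * ds.sds**2).sum()
                  + (ds.ns * (ds.means - mu) ** 2).sum()) / N
        dbar = (ds.ns * ds.doses).sum() / N
        sxx = (ds.ns * (ds.doses - dbar) ** 2).sum()
        var_ln = 1.0 / (2 * N) + sigma2 / (fit.params["beta"] ** 2 * sxx)
        z = 1.6448536269514722
        bmcl_delta = bmc * math.exp(-z * math.sqrt(var_ln))
        bmcu_delta = bmc * math.exp(z * math.sqrt(var_ln))
        assert bmcl == pytest.approx(bmcl_delta, rel=0.15)
        assert bmcu == pytest.approx(bmcu_delta, rel=0.15)

    def test_ordering_invariant_across_families(self):
        ds = generate_dose_response(recovery_spec("hill", seed=3))
        for model in ("linear", "hill"):
            fit = bmd.fit_model(ds, model)
            est = bmd.estimate_bmd(fit, ds)
            assert 0 < est.bmcl <= est.bmc <= est.bmcu


class TestFilterReliable:
    @staticmethod
    def _item(converged=True, gof=0.5, bmc=2.0, bmcl=1.0, model="linear"):
        fit = ModelFit(model=model, params={}, loglik=-10.0, n_mean_params=2,
                       converged=converged, direction="increasing", gof_p=gof)
        est = BMDEstimate(bmc=bmc, bmcl=bmcl, bmcu=bmc * 2)
        return fit, est

    def test_known_pass_fail_labels_recovered(self):
        items = [
            self._item(),                          # keep
            self._item(converged=False),           # drop: no convergence
            self._item(gof=0.05),                  # drop: lack of fit
            self._item(gof=0.10),                  # keep: boundary inclusive
            self._item(bmc=20.0, bmcl=0.5),        # drop: BMC/BMCL = 40
            self._item(gof=math.nan),              # drop: undefined test
        ]
        kept = bmd.filter_reliable(items)
        assert [items.index(k) for k in kept] == [0, 3]

    def test_all_failing_raises(self):
        with pytest.raises(NoReliableModelsError):
            bmd.filter_reliable([self._item(gof=0.01), self._item(converged=False)])

    def test_thresholds_configurable(self):
        items = [self._item(gof=0.05)]
        kept = bmd.filter_reliable(items, gof_min=0.01)
        assert len(kept) == 1


class TestPoolModels:
    @staticmethod
    def _item(model, bmc, bmcl, bmcu, aic):
        # aic = 2k - 2 loglik with k = 3 -> loglik = 3 - aic/2
        fit = ModelFit(model=model, params={}, loglik=3.0 - aic / 2.0,
                       n_mean_params=2, converged=True,
                       direction="increasing", gof_p=0.5)
        return fit, BMDEstimate(bmc=bmc, bmcl=bmcl, bmcu=bmcu)

    def test_identical_estimates_pool_to_point_mass(self):
        items = [self._item("linear", 5.0, 4.0, 6.0, 10.0),
                 self._item("power", 5.0, 4.0, 6.0, 12.0)]
        pool = bmd.pool_models(items)
        assert pool.bmcl_a.gm == pytest.approx(4.0)
        assert pool.bmcl_a.gsd == pytest.approx(1.0)

    def test_two_point_geometric_summary(self):
        items = [self._item("linear", 5.0, 4.0, 6.0, 10.0),
                 self._item("power", 10.0, 9.0, 11.0, 10.0)]
        pool = bmd.pool_models(items, weighting="equal")
        assert pool.bmcl_a.gm == pytest.approx(6.0)          # sqrt(4 * 9)
        assert pool.bmcl_a.gsd == pytest.approx(1.5)         # exp(ln 1.5)

    def test_akaike_weights_match_direct_computation(self):
        rng = np.random.default_rng(0)
        bmcls = rng.lognormal(math.log(9.4), 0.2, size=25)
        aics = rng.uniform(50, 60, size=25)
        items = [self._item(f"m{i}", b * 1.5, b, b * 3, a)
                 for i, (b, a) in enumerate(zip(bmcls, aics))]
        pool = bmd.pool_models(items)
        w = np.exp(-(aics - aics.min()) / 2)
        w /= w.sum()
        mu = (w * np.log(bmcls)).sum()
        sigma = math.sqrt((w * (np.log(bmcls) - mu) ** 2).sum())
        assert pool.bmcl_a.gm == pytest.approx(math.exp(mu), rel=1e-12)
        assert pool.bmcl_a.gsd == pytest.approx(math.exp(sigma), rel=1e-12)
        assert sum(pool.weights.values()) == pytest.approx(1.0)

    def test_single_model_warns(self):
        with pytest.warns(UserWarning, match="single reliable model"):
            pool = bmd.pool_models([self._item("linear", 5.0, 4.0, 6.0, 10.0)])
        assert pool.bmcl_a.gsd == 1.0

    def test_empty_pool_raises(self):
        with pytest.raises(NoReliableModelsError):
            bmd.pool_models([])


class TestCsvIO:
    def test_round_trip(self, tmp_path):
        ds = generate_dose_response(recovery_spec("linear", seed=5))
        path = tmp_path / "dr.csv"
        bmd.write_dose_response_csv([ds], path)
        back = bmd.read_dose_response_csv(path)
        assert len(back) == 1
        np.testing.assert_allclose(back[0].doses, ds.doses)
        np.testing.assert_allclose(back[0].means, ds.means)
        assert back[0].direction == ds.direction

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("study_id,dose_mg_m3\ns,0\n")
        with pytest.raises(ValueError, match="missing columns"):
            bmd.read_dose_response_csv(path)
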
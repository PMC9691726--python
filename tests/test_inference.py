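"""Fitting, fit quality, profile likelihoods and confidence intervals."""

import numpy as np
import pytest

from exportkinetics.inference import (
    FitResult,
    ProfileResult,
    chi2_threshold,
    classify_fit_quality,
    confidence_interval,
    fit_gene,
    fit_quality,
    profile_likelihood,
    sample_initial_params,
    theta_from_log10_ratios,
)
from exportkinetics.likelihood import GeneProblem, NuisanceParams
from exportkinetics.model import KineticParams


class TestChi2Threshold:
    def test_95_percent_value(self):
        assert chi2_threshold(0.95) == pytest.approx(3.841459, abs=1e-6)

    def test_median(self):
        assert chi2_threshold(0.5) == pytest.approx(0.4549, abs=1e-3)

    def test_monotone(self):
        grid = np.linspace(0.05, 0.99, 20)
        vals = [chi2_threshold(a) for a in grid]
        assert np.all(np.diff(vals) > 0)

    def test_domain(self):
        with pytest.raises(ValueError):
            chi2_threshold(1.0)


class TestInitialSampling:
    def test_ranges(self):
        rng = np.random.default_rng(0)
        l10 = np.array(
            [np.log10(sample_initial_params(rng)[0].k1_prime) for _ in range(1000)]
        )
        assert np.all(l10 >= -5) and np.all(l10 <= 5)
        assert l10.min() < -4 and l10.max() > 4  # actually spans the range

    def test_ratio_reconstruction_identity(self):
        # all four log-ratios zero -> every rate equals 1
        theta = theta_from_log10_ratios(0.0, 0.0, 0.0, 0.0)
        assert theta.k1_prime == theta.k2 == theta.k2_prime == theta.k_cyto_deg == 1.0
        # and a generic case divides through consistently
        theta = theta_from_log10_ratios(1.0, 2.0, -1.0, 3.0)
        assert np.log10(theta.k1_prime / theta.k2) == pytest.approx(2.0)
        assert np.log10(theta.k2 / theta.k2_prime) == pytest.approx(-1.0)
        assert np.log10(theta.k2_prime / theta.k_cyto_deg) == pytest.approx(3.0)

    def test_determinism(self):
        t1, a1 = sample_initial_params(np.random.default_rng(33))
        t2, a2 = sample_initial_params(np.random.default_rng(33))
        assert t1 == t2 and a1 == a2


class TestFitGene:
    def test_noiseless_recovery_of_effective_transport(self, noiseless_gene):
        fit = fit_gene(noiseless_gene.timecourses, n_starts=60, seed=2)
        true = noiseless_gene.gene.params.effective_transport
        assert fit.theta_hat.effective_transport == pytest.approx(true, rel=0.05)

    def test_seed_determinism(self, single_gene):
        f1 = fit_gene(single_gene.timecourses, n_starts=20, seed=5)
        f2 = fit_gene(single_gene.timecourses, n_starts=20, seed=5)
        assert f1.min_cost == f2.min_cost
        assert f1.theta_hat == f2.theta_hat
        assert f1.alpha_hat == f2.alpha_hat

    def test_min_cost_consistent_with_cost_function(self, single_gene):
        fit = fit_gene(single_gene.timecourses, n_starts=20, seed=5)
        prob = GeneProblem(single_gene.timecourses)
        c = prob.cost_fast(prob.pack_params(fit.theta_hat, fit.alpha_hat))
        assert c == pytest.approx(fit.min_cost, rel=1e-9)
        assert fit.n_converged > 0
        assert set(fit.residuals) >= {"nucleoplasm", "cytoplasm"}


class TestFitQuality:
    def _fit_with_residuals(self, res_np, res_cyto):
        theta = KineticParams(0.1, 0.1, 0.1, 0.01)
        return FitResult(
            gene_id="g",
            theta_hat=theta,
            alpha_hat=NuisanceParams(),
            min_cost=0.0,
            n_starts=1,
            n_converged=1,
            residuals={"nucleoplasm": np.asarray(res_np), "cytoplasm": np.asarray(res_cyto)},
        )

    def _data(self, single_gene):
        return single_gene.timecourses

    def test_zero_residuals_give_zero(self, single_gene):
        fit = self._fit_with_residuals(np.zeros(12), np.zeros(12))
        assert fit_quality(fit, self._data(single_gene)) == 0.0

    def test_alternating_residuals(self, single_gene):
        # residuals +e, -e, ... have lag-1 autocorrelation -1, so the metric
        # approaches e / range
        e = 0.25
        res = e * (-1.0) ** np.arange(12)
        fit = self._fit_with_residuals(np.zeros(12), res)
        data = self._data(single_gene)
        obs = data["cytoplasm"].log2_fpkm()
        expected = e / (obs.max() - obs.min())
        assert fit_quality(fit, data) == pytest.approx(expected, rel=1e-9)

    def test_bands(self):
        assert classify_fit_quality(0.011) == "good"
        assert classify_fit_quality(0.059) == "good"
        assert classify_fit_quality(0.06) == "moderate"
        assert classify_fit_quality(0.15) == "poor"

    def test_too_few_residuals_rejected(self, single_gene):
        fit = self._fit_with_residuals(np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            fit_quality(fit, self._data(single_gene))


@pytest.fixture(scope="module")
def fitted(single_gene):
    return fit_gene(single_gene.timecourses, n_starts=60, seed=1)


class TestProfileLikelihood:
    def test_profile_minimum_at_estimate(self, single_gene, fitted):
        prof = profile_likelihood(single_gene.timecourses, fitted, "k_cyto_deg")
        costs = np.array([c for _, c in prof.grid])
        assert costs.min() >= prof.min_cost - 1e-6
        assert prof.min_cost <= fitted.min_cost + 1e-6

    def test_ci_brackets_estimate_and_truth(self, single_gene, fitted):
        prof = profile_likelihood(single_gene.timecourses, fitted, "k_cyto_deg")
        assert prof.identifiability == "identifiable"
        assert prof.ci_lower <= prof.estimate <= prof.ci_upper
        assert prof.ci_lower <= single_gene.gene.params.k_cyto_deg <= prof.ci_upper

    def test_composite_parameter_profile(self, single_gene, fitted):
        prof = profile_likelihood(single_gene.timecourses, fitted, "effective_transport")
        assert prof.identifiability == "identifiable"
        true = single_gene.gene.params.effective_transport
        assert prof.ci_lower <= true * 1.05 and true * 0.95 <= prof.ci_upper

    def test_grid_confined_to_window(self, single_gene, fitted):
        prof = profile_likelihood(single_gene.timecourses, fitted, "k2")
        vals = np.array([v for v, _ in prof.grid])
        assert np.all(vals >= prof.estimate / 1001)
        assert np.all(vals <= prof.estimate * 1001)


class TestConfidenceInterval:
    def _quadratic_profile(self, x_hat=1.0, half_width_grid=4.0):
        # cost = min + (log-ish quadratic in the raw value): use value grid
        vals = x_hat + np.linspace(-half_width_grid, half_width_grid, 2001)
        costs = 10.0 + (vals - x_hat) ** 2 / 2.0
        return ProfileResult(
            param_name="k2",
            estimate=x_hat,
            grid=list(zip(vals, costs)),
            min_cost=10.0,
            threshold=chi2_threshold(0.95) / 2,
            ci_lower=None,
            ci_upper=None,
            identifiability="",
        )

    def test_quadratic_profile_half_width(self):
        prof = self._quadratic_profile(x_hat=5.0)
        lo, hi, klass = confidence_interval(prof)
        assert klass == "identifiable"
        assert hi - 5.0 == pytest.approx(np.sqrt(3.841459), abs=2e-3)
        assert 5.0 - lo == pytest.approx(np.sqrt(3.841459), abs=2e-3)

    def test_flat_profile_non_identifiable(self):
        vals = np.logspace(-3, 3, 101)
        prof = ProfileResult(
            "k1_prime", 1.0, list(zip(vals, np.full(101, 5.0))), 5.0,
            chi2_threshold(0.95) / 2, None, None, "",
        )
        lo, hi, klass = confidence_interval(prof)
        assert (lo, hi, klass) == (None, None, "non_identifiable")

    def test_left_crossing_only(self):
        vals = np.logspace(-3, 3, 301)
        costs = np.where(vals < 0.1, 50.0, 5.0)  # rises only below the estimate
        prof = ProfileResult(
            "k2", 1.0, list(zip(vals, costs)), 5.0, chi2_threshold(0.95) / 2,
            None, None, "",
        )
        lo, hi, klass = confidence_interval(prof)
        assert klass == "lower_bound_only"
        assert lo is not None and hi is None
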
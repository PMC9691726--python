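"""Observation model: Gamma moment matching, NB mixture, priors, cost."""

import numpy as np
import pytest
from scipy import stats

from exportkinetics.likelihood import (
    GeneProblem,
    NuisanceParams,
    cost,
    gamma_approx,
    loglik_timepoint,
    nb_logpmf,
    nb_mixture_tv,
    nb_observation,
    prior_logpdf,
    sigma_total_sq,
)
from exportkinetics.model import KineticParams


class TestSigmaTotal:
    @pytest.mark.parametrize(
        "sigma_b,sigma_t,slope,expected",
        [(0.1, 0.0, 12.3, 0.01), (0.0, 2.0, 0.5, 1.0), (0.1, 5.0, 0.2, 1.01)],
    )
    def test_examples(self, sigma_b, sigma_t, slope, expected):
        assert sigma_total_sq(sigma_b, sigma_t, slope) == pytest.approx(expected)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            sigma_total_sq(-0.1, 0.0, 0.0)


class TestGammaApprox:
    def test_moment_identities_exact(self):
        # Gamma mean/variance must equal the log-normal's for any inputs
        rng = np.random.default_rng(1)
        for _ in range(50):
            lg = rng.uniform(-3, 8)
            s2 = rng.uniform(1e-4, 5.0)
            k, theta = gamma_approx(lg, s2)
            mean_ln = np.exp(lg + s2 / 2)
            var_ln = np.expm1(s2) * np.exp(2 * lg + s2)
            assert k * theta == pytest.approx(mean_ln, rel=1e-12)
            assert k * theta**2 == pytest.approx(var_ln, rel=1e-12)

    def test_worked_example(self):
        # lg = ln 10, sigma^2 = ln 2 -> k = 1, theta = 10 sqrt(2)
        k, theta = gamma_approx(np.log(10.0), np.log(2.0))
        assert k == pytest.approx(1.0, rel=1e-12)
        assert theta == pytest.approx(10.0 * np.sqrt(2.0), rel=1e-12)

    def test_small_variance_limit(self):
        lg = np.log(25.0)
        k, theta = gamma_approx(lg, 1e-10)
        assert k > 1e9
        assert k * theta == pytest.approx(25.0, rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            gamma_approx(0.0, 0.0)


class TestNBObservation:
    def test_unit_dispersion_at_ln2(self):
        r, _ = nb_observation(10.0, np.log(2.0))
        assert r == pytest.approx(1.0, rel=1e-12)

    def test_mixture_matches_monte_carlo(self):
        # Gamma-Poisson draws vs the NB pmf: total variation over ~20
        # equal-probability bins stays <= 0.01 at 1e5 draws
        rng = np.random.default_rng(0)
        n_draws = 100_000
        for mu in (1.0, 10.0, 100.0):
            for s2 in (0.05, 0.3, 1.0):
                r, p = nb_observation(mu, s2)
                tv = nb_mixture_tv(rng, r, p, n_draws)
                assert tv <= 0.01, (mu, s2, tv)

    def test_poisson_limit(self):
        # variance/mean -> 1 as sigma^2 -> 0
        r, p = nb_observation(50.0, 1e-6)
        mean = r * p / (1 - p)
        var = r * p / (1 - p) ** 2
        assert var / mean == pytest.approx(1.0, rel=1e-2)
        assert mean == pytest.approx(50.0, rel=1e-3)

    def test_as_printed_variant_differs(self):
        r1, p1 = nb_observation(10.0, 0.3)
        r2, p2 = nb_observation(10.0, 0.3, variant="as_printed")
        assert r1 == r2
        assert p1 != p2


class TestLoglikTimepoint:
    def test_normalizes(self):
        r, p = nb_observation(20.0, 0.2)
        total = np.exp(nb_logpmf(np.arange(0, 4000), r, p)).sum()
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mode_maximizes(self):
        args = dict(
            predicted_fpkm=5.0, library_size=2e7, effective_length_bp=1000.0, sigma_sq=0.1
        )
        lls = [loglik_timepoint(n, **args) for n in range(0, 500)]
        mode = int(np.argmax(lls))
        assert 50 <= mode <= 150  # near expected counts = 5 * 1 * 20
        assert lls[mode] >= max(lls)

    def test_library_scale_invariance(self):
        # doubling library size and halving FPKM leaves expected counts fixed
        a = loglik_timepoint(80, 5.0, 2e7, 1000.0, 0.15)
        b = loglik_timepoint(80, 2.5, 4e7, 1000.0, 0.15)
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_prediction_finite_penalty(self):
        ll = loglik_timepoint(100, 0.0, 2e7, 1000.0, 0.1)
        assert np.isfinite(ll) and ll < -50


class TestPrior:
    def test_spar_mode(self):
        base = prior_logpdf(NuisanceParams(spar=0.45, sigma_t=1.0, sigma_b=0.1))
        for s in (0.40, 0.50, 0.60):
            assert prior_logpdf(NuisanceParams(spar=s, sigma_t=1.0, sigma_b=0.1)) < base

    def test_sigma_b_mode_at_zero(self):
        lp0 = prior_logpdf(NuisanceParams(spar=0.45, sigma_t=1.0, sigma_b=0.0))
        lp1 = prior_logpdf(NuisanceParams(spar=0.45, sigma_t=1.0, sigma_b=0.05))
        assert lp0 > lp1

    def test_spar_shift_costs_half_nat(self):
        # (0.05^2) / (2 * 0.0025) = 0.5 nats
        a = prior_logpdf(NuisanceParams(spar=0.45, sigma_t=2.0, sigma_b=0.1))
        b = prior_logpdf(NuisanceParams(spar=0.50, sigma_t=2.0, sigma_b=0.1))
        assert a - b == pytest.approx(0.5, rel=1e-9)


class TestCost:
    def test_fast_kernel_matches_reference(self, single_gene):
        prob = GeneProblem(single_gene.timecourses)
        rng = np.random.default_rng(5)
        for _ in range(5):
            theta = KineticParams(*(10.0 ** rng.uniform(-2.5, 0.5, 4)))
            alpha = NuisanceParams(
                spar=rng.uniform(0.2, 0.8),
                sigma_t=rng.uniform(0, 5),
                sigma_b=rng.uniform(0.05, 0.5),
            )
            c_fast = prob.cost_fast(prob.pack_params(theta, alpha))
            c_ref = prob.cost_reference(theta, alpha)
            assert c_fast == pytest.approx(c_ref, rel=1e-8)

    def test_additive_over_timepoints(self, single_gene):
        # dropping the last cytoplasmic timepoint removes exactly its term
        from dataclasses import replace

        tcs = dict(single_gene.timecourses)
        theta = single_gene.gene.params
        alpha = NuisanceParams(spar=0.45, sigma_t=1.0, sigma_b=0.2)
        full = GeneProblem(tcs)
        c_full = full.cost_reference(theta, alpha)

        cyto = tcs["cytoplasm"]
        tcs_drop = dict(tcs)
        tcs_drop["cytoplasm"] = replace(
            cyto,
            times=cyto.times[:-1],
            counts=cyto.counts[:-1],
            library_sizes=cyto.library_sizes[:-1],
        )
        c_drop = GeneProblem(tcs_drop).cost_reference(theta, alpha)

        traj = full.predict(theta, alpha)
        i = full.cyto_idx[-1]
        g = max(traj["z"][i], 1e-300)
        slope = (theta.k2_prime * traj["y"][i] - theta.k_cyto_deg * g) / g
        term = loglik_timepoint(
            cyto.counts[-1],
            g,
            cyto.library_sizes[-1],
            cyto.effective_length_bp,
            sigma_total_sq(alpha.sigma_b, alpha.sigma_t, slope),
        )
        assert c_full - c_drop == pytest.approx(-term, rel=1e-9)

    def test_truth_beats_perturbed_on_clean_data(self, noiseless_gene):
        theta = noiseless_gene.gene.params
        alpha = NuisanceParams(spar=0.45, sigma_t=0.1, sigma_b=0.05)
        c_true = cost(theta, alpha, noiseless_gene.timecourses)
        bad = KineticParams(
            theta.k1_prime, theta.k2, theta.k2_prime, theta.k_cyto_deg * 10
        )
        c_bad = cost(bad, alpha, noiseless_gene.timecourses)
        assert c_true < c_bad

    def test_disabling_priors_gives_pure_likelihood(self, single_gene):
        theta = single_gene.gene.params
        alpha = NuisanceParams(spar=0.45, sigma_t=1.0, sigma_b=0.2)
        c_with = cost(theta, alpha, single_gene.timecourses, include_priors=True)
        c_without = cost(theta, alpha, single_gene.timecourses, include_priors=False)
        assert c_with - c_without == pytest.approx(-prior_logpdf(alpha), rel=1e-9)

    def test_continuity_in_parameters(self, single_gene):
        prob = GeneProblem(single_gene.timecourses)
        alpha = NuisanceParams(spar=0.45, sigma_t=1.0, sigma_b=0.2)
        p0 = prob.pack_params(single_gene.gene.params, alpha)
        c0 = prob.cost_fast(p0)
        for i in range(4):
            p1 = p0.copy()
            p1[i] += 1e-5
            assert abs(prob.cost_fast(p1) - c0) < 1.0  # bounded finite difference
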
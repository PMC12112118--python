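"""H2O2 polynomial smoothing, radical profile, exposure, current-density law."""

import numpy as np
import pytest
from numpy.polynomial import polynomial as npoly
from scipy.integrate import quad

import ohfate as of

PRINTED_B = (3.09e-2, 3.39e-4, -3.10e-8, 8.81e-13)


def _poly(coeffs=PRINTED_B, t_max=18000.0):
    return of.H2O2Poly(coeffs, (0.0, t_max))


class TestPolynomialFit:
    def test_recovers_printed_coefficients_from_exact_samples(self):
        t = np.arange(0.0, 18001.0, 3600.0)
        y = npoly.polyval(t, np.asarray(PRINTED_B))
        fit = of.fit_h2o2_polynomial(t, y, order=3)
        np.testing.assert_allclose(fit.coefficients, PRINTED_B, rtol=1e-6)
        assert fit.fit_r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.valid_domain == (0.0, 18000.0)

    def test_constant_series(self):
        t = np.arange(0.0, 18001.0, 3600.0)
        fit = of.fit_h2o2_polynomial(t, np.full_like(t, 0.7), order=3)
        assert fit.coefficients[0] == pytest.approx(0.7, abs=1e-12)
        assert np.allclose(fit.coefficients[1:], 0.0, atol=1e-15)

    def test_noisy_fit_within_standard_errors(self):
        """With 5% multiplicative noise the OLS estimates stay within 3
        independently computed standard errors of the truth."""
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 18001.0, 600.0)
        truth = npoly.polyval(t, np.asarray(PRINTED_B))
        y = truth * (1 + 0.05 * rng.standard_normal(t.size))
        fit = of.fit_h2o2_polynomial(t, y, order=3)
        assert fit.fit_r2 < 1.0
        # standard errors from the scaled design, mapped back to raw time
        tm = t[-1]
        design = np.vander(t / tm, 4, increasing=True)
        resid = y - design @ (np.asarray(fit.coefficients) * tm ** np.arange(4))
        s2 = resid @ resid / (t.size - 4)
        cov = s2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov)) / tm ** np.arange(4)
        assert np.all(np.abs(np.asarray(fit.coefficients) - PRINTED_B) < 3 * se)

    def test_duplicate_times_rejected(self):
        t = np.array([0.0, 3600.0, 3600.0, 7200.0, 10800.0, 14400.0])
        with pytest.raises(of.EstimationError):
            of.fit_h2o2_polynomial(t, np.ones_like(t), order=3)

    def test_too_few_points_rejected(self):
        with pytest.raises(of.ContractViolation):
            of.fit_h2o2_polynomial([0, 1, 2, 3], [1, 2, 3, 4], order=3)


class TestOhStar:
    def test_printed_value_at_time_zero(self):
        profile = of.OhProfile(_poly(), 1e-10, 1.31e-4)
        assert of.oh_star(profile, 0.0) == pytest.approx(3.09e-12, rel=1e-12)

    def test_zero_polynomial_gives_zero(self):
        profile = of.OhProfile(_poly((0.0, 0.0)), 1e-10, 1.31e-4)
        assert of.oh_star(profile, 5000.0) == 0.0

    def test_negative_polynomial_is_clamped(self):
        profile = of.OhProfile(_poly((-0.5, 0.0)), 1e-10, 1.31e-4)
        assert of.oh_star(profile, 100.0) == 0.0

    def test_outside_domain_is_an_error_not_extrapolation(self):
        profile = of.OhProfile(_poly(), 1e-10, 1.31e-4)
        with pytest.raises(of.DomainError):
            of.oh_star(profile, 19000.0)
        with pytest.raises(of.DomainError):
            of.oh_star(profile, -50.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_non_negative_everywhere(self, seed):
        rng = np.random.default_rng(seed)
        coeffs = rng.uniform(-1, 1, 4) * np.array([1e-1, 1e-4, 1e-8, 1e-12])
        profile = of.OhProfile(_poly(tuple(coeffs)), 1e-10, 1e-4)
        t = np.linspace(0, 18000, 200)
        assert np.all(profile.oh_star(t) >= 0)


class TestOhExposure:
    def test_bpa_scenario_closed_form_value(self):
        profile = of.OhProfile(_poly(), 1e-10, 1.31e-4)
        u = of.oh_exposure(profile, 0.0, 18000.0)
        assert u == pytest.approx(2.40e-10, rel=5e-3)

    def test_degenerate_interval_is_zero(self):
        profile = of.OhProfile(_poly(), 1e-10, 1.31e-4)
        assert of.oh_exposure(profile, 5000.0, 5000.0) == 0.0

    def test_additive_over_subintervals(self):
        profile = of.OhProfile(_poly(), 1e-10, 1.31e-4)
        a, b = 4321.0, 17000.0
        whole = of.oh_exposure(profile, 0.0, b)
        split = of.oh_exposure(profile, 0.0, a) + of.oh_exposure(profile, a, b)
        assert split == pytest.approx(whole, rel=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_quadrature_including_clamped_regions(self, seed):
        """Closed-form piecewise integral vs adaptive quadrature of the
        clamped integrand, on sign-changing random cubics."""
        rng = np.random.default_rng(100 + seed)
        coeffs = rng.uniform(-1, 1, 4) * np.array([5e-2, 2e-4, 4e-8, 2e-12])
        profile = of.OhProfile(_poly(tuple(coeffs)), 1e-10, 1e-4)
        u = of.oh_exposure(profile, 0.0, 18000.0)
        # clamping makes the integrand kinked at the cubic's roots; hand the
        # independently computed roots to quad as breakpoints
        kinks = [float(r.real) for r in npoly.polyroots(coeffs)
                 if abs(r.imag) < 1e-9 and 0.0 < r.real < 18000.0]
        num, _ = quad(lambda t: profile.reference_conc * profile.oh_star(t),
                      0.0, 18000.0, limit=400, points=kinks or None)
        assert u == pytest.approx(num, rel=1e-8, abs=1e-22)

    def test_reversed_interval_rejected(self):
        profile = of.OhProfile(_poly(), 1e-10, 1.31e-4)
        with pytest.raises(of.ContractViolation):
            of.oh_exposure(profile, 100.0, 0.0)


class TestCurrentDensityLaw:
    def test_printed_line_at_operating_points(self):
        assert of.k_of_j(of.PRINTED_CURRENT_LAW, 20.0) == pytest.approx(
            1.38e-10, rel=5e-3)
        assert of.k_of_j(of.PRINTED_CURRENT_LAW, 15.0) == pytest.approx(
            1.06e-10, rel=5e-3)

    def test_zero_current_reads_intercept(self):
        assert of.k_of_j(of.PRINTED_CURRENT_LAW, 0.0) == pytest.approx(8.55e-12)

    def test_negative_current_rejected(self):
        with pytest.raises(of.ContractViolation):
            of.k_of_j(of.PRINTED_CURRENT_LAW, -1.0)

    def test_strictly_increasing_in_j(self):
        j = np.linspace(1, 25, 30)
        k = [of.k_of_j(of.PRINTED_CURRENT_LAW, x) for x in j]
        assert np.all(np.diff(k) > 0)

    def test_fit_recovers_exact_line(self):
        pairs = [(5.0, of.k_of_j(of.PRINTED_CURRENT_LAW, 5.0)),
                 (20.0, of.k_of_j(of.PRINTED_CURRENT_LAW, 20.0))]
        law = of.fit_current_law(pairs)
        assert law.slope == pytest.approx(6.48e-12, rel=1e-10)
        assert law.intercept == pytest.approx(8.55e-12, rel=1e-10)

    def test_perfect_line_r2_is_one(self):
        j = np.array([2.5, 5.0, 10.0, 15.0, 20.0])
        law = of.fit_current_law(list(zip(j, 2e-12 * j + 1e-12)))
        assert law.fit_r2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_fit_within_standard_errors(self):
        rng = np.random.default_rng(11)
        j = np.linspace(2.5, 20, 12)
        k = 6.48e-12 * j + 8.55e-12 + rng.normal(0, 3e-12, j.size)
        law = of.fit_current_law(list(zip(j, k)))
        design = np.column_stack([j, np.ones_like(j)])
        resid = k - design @ [law.slope, law.intercept]
        cov = (resid @ resid / (j.size - 2)) * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))
        assert abs(law.slope - 6.48e-12) < 3 * se[0]
        assert abs(law.intercept - 8.55e-12) < 3 * se[1]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(of.EstimationError):
            of.fit_current_law([(5.0, 1e-12), (5.0, 2e-12)])
        with pytest.raises(of.ContractViolation):
            of.fit_current_law([(5.0, 1e-12)])
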
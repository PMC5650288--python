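"""Linear-quadratic fitting, derived metrics and curve comparison."""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

from gicsurv.clonogenic import DoseSurvivalCurve, SurvivalPoint
from gicsurv.lqm import (
    NonIdentifiableDesignError,
    compare_curves,
    fit_lqm,
    fit_lqm_counts,
    lq_auc_closed_form,
    lqm_survival,
    radioresistance_ratio,
    radiosensitivity_metrics,
)
from gicsurv.synthetic import simulate_survival_curve_lognormal


def curve_from_sf(doses, sf_lists, culture="C1", condition="GIC"):
    points = [SurvivalPoint(0.0, 1.0, 0.0, 4, (1.0, 1.0, 1.0, 1.0))]
    for d, sfs in zip(doses, sf_lists):
        sfs = tuple(sfs)
        n = len(sfs)
        sem = float(np.std(sfs, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        points.append(SurvivalPoint(float(d), float(np.mean(sfs)), sem, n, sfs))
    return DoseSurvivalCurve(culture, condition, tuple(points))


def noiseless_curve(alpha, beta, doses=(2, 4, 6, 8), reps=4, **kw):
    return curve_from_sf(
        doses, [[lqm_survival(alpha, beta, d)] * reps for d in doses], **kw
    )


class TestLqmSurvival:
    @pytest.mark.parametrize(
        "alpha,beta,dose,expected",
        [
            (0.0, 0.0, 8.0, 1.0),
            (0.3, 0.03, 2.0, math.exp(-0.72)),
            (0.5, 0.1, 0.0, 1.0),
        ],
    )
    def test_values(self, alpha, beta, dose, expected):
        assert lqm_survival(alpha, beta, dose) == pytest.approx(expected, abs=1e-15)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            lqm_survival(-0.1, 0.0, 2.0)
        with pytest.raises(ValueError):
            lqm_survival(0.1, 0.0, -2.0)

    @given(
        st.floats(0.01, 1.0),
        st.floats(0.001, 0.2),
        st.floats(0.5, 8.0),
        st.floats(0.01, 0.5),
    )
    def test_strictly_decreasing_in_each_argument(self, alpha, beta, dose, bump):
        s = lqm_survival(alpha, beta, dose)
        assert lqm_survival(alpha + bump, beta, dose) < s
        assert lqm_survival(alpha, beta + bump, dose) < s
        assert lqm_survival(alpha, beta, dose + bump) < s


def normal_equation_oracle(doses, ys):
    """Independent closed-form WLS solution of y ~ a*D + b*D^2 (unit weights),
    solved exactly with rational arithmetic."""
    import sympy

    D = [sympy.Rational(d) for d in doses]
    Y = [sympy.nsimplify(y, rational=True) for y in ys]
    a, b = sympy.symbols("a b")
    eqs = [
        sum((Y[i] - a * D[i] - b * D[i] ** 2) * D[i] for i in range(len(D))),
        sum((Y[i] - a * D[i] - b * D[i] ** 2) * D[i] ** 2 for i in range(len(D))),
    ]
    sol = sympy.solve(eqs, [a, b])
    return float(sol[a]), float(sol[b])


class TestFitLqm:
    def test_noiseless_exact_recovery(self):
        curve = noiseless_curve(0.3, 0.03)
        fit = fit_lqm(curve)
        assert fit.alpha == pytest.approx(0.3, abs=1e-9)
        assert fit.beta == pytest.approx(0.03, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_symbolic_normal_equations_on_noisy_data(self):
        rng = np.random.default_rng(11)
        doses = (2, 4, 6, 8)
        sfs = [
            [lqm_survival(0.25, 0.02, d) * math.exp(rng.normal(0, 0.1))]
            for d in doses
        ]
        curve = curve_from_sf(doses, sfs)
        fit = fit_lqm(curve)
        ys = [-math.log(s[0]) for s in sfs]
        a, b = normal_equation_oracle(doses, ys)
        assert fit.alpha == pytest.approx(a, abs=1e-10)
        assert fit.beta == pytest.approx(b, abs=1e-10)

    def test_flat_curve_returns_zero_parameters(self):
        curve = curve_from_sf((2, 4, 6, 8), [[1.0, 1.0]] * 4)
        with pytest.warns(UserWarning, match="no decay"):
            fit = fit_lqm(curve)
        assert fit.alpha == 0.0 and fit.beta == 0.0
        assert np.allclose(fit.residuals, 0.0)

    def test_nonnegativity_clamp(self):
        # concave-up log-survival: unconstrained alpha would be negative
        doses = (2, 4, 6, 8)
        ys = [0.01, 0.2, 0.9, 2.2]  # ~ pure quadratic with a dip at low dose
        curve = curve_from_sf(doses, [[math.exp(-y)] for y in ys])
        fit = fit_lqm(curve)
        assert fit.alpha >= 0.0 and fit.beta >= 0.0
        a_unc, _ = normal_equation_oracle(doses, ys)
        assert a_unc < 0  # the clamp was actually exercised
        assert fit.alpha == 0.0

    def test_fit_idempotence(self):
        fit1 = fit_lqm(noiseless_curve(0.42, 0.017))
        fit2 = fit_lqm(noiseless_curve(fit1.alpha, fit1.beta))
        assert fit2.alpha == pytest.approx(fit1.alpha, abs=1e-9)
        assert fit2.beta == pytest.approx(fit1.beta, abs=1e-9)

    def test_weighting_options_agree_on_balanced_noiseless_data(self):
        curve = noiseless_curve(0.3, 0.03)
        for weighting in ("replicate", "none"):
            fit = fit_lqm(curve, weighting=weighting)
            assert fit.alpha == pytest.approx(0.3, abs=1e-9)

    def test_fractionated_mode_refuses_constant_fraction_design(self):
        with pytest.raises(NonIdentifiableDesignError, match="constant fraction"):
            fit_lqm(noiseless_curve(0.3, 0.03), mode="fractionated")


class TestFitLqmCounts:
    def _records(self, **kw):
        from gicsurv.synthetic import CloneSimConfig, simulate_colony_counts

        return simulate_colony_counts(CloneSimConfig(**kw))

    def test_noiseless_exact_recovery(self):
        fit = fit_lqm_counts(self._records(alpha_true=0.42, beta_true=0.017, noise="none"))
        assert fit.alpha == pytest.approx(0.42, abs=1e-9)
        assert fit.beta == pytest.approx(0.017, abs=1e-9)
        assert fit.mode == "acute_total_dose_binomial_mle"

    def test_less_variable_than_curve_fit_under_counting_noise(self, quiet):
        """The likelihood fit should track truth at least as well as the
        log-space curve fit on the same data, on average."""
        from gicsurv.clonogenic import build_survival_curve

        err_mle, err_wls = [], []
        for seed in range(1, 51):
            recs = self._records(rng_seed=seed)
            err_mle.append(abs(fit_lqm_counts(recs).alpha - 0.3))
            err_wls.append(abs(fit_lqm(build_survival_curve(recs)).alpha - 0.3))
        assert np.median(err_mle) <= np.median(err_wls)

    def test_zero_colony_wells_used_without_warning(self):
        recs = self._records(alpha_true=0.9, beta_true=0.1, rng_seed=7)
        assert any(r.colonies == 0 and r.dose_gy > 0 for r in recs)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = fit_lqm_counts(recs)
        assert fit.alpha > 0

    def test_requires_dose_zero(self):
        recs = [r for r in self._records(noise="none") if r.dose_gy > 0]
        with pytest.raises(ValueError, match="dose-0"):
            fit_lqm_counts(recs)

    def test_rejects_mixed_groups(self):
        recs = self._records(noise="none") + self._records(noise="none", culture_id="OTHER")
        with pytest.raises(ValueError, match="multiple"):
            fit_lqm_counts(recs)

    def test_covariance_is_positive_definite(self):
        fit = fit_lqm_counts(self._records(rng_seed=3))
        eig = np.linalg.eigvalsh(fit.covariance)
        assert np.all(eig > 0)


class TestAuc:
    def test_unit_survival(self):
        assert lq_auc_closed_form(0.0, 0.0, 8.0) == 8.0

    def test_pure_linear_term(self):
        assert lq_auc_closed_form(0.3, 0.0, 8.0) == pytest.approx(
            (1 - math.exp(-2.4)) / 0.3, abs=1e-12
        )

    @pytest.mark.parametrize("dmax", [4.0, 8.0])
    def test_matches_quadrature_on_grid(self, dmax):
        for alpha in np.linspace(0.0, 1.0, 6):
            for beta in np.linspace(0.0, 0.2, 5):
                expected, _ = integrate.quad(
                    lambda d: math.exp(-alpha * d - beta * d * d), 0.0, dmax
                )
                assert lq_auc_closed_form(alpha, beta, dmax) == pytest.approx(
                    expected, abs=1e-6
                )

    def test_trapezoid_on_worked_curve(self):
        doses = (2, 4, 6, 8)
        curve = curve_from_sf(doses, [[0.5], [0.25], [0.125], [0.0625]])
        fit = fit_lqm(curve)
        m = radiosensitivity_metrics(curve, fit)
        assert m.auc_trapezoid == pytest.approx(2.8125, abs=1e-12)


class TestMetrics:
    def test_observed_and_fitted_sf(self):
        curve = noiseless_curve(0.3, 0.03)
        fit = fit_lqm(curve)
        m = radiosensitivity_metrics(curve, fit)
        assert m.sf2_observed == pytest.approx(math.exp(-0.72), abs=1e-12)
        assert m.sf8_observed == pytest.approx(math.exp(-0.3 * 8 - 0.03 * 64), abs=1e-12)
        assert m.sf2_fitted == pytest.approx(m.sf2_observed, abs=1e-9)

    def test_missing_doses_flagged(self):
        curve = noiseless_curve(0.3, 0.03, doses=(1, 3, 5))
        fit = fit_lqm(curve)
        with pytest.warns(UserWarning, match="no observed point"):
            m = radiosensitivity_metrics(curve, fit)
        assert m.sf2_observed is None and m.sf8_observed is None

    @given(
        st.floats(0.05, 0.8),
        st.floats(0.005, 0.15),
        st.floats(0.01, 0.3),
        st.floats(0.001, 0.05),
    )
    def test_smaller_parameters_mean_larger_survival(self, a, b, da, db):
        """Lower alpha and beta (more radioresistant) => higher SF2 and SF8."""
        assert lqm_survival(a, b, 2.0) < lqm_survival(a - da * a, b - db * b, 2.0)
        assert lqm_survival(a, b, 8.0) < lqm_survival(a - da * a, b - db * b, 8.0)


class TestRatios:
    def test_self_ratio(self):
        fit = fit_lqm(noiseless_curve(0.3, 0.03))
        r = radioresistance_ratio(fit, fit)
        assert r.alpha_ratio == 1.0 and r.beta_ratio == 1.0

    def test_arithmetic(self):
        ref = fit_lqm(noiseless_curve(0.4, 0.04))
        test = fit_lqm(noiseless_curve(0.2, 0.02))
        r = radioresistance_ratio(ref, test)
        assert r.alpha_ratio == pytest.approx(2.0, abs=1e-9)
        assert r.beta_ratio == pytest.approx(2.0, abs=1e-9)

    def test_zero_denominator_named(self):
        ref = fit_lqm(noiseless_curve(0.4, 0.04))
        test = fit_lqm(noiseless_curve(0.2, 0.0))
        with pytest.raises(ZeroDivisionError, match="beta = 0"):
            radioresistance_ratio(ref, test)


def balanced_anova_oracle(y_a, y_b):
    """Culture main-effect F for a balanced two-way layout, from raw
    sums of squares computed with the hand formulas."""
    ya = np.asarray(y_a)  # shape (doses, reps)
    yb = np.asarray(y_b)
    all_ = np.concatenate([ya.ravel(), yb.ravel()])
    grand = all_.mean()
    n_d, r = ya.shape
    ss_culture = 2 * n_d * r * 0  # placeholder, computed below
    m_a, m_b = ya.mean(), yb.mean()
    ss_culture = n_d * r * ((m_a - grand) ** 2 + (m_b - grand) ** 2)
    dose_means = (ya.mean(axis=1) + yb.mean(axis=1)) / 2
    ss_dose = 2 * r * np.sum((dose_means - grand) ** 2)
    cell_means = np.stack([ya.mean(axis=1), yb.mean(axis=1)])
    ss_cells = r * np.sum((cell_means - grand) ** 2)
    ss_inter = ss_cells - ss_culture - ss_dose
    ss_tot = np.sum((all_ - grand) ** 2)
    ss_err = ss_tot - ss_cells
    df_err = 2 * n_d * (r - 1)
    return (ss_culture / 1) / (ss_err / df_err)


class TestCompareCurves:
    def test_identical_curves_give_null_result(self):
        curve = simulate_survival_curve_lognormal(0.3, 0.03, rng_seed=1, culture_id="A")
        twin = DoseSurvivalCurve("A", "DGC", curve.points)
        c = compare_curves(curve, twin)
        assert c.f_statistic == pytest.approx(0.0, abs=1e-10)
        assert c.p_value == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_sums_of_squares_when_balanced(self):
        ca = simulate_survival_curve_lognormal(0.3, 0.03, rng_seed=2, culture_id="A")
        cb = simulate_survival_curve_lognormal(0.5, 0.05, rng_seed=3, culture_id="A", condition="DGC")
        c = compare_curves(ca, cb)
        y_a = [[-math.log(s) for s in p.sf_replicates] for p in ca.points if p.dose_gy > 0]
        y_b = [[-math.log(s) for s in p.sf_replicates] for p in cb.points if p.dose_gy > 0]
        assert c.f_statistic == pytest.approx(balanced_anova_oracle(y_a, y_b), rel=1e-9)

    def test_mismatched_grids_rejected(self):
        ca = simulate_survival_curve_lognormal(0.3, 0.03, doses=(0, 2, 4), culture_id="A")
        cb = simulate_survival_curve_lognormal(0.3, 0.03, doses=(0, 2, 6), culture_id="A", condition="DGC")
        with pytest.raises(ValueError, match="grids differ"):
            compare_curves(ca, cb)

    def test_extra_sum_of_squares_detects_separation(self):
        ca = simulate_survival_curve_lognormal(0.2, 0.01, log_sd=0.05, rng_seed=4, culture_id="A")
        cb = simulate_survival_curve_lognormal(0.6, 0.08, log_sd=0.05, rng_seed=5, culture_id="A", condition="DGC")
        c = compare_curves(ca, cb, method="extra_sum_of_squares")
        assert c.method == "extra_sum_of_squares"
        assert c.p_value < 1e-4

    def test_p_decreases_with_separation(self):
        ps = []
        for alpha_b in (0.32, 0.45, 0.6):
            ca = simulate_survival_curve_lognormal(0.3, 0.03, log_sd=0.08, rng_seed=6, culture_id="A")
            cb = simulate_survival_curve_lognormal(alpha_b, 0.03, log_sd=0.08, rng_seed=7, culture_id="A", condition="DGC")
            ps.append(compare_curves(ca, cb).p_value)
        assert ps[0] > ps[1] > ps[2]
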
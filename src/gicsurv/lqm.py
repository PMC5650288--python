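"""Linear-quadratic model (LQM) fitting and radiosensitivity metrics.

The LQM writes the surviving fraction after an acute dose D as

    S(D) = exp(-alpha * D - beta * D**2)

with alpha (Gy^-1) read as intrinsic radiosensitivity and beta (Gy^-2) as
repair capacity.  Fits are done in log-survival space, where the model is
linear in (D, D^2) with no intercept: weighted least squares is exact and
convex.  Non-negativity of alpha and beta is enforced by active-set
clamping (negative radiosensitivity is non-physical).

Dose semantics: the default ``acute_total_dose`` mode regresses -ln SF on
the cumulative delivered dose, treating a 2 Gy/day fractionated course as
one curve over total dose — the standard way clonogenic data from a
constant dose-per-fraction schedule are summarised with distinct alpha and
beta.  A ``fractionated`` mode (-ln S = n*(alpha*d + beta*d^2)) is provided
for designs that vary dose per fraction; with a constant d the two
parameters are not separately identifiable and the fit refuses to run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .clonogenic import ColonyCountRecord, DoseSurvivalCurve

__all__ = [
    "LQMFit",
    "RadiosensitivityMetrics",
    "RadioresistanceRatios",
    "CurveComparison",
    "NonIdentifiableDesignError",
    "lqm_survival",
    "fit_lqm",
    "fit_lqm_counts",
    "lq_auc_closed_form",
    "radiosensitivity_metrics",
    "radioresistance_ratio",
    "compare_curves",
]


class NonIdentifiableDesignError(ValueError):
    """Raised when a fit design cannot separate alpha from beta."""


@dataclass(frozen=True)
class LQMFit:
    alpha: float  # Gy^-1
    beta: float  # Gy^-2
    covariance: np.ndarray  # 2x2, order (alpha, beta)
    r_squared: float
    residuals: np.ndarray  # log-survival scale, y - X theta
    n_points_used: int
    mode: str = "acute_total_dose"

    def predict_sf(self, dose):
        return lqm_survival(self.alpha, self.beta, dose)


@dataclass(frozen=True)
class RadiosensitivityMetrics:
    alpha: float
    beta: float
    sf2_observed: float | None
    sf8_observed: float | None
    sf2_fitted: float
    sf8_fitted: float
    auc_trapezoid: float
    auc_closed_form: float


@dataclass(frozen=True)
class RadioresistanceRatios:
    alpha_ratio: float
    beta_ratio: float


@dataclass(frozen=True)
class CurveComparison:
    f_statistic: float
    p_value: float
    df_numerator: int
    df_denominator: int
    method: str


def lqm_survival(alpha: float, beta: float, dose):
    """S(D) = exp(-alpha*D - beta*D^2); scalar or array dose."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    out = np.exp(-alpha * dose - beta * dose**2)
    return float(out) if out.ndim == 0 else out


def _fit_observations(
    curve: DoseSurvivalCurve, weighting: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (dose, y=-ln SF, weight) observations for the fit.

    ``replicate``: one observation per replicate SF > 0, unit weight.
    ``inverse_variance``: per-dose means of -ln SF weighted by n/var.
    ``none``: per-dose means, unit weight.
    Zero SFs are excluded (log undefined); dose 0 carries no information
    about (alpha, beta) as its mean is pinned at 1 and is excluded.
    """
    doses, ys, ws = [], [], []
    n_zero = 0
    for p in curve.points:
        if p.dose_gy == 0:
            continue
        logs = [-math.log(sf) for sf in p.sf_replicates if sf > 0]
        n_zero += sum(1 for sf in p.sf_replicates if sf == 0)
        if not logs:
            continue
        if weighting == "replicate":
            doses.extend([p.dose_gy] * len(logs))
            ys.extend(logs)
            ws.extend([1.0] * len(logs))
        else:
            doses.append(p.dose_gy)
            ys.append(float(np.mean(logs)))
            if weighting == "inverse_variance":
                var = float(np.var(logs, ddof=1)) if len(logs) > 1 else 0.0
                if var == 0:
                    ws.append(np.nan)  # patched to max finite weight below
                else:
                    ws.append(len(logs) / var)
            elif weighting == "none":
                ws.append(1.0)
            else:
                raise ValueError(f"unknown weighting {weighting!r}")
    if n_zero:
        warnings.warn(
            f"{curve.culture_id}/{curve.condition}: excluded {n_zero} "
            "zero-SF replicate(s) from the log-space fit",
            stacklevel=3,
        )
    w = np.array(ws)
    if np.any(np.isnan(w)):
        finite = w[~np.isnan(w)]
        fill = float(finite.max()) if finite.size else 1.0
        warnings.warn(
            "zero replicate variance at some dose; using the largest finite "
            "weight there",
            stacklevel=3,
        )
        w = np.where(np.isnan(w), fill, w)
    return np.array(doses), np.array(ys), w


def _wls_no_intercept(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted LS through the origin with theta >= 0 by active-set clamping."""
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    theta = np.linalg.solve(A, b)
    if np.all(theta >= 0):
        return theta, A
    # clamp each parameter in turn, refit the other, keep the feasible
    # candidate with the smaller weighted SSE
    candidates = []
    for free in (0, 1):
        t = np.zeros(2)
        denom = float(A[free, free])
        t[free] = max(0.0, b[free] / denom) if denom > 0 else 0.0
        sse = float(w @ (y - X @ t) ** 2)
        candidates.append((sse, t))
    sse, theta = min(candidates, key=lambda c: c[0])
    return theta, A


def fit_lqm(
    curve: DoseSurvivalCurve,
    weighting: str = "replicate",
    mode: str = "acute_total_dose",
    dose_per_fraction: float | None = None,
) -> LQMFit:
    """Fit S(D) = exp(-alpha*D - beta*D^2) to a survival curve.

    Parameters
    ----------
    weighting
        ``replicate`` (default): one log-survival observation per replicate.
        ``inverse_variance``: per-dose means weighted by n/var(-ln SF).
        ``none``: unweighted per-dose means.
    mode
        ``acute_total_dose`` (default) or ``fractionated``; the latter
        needs varying dose per fraction and refuses a constant-d design.
    """
    if mode == "fractionated":
        # with constant dose per fraction d, -ln S = n(ad + bd^2) = D(a + bd):
        # only the combination a + b*d is identifiable.
        raise NonIdentifiableDesignError(
            "fractionated mode needs doses delivered at varying dose per "
            "fraction; with a constant fraction size only alpha + beta*d is "
            "identifiable — fit in acute_total_dose mode instead"
        )
    if mode != "acute_total_dose":
        raise ValueError(f"unknown mode {mode!r}")

    D, y, w = _fit_observations(curve, weighting)
    if len(np.unique(D)) < 2:
        raise ValueError("need >= 2 distinct positive doses with SF > 0")
    X = np.column_stack([D, D**2])
    theta, A = _wls_no_intercept(X, y, w)
    if theta[0] == 0 and theta[1] == 0 and np.all(y <= 0):
        warnings.warn(
            f"{curve.culture_id}/{curve.condition}: no decay in survival; "
            "alpha = beta = 0 returned",
            stacklevel=2,
        )
    resid = y - X @ theta
    rss = float(w @ resid**2)
    tss = float(w @ y**2)  # uncentered: regression through the origin
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    n, k = len(y), int(np.sum(theta > 0)) or 1
    sigma2 = rss / (n - k) if n > k else float("nan")
    cov = sigma2 * np.linalg.inv(A)
    return LQMFit(
        alpha=float(theta[0]),
        beta=float(theta[1]),
        covariance=cov,
        r_squared=max(0.0, min(1.0, r2)),
        residuals=resid,
        n_points_used=n,
        mode=mode,
    )


def fit_lqm_counts(
    records: list[ColonyCountRecord],
    mode: str = "acute_total_dose",
) -> LQMFit:
    """Fit the LQ model to raw colony counts by binomial maximum likelihood.

    Models each well as colonies ~ Binomial(cells_seeded, PE * S(D)) and
    maximises the joint likelihood over (PE, alpha, beta).  Compared with
    the log-space least-squares fit on a normalised curve this estimator

    * weights wells by their actual information content (low-count
      high-dose wells are intrinsically noisier on the log scale),
    * propagates the plating-efficiency uncertainty instead of treating
      the dose-0 normaliser as exact, and
    * uses zero-colony wells directly (no log transform, no exclusion).

    It is the asymptotically efficient estimator under the counting model
    and is the recommended fit whenever raw counts are available; use
    ``fit_lqm`` when only a normalised survival curve is.  Fractional
    counts (expected-value data) are accepted as a quasi-likelihood.
    """
    if mode != "acute_total_dose":
        raise NonIdentifiableDesignError(
            "count-level fitting is defined for acute_total_dose only"
        )
    if not records:
        raise ValueError("no colony-count records given")
    groups = {(r.culture_id, r.condition) for r in records}
    if len(groups) > 1:
        raise ValueError(f"records span multiple culture/condition groups: {sorted(groups)}")
    D = np.array([r.dose_gy for r in records], dtype=float)
    k = np.array([r.colonies for r in records], dtype=float)
    n = np.array([r.cells_seeded for r in records], dtype=float)
    if not np.any(D == 0):
        raise ValueError("a dose-0 reference is required to identify PE")
    if len(np.unique(D[D > 0])) < 2:
        raise ValueError("need >= 2 distinct positive doses")

    # starting values: PE from dose-0 ratios, (alpha, beta) from an
    # unweighted log-space regression on the positive-count wells
    pe0 = float(np.mean(k[D == 0] / n[D == 0]))
    pe0 = min(max(pe0, 1e-6), 1 - 1e-6)
    pos = (D > 0) & (k > 0)
    if np.any(pos):
        y0 = -np.log(k[pos] / (n[pos] * pe0))
        X0 = np.column_stack([D[pos], D[pos] ** 2])
        theta0, _ = _wls_no_intercept(X0, y0, np.ones(pos.sum()))
    else:
        theta0 = np.zeros(2)

    def unpack(v):
        pe = 1.0 / (1.0 + np.exp(-v[0]))
        p = pe * np.exp(-(v[1] * D + v[2] * D**2))
        return pe, np.clip(p, 1e-300, 1 - 1e-12)

    def nll_grad(v):
        pe, p = unpack(v)
        nll = -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))
        # d nll / d p_i = -(k_i - n_i p_i) / (p_i (1 - p_i))
        g_p = -(k - n * p) / (p * (1.0 - p))
        grad = np.array(
            [
                float(np.sum(g_p * p * (1.0 - pe))),  # d p / d logit(pe) = p (1 - pe)
                float(np.sum(g_p * (-D * p))),
                float(np.sum(g_p * (-(D**2) * p))),
            ]
        )
        return nll, grad

    from scipy import optimize

    start = np.array([math.log(pe0 / (1.0 - pe0)), max(theta0[0], 0.0), max(theta0[1], 0.0)])
    res = optimize.minimize(
        nll_grad,
        start,
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None), (0.0, None), (0.0, None)],
        options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
    )
    pe_hat, p_hat = unpack(res.x)
    alpha, beta = float(res.x[1]), float(res.x[2])

    # covariance from the expected Fisher information at the optimum
    dp = np.column_stack([p_hat * (1.0 - pe_hat), -D * p_hat, -(D**2) * p_hat])
    info = (dp * (n / (p_hat * (1.0 - p_hat)))[:, None]).T @ dp
    try:
        cov = np.linalg.inv(info)[1:, 1:]
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)

    # log-scale diagnostics on the positive-count wells, for comparability
    # with the least-squares fit
    y = -np.log(np.clip(k[pos] / (n[pos] * pe_hat), 1e-300, None)) if np.any(pos) else np.array([])
    resid = y - (alpha * D[pos] + beta * D[pos] ** 2) if np.any(pos) else np.array([])
    tss = float(y @ y) if y.size else 0.0
    rss = float(resid @ resid)
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return LQMFit(
        alpha=alpha,
        beta=beta,
        covariance=cov,
        r_squared=max(0.0, min(1.0, r2)),
        residuals=resid,
        n_points_used=len(records),
        mode="acute_total_dose_binomial_mle",
    )


def lq_auc_closed_form(alpha: float, beta: float, dmax: float) -> float:
    """Integral of exp(-alpha*D - beta*D^2) from 0 to dmax.

    Uses the scaled complementary error function for numerical stability:
    for beta > 0,

        AUC = sqrt(pi/(4 beta)) * [erfcx(a) - erfcx(a + sqrt(beta) L) * S(L)]

    with a = alpha / (2 sqrt(beta)) and S(L) the surviving fraction at L.
    Limits: (1 - exp(-alpha L))/alpha when beta = 0, and L when both are 0.
    """
    if alpha < 0 or beta < 0 or dmax < 0:
        raise ValueError("alpha, beta and dmax must be non-negative")
    L = dmax
    if beta == 0:
        if alpha == 0:
            return float(L)
        return float((1.0 - math.exp(-alpha * L)) / alpha)
    sb = math.sqrt(beta)
    a = alpha / (2.0 * sb)
    return float(
        math.sqrt(math.pi) / (2.0 * sb)
        * (special.erfcx(a) - special.erfcx(a + sb * L) * math.exp(-alpha * L - beta * L**2))
    )


def radiosensitivity_metrics(
    curve: DoseSurvivalCurve, fit: LQMFit
) -> RadiosensitivityMetrics:
    """SF2, SF8 (observed means and fitted values) and AUC (trapezoid on
    observed means; closed form on the fitted curve), over the observed
    dose range."""
    p2, p8 = curve.point_at(2.0), curve.point_at(8.0)
    if p2 is None or p8 is None:
        missing = [d for d, p in ((2, p2), (8, p8)) if p is None]
        warnings.warn(
            f"{curve.culture_id}/{curve.condition}: no observed point at "
            f"{missing} Gy; observed SF left unset",
            stacklevel=2,
        )
    dmax = float(curve.doses.max())
    return RadiosensitivityMetrics(
        alpha=fit.alpha,
        beta=fit.beta,
        sf2_observed=p2.sf_mean if p2 else None,
        sf8_observed=p8.sf_mean if p8 else None,
        sf2_fitted=lqm_survival(fit.alpha, fit.beta, 2.0),
        sf8_fitted=lqm_survival(fit.alpha, fit.beta, 8.0),
        auc_trapezoid=float(np.trapezoid(curve.sf_means, curve.doses)),
        auc_closed_form=lq_auc_closed_form(fit.alpha, fit.beta, dmax),
    )


def radioresistance_ratio(
    fit_reference: LQMFit, fit_test: LQMFit
) -> RadioresistanceRatios:
    """alpha_ref/alpha_test and beta_ref/beta_test.

    With the differentiated culture as reference and the stem-like culture
    under test, a ratio above 1 means the test culture is the more
    radioresistant.
    """
    for name, denom in (("alpha", fit_test.alpha), ("beta", fit_test.beta)):
        if denom == 0:
            raise ZeroDivisionError(
                f"radioresistance ratio undefined: test fit has {name} = 0"
            )
    return RadioresistanceRatios(
        alpha_ratio=fit_reference.alpha / fit_test.alpha,
        beta_ratio=fit_reference.beta / fit_test.beta,
    )


def _anova_frame(curve_a, curve_b):
    rows = []
    for label, curve in (("a", curve_a), ("b", curve_b)):
        for p in curve.points:
            if p.dose_gy == 0:
                continue
            for sf in p.sf_replicates:
                if sf > 0:
                    rows.append((label, p.dose_gy, -math.log(sf)))
    return pd.DataFrame(rows, columns=["culture", "dose", "y"])


def compare_curves(
    curve_a: DoseSurvivalCurve,
    curve_b: DoseSurvivalCurve,
    method: str = "two_way_anova_culture_effect",
) -> CurveComparison:
    """Test whether two survival curves differ.

    ``two_way_anova_culture_effect`` runs a two-way ANOVA of -ln SF per
    replicate on culture and dose (with interaction) and reports the
    culture main effect; unbalanced replicate counts (e.g. after excluding
    zero-SF wells) are handled with Type-II sums of squares.
    ``extra_sum_of_squares`` compares a joint LQ fit against separate fits
    with an F test.
    """
    grid_a = sorted(p.dose_gy for p in curve_a.points if p.dose_gy > 0)
    grid_b = sorted(p.dose_gy for p in curve_b.points if p.dose_gy > 0)
    if grid_a != grid_b:
        raise ValueError(f"dose grids differ: {grid_a} vs {grid_b}")

    if method == "two_way_anova_culture_effect":
        design_counts = [
            p.n for c in (curve_a, curve_b) for p in c.points if p.dose_gy > 0
        ]
        if min(design_counts) < 2:
            raise ValueError("need >= 2 replicates per culture x dose cell")
        df = _anova_frame(curve_a, curve_b)
        # zero-SF wells were excluded; a dose with an empty cell in either
        # culture cannot enter the factorial layout and is dropped
        counts = df.groupby(["culture", "dose"]).size()
        full = counts.unstack("culture").dropna()
        usable = set(full.index)
        if usable != set(grid_a):
            warnings.warn(
                f"doses dropped from the ANOVA (no usable replicate in one "
                f"culture): {sorted(set(grid_a) - usable)}",
                stacklevel=2,
            )
            df = df[df["dose"].isin(usable)]
            counts = df.groupby(["culture", "dose"]).size()
        if counts.nunique() > 1:
            warnings.warn(
                "unbalanced replicate counts; using Type-II sums of squares",
                stacklevel=2,
            )
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        fit = smf.ols("y ~ C(culture) * C(dose)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        row = table.loc["C(culture)"]
        df1 = int(row["df"])
        df2 = int(table.loc["Residual", "df"])
        ss_culture = float(row["sum_sq"])
        if ss_culture <= 0 or not np.isfinite(row["F"]):
            # identical group means (or a saturated noiseless design)
            return CurveComparison(0.0, 1.0, df1, df2, method)
        return CurveComparison(float(row["F"]), float(row["PR(>F)"]), df1, df2, method)

    if method == "extra_sum_of_squares":
        def _rss(curves):
            D, y, w = [], [], []
            for c in curves:
                d_, y_, w_ = _fit_observations(c, "replicate")
                D.append(d_), y.append(y_), w.append(w_)
            D, y, w = map(np.concatenate, (D, y, w))
            X = np.column_stack([D, D**2])
            theta, _ = _wls_no_intercept(X, y, w)
            return float(w @ (y - X @ theta) ** 2), len(y)

        rss_joint, n_tot = _rss([curve_a, curve_b])
        rss_a, _ = _rss([curve_a])
        rss_b, _ = _rss([curve_b])
        rss_sep = rss_a + rss_b
        df1, df2 = 2, n_tot - 4
        if df2 <= 0:
            raise ValueError("too few observations for the extra-SS test")
        if rss_sep == 0:
            f = 0.0 if rss_joint == rss_sep else float("inf")
        else:
            f = max(0.0, (rss_joint - rss_sep) / df1 / (rss_sep / df2))
        p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        return CurveComparison(f, max(p, np.nextafter(0, 1)), df1, df2, method)

    raise ValueError(f"unknown method {method!r}")
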
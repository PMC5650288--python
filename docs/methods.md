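# Methods note

Modelling assumptions, estimator choices, numerical details and known
limitations of the `gicsurv` pipeline.

## Clonogenic survival processing

- **Plating efficiency (PE)** is the mean of per-replicate
  colonies/cells-seeded ratios in the unirradiated wells of the same
  culture and condition. Surviving fraction at dose D is
  (colonies/seeded)/PE. Normalisation never crosses cultures or
  conditions.
- **Zero-colony wells** yield SF = 0, which is recorded and counted but
  excluded from any log-space computation (the log transform is
  undefined); exclusions are reported with a warning. The count-level
  likelihood fit (below) uses such wells directly.
- The dose-0 point of a summarised curve is pinned at SF = 1 by
  construction; its replicate scatter is retained for diagnostics only.

## Linear-quadratic model

Survival after an acute dose D is S(D) = exp(−αD − βD²), α in Gy⁻¹,
β in Gy⁻². Data from a constant dose-per-fraction schedule (e.g. 2 Gy/day
to a cumulative 2–8 Gy) are fitted on total dose, the standard way such
designs are summarised. A `fractionated` mode (−ln S = n(αd + βd²)) exists
but refuses constant-fraction designs: with fixed d only α + βd is
identifiable, and fitting it anyway would silently return arbitrary
parameter splits.

### Curve-level fit (`fit_lqm`)

Weighted least squares of y = −ln SF on (D, D²) with no intercept — linear,
convex, closed-form. Weighting options:

- `replicate` (default): one observation per replicate, unit weight;
- `inverse_variance`: per-dose means weighted by n/var(−ln SF);
- `none`: unweighted per-dose means.

Non-negativity of (α, β) is enforced by active-set clamping: if the
unconstrained solution is feasible it is returned exactly; otherwise one
parameter is clamped to zero and the other refitted, keeping the feasible
candidate with the smaller weighted residual sum. Covariance comes from
standard WLS theory at the solution; R² is uncentred (regression through
the origin).

### Count-level fit (`fit_lqm_counts`)

When raw colony counts are available, each well is modelled as
colonies ~ Binomial(cells seeded, PE·S(D)) and (PE, α, β) are estimated by
joint maximum likelihood (L-BFGS-B with analytic gradient, started from PE
of the dose-0 ratios and a log-space regression; covariance from the
expected Fisher information). This estimator

- weights wells by actual information content — high-dose, low-count wells
  are far noisier on the log scale (var(−ln SF) ≈ 1/expected count);
- propagates plating-efficiency uncertainty instead of treating the dose-0
  normaliser as exact (a shared normaliser is a culture-level error term
  the curve-level fit cannot see);
- needs no zero-count exclusion.

In simulation at the generator defaults it attains the information bound
(median relative error of α̂ ≈ 9% vs ≈ 10–15% for the least-squares
variants). Fractional (expected-value) counts are accepted as a
quasi-likelihood, so noiseless data round-trip exactly. It is the
recommended fit whenever counts exist; `fit_lqm` remains for summarised
curves.

### Derived metrics

- SF2/SF8 are reported both as observed per-dose means and as fitted
  values S(2), S(8).
- AUC over the observed dose range is reported two ways: trapezoid rule on
  observed means (the conventional spreadsheet/Prism quantity) and the
  closed form of ∫₀^L exp(−αD − βD²) dD. The closed form uses the *scaled*
  complementary error function, AUC = √(π/4β)·[erfcx(a) −
  erfcx(a+√β·L)·S(L)] with a = α/(2√β), which avoids the catastrophic
  cancellation of the naive exp(α²/4β)(erf−erf) form; analytic limits
  (1−e^{−αL})/α at β = 0 and L at α = β = 0. Agreement with adaptive
  quadrature is ~1e−15 across the tested (α, β, L) grid.
- Radioresistance ratios α_ref/α_test and β_ref/β_test use the
  differentiated culture as reference, so ratios above 1 mean the
  stem-like culture is the more radioresistant. A zero denominator raises
  an error naming the offending parameter.

### Two-curve comparison

`compare_curves` defaults to a two-way ANOVA of per-replicate −ln SF on
culture × dose with interaction, reporting the culture main effect
(Type-II sums of squares, so unbalanced cells after zero-SF exclusion are
handled; a dose whose cell empties entirely is dropped with a warning).
An `extra_sum_of_squares` alternative compares one joint LQ fit against
separate fits by an F test.

**Known limitation.** When both curves are normalised by their own
estimated PE, the shared ln(PE) estimation error acts as a culture-level
random effect that the replicate-level ANOVA does not model. Under the
binomial count generator this inflates the null rejection rate to ≈ 0.08
*regardless of seeding density* (both the PE-error variance and the
replicate variance scale as 1/n, so their ratio is fixed). This is a
property of PE-normalised surviving fractions, not of the implementation;
the test is calibrated (rejection rate 0.048 over 1000 null runs) under
Gaussian log-survival noise, the model the ANOVA actually assumes.
p-values near 0.05 on count-derived curves should therefore be read
cautiously; the count-level likelihood machinery is the principled route
when this matters.

## Metagene subtype scoring

ΔCt = Ct(target) − mean Ct(GAPDH, GUSB) per sample; −ΔCt serves as a log2
expression index (relative expression 2^−ΔCt is also available, and
classification is invariant to the choice because z-scoring a monotone
per-gene transform of the same ranks differs only through linearity —
both indices are offered, log2 is the default). Each gene column is
z-scored across samples (ddof = 1); the PN and Mes metagene scores are the
mean z over the signature genes (SOX9, OLIG2, SOX2, PROM1 and FN1, CHI3L1,
CD44, CTGF), requiring at least 3 observed genes per signature. The call
is the sign of (Mes score − PN score); exact ties or insufficient coverage
give "undetermined". Genes with zero variance or observed in fewer than
two samples are dropped with a warning. Ct values outside 5–40 cycles are
flagged as implausible.

## Exact small-sample statistics

- **Spearman**: rho is the Pearson correlation of ranks. For tie-free
  samples with n ≤ 9 the two-sided p enumerates all n! rank permutations
  (9! = 362 880; the statistic is linear in Σ rᵢ·r*ᵢ, so enumeration is
  vectorised). Ties or larger n fall back, with a warning, to the
  t approximation.
- **Mann-Whitney**: tie-free pooled samples with n ≤ 12 enumerate all
  C(n, n_a) group assignments; otherwise a normal approximation with tie
  and continuity corrections. U uses half credit for ties.
- **Welch t**: Satterthwaite degrees of freedom; a two-observation group
  with zero variance collapses the Welch df, so that case falls back to
  the pooled test with a warning.
- Exact-path p-values are attained (p ≥ 1/#arrangements), so reported
  exact p-values are never zero; approximate p-values are floored at the
  smallest positive double.

The enumeration thresholds (9 and 12) are this package's choice: large
enough to cover realistic culture-cohort sizes, small enough that the
exact path stays sub-second.

## Outcome association

Cultures and patients are matched by identifier (unmatched entries dropped
with a warning; at least 3 matched pairs required). Each LQ parameter is
correlated with disease-free survival — and overall survival when present
for every patient — by the exact Spearman test; a metric that is constant
across the matched cultures is skipped with a warning rather than failing
the table.

## Synthetic data

The generators emulate the measurement process, not the biology:

- **Colony counts**: colonies ~ Binomial(cells seeded, PE·S(D)) per
  replicate well (defaults PE = 0.3, 500 cells/well, 4 replicates, doses
  {0, 2, 4, 6, 8} Gy, α = 0.3 Gy⁻¹, β = 0.03 Gy⁻² — an α/β of 10 Gy,
  the classic tumour value). `poisson` and `none` noise modes exist; the
  deterministic mode emits exact expected counts (possibly fractional) so
  that noiseless analyses round-trip to machine precision. A lognormal
  curve generator (Gaussian noise on −ln SF) provides the matched error
  model for calibration studies.
- **Ct matrices**: a PN and a Mes group (default 10 samples each) whose
  own-signature genes are shifted down by `effect_size` cycles (default 3;
  lower Ct = higher expression) around baseline 28, housekeeping at 20,
  Gaussian noise sd 0.5 cycles on every well.
- **Cohorts**: per-patient α drawn uniformly (default 0.1–0.7 Gy⁻¹),
  β = α/10; DFS = 30·α + truncated Gaussian noise (months, redrawn while
  non-positive), OS = DFS + 6. This encodes the hypothesis under test —
  more radiosensitive cultures, longer survival — as a monotone
  ground-truth association.

Not modelled: cell-cycle and hypoxia effects, plate/edge effects, count
overdispersion beyond binomial, censoring of survival times, batch effects
in qPCR. Conclusions drawn from these generators validate the statistical
machinery, not biological effect sizes.

Seeds: every stochastic routine takes an explicit `rng_seed`; derived
child seeds use (seed·1 000 003 + i) mod 2³¹ so all seeds stay in the
32-bit range.
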
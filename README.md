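# gicsurv

Quantitative radiobiology of patient-derived glioblastoma cultures: from raw
clonogenic colony counts to linear-quadratic radiosensitivity parameters,
transcriptional subtype calls, and exact small-sample association of
radiosensitivity with clinical outcome.

## Scientific problem

Glioblastoma-initiating cells (GICs, stem-like cultures) are frequently more
radioresistant than their differentiated counterparts (DGCs), and the degree
of intrinsic radiosensitivity of a patient's cultured cells may carry
prognostic information. Testing this involves a chain of small-sample
analyses, each easy to get subtly wrong:

1. **Clonogenic survival.** Cells are irradiated at graded doses
   (typically 0, 2, 4, 6, 8 Gy), seeded, and surviving colonies counted.
   Counts are normalised by the unirradiated plating efficiency to give
   surviving fractions (SF).
2. **Linear-quadratic model (LQM).** Survival is summarised by

   ```
   S(D) = exp(−α·D − β·D²)
   ```

   with α (Gy⁻¹) read as intrinsic radiosensitivity and β (Gy⁻²) as
   repair capacity. Derived metrics: SF2 and SF8 (survival at 2 and 8 Gy),
   area under the survival curve (AUC), DGC/GIC parameter ratios, and a
   formal two-curve comparison.
3. **Subtype scoring.** Proneural (PN) vs mesenchymal (Mes) metagene scores
   are computed from qPCR ΔCt values (SOX9, OLIG2, SOX2, PROM1 vs FN1,
   CHI3L1, CD44, CTGF, normalised to GAPDH/GUSB) by gene-wise z-scoring.
4. **Outcome association.** With cohorts of only four to six patients,
   asymptotic p-values are unreliable; Spearman correlations of α and β
   with disease-free and overall survival use exact permutation
   enumeration, as do Mann-Whitney group comparisons.

The package implements this pipeline as a tested, reusable library with a
synthetic-data module whose ground truth is known exactly, so every stage
can be validated end to end.

## Worked example

Simulate one patient's GIC/DGC pair at known parameters, fit both curves
from the raw counts, and compare them:

```python
from gicsurv import (
    CloneSimConfig, simulate_colony_counts, build_survival_curve,
    fit_lqm_counts, radiosensitivity_metrics, radioresistance_ratio,
    compare_curves,
)

gic = simulate_colony_counts(CloneSimConfig(
    alpha_true=0.25, beta_true=0.025, condition="GIC", culture_id="GBT1", rng_seed=11))
dgc = simulate_colony_counts(CloneSimConfig(
    alpha_true=0.45, beta_true=0.045, condition="DGC", culture_id="GBT1", rng_seed=12))

fit_gic, fit_dgc = fit_lqm_counts(gic), fit_lqm_counts(dgc)
curve_gic, curve_dgc = build_survival_curve(gic), build_survival_curve(dgc)
m = radiosensitivity_metrics(curve_gic, fit_gic)
r = radioresistance_ratio(fit_dgc, fit_gic)   # DGC as reference
cmp_ = compare_curves(curve_gic, curve_dgc)
```

Output (exact, reproducible from the seeds above):

```
GIC:  alpha=0.255 Gy^-1  beta=0.0266 Gy^-2
DGC:  alpha=0.409 Gy^-1  beta=0.0446 Gy^-2
GIC SF2=0.540  SF8=0.0237  AUC=2.661 Gy
alpha ratio (DGC/GIC) = 1.60   beta ratio = 1.67
curves differ: F=74.9, p=1.23e-07
```

The stem-like culture survives irradiation far better (both ratios ≈ 1.6,
i.e. smaller α and β than its differentiated sibling), and the two-way
ANOVA on log-survival confirms the difference.

Two fitting routes are provided:

- `fit_lqm_counts(records)` — binomial maximum likelihood on raw colony
  counts, jointly estimating plating efficiency, α and β. Statistically
  efficient; uses zero-colony wells directly. Recommended whenever raw
  counts are available.
- `fit_lqm(curve, weighting=...)` — weighted least squares on −ln SF of a
  normalised survival curve (weighting: `replicate`, `inverse_variance`,
  `none`), for when only summarised curves exist.

The same pipeline is scriptable from the command line:

```
gicsurv simulate cohort --out sim --seed 3
gicsurv run --config config.json --out report.json
gicsurv validate --counts counts.tsv --ct ct.tsv --outcomes outcomes.tsv
```

(`gicsurv --help` lists the subcommands: simulate, survival, fit, subtype,
correlate, run, validate.)

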
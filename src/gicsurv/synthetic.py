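"""Ground-truth synthetic data for every pipeline stage.

Three generators mirror the three kinds of input the analysis consumes:

* colony counts from a clonogenic assay irradiated on a fractionated
  2 Gy/day schedule (total doses 0–8 Gy), with per-well binomial sampling
  of colony formation under a plating efficiency times a linear-quadratic
  survival law;
* qPCR Ct matrices with a two-subtype (proneural vs mesenchymal) mean
  shift on the signature genes plus Gaussian cycle noise;
* small cohorts of cultures whose matched patient disease-free survival
  is a noisy increasing function of the culture's alpha.

Every generator is a pure function of its config, including the seed, so
identical configs reproduce identical data bit-for-bit, and noiseless
configs are exactly recovered by the downstream estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clonogenic import ColonyCountRecord
from .stats import PatientOutcome
from .subtype import HOUSEKEEPING_GENES, CtTable, SignatureSet

__all__ = [
    "CloneSimConfig",
    "CtSimConfig",
    "CohortSimConfig",
    "CultureGroundTruth",
    "SimulatedCtCohort",
    "SimulatedCohort",
    "simulate_colony_counts",
    "simulate_ct_matrix",
    "simulate_cohort",
    "simulate_survival_curve_lognormal",
]

DEFAULT_DOSES = (0.0, 2.0, 4.0, 6.0, 8.0)  # Gy total, 2 Gy/day fractions


@dataclass(frozen=True)
class CloneSimConfig:
    """Clonogenic-assay simulation parameters.

    Defaults describe a culture of intermediate radiosensitivity
    (alpha = 0.3 Gy^-1, beta = 0.03 Gy^-2, i.e. alpha/beta = 10 Gy) plated
    at moderate efficiency; ``noise`` selects per-well binomial sampling
    (the default: a seeded cell either founds a colony or it does not),
    Poisson sampling for large seedings, or deterministic expected counts.
    """

    alpha_true: float = 0.3  # Gy^-1
    beta_true: float = 0.03  # Gy^-2
    plating_efficiency_true: float = 0.3
    doses: tuple[float, ...] = DEFAULT_DOSES  # Gy, cumulative
    cells_seeded: int = 500
    replicates: int = 4
    rng_seed: int = 0
    culture_id: str = "SIM"
    condition: str = "GIC"
    noise: str = "binomial"  # "binomial" | "poisson" | "none"

    def __post_init__(self) -> None:
        if self.alpha_true < 0 or self.beta_true < 0:
            raise ValueError("alpha_true and beta_true must be non-negative")
        if not 0 < self.plating_efficiency_true <= 1:
            raise ValueError("plating_efficiency_true must lie in (0, 1]")
        if 0.0 not in self.doses:
            raise ValueError("doses must contain 0 (the untreated wells)")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if self.cells_seeded < 1 or self.replicates < 1:
            raise ValueError("cells_seeded and replicates must be positive")
        if self.noise not in ("binomial", "poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        for d in self.doses:
            p = self.plating_efficiency_true * math.exp(
                -self.alpha_true * d - self.beta_true * d**2
            )
            if p > 1:
                raise ValueError(f"colony probability {p} > 1 at dose {d}")


@dataclass(frozen=True)
class CtSimConfig:
    """Two-subtype qPCR cohort parameters.

    ``effect_size`` is the number of Ct cycles by which a group's own
    signature genes are shifted *down* (lower Ct = higher expression);
    3 cycles (an 8-fold expression change) with 0.5 cycles of technical
    noise is a clean but realistic qPCR contrast.
    """

    n_samples_per_group: int = 10
    effect_size: float = 3.0  # cycles
    noise_sd: float = 0.5  # cycles
    baseline_ct: float = 28.0  # cycles
    housekeeping_ct: float = 20.0  # cycles
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 2:
            raise ValueError("need >= 2 samples per group (z-scores undefined)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortSimConfig:
    """Culture-pair cohort with outcome tied to radiosensitivity.

    Six culture/patient pairs by default.  alpha is drawn uniformly from
    ``alpha_range``; beta follows alpha through a fixed alpha/beta ratio
    (10 Gy, the classic tumour value); DFS rises linearly with alpha at
    ``dfs_scale`` months per Gy^-1 plus Gaussian noise, truncated positive;
    OS is DFS plus a fixed positive offset.
    """

    n_patients: int = 6
    alpha_range: tuple[float, float] = (0.1, 0.7)  # Gy^-1
    alpha_over_beta: float = 10.0  # Gy
    dfs_scale: float = 30.0  # months per Gy^-1
    dfs_noise_sd: float = 2.0  # months
    os_offset_months: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.alpha_range
        if lo <= 0 or hi < lo:
            raise ValueError("alpha_range must be a positive interval")
        if self.alpha_over_beta <= 0:
            raise ValueError("alpha_over_beta must be positive")
        if self.dfs_scale <= 0 or self.dfs_noise_sd < 0:
            raise ValueError("dfs_scale must be positive, dfs_noise_sd >= 0")
        if self.os_offset_months <= 0:
            raise ValueError("os_offset_months must be positive")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")


@dataclass(frozen=True)
class CultureGroundTruth:
    culture_id: str
    alpha: float
    beta: float


@dataclass(frozen=True)
class SimulatedCtCohort:
    table: CtTable
    true_labels: pd.Series  # sample -> "PN" | "Mes"


@dataclass(frozen=True)
class SimulatedCohort:
    cultures: tuple[CultureGroundTruth, ...]
    outcomes: tuple[PatientOutcome, ...]


def simulate_colony_counts(config: CloneSimConfig) -> list[ColonyCountRecord]:
    """Draw one colony count per dose x replicate.

    Per well, colonies ~ Binomial(cells_seeded, PE * S(D)) with
    S(D) = exp(-alpha*D - beta*D^2); the ``poisson`` option uses the
    matching Poisson law (capped at cells seeded), and ``none`` emits the
    exact expected count (possibly fractional) for noiseless round-trips.
    """
    rng = np.random.default_rng(config.rng_seed)
    records = []
    for dose in config.doses:
        p = config.plating_efficiency_true * math.exp(
            -config.alpha_true * dose - config.beta_true * dose**2
        )
        for rep in range(1, config.replicates + 1):
            if config.noise == "binomial":
                colonies = float(rng.binomial(config.cells_seeded, p))
            elif config.noise == "poisson":
                colonies = float(
                    min(rng.poisson(config.cells_seeded * p), config.cells_seeded)
                )
            else:
                colonies = config.cells_seeded * p
            records.append(
                ColonyCountRecord(
                    culture_id=config.culture_id,
                    condition=config.condition,
                    dose_gy=float(dose),
                    cells_seeded=config.cells_seeded,
                    colonies=colonies,
                    replicate=rep,
                )
            )
    return records


def simulate_ct_matrix(
    config: CtSimConfig, signatures: SignatureSet = SignatureSet()
) -> SimulatedCtCohort:
    """Samples x genes Ct matrix with a subtype mean shift.

    Mesenchymal samples have their Mes-signature gene Cts reduced by
    ``effect_size`` (and symmetrically for proneural samples); all
    measured Cts, housekeeping included, carry i.i.d. Gaussian noise.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_samples_per_group
    samples = [f"PN_{i+1:02d}" for i in range(n)] + [f"MES_{i+1:02d}" for i in range(n)]
    labels = pd.Series(["PN"] * n + ["Mes"] * n, index=samples, name="true_label")
    genes = list(signatures.pn_genes) + list(signatures.mes_genes) + list(
        HOUSEKEEPING_GENES
    )
    ct = pd.DataFrame(index=samples, columns=genes, dtype=float)
    for g in genes:
        ct[g] = config.housekeeping_ct if g in HOUSEKEEPING_GENES else config.baseline_ct
    pn_genes = list(signatures.pn_genes)
    mes_genes = list(signatures.mes_genes)
    ct.loc[labels == "PN", pn_genes] -= config.effect_size
    ct.loc[labels == "Mes", mes_genes] -= config.effect_size
    if config.noise_sd > 0:
        ct += rng.normal(0.0, config.noise_sd, size=ct.shape)
    return SimulatedCtCohort(table=CtTable(ct), true_labels=labels)


def simulate_survival_curve_lognormal(
    alpha: float,
    beta: float,
    doses: tuple[float, ...] = DEFAULT_DOSES,
    replicates: int = 4,
    log_sd: float = 0.15,
    rng_seed: int = 0,
    culture_id: str = "SIM",
    condition: str = "GIC",
):
    """A dose--survival curve with multiplicative lognormal replicate noise.

    Replicate SFs are S(D) * exp(eps), eps ~ N(0, log_sd^2), i.e. the
    log-survival observations are exactly Gaussian around the LQ law.
    This is the reference noise model for calibrating curve-comparison
    statistics (which operate on -ln SF and assume Gaussian errors there):
    it isolates the statistic from colony-counting noise and from the
    shared plating-efficiency normalisation, both of which violate the
    Gaussian-error model.  The dose-0 point is pinned at SF = 1.
    """
    from .clonogenic import DoseSurvivalCurve, SurvivalPoint

    if alpha < 0 or beta < 0 or log_sd < 0 or replicates < 2:
        raise ValueError("need alpha, beta, log_sd >= 0 and replicates >= 2")
    rng = np.random.default_rng(rng_seed)
    points = [SurvivalPoint(0.0, 1.0, 0.0, replicates, (1.0,) * replicates)]
    for d in sorted(d for d in doses if d > 0):
        s = math.exp(-alpha * d - beta * d**2)
        sfs = tuple(s * math.exp(e) for e in rng.normal(0.0, log_sd, replicates))
        n = replicates
        sem = float(np.std(sfs, ddof=1) / math.sqrt(n))
        points.append(SurvivalPoint(float(d), float(np.mean(sfs)), sem, n, sfs))
    return DoseSurvivalCurve(culture_id, condition, tuple(points))


def simulate_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Per-culture true (alpha, beta) plus the matched patient outcomes.

    DFS_i = dfs_scale * alpha_i + N(0, dfs_noise_sd), redrawn while
    non-positive; OS_i = DFS_i + os_offset_months.
    """
    rng = np.random.default_rng(config.rng_seed)
    lo, hi = config.alpha_range
    alphas = rng.uniform(lo, hi, size=config.n_patients)
    cultures, outcomes = [], []
    for i, alpha in enumerate(alphas, start=1):
        cid = f"GBT{i:02d}"
        beta = alpha / config.alpha_over_beta
        dfs = config.dfs_scale * alpha
        if config.dfs_noise_sd > 0:
            dfs += rng.normal(0.0, config.dfs_noise_sd)
            while dfs <= 0:
                dfs = config.dfs_scale * alpha + rng.normal(0.0, config.dfs_noise_sd)
        cultures.append(CultureGroundTruth(cid, float(alpha), float(beta)))
        outcomes.append(
            PatientOutcome(cid, float(dfs), float(dfs + config.os_offset_months))
        )
    return SimulatedCohort(tuple(cultures), tuple(outcomes))
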
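"""End-to-end orchestration: counts -> survival curves -> LQ fits ->
subtype calls -> outcome associations, with input validation and a single
consolidated JSON-able report.

Each stage consumes only the declared types of the stage before it; partial
inputs yield partial reports with explicit skip records, and identical
config + seed reproduce an identical report body (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .clonogenic import ColonyCountRecord, DoseSurvivalCurve, build_survival_curve
from .lqm import (
    LQMFit,
    compare_curves,
    fit_lqm,
    radiosensitivity_metrics,
    radioresistance_ratio,
)
from .stats import PatientOutcome, correlate_radiosensitivity_outcomes
from .subtype import HOUSEKEEPING_GENES, CtTable, classify_cohort, results_frame
from .synthetic import (
    CloneSimConfig,
    CohortSimConfig,
    CtSimConfig,
    simulate_cohort,
    simulate_colony_counts,
    simulate_ct_matrix,
)

__all__ = ["RunConfig", "AnalysisReport", "ValidationIssue", "run_full_analysis", "validate_inputs"]

logger = logging.getLogger("gicsurv")


@dataclass
class RunConfig:
    """What to analyse and how.

    Either file inputs (``counts_path`` etc.) or simulation configs must be
    present.  Under ``cohort_sim``, per-culture clonogenic data are
    simulated with the cohort's true (alpha, beta) and the assay settings
    in ``clone_template`` (any :class:`CloneSimConfig` field).
    """

    counts_path: str | None = None
    ct_path: str | None = None
    outcomes_path: str | None = None
    cohort_sim: CohortSimConfig | None = None
    clone_sim: CloneSimConfig | None = None
    clone_template: dict = field(default_factory=dict)
    ct_sim: CtSimConfig | None = None
    weighting: str = "replicate"  # replicate | inverse_variance | none
    auc_method: str = "both"  # trapezoid | closed_form | both
    rng_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_files = any([self.counts_path, self.ct_path, self.outcomes_path])
        has_sims = any([self.cohort_sim, self.clone_sim, self.ct_sim])
        if not has_files and not has_sims:
            raise ValueError("config names neither input files nor simulations")
        if self.weighting not in ("replicate", "inverse_variance", "none"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.auc_method not in ("trapezoid", "closed_form", "both"):
            raise ValueError(f"unknown auc_method {self.auc_method!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort_sim" in d and isinstance(d["cohort_sim"], dict):
            cs = dict(d["cohort_sim"])
            if "alpha_range" in cs:
                cs["alpha_range"] = tuple(cs["alpha_range"])
            d["cohort_sim"] = CohortSimConfig(**cs)
        if "clone_sim" in d and isinstance(d["clone_sim"], dict):
            cl = dict(d["clone_sim"])
            if "doses" in cl:
                cl["doses"] = tuple(cl["doses"])
            d["clone_sim"] = CloneSimConfig(**cl)
        if "ct_sim" in d and isinstance(d["ct_sim"], dict):
            d["ct_sim"] = CtSimConfig(**d["ct_sim"])
        return cls(**d)


@dataclass(frozen=True)
class ValidationIssue:
    file: str
    line: int | None
    column: str | None
    severity: str  # "error" | "warning"
    message: str


@dataclass
class AnalysisReport:
    curves: dict
    fits: dict
    metrics: dict
    ratios: dict
    comparisons: dict
    subtype: dict | None
    associations: list | None
    ground_truth: dict | None
    skipped: list
    provenance: dict

    def to_dict(self, include_timestamp: bool = True) -> dict:
        d = {
            "curves": self.curves,
            "fits": self.fits,
            "metrics": self.metrics,
            "ratios": self.ratios,
            "comparisons": self.comparisons,
            "subtype": self.subtype,
            "associations": self.associations,
            "ground_truth": self.ground_truth,
            "skipped": self.skipped,
            "provenance": dict(self.provenance),
        }
        if not include_timestamp:
            d["provenance"].pop("timestamp", None)
        return d

    def write(self, path) -> None:
        gio.write_json(self.to_dict(), path)


def _child_seed(seed: int, i: int) -> int:
    return int((seed * 1_000_003 + i) % 2**31)


def _fit_dict(fit: LQMFit) -> dict:
    return {
        "alpha": fit.alpha,
        "beta": fit.beta,
        "covariance": np.asarray(fit.covariance).tolist(),
        "r_squared": fit.r_squared,
        "n_points_used": fit.n_points_used,
        "mode": fit.mode,
    }


def _gather_records(config: RunConfig):
    """Stage 0: obtain colony counts, the Ct table and outcomes."""
    records: list[ColonyCountRecord] = []
    outcomes: list[PatientOutcome] | None = None
    ground_truth: dict | None = None

    if config.counts_path:
        records = gio.read_colony_counts_tsv(config.counts_path)
        logger.info("read %d colony count rows from %s", len(records), config.counts_path)
    elif config.cohort_sim is not None:
        cohort = simulate_cohort(config.cohort_sim)
        outcomes = list(cohort.outcomes)
        ground_truth = {
            c.culture_id: {"alpha": c.alpha, "beta": c.beta} for c in cohort.cultures
        }
        for i, culture in enumerate(cohort.cultures):
            clone_cfg = CloneSimConfig(
                alpha_true=culture.alpha,
                beta_true=culture.beta,
                culture_id=culture.culture_id,
                rng_seed=_child_seed(config.cohort_sim.rng_seed, i + 1),
                **config.clone_template,
            )
            records.extend(simulate_colony_counts(clone_cfg))
        logger.info(
            "simulated %d colony count rows for %d cultures",
            len(records),
            len(cohort.cultures),
        )
    elif config.clone_sim is not None:
        records = simulate_colony_counts(config.clone_sim)
        ground_truth = {
            config.clone_sim.culture_id: {
                "alpha": config.clone_sim.alpha_true,
                "beta": config.clone_sim.beta_true,
            }
        }

    if config.outcomes_path:
        outcomes = gio.read_outcomes_tsv(config.outcomes_path)
        logger.info("read %d patient outcomes", len(outcomes))

    ct_table = None
    true_labels = None
    if config.ct_path:
        ct_table = gio.read_ct_tsv(config.ct_path)
    elif config.ct_sim is not None:
        sim = simulate_ct_matrix(config.ct_sim)
        ct_table, true_labels = sim.table, sim.true_labels
    return records, ct_table, true_labels, outcomes, ground_truth


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Execute every stage the config provides inputs for."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    records, ct_table, true_labels, outcomes, ground_truth = _gather_records(config)
    skipped: list[dict] = []

    curves: dict[tuple[str, str], DoseSurvivalCurve] = {}
    fits: dict[tuple[str, str], LQMFit] = {}
    curves_out, fits_out, metrics_out = {}, {}, {}

    if records:
        groups: dict[tuple[str, str], list[ColonyCountRecord]] = {}
        for r in records:
            groups.setdefault((r.culture_id, r.condition), []).append(r)
        for key in sorted(groups):
            curve = build_survival_curve(groups[key])
            fit = fit_lqm(curve, weighting=config.weighting)
            met = radiosensitivity_metrics(curve, fit)
            curves[key], fits[key] = curve, fit
            name = f"{key[0]}/{key[1]}"
            curves_out[name] = gio.curve_to_dict(curve)
            fits_out[name] = _fit_dict(fit)
            md = dataclasses.asdict(met)
            if config.auc_method == "trapezoid":
                md.pop("auc_closed_form")
            elif config.auc_method == "closed_form":
                md.pop("auc_trapezoid")
            metrics_out[name] = md
        logger.info("fitted %d survival curves", len(curves))
    else:
        skipped.append({"stage": "clonogenic", "reason": "no colony counts provided"})

    # paired DGC/GIC comparisons within each culture
    ratios_out, comparisons_out = {}, {}
    by_culture: dict[str, dict[str, tuple]] = {}
    for (cid, cond), fit in fits.items():
        by_culture.setdefault(cid, {})[cond] = (curves[(cid, cond)], fit)
    for cid, conds in sorted(by_culture.items()):
        if "DGC" in conds and "GIC" in conds:
            curve_d, fit_d = conds["DGC"]
            curve_g, fit_g = conds["GIC"]
            try:
                rr = radioresistance_ratio(fit_d, fit_g)
                ratios_out[cid] = dataclasses.asdict(rr)
            except ZeroDivisionError as exc:
                skipped.append({"stage": "ratios", "culture": cid, "reason": str(exc)})
            cmp_ = compare_curves(curve_d, curve_g)
            comparisons_out[cid] = dataclasses.asdict(cmp_)

    subtype_out = None
    if ct_table is not None:
        results = classify_cohort(ct_table)
        frame = results_frame(results)
        subtype_out = {
            "per_sample": frame.to_dict(orient="records"),
            "n_samples": len(results),
            "call_counts": frame["call"].value_counts().to_dict(),
            "reference_population": list(ct_table.samples),
        }
        if true_labels is not None:
            correct = sum(
                1
                for r in results
                if r.call == true_labels.get(r.sample, None)
            )
            subtype_out["true_label_accuracy"] = correct / len(results)
        logger.info("classified %d samples", len(results))
    else:
        skipped.append({"stage": "subtype", "reason": "no Ct table provided"})

    associations_out = None
    if outcomes and fits:
        # associations use the stem-like (GIC) compartment when present,
        # otherwise whichever single condition a culture has
        fit_by_culture: dict[str, LQMFit] = {}
        for cid, conds in by_culture.items():
            if "GIC" in conds:
                fit_by_culture[cid] = conds["GIC"][1]
            elif len(conds) == 1:
                fit_by_culture[cid] = next(iter(conds.values()))[1]
        table = correlate_radiosensitivity_outcomes(fit_by_culture, outcomes)
        associations_out = table.to_dict(orient="records")
        logger.info("computed %d associations", len(table))
    else:
        skipped.append(
            {"stage": "association", "reason": "needs both LQ fits and outcomes"}
        )

    provenance = {
        "config": _config_echo(config),
        "rng_seed": config.rng_seed,
        "software": "gicsurv",
        "version": _version(),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return AnalysisReport(
        curves=curves_out,
        fits=fits_out,
        metrics=metrics_out,
        ratios=ratios_out,
        comparisons=comparisons_out,
        subtype=subtype_out,
        associations=associations_out,
        ground_truth=ground_truth,
        skipped=skipped,
        provenance=provenance,
    )


def _version() -> str:
    from . import __version__

    return __version__


def _config_echo(config: RunConfig) -> dict:
    d = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        d[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
    return d


def validate_inputs(
    counts_path=None, ct_path=None, outcomes_path=None
) -> list[ValidationIssue]:
    """Machine-readable schema and invariant checks on input files.

    Line numbers are 1-based file lines (the header is line 1).
    """
    issues: list[ValidationIssue] = []

    if counts_path is not None:
        name = str(counts_path)
        try:
            df = pd.read_csv(counts_path, sep="\t")
        except Exception as exc:  # unreadable file
            return issues + [ValidationIssue(name, None, None, "error", str(exc))]
        for col in gio.COUNTS_COLUMNS:
            if col not in df.columns:
                issues.append(
                    ValidationIssue(name, 1, col, "error", f"missing column {col!r}")
                )
        if not issues:
            for idx, row in df.iterrows():
                line = int(idx) + 2
                if row["colonies"] > row["cells_seeded"]:
                    issues.append(
                        ValidationIssue(
                            name, line, "colonies", "error",
                            f"colonies ({row['colonies']}) exceed cells seeded "
                            f"({row['cells_seeded']})",
                        )
                    )
                if row["dose_gy"] < 0:
                    issues.append(
                        ValidationIssue(name, line, "dose_gy", "error", "negative dose")
                    )
            for (cid, cond), grp in df.groupby(["culture_id", "condition"]):
                if not (grp["dose_gy"] == 0).any():
                    issues.append(
                        ValidationIssue(
                            name, None, "dose_gy", "error",
                            f"{cid}/{cond}: no dose-0 (untreated) rows",
                        )
                    )

    if ct_path is not None:
        name = str(ct_path)
        try:
            df = pd.read_csv(ct_path, sep="\t")
        except Exception as exc:
            return issues + [ValidationIssue(name, None, None, "error", str(exc))]
        long_format = {"sample_id", "gene", "ct"}.issubset(df.columns)
        genes = set(df["gene"]) if long_format else set(df.columns) - {"sample_id"}
        present_hk = [g for g in HOUSEKEEPING_GENES if g in genes]
        if not present_hk:
            issues.append(
                ValidationIssue(
                    name, None, None, "error",
                    f"no housekeeping gene present (need one of {HOUSEKEEPING_GENES})",
                )
            )
        elif len(present_hk) < len(HOUSEKEEPING_GENES):
            missing = sorted(set(HOUSEKEEPING_GENES) - set(present_hk))
            issues.append(
                ValidationIssue(
                    name, None, None, "warning",
                    f"housekeeping gene(s) {missing} absent; "
                    "single-reference normalisation will be used",
                )
            )

    if outcomes_path is not None:
        name = str(outcomes_path)
        try:
            df = pd.read_csv(outcomes_path, sep="\t")
        except Exception as exc:
            return issues + [ValidationIssue(name, None, None, "error", str(exc))]
        for col in ("patient_id", "dfs_months"):
            if col not in df.columns:
                issues.append(
                    ValidationIssue(name, 1, col, "error", f"missing column {col!r}")
                )
        if "dfs_months" in df.columns:
            for idx, v in df["dfs_months"].items():
                if not v > 0:
                    issues.append(
                        ValidationIssue(
                            name, int(idx) + 2, "dfs_months", "error",
                            f"non-positive DFS ({v})",
                        )
                    )
    return issues
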
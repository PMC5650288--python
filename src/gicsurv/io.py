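"""Readers and writers for the pipeline's TSV and JSON formats."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clonogenic import ColonyCountRecord, DoseSurvivalCurve, SurvivalPoint
from .stats import PatientOutcome
from .subtype import CtTable

COUNTS_COLUMNS = ["culture_id", "condition", "dose_gy", "cells_seeded", "colonies", "replicate"]
OUTCOME_COLUMNS = ["patient_id", "dfs_months", "os_months"]


def read_colony_counts_tsv(path) -> list[ColonyCountRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        ColonyCountRecord(
            culture_id=str(r.culture_id),
            condition=str(r.condition),
            dose_gy=float(r.dose_gy),
            cells_seeded=int(r.cells_seeded),
            colonies=float(r.colonies),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]


def write_colony_counts_tsv(records: list[ColonyCountRecord], path) -> None:
    pd.DataFrame(
        [
            (r.culture_id, r.condition, r.dose_gy, r.cells_seeded, r.colonies, r.replicate)
            for r in records
        ],
        columns=COUNTS_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_ct_tsv(path) -> CtTable:
    """Read a Ct table: long format (sample_id, gene, ct[, replicate],
    replicates averaged) or wide format (sample_id index, genes as columns)."""
    df = pd.read_csv(path, sep="\t")
    if {"sample_id", "gene", "ct"}.issubset(df.columns):
        wide = df.pivot_table(index="sample_id", columns="gene", values="ct", aggfunc="mean")
        wide.index.name = None
        wide.columns.name = None
        return CtTable(wide)
    if "sample_id" in df.columns:
        wide = df.set_index("sample_id")
        wide.index.name = None
        return CtTable(wide.astype(float))
    raise ValueError(
        f"{path}: expected long columns (sample_id, gene, ct) or a wide "
        "matrix with a sample_id column"
    )


def write_ct_tsv(table: CtTable, path) -> None:
    out = table.ct.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_outcomes_tsv(path) -> list[PatientOutcome]:
    df = pd.read_csv(path, sep="\t")
    if "patient_id" not in df.columns or "dfs_months" not in df.columns:
        raise ValueError(f"{path}: needs columns patient_id, dfs_months[, os_months]")
    has_os = "os_months" in df.columns
    return [
        PatientOutcome(
            patient_id=str(r.patient_id),
            dfs_months=float(r.dfs_months),
            os_months=float(r.os_months) if has_os and pd.notna(r.os_months) else None,
        )
        for r in df.itertuples()
    ]


def write_outcomes_tsv(outcomes: list[PatientOutcome], path) -> None:
    pd.DataFrame(
        [(o.patient_id, o.dfs_months, o.os_months) for o in outcomes],
        columns=OUTCOME_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def curve_to_dict(curve: DoseSurvivalCurve) -> dict:
    return {
        "culture_id": curve.culture_id,
        "condition": curve.condition,
        "points": [
            {
                "dose_gy": p.dose_gy,
                "sf_mean": p.sf_mean,
                "sf_sem": p.sf_sem,
                "n": p.n,
                "sf_replicates": list(p.sf_replicates),
            }
            for p in curve.points
        ],
    }


def curve_from_dict(d: dict) -> DoseSurvivalCurve:
    return DoseSurvivalCurve(
        culture_id=d["culture_id"],
        condition=d["condition"],
        points=tuple(
            SurvivalPoint(
                dose_gy=p["dose_gy"],
                sf_mean=p["sf_mean"],
                sf_sem=p["sf_sem"],
                n=p["n"],
                sf_replicates=tuple(p["sf_replicates"]),
            )
            for p in d["points"]
        ),
    )


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        if isinstance(o, pd.Series):
            return o.to_dict()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, cls=_ReportEncoder, indent=2, sort_keys=True))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
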
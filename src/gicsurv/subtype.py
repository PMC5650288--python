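"""Proneural / mesenchymal subtype scoring from qPCR Ct data.

The scoring scheme: per-gene Ct values are normalised to the mean of the
housekeeping genes (GAPDH, GUSB) to give dCt; -dCt serves as a log2
expression index; each gene is z-scored across the samples of the table;
and a sample's metagene score for a signature is the mean z over that
signature's genes.  The call is mesenchymal when the Mes score exceeds the
PN score, proneural when the reverse holds, and undetermined on a tie or
when too few signature genes were measured.

Z-scoring on the log scale (-dCt) rather than linear 2^-dCt is the default:
linear-scale z-scores are dominated by the highest expressors.  The two
indices are monotone transforms of one another, so either is accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HOUSEKEEPING_GENES",
    "CtTable",
    "SignatureSet",
    "MetageneResult",
    "delta_ct",
    "delta_ct_table",
    "relative_expression",
    "zscore_genewise",
    "metagene_scores",
    "classify_cohort",
]

HOUSEKEEPING_GENES = ("GAPDH", "GUSB")
_CT_RANGE = (5.0, 40.0)


@dataclass(frozen=True)
class SignatureSet:
    """Four proneural and four mesenchymal marker genes."""

    pn_genes: tuple[str, ...] = ("SOX9", "OLIG2", "SOX2", "PROM1")
    mes_genes: tuple[str, ...] = ("FN1", "CHI3L1", "CD44", "CTGF")

    def __post_init__(self) -> None:
        if not self.pn_genes or not self.mes_genes:
            raise ValueError("signature gene sets must be non-empty")
        if set(self.pn_genes) & set(self.mes_genes):
            raise ValueError("PN and Mes signatures must be disjoint")

    def swapped(self) -> "SignatureSet":
        return SignatureSet(pn_genes=self.mes_genes, mes_genes=self.pn_genes)


@dataclass(frozen=True)
class CtTable:
    """Samples x genes matrix of (mean) Ct values; NaN marks missing."""

    ct: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.ct.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < _CT_RANGE[0] or finite.max() > _CT_RANGE[1]):
            warnings.warn(
                f"Ct values outside the plausible {_CT_RANGE} cycle range",
                stacklevel=2,
            )
        present = [g for g in HOUSEKEEPING_GENES if g in self.ct.columns]
        if not present:
            raise ValueError(
                f"Ct table must contain a housekeeping gene ({HOUSEKEEPING_GENES})"
            )
        if len(present) < len(HOUSEKEEPING_GENES):
            warnings.warn(
                f"only {present} of {HOUSEKEEPING_GENES} present; "
                "single-reference normalisation",
                stacklevel=2,
            )

    @property
    def samples(self) -> list[str]:
        return list(self.ct.index)

    @property
    def genes(self) -> list[str]:
        return list(self.ct.columns)


@dataclass(frozen=True)
class MetageneResult:
    sample: str
    mgs_pn: float  # NaN when undetermined
    mgs_mes: float
    n_genes_pn: int
    n_genes_mes: int
    call: str  # "PN" | "Mes" | "undetermined"


def delta_ct(ct_target: float, ct_housekeeping) -> float:
    """dCt = target Ct minus the arithmetic mean of housekeeping Cts."""
    hk = np.asarray(ct_housekeeping, dtype=float)
    hk = hk[np.isfinite(hk)]
    if hk.size == 0:
        raise ValueError("at least one housekeeping Ct is required")
    return float(ct_target - hk.mean())


def delta_ct_table(
    table: CtTable, housekeeping: tuple[str, ...] = HOUSEKEEPING_GENES
) -> pd.DataFrame:
    """Per-sample dCt for every non-housekeeping gene.

    Samples whose housekeeping Cts are all missing become all-missing rows
    (with a warning) rather than being dropped.
    """
    hk_cols = [g for g in housekeeping if g in table.ct.columns]
    hk_mean = table.ct[hk_cols].mean(axis=1, skipna=True)
    dead = hk_mean.index[hk_mean.isna()]
    if len(dead):
        warnings.warn(
            f"samples with no housekeeping Ct set to missing: {list(dead)}",
            stacklevel=2,
        )
    targets = [g for g in table.ct.columns if g not in hk_cols]
    return table.ct[targets].sub(hk_mean, axis=0)


def relative_expression(dct):
    """Relative expression 2^-dCt (scalar, array or frame)."""
    return 2.0 ** (-dct)


def zscore_genewise(expr: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene column across samples (n-1 denominator).

    Missing values propagate; genes observed in fewer than two samples or
    with zero variance are set all-missing with a warning.
    """
    if expr.shape[0] < 2:
        raise ValueError("z-scores need at least two samples")
    mean = expr.mean(axis=0, skipna=True)
    sd = expr.std(axis=0, ddof=1, skipna=True)
    n_obs = expr.notna().sum(axis=0)
    bad = list(expr.columns[(sd == 0) | (n_obs < 2)])
    z = expr.sub(mean, axis=1).div(sd, axis=1)
    if bad:
        warnings.warn(
            f"genes with zero variance or < 2 observations set to missing: {bad}",
            stacklevel=2,
        )
        z[bad] = np.nan
    return z


def metagene_scores(
    z: pd.DataFrame,
    signatures: SignatureSet = SignatureSet(),
    min_genes: int = 3,
) -> list[MetageneResult]:
    """Mean z over each signature; subtype call by the sign of Mes - PN.

    A score with fewer than ``min_genes`` non-missing signature genes is
    undetermined, and so is the call when either score is undetermined or
    the two are exactly tied.
    """
    pn = [g for g in signatures.pn_genes if g in z.columns]
    mes = [g for g in signatures.mes_genes if g in z.columns]
    if not pn and not mes:
        raise ValueError("no signature gene present in the table")
    results = []
    for sample, row in z.iterrows():
        pn_vals = row[pn].dropna()
        mes_vals = row[mes].dropna()
        mgs_pn = float(pn_vals.mean()) if len(pn_vals) >= min_genes else float("nan")
        mgs_mes = float(mes_vals.mean()) if len(mes_vals) >= min_genes else float("nan")
        if np.isnan(mgs_pn) or np.isnan(mgs_mes) or mgs_mes == mgs_pn:
            call = "undetermined"
        else:
            call = "Mes" if mgs_mes > mgs_pn else "PN"
        results.append(
            MetageneResult(
                sample=str(sample),
                mgs_pn=mgs_pn,
                mgs_mes=mgs_mes,
                n_genes_pn=len(pn_vals),
                n_genes_mes=len(mes_vals),
                call=call,
            )
        )
    return results


def classify_cohort(
    table: CtTable,
    signatures: SignatureSet = SignatureSet(),
    min_genes: int = 3,
    expression_index: str = "neg_delta_ct",
) -> list[MetageneResult]:
    """Full scoring pipeline: dCt -> expression index -> gene-wise z-scores
    -> metagene scores and calls.

    ``expression_index`` is ``neg_delta_ct`` (log2 scale, default) or
    ``linear`` (2^-dCt); the z-score reference population is all samples of
    the submitted table.
    """
    dct = delta_ct_table(table)
    if expression_index == "neg_delta_ct":
        expr = -dct
    elif expression_index == "linear":
        expr = 2.0 ** (-dct)
    else:
        raise ValueError(f"unknown expression_index {expression_index!r}")
    z = zscore_genewise(expr)
    return metagene_scores(z, signatures, min_genes)


def results_frame(results: list[MetageneResult]) -> pd.DataFrame:
    """Tabular view of metagene results (one row per sample)."""
    return pd.DataFrame(
        [
            {
                "sample": r.sample,
                "mgs_pn": r.mgs_pn,
                "mgs_mes": r.mgs_mes,
                "n_genes_pn": r.n_genes_pn,
                "n_genes_mes": r.n_genes_mes,
                "call": r.call,
            }
            for r in results
        ]
    )
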
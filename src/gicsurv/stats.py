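"""Exact small-sample rank statistics and the radiosensitivity--outcome
association.

Cohorts of paired patient-derived cultures are tiny (four to six pairs),
where asymptotic p-values are unreliable, so Spearman correlation and the
Mann-Whitney test take an exact enumeration path whenever the sample is
small enough and tie-free: the full permutation (or group-assignment)
distribution of the statistic is computed and the two-sided p-value is the
fraction of arrangements at least as extreme as the observed one.  Ties
break the distribution-free character of those null distributions, so tied
data fall back to the usual tie-corrected approximations with a warning.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lqm import LQMFit

__all__ = [
    "AssociationResult",
    "GroupTestResult",
    "PatientOutcome",
    "spearman_exact",
    "mann_whitney_exact",
    "welch_t",
    "correlate_radiosensitivity_outcomes",
]

SPEARMAN_EXACT_MAX_N = 9  # 9! = 362 880 permutations, still sub-second
MANN_WHITNEY_EXACT_MAX_N = 12  # C(12, 6) = 924 assignments

_TINY_P = float(np.nextafter(0, 1))


@dataclass(frozen=True)
class AssociationResult:
    rho: float
    p_two_sided: float
    n: int
    method: str  # "exact_permutation" | "asymptotic_t"


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_two_sided: float
    n_a: int
    n_b: int
    method: str


@dataclass(frozen=True)
class PatientOutcome:
    patient_id: str
    dfs_months: float
    os_months: float | None = None

    def __post_init__(self) -> None:
        if self.dfs_months <= 0:
            raise ValueError("DFS must be positive")
        if self.os_months is not None and self.os_months <= 0:
            raise ValueError("OS must be positive")


def _has_ties(v: np.ndarray) -> bool:
    return len(np.unique(v)) < len(v)


def spearman_exact(x, y, exact_threshold: int = SPEARMAN_EXACT_MAX_N) -> AssociationResult:
    """Two-sided Spearman rank correlation with exact enumeration.

    rho is the Pearson correlation of average ranks.  For tie-free data
    with n <= ``exact_threshold`` the p-value enumerates all n! rank
    permutations: p = #{perm : |rho*| >= |rho|} / n!.  Larger or tied
    samples use the t approximation rho*sqrt((n-2)/(1-rho^2)) ~ t_{n-2}.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        raise ValueError("rho undefined for a constant vector")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    tied = _has_ties(x) or _has_ties(y)
    if not tied and n <= exact_threshold:
        # untied ranks: rho is linear in S = sum(rx * ry_perm), so the
        # permutation distribution of S gives the distribution of rho
        perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
        s = perms @ rx
        rho_perm = (12.0 * s - 3.0 * n * (n + 1) ** 2) / (n * (n**2 - 1))
        count = int(np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12))
        return AssociationResult(rho, count / len(perms), n, "exact_permutation")

    if tied:
        warnings.warn(
            "ties present: exact enumeration disabled, using the t "
            "approximation with tie-corrected rho",
            stacklevel=2,
        )
    if abs(rho) >= 1.0:
        p = _TINY_P
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return AssociationResult(rho, min(max(p, _TINY_P), 1.0), n, "asymptotic_t")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a, with half credit for ties."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_exact(
    a, b, exact_threshold: int = MANN_WHITNEY_EXACT_MAX_N
) -> GroupTestResult:
    """Two-sided Mann-Whitney U test with exact enumeration.

    Tie-free data with n_a + n_b <= ``exact_threshold`` enumerate every
    C(n_a+n_b, n_a) assignment of the pooled values to the two groups:
    p = #{assignments : |U* - mu| >= |U - mu|} / C(n, n_a), mu = n_a*n_b/2.
    Otherwise a normal approximation with tie correction and continuity
    correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(a, b)
    mu = n_a * n_b / 2.0
    pooled = np.concatenate([a, b])
    tied = _has_ties(pooled)

    if not tied and n_a + n_b <= exact_threshold:
        n = n_a + n_b
        count = total = 0
        idx = np.arange(n)
        for comb in itertools.combinations(idx, n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(comb)] = True
            u_star = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_star - mu) >= abs(u - mu) - 1e-9:
                count += 1
        return GroupTestResult(u, count / total, n_a, n_b, "mann_whitney_exact")

    if tied:
        warnings.warn(
            "ties present: exact enumeration disabled, using the normal "
            "approximation with tie correction",
            stacklevel=2,
        )
    n = n_a + n_b
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(t_counts**3 - t_counts)) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all values identical
        return GroupTestResult(u, 1.0, n_a, n_b, "mann_whitney_normal")
    diff = u - mu
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(sigma2)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return GroupTestResult(u, min(max(p, _TINY_P), 1.0), n_a, n_b, "mann_whitney_normal")


def welch_t(a, b) -> GroupTestResult:
    """Unpaired two-sided t-test with Welch's unequal-variance statistic
    and Satterthwaite degrees of freedom.

    When a two-observation group has zero variance the Welch degrees of
    freedom collapse, so the test falls back to the pooled (Student)
    statistic with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()

    if va + vb == 0:
        # degenerate: no within-group variability at all
        p = 1.0 if diff == 0 else _TINY_P
        return GroupTestResult(0.0 if diff == 0 else math.inf * np.sign(diff),
                               p, n_a, n_b, "welch_t")

    if (va == 0 and n_a == 2) or (vb == 0 and n_b == 2):
        warnings.warn(
            "a two-observation group has zero variance; falling back to the "
            "pooled t-test",
            stacklevel=2,
        )
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
        t = diff / math.sqrt(sp2 * (1 / n_a + 1 / n_b))
        dof = n_a + n_b - 2
        p = 2.0 * float(sps.t.sf(abs(t), dof))
        return GroupTestResult(t, min(max(p, _TINY_P), 1.0), n_a, n_b, "welch_t")

    se2 = va / n_a + vb / n_b
    t = diff / math.sqrt(se2)
    dof = se2**2 / ((va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1))
    p = 2.0 * float(sps.t.sf(abs(t), dof))
    return GroupTestResult(t, min(max(p, _TINY_P), 1.0), n_a, n_b, "welch_t")


def correlate_radiosensitivity_outcomes(
    fits: Mapping[str, LQMFit],
    outcomes: list[PatientOutcome],
) -> pd.DataFrame:
    """Spearman association of each LQ parameter with each outcome.

    Cultures and patients are matched by identifier; unmatched entries are
    dropped with a warning.  Returns one row per (metric in {alpha, beta})
    x (outcome in {DFS, OS}) with rho, two-sided p, n and the method used.
    """
    by_patient = {o.patient_id: o for o in outcomes}
    matched = sorted(set(fits) & set(by_patient))
    unmatched = (set(fits) | set(by_patient)) - set(matched)
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} unmatched culture/patient id(s) dropped: "
            f"{sorted(unmatched)}",
            stacklevel=2,
        )
    if len(matched) < 3:
        raise ValueError(f"need >= 3 matched culture-outcome pairs, got {len(matched)}")

    metrics = {
        "alpha": np.array([fits[c].alpha for c in matched]),
        "beta": np.array([fits[c].beta for c in matched]),
    }
    outcome_vectors = {"DFS": np.array([by_patient[c].dfs_months for c in matched])}
    os_vals = [by_patient[c].os_months for c in matched]
    if all(v is not None for v in os_vals):
        outcome_vectors["OS"] = np.array(os_vals, dtype=float)

    rows = []
    for mname, mvec in metrics.items():
        for oname, ovec in outcome_vectors.items():
            try:
                res = spearman_exact(mvec, ovec)
            except ValueError as exc:
                warnings.warn(
                    f"{mname} vs {oname} skipped: {exc}", stacklevel=2
                )
                continue
            rows.append(
                {
                    "metric": mname,
                    "outcome": oname,
                    "rho": res.rho,
                    "p_two_sided": res.p_two_sided,
                    "n": res.n,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)
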
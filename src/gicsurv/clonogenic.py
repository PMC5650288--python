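"""Clonogenic / neurosphere assay processing.

Turns raw colony counts into plating efficiencies and dose--survival
curves.  A *colony count record* is one well: a known number of cells was
seeded, the well was irradiated (or not) and the colonies (adherent
cultures) or neurospheres (stem-like cultures) that grew out were scored.
The untreated wells give the plating efficiency (PE); each treated well's
colony yield, divided by seeded cells and then by the PE of the same
culture and condition, is its surviving fraction (SF).

Scoring thresholds (e.g. a minimum colony size) are wet-lab rules applied
before data reach this module; records hold already-scored counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColonyCountRecord",
    "PlatingEfficiency",
    "SurvivalPoint",
    "DoseSurvivalCurve",
    "ZeroPlatingEfficiencyError",
    "plating_efficiency",
    "surviving_fraction",
    "build_survival_curve",
]


class ZeroPlatingEfficiencyError(ValueError):
    """No untreated well produced a single colony: survival is undefined."""


@dataclass(frozen=True)
class ColonyCountRecord:
    """One scored well.

    ``colonies`` is a float so that deterministic (expected-count)
    simulations can carry fractional yields; sampled and real data are
    whole numbers.
    """

    culture_id: str
    condition: str  # "DGC" or "GIC", optionally tagged with an RT cycle, e.g. "GIC-R"
    dose_gy: float
    cells_seeded: int
    colonies: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ValueError(f"dose_gy must be >= 0, got {self.dose_gy}")
        if self.cells_seeded <= 0:
            raise ValueError(f"cells_seeded must be positive, got {self.cells_seeded}")
        if self.colonies < 0:
            raise ValueError(f"colonies must be >= 0, got {self.colonies}")
        if self.colonies > self.cells_seeded:
            raise ValueError(
                f"colonies ({self.colonies}) cannot exceed cells seeded "
                f"({self.cells_seeded}) in {self.culture_id}/{self.condition}"
            )
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")


@dataclass(frozen=True)
class PlatingEfficiency:
    culture_id: str
    condition: str
    pe: float
    n_replicates: int
    sem: float

    def __post_init__(self) -> None:
        if not 0 < self.pe <= 1:
            raise ValueError(f"plating efficiency must lie in (0, 1], got {self.pe}")


@dataclass(frozen=True)
class SurvivalPoint:
    dose_gy: float
    sf_mean: float
    sf_sem: float
    n: int
    sf_replicates: tuple[float, ...]


@dataclass(frozen=True)
class DoseSurvivalCurve:
    culture_id: str
    condition: str
    points: tuple[SurvivalPoint, ...]
    pe: PlatingEfficiency | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        doses = [p.dose_gy for p in self.points]
        if doses != sorted(doses) or len(set(doses)) != len(doses):
            raise ValueError("survival points must have strictly increasing doses")
        if not doses or doses[0] != 0:
            raise ValueError("survival curve must contain dose 0")

    @property
    def doses(self) -> np.ndarray:
        return np.array([p.dose_gy for p in self.points])

    @property
    def sf_means(self) -> np.ndarray:
        return np.array([p.sf_mean for p in self.points])

    def point_at(self, dose: float) -> SurvivalPoint | None:
        for p in self.points:
            if math.isclose(p.dose_gy, dose):
                return p
        return None


def _check_homogeneous(records: list[ColonyCountRecord]) -> tuple[str, str]:
    keys = {(r.culture_id, r.condition) for r in records}
    if len(keys) != 1:
        raise ValueError(f"records mix cultures/conditions: {sorted(keys)}")
    return keys.pop()


def plating_efficiency(records: list[ColonyCountRecord]) -> PlatingEfficiency:
    """Mean per-replicate growth ratio of untreated wells.

    PE is the arithmetic mean over replicates of colonies/cells_seeded
    (the per-replicate-ratio convention, not pooled counts over pooled
    seeding), with SEM = sd/sqrt(n) (0 for a single replicate).
    """
    if not records:
        raise ValueError("no dose-0 records supplied")
    culture_id, condition = _check_homogeneous(records)
    if any(r.dose_gy != 0 for r in records):
        raise ValueError("plating efficiency requires dose-0 records only")
    ratios = np.array([r.colonies / r.cells_seeded for r in records])
    pe = float(ratios.mean())
    if pe == 0:
        raise ZeroPlatingEfficiencyError(
            f"zero plating efficiency for {culture_id}/{condition}: "
            "no colonies in any untreated replicate"
        )
    n = len(ratios)
    sem = float(ratios.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return PlatingEfficiency(culture_id, condition, pe, n, sem)


def surviving_fraction(record: ColonyCountRecord, pe: PlatingEfficiency) -> float:
    """SF = (colonies / cells seeded) / PE, using the same-culture,
    same-condition untreated PE.

    A zero-colony well yields SF = 0 with a warning: its log-survival is
    undefined and fitting code excludes it.
    """
    if pe.pe <= 0:
        raise ValueError("plating efficiency must be positive")
    if (record.culture_id, record.condition) != (pe.culture_id, pe.condition):
        raise ValueError(
            f"record {record.culture_id}/{record.condition} does not match "
            f"PE {pe.culture_id}/{pe.condition}"
        )
    if record.colonies == 0:
        warnings.warn(
            f"zero colonies at {record.dose_gy} Gy "
            f"({record.culture_id}/{record.condition} rep {record.replicate}): "
            "SF = 0, excluded from log-space fits",
            stacklevel=2,
        )
        return 0.0
    return (record.colonies / record.cells_seeded) / pe.pe


def build_survival_curve(records: list[ColonyCountRecord]) -> DoseSurvivalCurve:
    """Assemble a dose--survival curve for one culture and condition.

    The dose-0 point is pinned at SF = 1 (self-normalisation) with the SEM
    of the self-normalised untreated replicates; treated doses carry the
    mean and SEM over replicate SFs.  No monotonicity is imposed: a
    non-monotone curve is preserved and only warned about.
    """
    if not records:
        raise ValueError("no records supplied")
    culture_id, condition = _check_homogeneous(records)
    zero = [r for r in records if r.dose_gy == 0]
    if not zero:
        raise ValueError(f"missing dose-0 records for {culture_id}/{condition}")
    pe = plating_efficiency(zero)

    by_dose: dict[float, list[ColonyCountRecord]] = {}
    for r in records:
        by_dose.setdefault(float(r.dose_gy), []).append(r)
    positive_doses = sorted(d for d in by_dose if d > 0)
    if len(positive_doses) < 2:
        raise ValueError(
            f"{culture_id}/{condition}: need >= 2 distinct positive doses, "
            f"got {positive_doses}"
        )

    points = []
    # dose 0: per-replicate self-normalised SFs have mean exactly 1 under
    # the per-replicate-ratio PE convention; the point is pinned at 1.
    zero_sfs = tuple((r.colonies / r.cells_seeded) / pe.pe for r in zero)
    n0 = len(zero_sfs)
    sem0 = float(np.std(zero_sfs, ddof=1) / math.sqrt(n0)) if n0 > 1 else 0.0
    points.append(SurvivalPoint(0.0, 1.0, sem0, n0, zero_sfs))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-colony warnings collected below
        for d in positive_doses:
            sfs = tuple(surviving_fraction(r, pe) for r in by_dose[d])
            n = len(sfs)
            sem = float(np.std(sfs, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
            points.append(SurvivalPoint(d, float(np.mean(sfs)), sem, n, sfs))

    n_zero = sum(1 for p in points for sf in p.sf_replicates if sf == 0)
    if n_zero:
        warnings.warn(
            f"{culture_id}/{condition}: {n_zero} zero-colony well(s); their "
            "SF = 0 enters dose means but is excluded from log-space fits",
            stacklevel=2,
        )
    means = [p.sf_mean for p in points]
    if any(b > a for a, b in zip(means, means[1:])):
        warnings.warn(
            f"{culture_id}/{condition}: surviving fraction is not monotone in "
            "dose; data passed through unchanged",
            stacklevel=2,
        )
    return DoseSurvivalCurve(culture_id, condition, tuple(points), pe)
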
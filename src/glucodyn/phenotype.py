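"""Scalar metabolic phenotyping computations.

Dysglycemia classification from fasting and 2-h glucose, HOMA-IR,
normalized group caloric intake with period-wise marginal means,
adipocyte size-class binning, and the liver-to-body mass ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DysglycemiaThresholds",
    "DietSpec",
    "AdipocyteSizeClasses",
    "STD_DIET",
    "HFHSD_DIET",
    "classify_dysglycemia",
    "homa_ir",
    "insulin_unit_convert",
    "caloric_intake_normalized",
    "period_marginal_means",
    "bin_adipocyte_areas",
    "derive_size_class_boundaries",
    "liver_mass_ratio",
]

HOMA_IR_DIVISOR = 405.0  # (mg/dL * uU/mL) per HOMA-IR unit


@dataclass(frozen=True)
class DysglycemiaThresholds:
    """Diagnostic cutoffs in mg/dL.

    Prediabetes and diabetes bands are contiguous half-open intervals:
    fasting glucose in [100, 126) or 2-h glucose in [140, 200) reads
    prediabetes; fasting >= 126 or 2-h >= 200 reads diabetes.
    """

    fasting_prediabetes_low: float = 100.0
    fasting_diabetes: float = 126.0
    twohour_prediabetes_low: float = 140.0
    twohour_diabetes: float = 200.0

    def __post_init__(self) -> None:
        if not (0 < self.fasting_prediabetes_low < self.fasting_diabetes):
            raise ValueError("fasting thresholds must satisfy 0 < low < diabetes")
        if not (0 < self.twohour_prediabetes_low < self.twohour_diabetes):
            raise ValueError("2-h thresholds must satisfy 0 < low < diabetes")


@dataclass(frozen=True)
class DietSpec:
    """A diet with its metabolic energy density and macronutrient split."""

    name: str
    energy_density_kcal_per_g: float
    carbohydrate_pct: float
    fat_pct: float
    protein_pct: float

    def __post_init__(self) -> None:
        if self.energy_density_kcal_per_g <= 0:
            raise ValueError("energy density must be positive")
        total = self.carbohydrate_pct + self.fat_pct + self.protein_pct
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"macronutrient percentages must sum to 100, got {total}")


#: Standard chow: 2.84 kcal/g, 65% carbohydrate / 11% fat / 24% protein.
STD_DIET = DietSpec("STD", 2.84, 65.0, 11.0, 24.0)
#: High-fat high-sucrose diet: 3.89 kcal/g, 56% carbohydrate / 28% fat / 16% protein.
HFHSD_DIET = DietSpec("HFHSD", 3.89, 56.0, 28.0, 16.0)

DIETS: Mapping[str, DietSpec] = {"STD": STD_DIET, "HFHSD": HFHSD_DIET}


@dataclass(frozen=True)
class AdipocyteSizeClasses:
    """Ascending area boundaries (um^2) splitting adipocytes into 4 classes.

    Default boundaries derive from the quartile grid of standard-diet
    animals: class 1 < 2197.5, class 2 [2197.5, 4395), class 3
    [4395, 6592), class 4 >= 6592 um^2.
    """

    boundaries_um2: tuple[float, float, float] = (2197.5, 4395.0, 6592.0)
    degenerate: bool = False

    def __post_init__(self) -> None:
        b = self.boundaries_um2
        if len(b) != 3 or any(x <= 0 for x in b):
            raise ValueError("need 3 positive boundaries")
        if not self.degenerate and not (b[0] < b[1] < b[2]):
            raise ValueError("boundaries must be strictly ascending")


@dataclass(frozen=True)
class DysglycemiaCall:
    label: str  # "normal" | "prediabetes" | "diabetes"
    fasting_label: str
    twohour_label: str


_SEVERITY = {"normal": 0, "prediabetes": 1, "diabetes": 2}


def _grade(value: float, low: float, high: float) -> str:
    if value >= high:
        return "diabetes"
    if value >= low:
        return "prediabetes"
    return "normal"


def classify_dysglycemia(
    g_fasting: float,
    g_2h: float,
    thresholds: DysglycemiaThresholds = DysglycemiaThresholds(),
) -> DysglycemiaCall:
    """Classify dysglycemia from fasting and 2-h glucose (mg/dL).

    The overall label is the worse of the two per-criterion calls; both
    per-criterion labels are returned.
    """
    if g_fasting <= 0 or g_2h <= 0:
        raise ValueError("glucose values must be positive")
    f = _grade(g_fasting, thresholds.fasting_prediabetes_low, thresholds.fasting_diabetes)
    h = _grade(g_2h, thresholds.twohour_prediabetes_low, thresholds.twohour_diabetes)
    label = f if _SEVERITY[f] >= _SEVERITY[h] else h
    return DysglycemiaCall(label=label, fasting_label=f, twohour_label=h)


def homa_ir(fasting_glucose_mgdl: float, fasting_insulin_uU_ml: float) -> float:
    """HOMA-IR = fasting glucose (mg/dL) x fasting insulin (uU/mL) / 405."""
    if fasting_glucose_mgdl < 0 or fasting_insulin_uU_ml < 0:
        raise ValueError("inputs must be non-negative")
    return fasting_glucose_mgdl * fasting_insulin_uU_ml / HOMA_IR_DIVISOR


def insulin_unit_convert(insulin_ng_ml: float, uU_per_ng: float | None = None) -> float:
    """Convert insulin from ng/mL to uU/mL with an explicit assay factor.

    The uU-per-ng factor is assay dependent and must be supplied by the
    caller; there is deliberately no default.
    """
    if uU_per_ng is None:
        raise ValueError(
            "insulin unit conversion requires an explicit uU-per-ng factor; "
            "it is assay dependent and no default is assumed"
        )
    if uU_per_ng <= 0:
        raise ValueError("conversion factor must be positive")
    return insulin_ng_ml * uU_per_ng


def caloric_intake_normalized(
    group_food_g: float, diet: DietSpec, group_mass_g: float
) -> float:
    """Whole-group caloric intake per gram of group body mass (kcal/g).

    food grams x diet energy density (kcal/g) / summed group body mass
    (g), one value per group-week.  Using kcal rather than grams of
    food, and group mass rather than head counts, cancels both the
    energy-density difference between diets and animal attrition.
    """
    if group_mass_g <= 0:
        raise ValueError("group body mass must be positive")
    if group_food_g < 0:
        raise ValueError("food mass must be non-negative")
    return group_food_g * diet.energy_density_kcal_per_g / group_mass_g


def period_marginal_means(
    weekly_values: Mapping[int, float] | pd.Series,
    periods: Mapping[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Marginal mean and SE of a weekly series over named study periods.

    Default periods: pre-intervention weeks 1-5, early intervention 6-10,
    long-term intervention 11-18 (week 10 is assigned to the early
    period; the study's printed windows overlap at week 10).
    """
    if periods is None:
        periods = {"pre": (1, 5), "early": (6, 10), "long_term": (11, 18)}
    s = pd.Series(dict(weekly_values)).sort_index()
    rows = []
    for name, (lo, hi) in periods.items():
        vals = s.loc[(s.index >= lo) & (s.index <= hi)]
        if vals.empty:
            raise ValueError(f"period {name!r} (weeks {lo}-{hi}) has no data")
        se = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append({"period": name, "week_lo": lo, "week_hi": hi,
                     "mean": float(vals.mean()), "se": se, "n_weeks": len(vals)})
    return pd.DataFrame(rows)


def bin_adipocyte_areas(
    areas_um2: Sequence[float] | np.ndarray,
    classes: AdipocyteSizeClasses = AdipocyteSizeClasses(),
) -> pd.DataFrame:
    """Count adipocytes per size class with half-open bins.

    Bins: [0, b1), [b1, b2), [b2, b3), [b3, inf); a cell exactly on a
    boundary falls in the upper class.
    """
    areas = np.asarray(areas_um2, dtype=float)
    if areas.size == 0:
        raise ValueError("no adipocyte areas supplied")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    edges = np.array([0.0, *classes.boundaries_um2, np.inf])
    counts, _ = np.histogram(areas, bins=edges)
    return pd.DataFrame({
        "size_class": [1, 2, 3, 4],
        "lower_um2": edges[:-1],
        "upper_um2": edges[1:],
        "count": counts,
        "fraction": counts / areas.size,
    })


def derive_size_class_boundaries(
    std_group_areas: Sequence[float] | np.ndarray,
) -> AdipocyteSizeClasses:
    """Derive size-class boundaries from pooled standard-diet areas.

    Boundaries are the linear-interpolation quartiles (Q1, median, Q3)
    of the pooled distribution.  All-equal inputs yield a degenerate,
    flagged class set.
    """
    areas = np.asarray(std_group_areas, dtype=float)
    if areas.size < 4:
        raise ValueError("need at least 4 areas to derive quartile boundaries")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    q1, q2, q3 = np.quantile(areas, [0.25, 0.5, 0.75], method="linear")
    degenerate = not (q1 < q2 < q3)
    return AdipocyteSizeClasses((float(q1), float(q2), float(q3)), degenerate=degenerate)


def liver_mass_ratio(liver_g: float, body_g: float) -> float:
    """Liver-to-body mass ratio as a percentage."""
    if body_g <= 0:
        raise ValueError("body mass must be positive")
    if liver_g < 0:
        raise ValueError("liver mass must be non-negative")
    return 100.0 * liver_g / body_g
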
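"""Range-based triangulation of adjusted effect-size estimates.

Rather than trusting a single pooled mean, a sensitivity analysis
collects every adjusted estimate of the mean validity — the random- and
fixed-effects means, the leave-one-out extremes, trim-and-fill, the two
selection models, and the selected PET-PEESE value — and summarises their
spread. The baseline range estimate (BRE) is the absolute distance from
the RE mean to the estimate farthest from it; the maximum range estimate
(MRE) is the distance between the lowest and highest members. Both are
expressed relative to the RE mean (as 100%) and classified as negligible
(< 20%), moderate (20–40%) or large (>= 40%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .bias_battery import BatteryRow

__all__ = [
    "EstimateSet",
    "TriangulationResult",
    "ClassificationThresholds",
    "collect_estimates",
    "compute_ranges",
    "classify",
    "conclude",
    "triangulate",
    "utility_difference",
]

_SEVERITY = {"negligible": 0, "moderate": 1, "large": 2}


@dataclass(frozen=True)
class ClassificationThresholds:
    """Percent cut-offs for the practical-difference classification.

    The upper boundary is inclusive for "large" (a relative range of
    exactly 40% is classified large, matching reporting practice even
    though the verbal rule says "larger than 40%").
    """

    moderate: float = 20.0
    large: float = 40.0


@dataclass(frozen=True)
class EstimateSet:
    """The adjusted estimates entering the range scan; None = unavailable.

    The probability-valued TES never enters; p-uniform joins only on
    request (it is excluded by default for its poor behaviour under
    heterogeneity).
    """

    re_mean: float
    fe_mean: float | None = None
    osr_min: float | None = None
    osr_median: float | None = None
    osr_max: float | None = None
    tf_mean: float | None = None
    sm_moderate: float | None = None
    sm_severe: float | None = None
    petpeese_selected: float | None = None
    p_uniform: float | None = None

    def members(self) -> list[float]:
        return [
            getattr(self, f.name)
            for f in fields(self)
            if getattr(self, f.name) is not None
        ]


@dataclass(frozen=True)
class TriangulationResult:
    lowest: float
    highest: float
    bre_abs: float
    bre_pct: float              # unrounded
    bre_pct_int: int
    mre_abs: float
    mre_pct: float
    mre_pct_int: int
    class_bre: str
    class_mre: str
    conclusion: str


def collect_estimates(
    battery_row: BatteryRow, include_p_uniform: bool = False
) -> EstimateSet:
    """Map a battery row into the estimate set scanned for ranges.

    Selection-model estimates marked not-applicable (nonsensical variance
    component) are dropped, as are any methods the battery skipped.
    """
    if battery_row.pooled is None:
        raise ValueError("battery row lacks the RE pooled result")
    row = battery_row

    def sm_value(res) -> float | None:
        if res is None or not res.applicable:
            return None
        return res.adjusted_mean

    return EstimateSet(
        re_mean=row.pooled.mean,
        fe_mean=row.pooled_fe.mean if row.pooled_fe is not None else None,
        osr_min=row.osr.min_mean if row.osr else None,
        osr_median=row.osr.median_mean if row.osr else None,
        osr_max=row.osr.max_mean if row.osr else None,
        tf_mean=row.trim_fill.adjusted_mean if row.trim_fill else None,
        sm_moderate=sm_value(row.sm_moderate),
        sm_severe=sm_value(row.sm_severe),
        petpeese_selected=row.petpeese.selected if row.petpeese else None,
        p_uniform=(
            row.puniform.estimate if (include_p_uniform and row.puniform) else None
        ),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def compute_ranges(
    est: EstimateSet,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    round_members: int | None = 2,
) -> TriangulationResult:
    """BRE/MRE absolute and relative ranges with classifications.

    ``round_members`` rounds every member (and the RE base) to that many
    decimals before computing ranges, matching how reported two-decimal
    estimates yield printed integer percentages; pass None to use the
    unrounded estimates.
    """
    members = est.members()
    if len(members) < 2:
        raise ValueError("need at least two present estimates")
    base = est.re_mean
    if round_members is not None:
        members = [round(m, round_members) for m in members]
        base = round(base, round_members)
    if base == 0:
        raise ZeroDivisionError("RE mean is zero; relative ranges undefined")

    lowest, highest = min(members), max(members)
    bre_abs = max(abs(base - lowest), abs(highest - base))
    mre_abs = highest - lowest
    bre_pct = 100.0 * bre_abs / abs(base)
    mre_pct = 100.0 * mre_abs / abs(base)
    class_bre = classify(bre_pct, thresholds)
    class_mre = classify(mre_pct, thresholds)
    return TriangulationResult(
        lowest=lowest, highest=highest,
        bre_abs=bre_abs, bre_pct=bre_pct, bre_pct_int=_round_half_up(bre_pct),
        mre_abs=mre_abs, mre_pct=mre_pct, mre_pct_int=_round_half_up(mre_pct),
        class_bre=class_bre, class_mre=class_mre,
        conclusion=conclude(class_bre, class_mre),
    )


def classify(
    pct: float, thresholds: ClassificationThresholds = ClassificationThresholds()
) -> str:
    """Classify a relative range (percent) as negligible/moderate/large."""
    if pct < 0:
        raise ValueError(f"negative relative range: {pct}")
    if pct < thresholds.moderate:
        return "negligible"
    if pct < thresholds.large:
        return "moderate"
    return "large"


def conclude(class_bre: str, class_mre: str) -> str:
    """Verbal conclusion combining the BRE and MRE classifications."""
    for c in (class_bre, class_mre):
        if c not in _SEVERITY:
            raise ValueError(f"unknown class {c!r}")
    if class_bre == class_mre:
        return f"{class_bre.capitalize()} difference"
    a, b = sorted((class_bre, class_mre), key=_SEVERITY.get)
    return f"{a.capitalize()} to {b} difference"


def triangulate(
    battery_row: BatteryRow,
    include_p_uniform: bool = False,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> TriangulationResult:
    """Convenience: collect the estimate set and compute its ranges."""
    return compute_ranges(
        collect_estimates(battery_row, include_p_uniform), thresholds
    )


def utility_difference(
    validity_a: float,
    validity_b: float,
    n_hired: int,
    years: float,
    salary: float,
    sd_fraction: float = 0.4,
    selectee_z: float = 1.0364,
) -> float:
    """Dollar utility gap between two validity estimates.

    Brogden–Cronbach–Gleser utility: Delta-U = n_hired * years *
    (sd_fraction * salary) * (validity_a - validity_b) * selectee_z, with
    the performance SD in dollars taken as a fraction of salary and
    ``selectee_z`` the mean standard score of those hired (default: the
    85th-percentile score, z ~= 1.0364).
    """
    for name, val in (("n_hired", n_hired), ("years", years), ("salary", salary),
                      ("sd_fraction", sd_fraction), ("selectee_z", selectee_z)):
        if val <= 0:
            raise ValueError(f"{name} must be positive")
    for name, val in (("validity_a", validity_a), ("validity_b", validity_b)):
        if abs(val) >= 1:
            raise ValueError(f"{name} must be a correlation in (-1, 1)")
    sdy = sd_fraction * salary
    return n_hired * years * sdy * (validity_a - validity_b) * selectee_z
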
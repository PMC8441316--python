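"""Collagen-reporter surrogate assay: categorization, decline fit, dose choice.

Per-animal GFP intensities observed over adulthood days are binned into
four ordered intensity categories, the population decline is fit by OLS,
and treated-vs-control contrasts at a scoring day drive dose selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from matreoscreen.signature import bh_adjust

CATEGORIES = ("none/very-low", "low", "medium", "high")


@dataclass(frozen=True)
class CategoryThresholds:
    """Three strictly increasing cutoffs defining four intensity bins."""

    t1: float
    t2: float
    t3: float

    def __post_init__(self) -> None:
        if not (self.t1 < self.t2 < self.t3):
            raise ValueError("thresholds must be strictly increasing")


@dataclass
class DoseResponse:
    """Per-dose treated-vs-control effects with BH-adjusted significance."""

    table: pd.DataFrame  # columns: dose, effect, p, q, n_treated, n_control
    selected_dose: float | None = None
    scoring_day: int = 4
    alpha: float = 0.05


def categorize_intensity(intensity: float, thresholds: CategoryThresholds) -> str:
    """Bin intensity into 4 categories by half-open intervals [0,t1), [t1,t2), ..."""
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    if intensity < thresholds.t1:
        return CATEGORIES[0]
    if intensity < thresholds.t2:
        return CATEGORIES[1]
    if intensity < thresholds.t3:
        return CATEGORIES[2]
    return CATEGORIES[3]


def default_thresholds(control_day1_intensities) -> CategoryThresholds:
    """Quartile cutoffs of the day-1 control intensity distribution."""
    q1, q2, q3 = np.quantile(np.asarray(control_day1_intensities, dtype=float), [0.25, 0.5, 0.75])
    return CategoryThresholds(float(q1), float(q2), float(q3))


def fit_decline(mean_intensity, days) -> tuple[float, float, float]:
    """OLS fit of mean intensity on day: returns (slope, intercept, R^2)."""
    days = np.asarray(days, dtype=float)
    y = np.asarray(mean_intensity, dtype=float)
    if np.unique(days).size < 3:
        raise ValueError("need at least 3 distinct days")
    res = stats.linregress(days, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def prolongation_effect(treated, control, day: int | None = None) -> tuple[float, float, bool]:
    """Standardized treated-vs-control intensity difference at one day.

    Effect is (mean_treated - mean_control) / pooled SD; p is from a
    two-sided Wilcoxon-Mann-Whitney test. Positive effect means prolonged
    reporter expression. Returns (effect, p, degenerate). A zero-variance
    pair of arms yields (0.0, 1.0, True).
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size < 5 or c.size < 5:
        raise ValueError("need >=5 animals per arm")
    vt, vc = t.var(ddof=1), c.var(ddof=1)
    if vt == 0 and vc == 0:
        return 0.0, 1.0, True
    pooled = np.sqrt(((t.size - 1) * vt + (c.size - 1) * vc) / (t.size + c.size - 2))
    effect = float((t.mean() - c.mean()) / pooled)
    p = float(stats.mannwhitneyu(t, c, alternative="two-sided").pvalue)
    return effect, p, False


def dose_response(
    trajectories: pd.DataFrame,
    drug: str,
    scoring_day: int = 4,
    alpha: float = 0.05,
    control_label: str = "control",
) -> DoseResponse:
    """Per-dose prolongation effects at the scoring day, BH-adjusted.

    ``trajectories`` is tidy: columns animal_id, day, drug, dose, intensity.
    """
    day_rows = trajectories[trajectories["day"] == scoring_day]
    control = day_rows.loc[day_rows["drug"] == control_label, "intensity"].to_numpy()
    arm = day_rows[day_rows["drug"] == drug]
    doses = sorted(arm["dose"].unique())
    if not doses:
        raise ValueError(f"no doses found for drug {drug!r} at day {scoring_day}")
    rows = []
    for dose in doses:
        treated = arm.loc[arm["dose"] == dose, "intensity"].to_numpy()
        effect, p, _ = prolongation_effect(treated, control)
        rows.append(
            {"dose": dose, "effect": effect, "p": p,
             "n_treated": treated.size, "n_control": control.size}
        )
    table = pd.DataFrame(rows)
    table["q"], _ = bh_adjust(table["p"].to_numpy(), alpha=alpha)
    dr = DoseResponse(table=table, scoring_day=scoring_day, alpha=alpha)
    dr.selected_dose = select_dose(dr, alpha=alpha)
    return dr


def select_dose(dose_resp: DoseResponse, alpha: float = 0.05) -> float | None:
    """Pick the significant positive-effect dose with the largest effect.

    Ties go to the lowest dose; with no qualifying dose returns None.
    """
    tab = dose_resp.table
    if tab.empty:
        raise ValueError("no doses tested")
    ok = tab[(tab["q"] <= alpha) & (tab["effect"] > 0)]
    if ok.empty:
        return None
    best = ok.sort_values(["effect", "dose"], ascending=[False, True]).iloc[0]
    return float(best["dose"])


def category_distribution(
    trajectories: pd.DataFrame, thresholds: CategoryThresholds
) -> pd.DataFrame:
    """Counts of the 4 intensity categories per (drug, dose, day)."""
    df = trajectories.copy()
    df["category"] = [categorize_intensity(v, thresholds) for v in df["intensity"]]
    out = (
        df.groupby(["drug", "dose", "day", "category"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    return out
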
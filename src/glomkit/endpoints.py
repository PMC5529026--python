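"""Longitudinal clinical-endpoint statistics.

Urinary analytes are normalized to urine creatinine before comparison
(μg/dL over mg/dL gives μg/mg).  Cohort contrasts follow the two families
conventionally reported in lean-vs-obese longitudinal designs: obese versus
age-matched lean at every age, and every obese cohort versus the youngest
obese cohort, both drawn from one Tukey HSD family over all group × age
cells.  Biomarker-fibrosis relationships are summarized by ordinary
least-squares R² over all animals pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_to_creatinine",
    "group_fold_change",
    "anova_tukey",
    "correlate",
    "CorrelationResult",
]

# unit of value / unit of creatinine (mg/dL) → ratio unit
_RATIO_UNITS = {"ug/dL": "ug/mg", "ng/mL": "ng/mg", "mg/dL": "mg/mg"}


def normalize_to_creatinine(records: pd.DataFrame) -> pd.DataFrame:
    """Analyte / urine-creatinine ratio per record.

    Requires a positive ``urine_creatinine`` for every row; a missing value
    is a contract violation and raises rather than silently dropping rows.
    """
    df = records.copy()
    creat = df["urine_creatinine"]
    if creat.isna().any():
        bad = df.loc[creat.isna(), "animal_id"].unique()
        raise ValueError(f"urine creatinine missing for animals: {list(bad)[:5]}")
    if (creat <= 0).any():
        raise ValueError("urine creatinine must be positive")
    df["ratio"] = df["value"] / creat
    if "units" in df.columns:
        df["ratio_units"] = [
            _RATIO_UNITS.get(u, f"{u} per mg/dL creatinine") for u in df["units"]
        ]
    return df


def group_fold_change(
    ratios: pd.DataFrame | None = None,
    age_week: int | None = None,
    value_col: str = "ratio",
    obese_mean: float | None = None,
    lean_mean: float | None = None,
) -> tuple[float, float]:
    """Obese-mean over lean-mean fold change at one age.

    Either pass a ratio table (with ``group``/``age_week`` columns) or the
    two cohort means directly.  Returns ``(raw, headline)`` where the
    headline value is rounded to the nearest ten for reporting (e.g. a raw
    89.6 reads as a 90-fold difference).
    """
    if obese_mean is None or lean_mean is None:
        if ratios is None or age_week is None:
            raise ValueError("pass either a ratio table + age or both cohort means")
        at_age = ratios[ratios["age_week"] == age_week]
        lean_vals = at_age.loc[at_age["group"] == "lean", value_col]
        obese_vals = at_age.loc[at_age["group"] == "obese", value_col]
        if lean_vals.empty or obese_vals.empty:
            raise ValueError(f"both cohorts must be non-empty at age {age_week}")
        lean_mean = float(lean_vals.mean())
        obese_mean = float(obese_vals.mean())
    if lean_mean == 0:
        raise ZeroDivisionError("lean cohort mean is zero")
    raw = obese_mean / lean_mean
    return raw, round(raw / 10.0) * 10.0


def anova_tukey(
    data: pd.DataFrame,
    value_col: str = "value",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-way (group × age) ANOVA with Tukey multiple comparisons.

    Tukey HSD is run over the full set of group × age cells; the returned
    table keeps the two reported comparison families:

    * ``obese_vs_lean`` — obese versus age-matched lean at each age;
    * ``obese_vs_baseline`` — each obese cohort versus the youngest obese
      cohort.

    One row per comparison with the adjusted p-value and a significance
    flag at ``p ≤ alpha``.
    """
    df = data.dropna(subset=[value_col])
    grouped = df.groupby(["group", "age_week"])[value_col]
    n_cell = grouped.size()
    if n_cell.empty or (n_cell < 2).any():
        raise ValueError("every group × age cell needs ≥ 2 animals")
    expected = {
        (g, a)
        for g in df["group"].unique()
        for a in df["age_week"].unique()
    }
    missing = expected - set(n_cell.index)
    if missing:
        raise ValueError(f"empty group × age cell(s): {sorted(missing)}")
    means = grouped.mean()
    k = len(n_cell)
    df_resid = int(n_cell.sum()) - k
    mse = float(
        grouped.apply(lambda v: ((v - v.mean()) ** 2).sum()).sum() / df_resid
    )

    ages = sorted(df["age_week"].unique())
    base_age = ages[0]
    wanted: list[tuple[str, int, tuple, tuple]] = []
    for age in ages:
        wanted.append(("obese_vs_lean", age, ("lean", age), ("obese", age)))
    for age in ages[1:]:
        wanted.append(
            ("obese_vs_baseline", age, ("obese", base_age), ("obese", age))
        )
    # Tukey-Kramer studentized-range statistic over the full k-cell family
    qs = np.array(
        [
            abs(means[b] - means[a])
            / math.sqrt(mse / 2.0 * (1.0 / n_cell[a] + 1.0 / n_cell[b]))
            if mse > 0 else (0.0 if means[b] == means[a] else np.inf)
            for _, _, a, b in wanted
        ]
    )
    with np.errstate(invalid="ignore"):
        p_adj = np.clip(stats.studentized_range.sf(qs, k, df_resid), 0.0, 1.0)
    rows = [
        {
            "family": family,
            "age_week": age,
            "comparison": f"{b[0]}@{b[1]} vs {a[0]}@{a[1]}",
            "p_adj": float(p),
            "significant": bool(p <= alpha),
        }
        for (family, age, a, b), p in zip(wanted, p_adj)
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    slope: float
    intercept: float
    r_squared: float
    n: int


def correlate(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationResult:
    """OLS linear regression of y on x over all animals pooled; reports R²."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be paired 1-D series")
    if len(xv) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xv) == 0:
        raise ValueError("zero variance in x")
    if np.ptp(yv) == 0:
        fit = stats.linregress(xv, yv)
        return CorrelationResult(x_name, y_name, 0.0, float(np.mean(yv)), 0.0, len(xv))
    fit = stats.linregress(xv, yv)
    return CorrelationResult(
        x_name, y_name, float(fit.slope), float(fit.intercept),
        float(fit.rvalue**2), len(xv),
    )
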
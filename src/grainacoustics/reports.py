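"""Report tables: O2 budgets, depletion times/rates, regression coefficients.

These builders reduce a tidy per-observation treatment table to the three
summary tables a hermetic-storage report prints: per-treatment O2 volume
budgets, times to 5%/2% residual O2 with the depletion-rate statistic, and
the pooled activity-vs-depletion regression coefficients. Rounding follows
report conventions: volumes to 1 decimal place, rates and percentages to 2.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .coefficients import MEASURES
from .hermetic import (
    depletion_rate,
    fit_activity_regression,
    oxygen_budget,
    time_to_o2_level,
)

__all__ = ["budget_table", "depletion_table", "regression_table"]


def _sem(values) -> float:
    values = pd.Series(values).dropna()
    if len(values) < 2:
        return math.nan
    return float(values.std(ddof=1) / math.sqrt(len(values)))


def budget_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment O2 budgets: initial/final volumes and ml consumed per insect.

    Each replicate's initial (first-reading) and final (last-reading)
    residual percentages are converted to volumes through the jar's air
    volume; per-insect consumption is averaged over replicates (mean, SEM).
    """
    rows = []
    for tid, group in records.groupby("treatment_id", sort=False):
        n_insects = int(group["n_insects"].iloc[0])
        air = float(group["air_volume_ml"].iloc[0])
        initials, finals, consumed = [], [], []
        for _, rep in group.groupby("replicate"):
            rep = rep.sort_values("day")
            budget = oxygen_budget(
                air, rep["residual_o2_pct"].iloc[0], rep["residual_o2_pct"].iloc[-1],
                n_insects,
            )
            initials.append(budget.initial_volume)
            finals.append(budget.final_volume)
            consumed.append(budget.consumed_per_insect)
        rows.append(
            {
                "treatment_id": tid,
                "n_insects": n_insects,
                "jar_ml": int(group["jar_ml"].iloc[0]),
                "initial_ml": round(float(np.mean(initials)), 1),
                "initial_ml_sem": round(_sem(initials), 2),
                "final_ml": round(float(np.mean(finals)), 1),
                "final_ml_sem": round(_sem(finals), 2),
                "consumed_per_insect_ml": round(float(np.mean(consumed)), 1),
                "consumed_per_insect_sem": round(_sem(consumed), 2),
            }
        )
    return pd.DataFrame(rows)


def depletion_table(records: pd.DataFrame) -> pd.DataFrame:
    """Times to 5% and 2% residual O2 and the depletion-rate statistic.

    Crossing times are linearly interpolated per replicate and averaged;
    the depletion rate is the jar population divided by its mean days to
    2%, reported to 2 decimal places.
    """
    rows = []
    for tid, group in records.groupby("treatment_id", sort=False):
        n_insects = int(group["n_insects"].iloc[0])
        t5s, t2s = [], []
        for _, rep in group.groupby("replicate"):
            series = list(
                rep.sort_values("day")[["day", "residual_o2_pct"]].itertuples(
                    index=False, name=None
                )
            )
            t5 = time_to_o2_level(series, 5.0)
            t2 = time_to_o2_level(series, 2.0)
            t5s.append(math.nan if t5 is None else t5)
            t2s.append(math.nan if t2 is None else t2)
        mean_t2 = float(np.nanmean(t2s)) if not all(math.isnan(v) for v in t2s) else math.nan
        mean_t5 = float(np.nanmean(t5s)) if not all(math.isnan(v) for v in t5s) else math.nan
        rate = depletion_rate(n_insects, mean_t2) if not math.isnan(mean_t2) else math.nan
        rows.append(
            {
                "treatment_id": tid,
                "n_insects": n_insects,
                "jar_ml": int(group["jar_ml"].iloc[0]),
                "days_to_5pct": round(mean_t5, 1) if not math.isnan(mean_t5) else math.nan,
                "days_to_5pct_sem": round(_sem(t5s), 2),
                "days_to_2pct": round(mean_t2, 1) if not math.isnan(mean_t2) else math.nan,
                "days_to_2pct_sem": round(_sem(t2s), 2),
                "depletion_rate_per_day": rate,
            }
        )
    return pd.DataFrame(rows)


def regression_table(records: pd.DataFrame) -> pd.DataFrame:
    """Pooled activity-vs-depletion fits for all three measures.

    Coefficients are reported both raw and on the conventional x1e-3 scale.
    """
    rows = []
    for measure in MEASURES:
        fit = fit_activity_regression(records, measure)
        rows.append(
            {
                "measure": measure,
                "transform": fit.transform,
                "intercept": fit.intercept,
                "slope": fit.slope,
                "intercept_e3": fit.intercept * 1e3,
                "slope_e3": fit.slope * 1e3,
                "intercept_se_e3": fit.intercept_se * 1e3,
                "slope_se_e3": fit.slope_se * 1e3,
                "r_squared": round(fit.r_squared, 4),
                "f_stat": round(fit.f_stat, 2) if math.isfinite(fit.f_stat) else fit.f_stat,
                "df_num": fit.df[0],
                "df_den": fit.df[1],
                "p_value": fit.p_value,
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows)
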
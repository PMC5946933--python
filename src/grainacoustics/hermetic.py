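"""Hermetic-storage analysis: oxygen budgets, depletion statistics,
activity-vs-oxygen regressions, and grain-quality metrics.

In sealed (hermetic) storage, insect respiration depletes the jar's oxygen
from the ambient ~21% toward levels at which activity ceases (~5%) and
mortality follows (~2%). This module turns tidy per-observation treatment
tables into:

* per-treatment oxygen volume budgets (ml consumed per insect),
* interpolated times to 5%/2% residual O2 and the depletion-rate statistic
  (insects per day to reach 2%),
* linear regressions of activity on O2 depletion, with the rate measures
  first normalized per insect and Log10(x+1)-transformed,
* count-and-weigh grain weight loss and germination capacity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .coefficients import MEASURES

__all__ = [
    "GrainCounts",
    "O2Budget",
    "RegressionFit",
    "oxygen_budget",
    "oxygen_budget_from_volumes",
    "time_to_o2_level",
    "depletion_rate",
    "add_depletion",
    "fit_activity_regression",
    "fit_treatment_regression",
    "weight_loss",
    "germination_capacity",
    "summarize_treatments",
    "AMBIENT_O2_PCT",
]

AMBIENT_O2_PCT = 21.0

#: Columns a treatment table must provide.
RECORD_COLUMNS = (
    "treatment_id", "n_insects", "jar_ml", "air_volume_ml", "replicate",
    "day", "residual_o2_pct", "rb", "nb", "rbimp",
)


@dataclass(frozen=True)
class GrainCounts:
    """Counts and weights of damaged/undamaged grain portions (count-and-weigh)."""

    wu: float  # weight of undamaged grains, g
    wd: float  # weight of damaged grains, g
    nu: int    # number of undamaged grains
    nd: int    # number of damaged grains

    def __post_init__(self) -> None:
        if min(self.wu, self.wd, self.nu, self.nd) < 0:
            raise ValueError("grain counts and weights must be non-negative")
        if self.nu + self.nd == 0:
            raise ValueError("at least one grain required")
        if self.nu > 0 and not self.wu > 0:
            raise ValueError("undamaged grains present but weigh nothing")


@dataclass(frozen=True)
class O2Budget:
    """Initial/final O2 volumes (ml) and consumption per insect."""

    initial_volume: float
    final_volume: float
    consumed_per_insect: float
    n_insects: int

    def __post_init__(self) -> None:
        if not self.initial_volume >= self.final_volume >= 0:
            raise ValueError("O2 volumes must satisfy initial >= final >= 0")


@dataclass(frozen=True)
class RegressionFit:
    """A simple linear fit with its F-statistic bookkeeping.

    ``transform`` records how the response was built from the raw measure:
    ``log10p1_per_insect`` for the per-insect Log10(x+1) rate models,
    ``identity`` for impulses-per-burst and the per-treatment fits.
    """

    intercept: float
    slope: float
    r_squared: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    transform: str
    n: int
    intercept_se: float = math.nan
    slope_se: float = math.nan
    s2: float = math.nan  # residual (error) variance
    s: float = math.nan   # residual standard deviation

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 must lie in [0, 1]")
        if self.r_squared < 1.0 and np.isfinite(self.f_stat):
            expected_f = (self.r_squared / (1.0 - self.r_squared)) * (
                self.df[1] / self.df[0]
            )
            if abs(expected_f - self.f_stat) > 1e-6 * max(1.0, abs(self.f_stat)):
                raise ValueError(
                    f"F {self.f_stat} inconsistent with R^2 {self.r_squared} "
                    f"at df {self.df}"
                )

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval for the slope from its standard error."""
        from scipy import stats

        half = stats.t.ppf(0.5 + level / 2.0, self.df[1]) * self.slope_se
        return (self.slope - half, self.slope + half)


def oxygen_budget(
    air_volume: float, initial_o2_pct: float, final_o2_pct: float, n_insects: int
) -> O2Budget:
    """O2 budget from percentages: volumes are pct/100 x air volume (ml)."""
    if air_volume <= 0:
        raise ValueError("air volume must be positive")
    if not 0 <= final_o2_pct <= initial_o2_pct <= 100:
        raise ValueError(
            f"need 0 <= final <= initial <= 100, got {initial_o2_pct}, {final_o2_pct}"
        )
    return oxygen_budget_from_volumes(
        initial_o2_pct / 100.0 * air_volume,
        final_o2_pct / 100.0 * air_volume,
        n_insects,
    )


def oxygen_budget_from_volumes(
    initial_ml: float, final_ml: float, n_insects: int
) -> O2Budget:
    """O2 budget from measured volumes directly (report-table mode)."""
    if n_insects <= 0:
        raise ValueError("n_insects must be positive")
    if final_ml > initial_ml:
        raise ValueError(f"final volume {final_ml} ml exceeds initial {initial_ml} ml")
    consumed = (initial_ml - final_ml) / n_insects
    return O2Budget(
        initial_volume=initial_ml,
        final_volume=final_ml,
        consumed_per_insect=consumed,
        n_insects=n_insects,
    )


def time_to_o2_level(
    series: Sequence[tuple[float, float]], target_pct: float
) -> float | None:
    """First crossing time (days) of a residual-O2 series below a target.

    Linear interpolation between the bracketing observations; 0 when the
    first observation is already at or below target; ``None`` when the
    series never reaches it.
    """
    series = list(series)
    if not series:
        raise ValueError("empty oxygen series")
    days = [d for d, _ in series]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be strictly ascending")
    if series[0][1] <= target_pct:
        return 0.0
    for (d0, o0), (d1, o1) in zip(series, series[1:]):
        if o1 <= target_pct:
            if o0 == o1:
                return float(d1)
            return float(d0 + (o0 - target_pct) * (d1 - d0) / (o0 - o1))
    return None


def depletion_rate(n_insects: int, days_to_2pct: float | None) -> float:
    """Depletion-rate statistic: jar population / days to reach 2% O2.

    Reported to two decimal places; NaN when 2% was never reached.
    """
    if days_to_2pct is None or (isinstance(days_to_2pct, float) and math.isnan(days_to_2pct)):
        return math.nan
    if not days_to_2pct > 0:
        raise ValueError("days to 2% must be positive")
    return round(n_insects / days_to_2pct, 2)


# ---------------------------------------------------------------------------
# regressions


def add_depletion(records: pd.DataFrame) -> pd.DataFrame:
    """Attach per-row O2 depletion (percentage points).

    Each replicate's initial O2 is its own earliest reading (not the
    nominal 21%), so day-one spread between jars is respected; depletion is
    that initial minus the row's residual.
    """
    out = records.copy()
    first = (
        out.sort_values("day")
        .groupby(["treatment_id", "replicate"], sort=False)["residual_o2_pct"]
        .transform("first")
    )
    out["initial_o2_pct"] = first
    out["depletion"] = out["initial_o2_pct"] - out["residual_o2_pct"]
    return out


def _ols_fit(x: np.ndarray, y: np.ndarray, transform: str) -> RegressionFit:
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = model.params
        int_se, slope_se = model.bse
        df_num = int(model.df_model)
        df_den = int(model.df_resid)
        r2 = float(model.rsquared)
        s2 = float(model.ssr / df_den) if df_den > 0 else math.nan
        fstat = float(model.fvalue) if np.isfinite(model.fvalue) else math.inf
        pval = float(model.f_pvalue) if np.isfinite(model.f_pvalue) else 0.0
    # guard against tiny negative rounding of a perfect fit
    r2 = min(max(r2, 0.0), 1.0)
    return RegressionFit(
        intercept=float(intercept),
        slope=float(slope),
        r_squared=r2,
        f_stat=fstat,
        df=(max(df_num, 1), df_den),
        p_value=min(max(pval, np.finfo(float).tiny), 1.0),
        transform=transform,
        n=len(y),
        intercept_se=float(int_se),
        slope_se=float(slope_se),
        s2=s2,
        s=math.sqrt(s2) if s2 >= 0 else math.nan,
    )


def fit_activity_regression(records: pd.DataFrame, measure: str) -> RegressionFit:
    """OLS of an activity measure on O2 depletion, pooled across treatments.

    The rate measures (``rb``, ``rbimp``) are normalized per insect and
    transformed as Log10(measure / n_insects + 1); impulses per burst
    (``nb``) is already on a narrow 3-6 scale and is fit untransformed.
    Rows with an undefined measure are dropped (their count is noted in a
    warning); at least three usable rows are required.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")
    data = add_depletion(records)
    usable = data.dropna(subset=[measure, "depletion"])
    dropped = len(data) - len(usable)
    if dropped:
        warnings.warn(f"{dropped} records with undefined {measure} dropped from fit",
                      stacklevel=2)
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 records with defined {measure}, have {len(usable)}"
        )
    if measure == "nb":
        y = usable[measure].to_numpy(dtype=float)
        transform = "identity"
    else:
        y = np.log10(usable[measure].to_numpy(dtype=float)
                     / usable["n_insects"].to_numpy(dtype=float) + 1.0)
        transform = "log10p1_per_insect"
    x = usable["depletion"].to_numpy(dtype=float)
    return _ols_fit(x, y, transform)


def fit_treatment_regression(
    records: pd.DataFrame, x: str = "residual_o2_pct", y: str = "rb"
) -> RegressionFit:
    """Simple OLS of one burst metric on O2 within a single treatment.

    Values are untransformed; the fit reports R^2 along with the error
    variance s^2 and standard deviation s.
    """
    ids = records["treatment_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"records span {len(ids)} treatments; expected one")
    usable = records.dropna(subset=[x, y])
    if len(usable) < 3:
        raise ValueError(f"need >= 3 usable records, have {len(usable)}")
    return _ols_fit(usable[x].to_numpy(dtype=float),
                    usable[y].to_numpy(dtype=float), "identity")


# ---------------------------------------------------------------------------
# grain quality


def weight_loss(gc: GrainCounts) -> float:
    """Count-and-weigh percentage weight loss.

    loss % = 100 * (ND*WU - NU*WD) / (WU * (NU + ND))

    Zero when no grains are damaged or when damaged and undamaged grains
    have equal per-grain weights. Pathological inputs (damaged grains
    heavier per grain than undamaged) give a negative value, returned as
    computed with a warning.
    """
    if not gc.wu > 0:
        raise ValueError("undamaged weight WU must be positive")
    loss = 100.0 * (gc.nd * gc.wu - gc.nu * gc.wd) / (gc.wu * (gc.nu + gc.nd))
    if loss < 0:
        warnings.warn(
            f"negative weight loss {loss:.3f}%: damaged grains outweigh "
            "undamaged per grain", stacklevel=2,
        )
    return loss


def germination_capacity(
    germinated_counts: Sequence[int], seeds_per_dish: int = 25
) -> tuple[float, list[float]]:
    """Germination capacity from replicate dishes of a fixed seed count.

    Returns ``(overall %, per-dish %)`` where the overall figure is total
    germinated over total seeds across dishes.
    """
    counts = list(germinated_counts)
    if not counts:
        raise ValueError("no dishes counted")
    for c in counts:
        if not 0 <= c <= seeds_per_dish:
            raise ValueError(f"count {c} outside 0..{seeds_per_dish}")
    per_dish = [100.0 * c / seeds_per_dish for c in counts]
    overall = 100.0 * sum(counts) / (seeds_per_dish * len(counts))
    return overall, per_dish


# ---------------------------------------------------------------------------
# summaries


def _sem(values: pd.Series) -> float:
    n = values.count()
    if n < 2:
        return math.nan
    return float(values.std(ddof=1) / math.sqrt(n))


def summarize_treatments(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM per treatment x day for O2 and the activity measures.

    SEM is the sample SD over replicates divided by sqrt(n); it is missing
    for single-replicate cells. Output columns follow the report-table
    layout: one row per (treatment, day) with ``<var>_mean``/``<var>_sem``.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    variables = ["residual_o2_pct", "rb", "nb", "rbimp"]
    grouped = records.groupby(["treatment_id", "day"], sort=True)
    rows = []
    for (tid, day), cell in grouped:
        row: dict[str, object] = {
            "treatment_id": tid,
            "day": day,
            "n": int(len(cell)),
        }
        for var in variables:
            row[f"{var}_mean"] = float(cell[var].mean())
            row[f"{var}_sem"] = _sem(cell[var])
        rows.append(row)
    return pd.DataFrame(rows)
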
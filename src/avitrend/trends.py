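"""CI-weighted linear trend estimation, T% change and trend classification.

The long-term trend of a species is the slope of a weighted least squares
regression of the yearly median population index on calendar year, with
the reciprocal of each year's 95% confidence-interval width as weight
(I_t = beta * year + eps, w = 1/CI).  A trend is significant at
p(beta) <= 0.05; the population change over the series span,
T% = (I_last - I_first) / I_first * 100, is computed from the WLS fitted
endpoint values.  Significant declines with T% below -50 are flagged as
steep.

``summarize_results`` reproduces results-table roll-ups (counts by
selected model family and by trend class) and works both on pipeline
output and on the packaged transcription of the study's species table
(``load_table1``).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .index_prediction import YearlyIndexSeries

__all__ = [
    "TrendFit",
    "fit_wls_trend",
    "percent_change",
    "classify_trend",
    "summarize_results",
    "load_table1",
]

ALPHA = 0.05
STEEP_CUT = -50.0


@dataclass
class TrendFit:
    """WLS trend fit for one species' yearly index series."""

    species_id: str | None
    slope: float
    intercept: float
    se: float
    t_value: float
    p_value: float
    pct_change: float  # T% over the series span; NaN when undefined
    adj_r2: float      # floored at 0
    first_year: int
    last_year: int
    n_years: int

    @property
    def trend_class(self) -> str:
        return classify_trend(self.p_value, self.pct_change, slope=self.slope)

    @property
    def steep_decline(self) -> bool:
        return (
            self.trend_class == "significant decline"
            and np.isfinite(self.pct_change)
            and self.pct_change < STEEP_CUT
        )

    def fitted(self, year) -> float:
        return self.intercept + self.slope * np.asarray(year, float)


def fit_wls_trend(series: YearlyIndexSeries | pd.DataFrame,
                  species_id: str | None = None) -> TrendFit:
    """Weighted least squares of median index on year, weights 1/ci_width.

    Years with a zero CI width get their weight capped at 10x the largest
    finite weight in the series; if every width is zero the fit degrades to
    ordinary least squares with a warning.
    """
    if isinstance(series, YearlyIndexSeries):
        tab = series.table
        species_id = species_id or series.species_id
    else:
        tab = series
    if len(tab) < 3:
        raise ValueError("need at least 3 yearly indices for a trend")
    year = tab["year"].to_numpy(float)
    idx = tab["median"].to_numpy(float)
    width = tab["ci_width"].to_numpy(float)
    if np.any(width < 0):
        raise ValueError("negative CI width")
    with np.errstate(divide="ignore"):
        w = 1.0 / width
    if np.all(~np.isfinite(w)):
        warnings.warn("all CI widths are zero; falling back to OLS")
        w = np.ones_like(w)
    elif np.any(~np.isfinite(w)):
        w[~np.isfinite(w)] = w[np.isfinite(w)].max() * 10.0

    Xd = sm.add_constant(year)
    res = sm.WLS(idx, Xd, weights=w).fit()
    slope, intercept = float(res.params[1]), float(res.params[0])
    fit = TrendFit(
        species_id=species_id,
        slope=slope,
        intercept=intercept,
        se=float(res.bse[1]),
        t_value=float(res.tvalues[1]),
        p_value=float(res.pvalues[1]),
        pct_change=np.nan,
        adj_r2=max(0.0, float(res.rsquared_adj)),
        first_year=int(year.min()),
        last_year=int(year.max()),
        n_years=len(tab),
    )
    fit.pct_change = percent_change(fit)
    return fit


def percent_change(fit: TrendFit) -> float:
    """T% between the first and last year of the series, from WLS fitted values.

    Species entering the survey late use their own first recorded year as
    the baseline.  A non-positive fitted baseline leaves T% undefined (NaN).
    """
    i_first = fit.fitted(fit.first_year)
    i_last = fit.fitted(fit.last_year)
    if i_first <= 0:
        warnings.warn(
            f"fitted index at {fit.first_year} is non-positive for "
            f"{fit.species_id!r}; T% undefined"
        )
        return float("nan")
    return float((i_last - i_first) / i_first * 100.0)


def classify_trend(
    p_value: float,
    pct_change: float,
    alpha: float = ALPHA,
    slope: float | None = None,
) -> str:
    """Trend class from the WLS p-value and T%.

    Significant iff p <= alpha (the boundary counts as significant);
    direction from the sign of T%, falling back to the slope sign when T%
    is undefined.
    """
    if not np.isfinite(p_value):
        raise ValueError("missing p value")
    if p_value > alpha:
        return "non-significant"
    direction = pct_change if np.isfinite(pct_change) else slope
    if direction is None or not np.isfinite(direction):
        raise ValueError("neither T% nor slope available for direction")
    return "significant increase" if direction > 0 else "significant decline"


def _parse_p(p) -> float:
    if isinstance(p, str) and p.strip().startswith("<"):
        return float(p.strip()[1:]) / 2.0  # below the printed bound
    return float(p)


def summarize_results(table: pd.DataFrame) -> dict:
    """Roll up a per-species results table.

    Expects columns ``wls_model`` (selected family), ``p_value`` and
    ``pct_change`` (T%); printed p values like ``"<0.001"`` are accepted.
    Returns counts by family, counts by trend class, the number of steep
    declines (significant and T% < -50) and the share of species increasing.
    """
    for col in ("wls_model", "p_value", "pct_change"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    fam_counts = table["wls_model"].value_counts().to_dict() if len(table) else {}
    classes = {"significant increase": 0, "significant decline": 0, "non-significant": 0}
    steep = 0
    for _, row in table.iterrows():
        cls = classify_trend(_parse_p(row["p_value"]), float(row["pct_change"]))
        classes[cls] += 1
        if cls == "significant decline" and float(row["pct_change"]) < STEEP_CUT:
            steep += 1
    n = len(table)
    return {
        "n_species": n,
        "family_counts": fam_counts,
        "trend_classes": classes,
        "steep_declines": steep,
        "increase_share_pct": 100.0 * classes["significant increase"] / n if n else 0.0,
        "decline_share_pct": 100.0 * classes["significant decline"] / n if n else 0.0,
    }


def load_table1() -> pd.DataFrame:
    """The packaged per-species WLS results table (verbatim transcription)."""
    ref = importlib.resources.files("avitrend") / "fixtures" / "table1.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
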
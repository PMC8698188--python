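"""Functional-group trend models.

To compare trends across species that differ wildly in absolute abundance,
each species' yearly index series is normalized by its own first-year
median (so the series starts at 1 and the 2.5/97.5 percentile bounds are
expressed on the same relative scale).  The normalized records of all
species are then pooled into one weighted linear model per trait:

    index ~ group + year + year:group,   weights = 1 / (normalized CI width)

The year:group interaction terms are the per-group trends.  Hypotheses —
each group's slope equal to zero and pairwise slope equality — are tested
with the finite-sample F statistic on linear contrasts of the fitted
coefficients (for a single constraint, F = t^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .index_prediction import YearlyIndexSeries

__all__ = [
    "normalize_index_series",
    "NormalizedSeries",
    "GroupModelFit",
    "fit_group_trend_model",
    "test_group_hypotheses",
]


@dataclass
class NormalizedSeries:
    """Index series rescaled so the first recorded year's median is 1."""

    species_id: str | None
    base_year: int
    table: pd.DataFrame  # year, median, lo, hi, ci_width, weight


def normalize_index_series(series: YearlyIndexSeries) -> NormalizedSeries:
    """Divide median, lo and hi by the first recorded year's median.

    Species absent at the start of the survey are normalized to their own
    first recorded year.  Weights are recomputed from the normalized
    interval widths.
    """
    tab = series.table.sort_values("year").reset_index(drop=True)
    base_year = int(tab["year"].iloc[0])
    base = float(tab["median"].iloc[0])
    if base <= 0:
        raise ValueError(
            f"base-year median is non-positive for species {series.species_id!r}"
        )
    out = tab.copy()
    for c in ("median", "lo", "hi"):
        out[c] = tab[c] / base
    out["ci_width"] = out["hi"] - out["lo"]
    with np.errstate(divide="ignore"):
        w = 1.0 / out["ci_width"].to_numpy()
    finite = np.isfinite(w)
    if not finite.all():
        cap = w[finite].max() * 10.0 if finite.any() else 1.0
        w[~finite] = cap
    out["weight"] = w
    return NormalizedSeries(species_id=series.species_id, base_year=base_year, table=out)


@dataclass
class GroupModelFit:
    """Pooled weighted year x group interaction model for one trait."""

    trait: str
    reference: str
    levels: list
    coef_table: pd.DataFrame
    adj_r2: float
    result: object = field(repr=False)  # statsmodels WLS results
    n_records: int = 0
    group_sizes: dict = field(default_factory=dict)

    def slope(self, level: str) -> float:
        """Fitted trend of a group: year coefficient + its interaction."""
        s = float(self.result.params[self._ix("year")])
        if level != self.reference:
            s += float(self.result.params[self._ix(f"year:{level}")])
        return s

    def _ix(self, name: str) -> int:
        return list(self.coef_table.index).index(name)


def fit_group_trend_model(
    normalized: dict[str, NormalizedSeries],
    groups: dict[str, str],
    trait: str = "group",
    reference: str | None = None,
) -> GroupModelFit:
    """Fit the pooled weighted model index ~ group + year + year:group.

    ``normalized`` maps species to their normalized series, ``groups`` maps
    species to a trait level.  Each level needs at least 2 species and more
    than one distinct year.  The reference level defaults to the
    alphabetically first one.
    """
    rows = []
    for sp, ns in normalized.items():
        if sp not in groups:
            continue
        t = ns.table
        rows.append(pd.DataFrame({
            "species_id": sp,
            "year": t["year"].to_numpy(float),
            "index": t["median"].to_numpy(float),
            "weight": t["weight"].to_numpy(float),
            "level": groups[sp],
        }))
    if not rows:
        raise ValueError("no species with both a series and a group label")
    data = pd.concat(rows, ignore_index=True)
    if np.any(data["weight"] <= 0):
        raise ValueError("non-positive weights")

    levels = sorted(data["level"].unique())
    sizes = data.groupby("level")["species_id"].nunique().to_dict()
    bad = [lv for lv in levels if sizes.get(lv, 0) < 2]
    if len(levels) < 2:
        raise ValueError("need at least 2 trait levels")
    if bad:
        raise ValueError(f"levels with fewer than 2 species: {bad}")
    for lv in levels:
        if data.loc[data["level"] == lv, "year"].nunique() < 2:
            raise ValueError(f"level {lv!r} has a single year: singular design")
    reference = reference if reference is not None else levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present")
    others = [lv for lv in levels if lv != reference]

    n = len(data)
    cols = [np.ones(n)]
    names = ["Intercept"]
    lev = data["level"].to_numpy()
    yr = data["year"].to_numpy(float)
    for lv in others:
        cols.append((lev == lv).astype(float))
        names.append(lv)
    cols.append(yr)
    names.append("year")
    for lv in others:
        cols.append(yr * (lev == lv))
        names.append(f"year:{lv}")
    X = np.column_stack(cols)
    res = sm.WLS(data["index"].to_numpy(float), X, weights=data["weight"].to_numpy()).fit()

    coef = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "t_value": res.tvalues,
            "p_value": res.pvalues,
        },
        index=names,
    )
    return GroupModelFit(
        trait=trait,
        reference=reference,
        levels=levels,
        coef_table=coef,
        adj_r2=float(res.rsquared_adj),
        result=res,
        n_records=n,
        group_sizes=sizes,
    )


def test_group_hypotheses(fit: GroupModelFit) -> pd.DataFrame:
    """Finite-sample F tests on the fitted group slopes.

    For every group: H0 slope = 0 (year + interaction for non-reference
    levels).  For every level pair: H0 slope equality.  Single-constraint
    tests satisfy F = t^2 exactly.
    """
    res = fit.result
    names = list(fit.coef_table.index)
    p = len(names)

    def contrast(level: str) -> np.ndarray:
        r = np.zeros(p)
        r[names.index("year")] = 1.0
        if level != fit.reference:
            r[names.index(f"year:{level}")] = 1.0
        return r

    rows = []
    for lv in fit.levels:
        ft = res.f_test(contrast(lv))
        rows.append({
            "hypothesis": f"slope[{lv}] = 0",
            "F": float(ft.fvalue),
            "p_value": float(ft.pvalue),
            "df_num": int(ft.df_num),
            "df_denom": int(ft.df_denom),
        })
    for i, a in enumerate(fit.levels):
        for b in fit.levels[i + 1:]:
            r = contrast(a) - contrast(b)
            if not np.any(r):
                raise ValueError("rank-deficient contrast")
            ft = res.f_test(r)
            rows.append({
                "hypothesis": f"slope[{a}] = slope[{b}]",
                "F": float(ft.fvalue),
                "p_value": float(ft.pvalue),
                "df_num": int(ft.df_num),
                "df_denom": int(ft.df_denom),
            })
    return pd.DataFrame(rows)
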
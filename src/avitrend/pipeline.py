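"""End-to-end per-species convenience wrapper.

Glues the pipeline stages together for one species: align its pair counts
with the site table, fit the candidate count families on a shared design,
select by AIC, build the standardized prediction covariates (with the
convex-hull range mask), bootstrap the yearly index series and fit the
CI-weighted trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .count_models import FittedCountModel, fit_all_families, select_best_model
from .design import ModelDesign
from .index_prediction import (
    YearlyIndexSeries,
    bootstrap_indices,
    compute_range_mask,
    standardize_covariates,
)
from .trends import TrendFit, fit_wls_trend

__all__ = ["SpeciesResult", "run_species_pipeline"]


@dataclass
class SpeciesResult:
    species_id: str
    fit: FittedCountModel
    series: YearlyIndexSeries
    trend: TrendFit
    aic_table: dict


def run_species_pipeline(
    counts: pd.DataFrame,
    sites: pd.DataFrame,
    species_id: str,
    snapshots: pd.DataFrame,
    region,
    design: ModelDesign | None = None,
    families: list[str] | None = None,
    B: int = 1000,
    seed: int = 0,
    use_mask: bool = True,
    compute_deviance: bool = False,
    **design_kwargs,
) -> SpeciesResult:
    """Counts + sites + snapshots -> selected model, index series, trend."""
    sub = counts[counts["species_id"] == species_id]
    merged = sites.merge(
        sub[["site_id", "year", "pairs"]], on=["site_id", "year"], how="left"
    )
    merged["pairs"] = merged["pairs"].fillna(0).astype(int)

    if design is None:
        design = ModelDesign.build(merged, **design_kwargs)
    fits = fit_all_families(
        design, merged, merged["pairs"], species_id=species_id,
        families=families, compute_deviance=compute_deviance,
    )
    best = select_best_model(fits)

    mask = None
    if use_mask:
        presence = merged.loc[merged["pairs"] > 0, ["x", "y"]]
        mask = compute_range_mask(presence, region, species_id=species_id)
    std_cov = standardize_covariates(
        snapshots, sorted(merged["year"].unique()), merged, mask=mask
    )
    series = bootstrap_indices(best, std_cov, B=B, seed=seed)
    trend = fit_wls_trend(series, species_id=species_id)
    return SpeciesResult(
        species_id=species_id,
        fit=best,
        series=series,
        trend=trend,
        aic_table={f.family: f.aic for f in fits.values()},
    )
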
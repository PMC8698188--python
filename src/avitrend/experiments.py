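"""Calibration experiments for the trend pipeline on synthetic truth.

Each function sets up a small simulation study with known ground truth,
runs the package's own estimators on it, and returns the operating
characteristic being measured: test size of the CI-weighted trend test
under a flat truth, AIC family-selection accuracy under a well-separated
zero-inflated negative binomial truth, coverage of the parametric-
bootstrap index intervals, group-slope recovery of the pooled interaction
model, and sign recovery of species trends through the full pipeline.

Problem sizes are arguments with defaults chosen so every experiment runs
in minutes on one core; all randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .count_models import fit_all_families, fit_count_model, select_best_model
from .design import ModelDesign
from .group_models import fit_group_trend_model, normalize_index_series
from .index_prediction import YearlyIndexSeries, bootstrap_indices
from .pipeline import run_species_pipeline
from .preprocess import apply_conversion_factors
from .synthetic import (
    RegionSpec,
    SpeciesSimSpec,
    generate_sites,
    random_species_specs,
    simulate_counts,
)
from .trends import fit_wls_trend

__all__ = [
    "wls_null_rejection_rate",
    "aic_family_selection_rate",
    "bootstrap_index_coverage",
    "group_slope_recovery",
    "trend_sign_recovery",
]


def wls_null_rejection_rate(
    n_series: int = 1000,
    years: list[int] | None = None,
    sigma_range: tuple[float, float] = (0.05, 0.15),
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the CI-weighted trend test under a flat truth.

    Each replicate series mimics pipeline output for a stable population:
    yearly medians scatter around a constant index of 1 with year-specific
    noise SD drawn from ``sigma_range``, and the 95% CI width is the
    corresponding normal width (3.92 sigma), so weights are 1/CI as in the
    real fit.  Returns the fraction of replicates with p <= alpha.
    """
    years = years or [y for y in range(1992, 2020) if y not in (1993, 1994, 1997, 1998)]
    rng = np.random.default_rng(seed)
    yrs = np.asarray(years, float)
    reject = 0
    for _ in range(n_series):
        sigma = rng.uniform(*sigma_range, size=len(yrs))
        med = 1.0 + rng.normal(0, sigma)
        width = 2 * 1.959963984540054 * sigma
        tab = pd.DataFrame({"year": yrs, "median": med, "ci_width": width})
        if fit_wls_trend(tab).p_value <= alpha:
            reject += 1
    return reject / n_series


def _flat_sites(n: int, n_years: int, rng: np.random.Generator) -> pd.DataFrame:
    """Covariate table without spatial placement, for model-level sims."""
    years = np.repeat(np.arange(2000, 2000 + n_years), n // n_years)
    n = len(years)
    return pd.DataFrame(
        {
            "site_id": [f"S{i:05d}" for i in range(n)],
            "year": years,
            "lc01": rng.uniform(0, 1, n),
            "elevation": rng.uniform(100, 1500, n),
            "urban_2500": rng.uniform(0, 1, n),
            "forest_2500": rng.uniform(0, 1, n),
        }
    )


def aic_family_selection_rate(
    n_reps: int = 100,
    n_obs: int = 5000,
    true_family: str = "ZINB",
    seed: int = 0,
) -> float:
    """Fraction of replicates in which AIC picks the true count family.

    Truth is a well-separated zero-inflated negative binomial process
    (strong structural-zero mass, clear overdispersion) generated by the
    synthetic count simulator on a covariate table; all four families are
    fitted on an intercept + year + smooth(covariate) design and the
    minimum-AIC converged fit is scored against the truth.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for rep in range(n_reps):
        sites = _flat_sites(n_obs, 2, rng)
        spec = SpeciesSimSpec(
            species_id="sim",
            family=true_family,
            baseline_log_mean=1.0,
            covariate_effects={"lc01": 0.8},
            true_log_trend=0.0,
            nb_dispersion=1.0,
            zi_coefficients=(-0.2, 0.0, 0.6, -0.6),
        )
        counts, _ = simulate_counts(sites, [spec], seed=int(rng.integers(2**31)))
        y = counts["individuals"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design = ModelDesign.build(
                sites, smooth_cols=["lc01"], linear_cols=[],
                zero_cols=["urban_2500", "forest_2500"], include_spatial=False,
            )
            fits = fit_all_families(design, sites, y, compute_deviance=False)
            best = select_best_model(fits)
        if best.family == true_family:
            hits += 1
    return hits / n_reps


def bootstrap_index_coverage(
    n_reps: int = 200,
    B: int = 200,
    n_sites: int = 60,
    n_years: int = 8,
    seed: int = 0,
) -> float:
    """Coverage of the 95% bootstrap interval for the true yearly index.

    Truth is a Poisson process with a log-linear year trend; the model is
    the intercept + year-factor Poisson fit, so the per-year expected
    pairs per site are identified and the interval should cover the truth
    in about 95% of replicates (pooled over years).
    """
    rng = np.random.default_rng(seed)
    covered = total = 0
    for rep in range(n_reps):
        sites = _flat_sites(n_sites * n_years, n_years, rng)
        spec = SpeciesSimSpec(
            species_id="sim", family="P", baseline_log_mean=0.3,
            true_log_trend=-0.02,
        )
        counts, truth = simulate_counts(sites, [spec], seed=int(rng.integers(2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design = ModelDesign.build(
                sites, smooth_cols=[], linear_cols=[], zero_cols=[],
                include_spatial=False,
            )
            fit = fit_count_model(
                design, sites, counts["individuals"].to_numpy(), "P",
                compute_deviance=False,
            )
            std_cov = pd.DataFrame({"year": sorted(sites["year"].unique())})
            series = bootstrap_indices(fit, std_cov, B=B, seed=int(rng.integers(2**31)))
        true_idx = truth.yearly_index["sim"]
        for _, row in series.table.iterrows():
            total += 1
            if row["lo"] <= true_idx[int(row["year"])] <= row["hi"]:
                covered += 1
    return covered / total


def group_slope_recovery(
    slopes: dict[str, float] | None = None,
    n_species_per_group: int = 20,
    years: list[int] | None = None,
    noise_sd: float = 0.05,
    ci_width: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Recovery of configured group trends by the pooled interaction model.

    Each species' normalized index is linear in year with its group's
    slope plus observation noise.  Returns one row per group with the true
    slope, the estimated slope, its SE and the absolute z-error.
    """
    slopes = slopes or {"farmland": -0.02, "woodland": 0.01}
    years = years or list(range(1992, 2020))
    rng = np.random.default_rng(seed)
    yrs = np.asarray(years, float)
    normalized, groups = {}, {}
    i = 0
    for group, slope in slopes.items():
        for _ in range(n_species_per_group):
            sp = f"sp{i:03d}"
            i += 1
            med = 1.0 + slope * (yrs - yrs[0]) + rng.normal(0, noise_sd, len(yrs))
            tab = pd.DataFrame(
                {
                    "year": yrs.astype(int), "median": med,
                    "lo": med - ci_width / 2, "hi": med + ci_width / 2,
                }
            )
            tab["ci_width"] = tab["hi"] - tab["lo"]
            # normalization base: the noiseless first-year value (1.0) keeps
            # the configured slopes on the normalized scale exactly
            tab.loc[0, "median"] = 1.0
            normalized[sp] = normalize_index_series(
                YearlyIndexSeries(species_id=sp, table=tab)
            )
            groups[sp] = group
    fit = fit_group_trend_model(normalized, groups, trait="group")
    rows = []
    for group, slope in slopes.items():
        est = fit.slope(group)
        if group == fit.reference:
            se = float(fit.coef_table.loc["year", "se"])
        else:
            # SE of year + interaction via the coefficient covariance
            names = list(fit.coef_table.index)
            r = np.zeros(len(names))
            r[names.index("year")] = 1.0
            r[names.index(f"year:{group}")] = 1.0
            se = float(np.sqrt(r @ fit.result.cov_params() @ r))
        rows.append(
            {"group": group, "true_slope": slope, "estimated_slope": est,
             "se": se, "abs_z_error": abs(est - slope) / se}
        )
    return pd.DataFrame(rows)


def trend_sign_recovery(
    n_species: int = 12,
    n_per_year: int = 100,
    n_years: int = 12,
    min_abs_slope: float = 0.02,
    B: int = 200,
    seed: int = 0,
) -> float:
    """Share of species whose estimated WLS trend sign matches the truth.

    Full pipeline under unbiased site sampling: site generation, count
    simulation (Poisson and zero-inflated Poisson species with
    |true log trend| >= ``min_abs_slope``), pair conversion, model
    selection, bootstrap indices and the weighted trend fit.
    """
    rng = np.random.default_rng(seed)
    region = RegionSpec(
        extent=(0, 0, 30_000.0, 30_000.0),
        survey_years=list(range(2000, 2000 + n_years)),
    )
    sites, land = generate_sites(region, n_per_year, seed=int(rng.integers(2**31)))
    specs = random_species_specs(
        n_species, seed=int(rng.integers(2**31)), families=["P", "ZIP"],
        covariate_cols=["lc03", "lc10"], baseline_range=(-0.3, 1.0),
    )
    for j, spec in enumerate(specs):  # pin slopes at +/- the target magnitude
        mag = min_abs_slope * float(rng.uniform(1.0, 2.0))
        spec.true_log_trend = mag if j % 2 == 0 else -mag
    counts, truth = simulate_counts(sites, specs, seed=int(rng.integers(2**31)))
    counts = apply_conversion_factors(counts, {s.species_id: s.cf for s in specs})
    snaps = land.snapshot_table(
        years=[region.survey_years[0] - 1, *region.survey_years[3::4],
               region.survey_years[-1] + 1]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = ModelDesign.build(
            sites.assign(pairs=0), smooth_cols=["lc03", "lc10", "elevation"],
        )
        hits = 0
        for spec in specs:
            res = run_species_pipeline(
                counts, sites, spec.species_id, snaps, region,
                design=design, B=B, seed=int(rng.integers(2**31)),
            )
            if np.sign(res.trend.slope) == np.sign(truth.true_log_trend[spec.species_id]):
                hits += 1
    return hits / n_species
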
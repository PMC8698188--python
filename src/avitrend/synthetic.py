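"""Synthetic point-count survey generator with known ground truth.

Emulates the statistical structure of a long-term multi-project breeding
bird survey: heterogeneous site placement over a planar (UTM-like) region,
spatially autocorrelated environmental covariates (17 land-cover fractions
at the 250 m scale, topography, urban/forest cover at the 2500 m scale),
slow land-cover change over decades, and per-species count processes drawn
from Poisson / NB2 / zero-inflated families with log-linear true year
trends.  Gregarious species emit raw individual counts built from pairs and
a conversion factor so the pair-conversion step is exercised downstream.

Everything is seeded and bit-reproducible; the ground truth (true family,
true log-trend, true yearly expected index, trait-group memberships) is
returned alongside the data so recovery tests can score the pipeline.

What it deliberately does not model: real GIS rasters, within-season
repeat visits, or a detection-probability process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DEFAULT_LANDCOVER_COLS

__all__ = [
    "RegionSpec",
    "SyntheticLandscape",
    "SpeciesSimSpec",
    "TruthRecord",
    "generate_sites",
    "simulate_counts",
    "generate_trait_table",
    "random_species_specs",
    "SURVEY_YEARS_1992_2019",
    "SNAPSHOT_YEARS_DUSAF",
]

#: the study's surveyed years: 1992-2019 with no data in 1993-94 and 1997-98
SURVEY_YEARS_1992_2019 = [
    y for y in range(1992, 2020) if y not in (1993, 1994, 1997, 1998)
]
#: land-cover snapshot map years
SNAPSHOT_YEARS_DUSAF = [1980, 1999, 2007, 2012, 2015, 2018]

MIN_SPACING = 500.0  # metres, within-year

TRAIT_COLUMNS = [
    "wing_length", "body_mass", "clutch_size", "broods_per_year",
    "incubation_days", "migration", "brood_parasite",
    "diet_vertebrates", "diet_plants", "diet_invertebrates", "diet_other",
    "nest_raw",
    "cover_urban", "cover_agricultural", "cover_forest",
    "cover_natural_open", "cover_wetland",
]


@dataclass
class RegionSpec:
    """Planar study region and temporal frame of the synthetic survey."""

    extent: tuple[float, float, float, float] = (0.0, 0.0, 50_000.0, 50_000.0)
    survey_years: list[int] = field(default_factory=lambda: list(SURVEY_YEARS_1992_2019))
    snapshot_years: list[int] = field(default_factory=lambda: list(SNAPSHOT_YEARS_DUSAF))

    def __post_init__(self):
        x0, y0, x1, y1 = self.extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("degenerate extent")
        if not self.survey_years:
            raise ValueError("survey_years is empty")

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.extent
        return (x1 - x0) * (y1 - y0)

    @property
    def width(self) -> float:
        return self.extent[2] - self.extent[0]

    @property
    def height(self) -> float:
        return self.extent[3] - self.extent[1]

    def packing_capacity(self, spacing: float = MIN_SPACING) -> int:
        """Sites that fit at square packing with the given minimum spacing."""
        return (math.floor(self.width / spacing) + 1) * (
            math.floor(self.height / spacing) + 1
        )


class SyntheticLandscape:
    """Spatially autocorrelated covariate fields over a region.

    Each latent surface is a low-rank Gaussian random field built from
    random Fourier features; land-cover fractions come from a
    logistic-normal construction over the 17 classes plus a remainder, so
    fractions lie in [0, 1] and sum to <= 1.  Class latents drift linearly
    in time (urbanization up, arable down, forest up by default) so
    land-cover snapshot tables change across decades.
    """

    N_LC = 17
    FOREST_CLASSES = [9, 10, 11]   # 0-based: broadleaved, mixed, coniferous
    URBAN_CLASSES = [0, 1]

    def __init__(
        self,
        region: RegionSpec,
        seed: int,
        length_scale: float = 8_000.0,
        n_features: int = 48,
        drift_per_year: dict[int, float] | None = None,
        ref_year: int | None = None,
    ):
        self.region = region
        self.length_scale = length_scale
        rng = np.random.default_rng(seed)
        self.ref_year = ref_year if ref_year is not None else min(region.survey_years)
        # one latent GRF per land-cover class + remainder + elevation + slope
        n_fields = self.N_LC + 1 + 2
        self._w = rng.normal(0, 1.0 / length_scale, size=(n_fields, n_features, 2))
        self._b = rng.uniform(0, 2 * np.pi, size=(n_fields, n_features))
        self._a = rng.normal(0, np.sqrt(2.0 / n_features), size=(n_fields, n_features))
        # mild class-mean offsets so covers are unequal but none dominates
        self._mu = rng.normal(0, 0.5, size=self.N_LC + 1)
        drift = {0: 0.010, 2: -0.008, 9: 0.008}  # urban up, arable down, forest up
        if drift_per_year is not None:
            drift = drift_per_year
        self._drift = drift

    def _latents(self, xy: np.ndarray) -> np.ndarray:
        # (n_fields, n_points)
        proj = np.einsum("fkd,nd->fkn", self._w, xy) + self._b[:, :, None]
        return np.einsum("fk,fkn->fn", self._a, np.cos(proj))

    def covariates(self, xy: np.ndarray, year: int | np.ndarray) -> pd.DataFrame:
        """Covariate table for planar points in a given year."""
        xy = np.asarray(xy, float)
        z = self._latents(xy)
        dt = np.asarray(year) - self.ref_year
        lat_lc = z[: self.N_LC + 1] + self._mu[:, None]
        for cls, d in self._drift.items():
            lat_lc[cls] = lat_lc[cls] + d * dt
        expz = np.exp(lat_lc - lat_lc.max(axis=0, keepdims=True))
        frac = expz / expz.sum(axis=0, keepdims=True)  # 18 rows summing to 1
        lc = frac[: self.N_LC]

        elev = 600.0 + 450.0 * z[self.N_LC + 1]
        elev = np.clip(elev, 0.0, 4000.0)
        slope = np.clip(12.0 + 9.0 * z[self.N_LC + 2], 0.0, 60.0)
        # aspect: deterministic angle field from the same latents
        theta = np.arctan2(z[self.N_LC + 2], z[self.N_LC + 1])
        out = {f"lc{i + 1:02d}": lc[i] for i in range(self.N_LC)}
        out.update(
            x=xy[:, 0], y=xy[:, 1],
            elevation=elev, slope=slope,
            aspect_sin=np.sin(theta), aspect_cos=np.cos(theta),
            urban_2500=np.clip(lc[self.URBAN_CLASSES].sum(axis=0) * 1.4, 0, 1),
            forest_2500=np.clip(lc[self.FOREST_CLASSES].sum(axis=0) * 1.4, 0, 1),
        )
        df = pd.DataFrame(out)
        df["year"] = year
        return df

    def snapshot_table(self, years: list[int] | None = None, grid_n: int = 24,
                       mask=None) -> pd.DataFrame:
        """Regional mean land-cover fractions per class per snapshot year.

        Means are taken over a regular evaluation grid, optionally
        restricted to a shapely ``mask`` polygon.
        """
        years = years if years is not None else self.region.snapshot_years
        x0, y0, x1, y1 = self.region.extent
        gx, gy = np.meshgrid(
            np.linspace(x0, x1, grid_n), np.linspace(y0, y1, grid_n)
        )
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        if mask is not None:
            from shapely import points as shp_points

            inside = np.array([mask.covers(p) for p in shp_points(pts)])
            if inside.sum() >= 3:
                pts = pts[inside]
        rows = []
        for yr in years:
            cov = self.covariates(pts, yr)
            row = {"year": yr}
            row.update({c: float(cov[c].mean()) for c in DEFAULT_LANDCOVER_COLS})
            rows.append(row)
        return pd.DataFrame(rows)


def generate_sites(
    region: RegionSpec,
    n_per_year: int,
    bias=None,
    seed: int = 0,
    landscape: SyntheticLandscape | None = None,
    candidate_factor: int = 12,
) -> tuple[pd.DataFrame, SyntheticLandscape]:
    """Place surveyed sites year by year with 500 m minimum spacing.

    ``bias`` is ``None`` (uniform sampling) or a callable
    ``bias(year, covariates_df) -> weights`` giving unnormalized sampling
    weights over candidate locations; epoch-dependent weights emulate the
    changing designs of the merged survey projects (environmental bias).

    Returns ``(sites, landscape)``: one row per site-year with all model
    covariates.  Raises if ``n_per_year`` exceeds the square-packing
    capacity of the extent at 500 m spacing or if spacing-constrained
    sampling cannot place the requested sites.
    """
    if n_per_year < 1:
        raise ValueError("n_per_year must be >= 1")
    cap = region.packing_capacity()
    if n_per_year > cap:
        raise ValueError(
            f"{n_per_year} sites per year infeasible: packing capacity of the "
            f"extent at {MIN_SPACING:.0f} m spacing is {cap}"
        )
    rng = np.random.default_rng(seed)
    if landscape is None:
        landscape = SyntheticLandscape(region, seed=int(rng.integers(2**31)))
    x0, y0, x1, y1 = region.extent

    frames = []
    counter = 0
    for year in region.survey_years:
        n_cand = max(candidate_factor * n_per_year, 200)
        xy = np.column_stack(
            [rng.uniform(x0, x1, n_cand), rng.uniform(y0, y1, n_cand)]
        )
        cov = landscape.covariates(xy, year)
        if bias is not None:
            w = np.asarray(bias(year, cov), float)
            if w.shape != (n_cand,) or np.any(w < 0) or not np.any(w > 0):
                raise ValueError("bias weights must be non-negative with a positive sum")
            p = w / w.sum()
        else:
            p = np.full(n_cand, 1.0 / n_cand)
        order = rng.choice(n_cand, size=n_cand, replace=False, p=p)
        kept: list[int] = []
        kept_xy = np.empty((0, 2))
        for idx in order:
            if len(kept) == n_per_year:
                break
            pnt = xy[idx]
            if len(kept) and np.min(np.hypot(*(kept_xy - pnt).T)) < MIN_SPACING:
                continue
            kept.append(idx)
            kept_xy = np.vstack([kept_xy, pnt])
        if len(kept) < n_per_year:
            raise ValueError(
                f"could not place {n_per_year} sites at {MIN_SPACING:.0f} m "
                f"spacing in year {year} (placed {len(kept)})"
            )
        sub = cov.iloc[kept].reset_index(drop=True)
        sub.insert(0, "site_id", [f"S{counter + i:05d}" for i in range(n_per_year)])
        counter += n_per_year
        frames.append(sub)
    return pd.concat(frames, ignore_index=True), landscape


# ---------------------------------------------------------------------------
# species simulation


@dataclass
class SpeciesSimSpec:
    """True data-generating process for one species."""

    species_id: str
    family: str = "P"  # P | NB | ZIP | ZINB
    baseline_log_mean: float = 0.0
    covariate_effects: dict = field(default_factory=dict)  # col -> callable or slope
    true_log_trend: float = 0.0
    nb_dispersion: float | None = None  # k in var = mu + mu^2/k
    zi_coefficients: tuple[float, float, float, float] | None = None
    cf: int = 1
    traits: dict | None = None
    group: str | None = None

    def __post_init__(self):
        if self.family not in ("P", "NB", "ZIP", "ZINB"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("NB", "ZINB"):
            if not (self.nb_dispersion and self.nb_dispersion > 0):
                raise ValueError("NB-type family needs nb_dispersion > 0")
        if self.family in ("ZIP", "ZINB") and self.zi_coefficients is None:
            raise ValueError("ZI family needs zi_coefficients")
        if self.cf < 1:
            raise ValueError("cf must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth captured during simulation, keyed by species."""

    true_log_trend: dict = field(default_factory=dict)
    family: dict = field(default_factory=dict)
    cf: dict = field(default_factory=dict)
    group: dict = field(default_factory=dict)
    yearly_index: dict = field(default_factory=dict)  # species -> {year: E[pairs/site]}


def _effect_value(effect, x: np.ndarray) -> np.ndarray:
    return effect(x) if callable(effect) else float(effect) * x


def _linear_predictor(spec: SpeciesSimSpec, sites: pd.DataFrame, ref_year: int):
    eta = np.full(len(sites), spec.baseline_log_mean)
    for col, eff in spec.covariate_effects.items():
        eta = eta + _effect_value(eff, sites[col].to_numpy(float))
    eta = eta + spec.true_log_trend * (sites["year"].to_numpy() - ref_year)
    return eta


def _zi_probability(spec: SpeciesSimSpec, sites: pd.DataFrame, norms) -> np.ndarray:
    c0, c_elev, c_urb, c_for = spec.zi_coefficients
    elev = (sites["elevation"].to_numpy(float) - norms["elev_mean"]) / norms["elev_sd"]
    eta = (
        c0
        + c_elev * elev
        + c_urb * sites["urban_2500"].to_numpy(float)
        + c_for * sites["forest_2500"].to_numpy(float)
    )
    return 1.0 / (1.0 + np.exp(-eta))


def simulate_counts(
    sites: pd.DataFrame,
    specs: list[SpeciesSimSpec],
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw counts for every site-year-species from each spec's family.

    The log mean is ``baseline + covariate effects + trend * (year - y0)``;
    zero-inflated families add structural zeros with a logit probability on
    (standardized elevation, urban_2500, forest_2500).  For gregarious
    species (cf > 1) the emitted ``individuals`` value is built from the
    drawn pair count as ``(pairs - 1) * cf + U{1..cf}``, so ceiling division
    by the conversion factor recovers pairs exactly.
    """
    if not specs:
        raise ValueError("specs is empty")
    rng = np.random.default_rng(seed)
    ref_year = int(sites["year"].min())
    norms = {
        "elev_mean": float(sites["elevation"].mean()),
        "elev_sd": float(sites["elevation"].std()) or 1.0,
    }
    years = np.sort(sites["year"].unique())
    truth = TruthRecord()
    frames = []
    for spec in specs:
        eta = _linear_predictor(spec, sites, ref_year)
        if not np.all(np.isfinite(eta)):
            bad = sites.loc[~np.isfinite(eta), "site_id"].iloc[0]
            raise FloatingPointError(
                f"non-finite linear predictor for species {spec.species_id!r} at site {bad!r}"
            )
        mu = np.exp(eta)
        if spec.family in ("NB", "ZINB"):
            k = spec.nb_dispersion
            lam = rng.gamma(k, mu / k)
            pairs = rng.poisson(lam)
        else:
            pairs = rng.poisson(mu)
        if spec.family in ("ZIP", "ZINB"):
            pi = _zi_probability(spec, sites, norms)
            pairs = np.where(rng.random(len(pairs)) < pi, 0, pairs)
        else:
            pi = np.zeros(len(pairs))

        if spec.cf > 1:
            extra = rng.integers(1, spec.cf + 1, size=len(pairs))
            individuals = np.where(pairs > 0, (pairs - 1) * spec.cf + extra, 0)
        else:
            individuals = pairs
        frames.append(
            pd.DataFrame(
                {
                    "site_id": sites["site_id"].to_numpy(),
                    "year": sites["year"].to_numpy(),
                    "species_id": spec.species_id,
                    "individuals": individuals.astype(np.int64),
                }
            )
        )
        # true yearly index: mean unconditional E[pairs] per site with the
        # year term set to each survey year (covariate mix held at the
        # pooled surveyed sites)
        base = eta - spec.true_log_trend * (sites["year"].to_numpy() - ref_year)
        idx = {}
        for yr in years:
            mu_y = np.exp(base + spec.true_log_trend * (yr - ref_year))
            idx[int(yr)] = float(np.mean((1.0 - pi) * mu_y))
        truth.true_log_trend[spec.species_id] = spec.true_log_trend
        truth.family[spec.species_id] = spec.family
        truth.cf[spec.species_id] = spec.cf
        truth.group[spec.species_id] = spec.group
        truth.yearly_index[spec.species_id] = idx
    counts = pd.concat(frames, ignore_index=True)
    return counts, truth


# ---------------------------------------------------------------------------
# trait table


USAGE_AXES = {
    "food_type": 6,
    "acquisition_behavior": 5,
    "substrate": 5,
    "foraging_habitat": 7,
    "nesting_habitat": 5,
}

_GROUP_COVER = {
    "farmland": "cover_agricultural",
    "woodland": "cover_forest",
    "natural open-habitat": "cover_natural_open",
    "urban": "cover_urban",
}


def random_traits(rng: np.random.Generator, group: str | None = None) -> dict:
    """One plausible raw trait row; ``group`` pins the landscape preference."""
    wing = float(rng.uniform(55, 320))
    mass = float(rng.lognormal(np.log(30), 0.8))
    clutch = float(rng.uniform(2, 8))
    broods = float(rng.integers(1, 4))
    inc = float(rng.uniform(11, 30))
    migration = str(rng.choice(["sedentary", "short-distance", "long-distance"]))
    nest = str(rng.choice(["open-arboreal", "closed-arboreal", "ground", "ground-closer", "hole"]))
    d = rng.dirichlet(np.ones(4) * 0.8)
    covers = {c: float(v) for c, v in zip(
        ["cover_urban", "cover_agricultural", "cover_forest",
         "cover_natural_open", "cover_wetland"],
        rng.dirichlet(np.ones(5)),
    )}
    if group in _GROUP_COVER:
        dominant = _GROUP_COVER[group]
        covers = {c: float(v * 0.40) for c, v in covers.items()}
        covers[dominant] = float(rng.uniform(0.55, 0.85))
    traits = {
        "wing_length": wing, "body_mass": mass, "clutch_size": clutch,
        "broods_per_year": broods, "incubation_days": inc,
        "migration": migration, "brood_parasite": False, "nest_raw": nest,
        "diet_vertebrates": float(d[0]), "diet_plants": float(d[1]),
        "diet_invertebrates": float(d[2]), "diet_other": float(d[3]),
        **covers,
    }
    for axis, k in USAGE_AXES.items():
        n_used = int(rng.integers(1, k + 1))
        used = np.zeros(k, dtype=int)
        used[rng.choice(k, size=n_used, replace=False)] = 1
        traits[f"usage_{axis}"] = used.tolist()
    return traits


def generate_trait_table(specs: list[SpeciesSimSpec], seed: int = 0) -> pd.DataFrame:
    """One row per species with its raw trait measures (pass-through).

    Missing trait values are an error: every retained species must be
    classifiable on every trait.
    """
    rows = []
    for spec in specs:
        if spec.traits is None:
            raise ValueError(f"species {spec.species_id!r} has no traits")
        missing = [c for c in TRAIT_COLUMNS if c not in spec.traits]
        missing += [f"usage_{a}" for a in USAGE_AXES if f"usage_{a}" not in spec.traits]
        if missing:
            raise ValueError(f"species {spec.species_id!r} missing traits: {missing}")
        row = {"species_id": spec.species_id, "group": spec.group}
        row.update(spec.traits)
        rows.append(row)
    return pd.DataFrame(rows)


def random_species_specs(
    n_species: int,
    seed: int = 0,
    families: list[str] | None = None,
    group_slopes: dict[str, float] | None = None,
    slope_sd: float = 0.004,
    baseline_range: tuple[float, float] = (-1.0, 0.8),
    covariate_cols: list[str] | None = None,
) -> list[SpeciesSimSpec]:
    """A community of species specs with known group-level trend structure.

    When ``group_slopes`` maps landscape groups (e.g. ``{"farmland": -0.02,
    "woodland": 0.01}``) each species in a group gets that common trend
    component plus a small species deviation (``slope_sd``); otherwise
    trends are drawn around zero.
    """
    rng = np.random.default_rng(seed)
    families = families or ["P", "NB", "ZIP", "ZINB"]
    cols = covariate_cols if covariate_cols is not None else ["lc03", "lc10", "elevation"]
    groups = list(group_slopes) if group_slopes else [None]
    specs = []
    for i in range(n_species):
        group = groups[i % len(groups)]
        fam = families[int(rng.integers(len(families)))]
        slope = (
            group_slopes[group] + rng.normal(0, slope_sd)
            if group_slopes
            else rng.normal(0, 0.01)
        )
        effects = {}
        for c in cols:
            scale = 0.001 if c == "elevation" else 1.0
            effects[c] = float(rng.normal(0, 0.4)) * scale
        zi = (
            (float(rng.normal(-0.5, 0.3)), float(rng.normal(0.5, 0.2)),
             float(rng.normal(0.5, 0.3)), float(rng.normal(-0.5, 0.3)))
            if fam in ("ZIP", "ZINB")
            else None
        )
        specs.append(
            SpeciesSimSpec(
                species_id=f"sp{i:03d}",
                family=fam,
                baseline_log_mean=float(rng.uniform(*baseline_range)),
                covariate_effects=effects,
                true_log_trend=float(slope),
                nb_dispersion=float(rng.uniform(0.8, 3.0)) if fam in ("NB", "ZINB") else None,
                zi_coefficients=zi,
                cf=int(rng.choice([1, 1, 1, 8, 11, 14])),
                traits=random_traits(rng, group),
                group=group,
            )
        )
    return specs
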
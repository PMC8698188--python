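"""Yearly population indices via parametric bootstrap.

The selected count model is evaluated on a single standardized covariate
vector per surveyed year: land-cover values follow a smooth-in-year fit to
the snapshot-map averages, topography is fixed at its overall mean and the
coordinates at the area centroid.  Covariate extraction can be masked to
the species' range, taken as the minimum convex hull (MCH) of its presence
points when the hull covers less than 80% of the region.

Uncertainty comes from a parametric bootstrap: coefficient vectors are
drawn from the asymptotic multivariate normal N(theta_hat, Sigma_hat) of
the fitted model and the unconditional expected pairs per site,
(1 - pi) * mu for zero-inflated families, is recomputed per draw and year.
The yearly index is the median of the bootstrap distribution; the 95%
confidence band is the 2.5th/97.5th percentile (type-7 interpolation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon, box

from .count_models import FittedCountModel
from .design import DEFAULT_LANDCOVER_COLS

__all__ = [
    "RangeMask",
    "compute_range_mask",
    "standardize_covariates",
    "YearlyIndexSeries",
    "bootstrap_indices",
    "MCH_AREA_RULE",
]

#: hull-to-region area ratio below which the hull masks covariate extraction
MCH_AREA_RULE = 0.80


@dataclass
class RangeMask:
    """Species range approximation from presence points."""

    species_id: str | None
    hull: Polygon
    area_ratio: float
    use_hull: bool

    @property
    def polygon(self) -> Polygon:
        """The polygon that actually masks covariate extraction."""
        return self.hull if self.use_hull else self._region

    _region: Polygon = field(default=None, repr=False)


def _region_polygon(region) -> Polygon:
    if isinstance(region, Polygon):
        return region
    x0, y0, x1, y1 = region.extent if hasattr(region, "extent") else region
    return box(x0, y0, x1, y1)


def compute_range_mask(presence_points, region, species_id=None) -> RangeMask:
    """Minimum convex hull of presence points with the 0.80 area rule.

    ``presence_points`` is an (n, 2) array or a frame with x/y columns;
    ``region`` a :class:`~avitrend.synthetic.RegionSpec`, extent tuple or
    polygon.  Fewer than 3 non-collinear points fall back to the whole
    region with a warning; no points at all is an error.
    """
    if isinstance(presence_points, pd.DataFrame):
        pts = presence_points[["x", "y"]].to_numpy(float)
    else:
        pts = np.asarray(presence_points, float)
    if pts.size == 0:
        raise ValueError(f"no presence points for species {species_id!r}")
    reg = _region_polygon(region)
    hull = MultiPoint([tuple(p) for p in np.unique(pts, axis=0)]).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        warnings.warn(
            f"degenerate presence hull for {species_id!r}; using the whole region"
        )
        mask = RangeMask(species_id, reg, 1.0, use_hull=False)
        mask._region = reg
        return mask
    ratio = hull.area / reg.area
    mask = RangeMask(species_id, hull, float(ratio), use_hull=ratio < MCH_AREA_RULE)
    mask._region = reg
    return mask


def standardize_covariates(
    snapshots: pd.DataFrame,
    survey_years: list[int],
    sites: pd.DataFrame,
    mask: RangeMask | None = None,
    max_extrapolation: float = 5.0,
) -> pd.DataFrame:
    """Standardized prediction covariates, one row per surveyed year.

    Land-cover classes are fitted as a polynomial smooth of year on the
    snapshot values (degree ``min(4, n_snapshots - 1)``), evaluated at the
    survey years and clamped to [0, 1].  Topographic covariates are the
    overall mean over (masked) sites; coordinates are the mask centroid.
    Survey years outside the snapshot span +/- ``max_extrapolation`` years
    are refused.
    """
    if len(snapshots) < 2:
        raise ValueError("need at least 2 snapshot years")
    snap_years = snapshots["year"].to_numpy(float)
    lo, hi = snap_years.min() - max_extrapolation, snap_years.max() + max_extrapolation
    for yr in survey_years:
        if not lo <= yr <= hi:
            raise ValueError(
                f"survey year {yr} outside snapshot span [{lo:.0f}, {hi:.0f}]"
            )
    masked_sites = sites
    if mask is not None and mask.use_hull:
        from shapely import points as shp_points

        xy = sites[["x", "y"]].to_numpy(float)
        inside = np.array([mask.hull.covers(p) for p in shp_points(xy)])
        if inside.sum() >= 3:
            masked_sites = sites[inside]
        else:
            warnings.warn("mask covers < 3 sites; topography uses all sites")

    deg = min(4, len(snapshots) - 1)
    yrs = np.asarray(survey_years, float)
    out = pd.DataFrame({"year": np.asarray(survey_years, int)})
    lc_cols = [c for c in snapshots.columns if c in DEFAULT_LANDCOVER_COLS]
    for c in lc_cols:
        coef = np.polyfit(snap_years, snapshots[c].to_numpy(float), deg)
        pred = np.polyval(coef, yrs)
        clipped = np.clip(pred, 0.0, 1.0)
        if np.any(pred != clipped):
            warnings.warn(f"{c}: smoothed cover outside [0, 1] clamped")
        out[c] = clipped
    for c in ("elevation", "slope", "aspect_sin", "aspect_cos",
              "urban_2500", "forest_2500"):
        if c in masked_sites.columns:
            out[c] = float(masked_sites[c].mean())
    centroid = (mask.polygon if mask is not None else _region_polygon(
        (sites["x"].min(), sites["y"].min(), sites["x"].max(), sites["y"].max())
    )).centroid
    out["x"] = centroid.x
    out["y"] = centroid.y
    return out


@dataclass
class YearlyIndexSeries:
    """Per-year median population index with a 95% percentile band."""

    species_id: str | None
    table: pd.DataFrame  # columns: year, median, lo, hi, ci_width

    @property
    def years(self) -> np.ndarray:
        return self.table["year"].to_numpy()


def _nearest_psd(cov: np.ndarray, rel_fail: float = 0.1):
    """Clip negative eigenvalues; fail if the repair is large."""
    cov = (cov + cov.T) / 2.0
    w, v = np.linalg.eigh(cov)
    wmax = float(w.max()) if w.size else 0.0
    if w.min() >= -1e-10 * max(wmax, 1.0):
        return cov, False
    if w.min() < -rel_fail * max(wmax, 1e-300):
        raise ValueError("coefficient covariance is far from positive semidefinite")
    warnings.warn("coefficient covariance repaired to nearest PSD")
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T, True


def bootstrap_indices(
    fit: FittedCountModel,
    std_cov: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
) -> YearlyIndexSeries:
    """Parametric-bootstrap yearly index series for one fitted model.

    Draws ``B`` coefficient vectors from N(theta_hat, Sigma_hat) and
    evaluates the unconditional expected pairs per site at the standardized
    covariates of every surveyed year.  With a zero covariance the band
    collapses onto the point prediction.
    """
    if not fit.converged:
        raise ValueError("refusing to bootstrap a non-converged fit")
    X = fit.design.count_matrix(std_cov)
    Z = fit.design.zero_matrix(std_cov) if fit.is_zero_inflated else None
    theta = fit.params.to_numpy()
    cov, _ = _nearest_psd(fit.cov.to_numpy())
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(theta, cov, size=B, method="svd")
    preds = np.empty((B, len(std_cov)))
    for b in range(B):
        preds[b] = fit.predict_mean(X, Z, params=draws[b])
    med = np.percentile(preds, 50, axis=0)
    lo = np.percentile(preds, 2.5, axis=0)
    hi = np.percentile(preds, 97.5, axis=0)
    table = pd.DataFrame(
        {
            "year": std_cov["year"].to_numpy(int),
            "median": med,
            "lo": lo,
            "hi": hi,
            "ci_width": hi - lo,
        }
    )
    return YearlyIndexSeries(species_id=fit.species_id, table=table)
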
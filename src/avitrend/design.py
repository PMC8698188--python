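"""Fixed-df spline design matrices for the count models.

The candidate models are GAM-style regressions with a log link: survey year
enters as a categorical factor (first surveyed year as reference), each
continuous environmental covariate through a fixed-df cubic regression
spline basis (df <= 4, knots at covariate quantiles), aspect sine/cosine as
plain linear terms, and a tensor-product smooth in the planar (x, y)
coordinates for the residual spatial trend.  Zero-inflated families add a
second (logit) design for the structural-zero probability built from
landscape-scale covariates.

Bases are unpenalized, so maximum likelihood, AIC parameter counts and the
coefficient covariance are all standard.  A fitted :class:`ModelDesign`
stores its knots, factor levels and the surviving (non-aliased) columns and
can reproduce the exact same matrix for new covariate tables, which is what
the bootstrap prediction step requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "ModelDesign", "DEFAULT_LANDCOVER_COLS"]

DEFAULT_LANDCOVER_COLS = [f"lc{i:02d}" for i in range(1, 18)]


@dataclass
class SplineBasis:
    """Cubic B-spline basis with fixed df and quantile interior knots.

    The full basis on ``df - 3`` interior knots has ``df + 1`` columns; the
    first is dropped so the basis is identifiable next to a model intercept
    while still spanning cubic polynomials (for df >= 3... df=4 spans
    cubics exactly together with the intercept).
    """

    name: str
    df: int
    knots: np.ndarray  # full knot vector (boundary knots repeated 4x)

    @classmethod
    def fit(cls, x: np.ndarray, name: str, df: int = 4) -> "SplineBasis":
        if df < 3:
            raise ValueError("cubic basis needs df >= 3")
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            raise ValueError(f"covariate {name!r} is constant")
        n_interior = df - 3
        if n_interior:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(x, qs)
            # quantile ties collapse to boundary-adjacent knots
            interior = np.clip(interior, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
        else:
            interior = np.array([])
        t = np.concatenate([[lo] * 4, interior, [hi] * 4])
        return cls(name=name, df=df, knots=t)

    def transform(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.knots[0], self.knots[-1]
        xc = np.clip(np.asarray(x, float), lo, hi)
        full = BSpline.design_matrix(xc, self.knots, 3).toarray()
        return full[:, 1:]

    @property
    def column_names(self) -> list[str]:
        return [f"s({self.name}).{j}" for j in range(1, self.df + 1)]


def _tensor_basis(bx: np.ndarray, by: np.ndarray, names_x, names_y):
    cols, names = [], []
    for i, nx in enumerate(names_x):
        for j, ny in enumerate(names_y):
            cols.append(bx[:, i] * by[:, j])
            names.append(f"te({nx},{ny})")
    return np.column_stack(cols), names


@dataclass
class ModelDesign:
    """Deterministic covariate-table -> design-matrix mapping.

    Parameters are established by :meth:`build` on the fitting data; the
    resulting object transforms any covariate table with the same columns
    (used for the standardized prediction matrix).
    """

    smooth_cols: list = field(default_factory=list)
    smooth_df: int = 4
    spatial_df: int = 3
    linear_cols: list = field(default_factory=lambda: ["aspect_sin", "aspect_cos"])
    zero_cols: list = field(default_factory=lambda: ["elevation", "urban_2500", "forest_2500"])
    include_spatial: bool = True

    # fitted state
    year_levels: list = field(default_factory=list, repr=False)
    _bases: dict = field(default_factory=dict, repr=False)
    _zero_bases: dict = field(default_factory=dict, repr=False)
    _spatial: tuple | None = field(default=None, repr=False)
    _keep_count: np.ndarray | None = field(default=None, repr=False)
    _keep_zero: np.ndarray | None = field(default=None, repr=False)
    count_names: list = field(default_factory=list, repr=False)
    zero_names: list = field(default_factory=list, repr=False)
    dropped_columns: list = field(default_factory=list, repr=False)

    @classmethod
    def build(
        cls,
        sites: pd.DataFrame,
        smooth_cols: list | None = None,
        smooth_df: int = 4,
        spatial_df: int = 3,
        linear_cols: list | None = None,
        zero_cols: list | None = None,
        include_spatial: bool = True,
    ) -> "ModelDesign":
        """Construct and freeze a design from the fitting covariate table."""
        if smooth_cols is None:
            smooth_cols = [
                c
                for c in DEFAULT_LANDCOVER_COLS + ["elevation", "slope"]
                if c in sites.columns
            ]
        self = cls(
            smooth_cols=list(smooth_cols),
            smooth_df=smooth_df,
            spatial_df=spatial_df,
            linear_cols=list(linear_cols) if linear_cols is not None else ["aspect_sin", "aspect_cos"],
            zero_cols=list(zero_cols) if zero_cols is not None else ["elevation", "urban_2500", "forest_2500"],
            include_spatial=include_spatial,
        )
        years = sorted(pd.unique(sites["year"]))
        if len(years) < 2:
            raise ValueError("need at least 2 distinct survey years")
        self.year_levels = [int(y) for y in years]

        for c in self.smooth_cols:
            try:
                self._bases[c] = SplineBasis.fit(sites[c].to_numpy(float), c, smooth_df)
            except ValueError:
                warnings.warn(f"covariate {c!r} is constant; smooth dropped")
        self.linear_cols = [c for c in self.linear_cols if c in sites.columns]
        if self.include_spatial:
            self._spatial = (
                SplineBasis.fit(sites["x"].to_numpy(float), "x", spatial_df),
                SplineBasis.fit(sites["y"].to_numpy(float), "y", spatial_df),
            )
        for c in self.zero_cols:
            try:
                self._zero_bases[c] = SplineBasis.fit(sites[c].to_numpy(float), c, smooth_df)
            except ValueError:
                warnings.warn(f"zero-part covariate {c!r} is constant; smooth dropped")

        # rank screen on the training matrices (pivoted QR); surviving
        # columns are frozen so prediction uses the identical reduced design
        X, xnames = self._raw_count_matrix(sites)
        self._keep_count, dropped = _full_rank_columns(X, xnames)
        self.count_names = [xnames[i] for i in self._keep_count]
        Z, znames = self._raw_zero_matrix(sites)
        self._keep_zero, zdropped = _full_rank_columns(Z, znames)
        self.zero_names = [znames[i] for i in self._keep_zero]
        self.dropped_columns = dropped + zdropped
        if self.dropped_columns:
            warnings.warn(f"dropped aliased design columns: {self.dropped_columns}")
        return self

    # -- matrix assembly ---------------------------------------------------
    def _raw_count_matrix(self, df: pd.DataFrame):
        n = len(df)
        cols = [np.ones(n)]
        names = ["Intercept"]
        yr = df["year"].to_numpy()
        for lev in self.year_levels[1:]:
            cols.append((yr == lev).astype(float))
            names.append(f"year[{lev}]")
        for c, basis in self._bases.items():
            cols.append(basis.transform(df[c].to_numpy(float)))
            names.extend(basis.column_names)
        for c in self.linear_cols:
            cols.append(df[c].to_numpy(float))
            names.append(c)
        if self._spatial is not None:
            bx, by = self._spatial
            tb, tn = _tensor_basis(
                bx.transform(df["x"].to_numpy(float)),
                by.transform(df["y"].to_numpy(float)),
                bx.column_names,
                by.column_names,
            )
            cols.append(tb)
            names.extend(tn)
        X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
        return X, names

    def _raw_zero_matrix(self, df: pd.DataFrame):
        n = len(df)
        cols = [np.ones(n)]
        names = ["zi.Intercept"]
        for c, basis in self._zero_bases.items():
            cols.append(basis.transform(df[c].to_numpy(float)))
            names.extend([f"zi.{nm}" for nm in basis.column_names])
        Z = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
        return Z, names

    def count_matrix(self, df: pd.DataFrame) -> np.ndarray:
        X, _ = self._raw_count_matrix(df)
        return X[:, self._keep_count]

    def zero_matrix(self, df: pd.DataFrame) -> np.ndarray:
        Z, _ = self._raw_zero_matrix(df)
        return Z[:, self._keep_zero]


def _full_rank_columns(X: np.ndarray, names: list):
    """Indices of a maximal full-rank column subset (pivoted QR), original order."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    dropped = [names[i] for i in sorted(set(range(X.shape[1])) - set(keep.tolist()))]
    return keep, dropped
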
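"""Survey-table preprocessing.

Point-count surveys record the number of *individuals* detected per site,
year and species.  For gregarious species detected in family groups, raw
individual counts overestimate the number of breeding pairs, so counts are
converted to pairs with a species conversion factor (CF): 1..CF individuals
count as one pair, CF+1..2*CF as two, and so on (ceiling division).  Rare
species are dropped by an overall relative-frequency filter before trend
modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "apply_conversion_factors",
    "filter_species_by_frequency",
    "validate_survey",
    "ValidationReport",
    "MIN_SITE_SPACING_M",
]

#: minimum within-year distance between sampling locations (metres)
MIN_SITE_SPACING_M = 500.0


def apply_conversion_factors(
    counts: pd.DataFrame, cf_map: dict[str, int] | None = None
) -> pd.DataFrame:
    """Convert individual counts to breeding pairs.

    Parameters
    ----------
    counts
        Table with columns ``site_id``, ``year``, ``species_id``,
        ``individuals`` (non-negative integers).
    cf_map
        Mapping ``species_id -> conversion factor`` (positive integer:
        the number of individuals considered one breeding pair).  Species
        not in the map use CF = 1.

    Returns
    -------
    A copy of ``counts`` with a ``pairs`` column:
    ``pairs = ceil(individuals / CF)``.
    """
    cf_map = cf_map or {}
    for sp, cf in cf_map.items():
        if not (isinstance(cf, (int, np.integer)) and cf >= 1):
            raise ValueError(f"conversion factor for {sp!r} must be a positive integer, got {cf!r}")

    ind = counts["individuals"].to_numpy()
    if not np.issubdtype(ind.dtype, np.integer):
        as_int = ind.astype(np.int64, casting="unsafe")
        if not np.all(as_int == ind):
            raise ValueError("individuals must be integers")
        ind = as_int
    if np.any(ind < 0):
        raise ValueError("individuals must be non-negative")

    cf = counts["species_id"].map(lambda s: cf_map.get(s, 1)).to_numpy(dtype=np.int64)
    out = counts.copy()
    out["pairs"] = -(-ind // cf)  # ceiling division
    return out


def filter_species_by_frequency(
    counts: pd.DataFrame, site_total: int, threshold: float = 0.02
) -> list:
    """Species with overall relative frequency strictly above ``threshold``.

    Relative frequency is presence/absence based: the number of point counts
    at which the species was detected (pairs > 0, or individuals > 0 when no
    ``pairs`` column exists) divided by ``site_total``, the total number of
    distinct point counts in the dataset.  The comparison is strict
    (frequency *higher than* the threshold), so a species sitting exactly on
    the boundary is excluded.
    """
    if site_total <= 0:
        raise ValueError("site_total must be a positive integer")
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    col = "pairs" if "pairs" in counts.columns else "individuals"
    present = counts[counts[col] > 0]
    n_present = (
        present.drop_duplicates(["species_id", "site_id", "year"])
        .groupby("species_id")
        .size()
    )
    freq = n_present / site_total
    return sorted(freq.index[freq > threshold].tolist())


@dataclass
class ValidationReport:
    """Outcome of referential/spacing checks on a survey table."""

    spacing_warnings: list = field(default_factory=list)
    empty_years: list = field(default_factory=list)
    n_counts: int = 0
    n_sites: int = 0

    @property
    def ok(self) -> bool:
        return not self.spacing_warnings and not self.empty_years


def validate_survey(counts: pd.DataFrame, sites: pd.DataFrame) -> ValidationReport:
    """Check a count table against its site table.

    Unknown ``site_id`` references in ``counts`` are an error.  Within-year
    site pairs closer than :data:`MIN_SITE_SPACING_M` and surveyed years with
    no count records are reported as warnings in the returned
    :class:`ValidationReport` (real-world tables are accepted as-is).
    """
    known = set(zip(sites["site_id"], sites["year"]))
    refs = set(zip(counts["site_id"], counts["year"]))
    orphans = refs - known
    if orphans:
        raise ValueError(f"counts reference unknown site-years: {sorted(orphans)[:5]}")

    report = ValidationReport(n_counts=len(counts), n_sites=len(sites))

    for year, grp in sites.groupby("year"):
        xy = grp[["x", "y"]].to_numpy(float)
        ids = grp["site_id"].to_numpy()
        if len(xy) < 2:
            continue
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(xy))
        iu = np.triu_indices(len(xy), k=1)
        close = d[iu] < MIN_SITE_SPACING_M
        for i, j in zip(iu[0][close], iu[1][close]):
            report.spacing_warnings.append((int(year), ids[i], ids[j], float(d[i, j])))

    years_with_data = set(counts["year"].unique())
    report.empty_years = sorted(set(sites["year"].unique()) - years_with_data)
    return report
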
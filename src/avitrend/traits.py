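"""Life-history and ecological trait derivation.

Eight traits per species feed the functional-group analysis:

* migration strategy (sedentary / short-distance / long-distance);
* dispersal ratio DR = wing length [mm] / cube root of body mass [g],
  a mobility surrogate;
* annual fecundity AF = mean clutch size x mean broods per year
  (brood parasites are forced to one brood);
* incubation period IP = mean incubation duration in days;
* diet class by the 70% rule over diet fractions (scavenging counts
  toward vertebrates);
* nest type reclassified to elevated- / ground- / hole-nesters;
* landscape type by the strict >50% median-cover rule
  (farmland / woodland / natural open-habitat / several);
* overall specialization index SI: the mean of five single-axis
  specialization indices (SSI), each the coefficient of variation of a
  binary resource-usage vector across that axis's categories.

Numeric traits (DR, AF, IP, SI) are discretized into low / intermediate /
high classes by the first and third quartiles across the analyzed species
(type-7 quantiles; the boundary values are inclusive).  Trait pairs are
screened for redundancy with Cramer's V (chi-square, or Fisher's exact
test for 2x2 tables with small expected counts).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "derive_numeric_traits",
    "categorize_by_quartiles",
    "assign_diet",
    "assign_nest_type",
    "assign_landscape_type",
    "compute_specialization",
    "derive_trait_table",
    "screen_trait_associations",
    "cramers_v",
    "REFERENCE_QUARTILES",
]

#: the study's published quartile cut-offs, shipped as reference constants
REFERENCE_QUARTILES = {
    "dispersal_ratio": (28.278, 33.737),
    "annual_fecundity": (5.0, 10.625),
    "incubation_period": (13.0, 17.25),
}

DIET_THRESHOLD = 0.70
LANDSCAPE_THRESHOLD = 0.50

_NEST_MAP = {
    "open-arboreal": "elevated-nesters",
    "closed-arboreal": "elevated-nesters",
    "ground": "ground-nesters",
    "ground-closer": "ground-nesters",
    "hole": "hole-nesters",
}

_LANDSCAPE_MAP = {
    "cover_agricultural": "farmland",
    "cover_forest": "woodland",
    "cover_natural_open": "natural open-habitat",
}


def derive_numeric_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """DR, AF and IP from raw measures (one row per species)."""
    for col in ("wing_length", "body_mass", "clutch_size", "broods_per_year",
                "incubation_days"):
        vals = raw[col].to_numpy(float)
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError(f"non-positive or missing values in {col!r}")
    broods = raw["broods_per_year"].to_numpy(float).copy()
    if "brood_parasite" in raw.columns:
        broods[raw["brood_parasite"].astype(bool).to_numpy()] = 1.0
    out = pd.DataFrame(index=raw.index)
    if "species_id" in raw.columns:
        out["species_id"] = raw["species_id"]
    out["dispersal_ratio"] = raw["wing_length"] / np.cbrt(raw["body_mass"])
    out["annual_fecundity"] = raw["clutch_size"].to_numpy(float) * broods
    out["incubation_period"] = raw["incubation_days"].astype(float)
    return out


def categorize_by_quartiles(
    values, labels: tuple[str, str, str] = ("low", "intermediate", "high"),
    quartiles: tuple[float, float] | None = None,
):
    """low if value <= Q1, high if value >= Q3, else intermediate.

    Quartiles are type-7 (linear interpolation) over all analyzed species
    unless supplied explicitly (e.g. the published cut-offs).  Returns
    ``(classes, (q1, q3))``.
    """
    vals = np.asarray(values, float)
    if quartiles is None:
        if vals.size < 4:
            raise ValueError("need at least 4 species to form quartiles")
        q1, q3 = np.quantile(vals, [0.25, 0.75])
    else:
        q1, q3 = quartiles
    if q1 == q3:
        warnings.warn("degenerate quartiles: all values in the low class")
    classes = np.where(vals <= q1, labels[0], np.where(vals >= q3, labels[2], labels[1]))
    out = pd.Series(classes, index=getattr(values, "index", None))
    return out, (float(q1), float(q3))


def assign_diet(fractions: dict, tol: float = 1e-6) -> str:
    """70% rule over {vertebrates, plants, invertebrates, other} fractions."""
    keys = ("vertebrates", "plants", "invertebrates", "other")
    fr = {k: float(fractions[k]) for k in keys}
    total = sum(fr.values())
    if abs(total - 1.0) > tol:
        raise ValueError(f"diet fractions sum to {total}, not 1")
    if fr["vertebrates"] >= DIET_THRESHOLD:   # scavenging counts here
        return "vertebrates"
    if fr["plants"] >= DIET_THRESHOLD:
        return "plant-eaters"
    if fr["invertebrates"] >= DIET_THRESHOLD:
        return "invertebrates"
    return "omnivores"


def assign_nest_type(nest_raw: str) -> str:
    try:
        return _NEST_MAP[nest_raw]
    except KeyError:
        raise ValueError(f"unknown nest category {nest_raw!r}") from None


def assign_landscape_type(cover_medians: dict) -> str:
    """The unique landscape level whose median cover exceeds 50% (strict)."""
    above = {k: v for k, v in cover_medians.items() if v > LANDSCAPE_THRESHOLD}
    if len(above) > 1:
        raise AssertionError("two cover medians above 0.5 cannot both hold")
    if not above:
        return "several"
    key = next(iter(above))
    return _LANDSCAPE_MAP.get(key, "several")


def _ssi(usage: np.ndarray) -> float:
    """Coefficient of variation (population SD / mean) of binary usage."""
    u = np.asarray(usage, float)
    if u.size < 2:
        raise ValueError("axis needs at least 2 categories")
    if not u.any():
        raise ValueError("species uses no category on an axis")
    return float(np.std(u) / np.mean(u))


def compute_specialization(usage_vectors: dict) -> tuple[dict, float]:
    """Per-axis SSI and the overall SI (their mean) for one species.

    A species using all K categories of an axis scores SSI = 0 (complete
    generalist); using a single category scores sqrt(K - 1).
    """
    ssi = {axis: _ssi(vec) for axis, vec in usage_vectors.items()}
    return ssi, float(np.mean(list(ssi.values())))


def derive_trait_table(
    raw: pd.DataFrame,
    quartiles: dict | None = None,
) -> pd.DataFrame:
    """Full derived-trait table: 8 categorical traits per species.

    ``raw`` is one row per species with the measures produced by the
    synthetic generator (or transcribed from handbooks): wing/mass/clutch/
    broods/incubation, migration, diet fractions ``diet_*``, ``nest_raw``,
    landscape cover medians ``cover_*`` and binary ``usage_<axis>`` lists.
    ``quartiles`` optionally pins the DR/AF/IP/SI cut-offs (e.g. the
    published values) instead of recomputing them from the table.
    """
    quartiles = quartiles or {}
    num = derive_numeric_traits(raw)
    out = num.copy()
    out["migration"] = raw["migration"].to_numpy()
    for trait, labels in (
        ("dispersal_ratio", ("low dispersal ratio", "intermediate dispersal ratio", "high dispersal ratio")),
        ("annual_fecundity", ("low annual fecundity", "intermediate annual fecundity", "high annual fecundity")),
        ("incubation_period", ("short incubation period", "intermediate incubation period", "long incubation period")),
    ):
        cls, qq = categorize_by_quartiles(
            out[trait], labels, quartiles.get(trait)
        )
        out[trait + "_class"] = cls.to_numpy()
    out["diet_class"] = [
        assign_diet(
            {
                "vertebrates": r["diet_vertebrates"],
                "plants": r["diet_plants"],
                "invertebrates": r["diet_invertebrates"],
                "other": r["diet_other"],
            }
        )
        for _, r in raw.iterrows()
    ]
    out["nest_class"] = [assign_nest_type(v) for v in raw["nest_raw"]]
    cover_cols = [c for c in raw.columns if c.startswith("cover_")]
    out["landscape_class"] = [
        assign_landscape_type({c: r[c] for c in cover_cols}) for _, r in raw.iterrows()
    ]
    usage_cols = [c for c in raw.columns if c.startswith("usage_")]
    si = []
    for _, r in raw.iterrows():
        _, overall = compute_specialization({c: np.asarray(r[c]) for c in usage_cols})
        si.append(overall)
    out["specialization_index"] = si
    cls, _ = categorize_by_quartiles(
        out["specialization_index"],
        ("generalist", "intermediate", "specialist"),
        quartiles.get("specialization_index"),
    )
    out["specialization_class"] = cls.to_numpy()
    return out


def cramers_v(table: np.ndarray) -> float:
    """Cramer's V of a contingency table (chi-square without correction)."""
    table = np.asarray(table, float)
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    n = table.sum()
    r, c = table.shape
    denom = n * (min(r, c) - 1)
    return float(np.sqrt(chi2 / denom)) if denom > 0 else float("nan")


def screen_trait_associations(
    trait_table: pd.DataFrame,
    columns: list[str] | None = None,
    v_cut: float = 0.5,
    alpha: float = 0.05,
    drop: list[str] | None = None,
) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Pairwise association screen over categorical traits.

    For every pair: contingency table, chi-square test of independence
    (Fisher's exact test for 2x2 tables with any expected cell < 5) and
    Cramer's V.  Pairs that are significantly associated with V >= ``v_cut``
    are flagged; flagged traits are dropped either from the explicit
    ``drop`` list or, by default, the member of each flagged pair with the
    higher mean V across all pairs.

    Returns ``(retained_traits, v_matrix, report)``.
    """
    cols = columns or [
        c for c in trait_table.columns
        if trait_table[c].dtype == object and trait_table[c].nunique() > 1
    ]
    single = [c for c in (columns or []) if trait_table[c].nunique() < 2]
    if single:
        warnings.warn(f"traits with a single level excluded from screening: {single}")
        cols = [c for c in cols if c not in single]
    if len(cols) < 2:
        raise ValueError("need at least 2 categorical traits to screen")

    V = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    records = []
    flagged_pairs = []
    for a, b in itertools.combinations(cols, 2):
        tab = pd.crosstab(trait_table[a], trait_table[b]).to_numpy()
        v = cramers_v(tab)
        expected = stats.contingency.expected_freq(tab)
        if tab.shape == (2, 2) and (expected < 5).any():
            test = "fisher"
            p = float(stats.fisher_exact(tab)[1])
        else:
            test = "chi2"
            if (expected < 5).any() and tab.shape != (2, 2):
                test = "chi2 (small expected counts)"
            p = float(stats.chi2_contingency(tab, correction=False)[1])
        flag = p <= alpha and v >= v_cut
        V.loc[a, b] = V.loc[b, a] = v
        records.append(
            {"trait_a": a, "trait_b": b, "cramers_v": v, "test": test,
             "p_value": p, "flagged": flag}
        )
        if flag:
            flagged_pairs.append((a, b))
    report = pd.DataFrame(records)

    if drop is not None:
        to_drop = set(drop)
    else:
        to_drop = set()
        mean_v = (V.sum(axis=1) - 1.0) / (len(cols) - 1)
        for a, b in flagged_pairs:
            if a in to_drop or b in to_drop:
                continue
            to_drop.add(a if mean_v[a] >= mean_v[b] else b)
    retained = [c for c in cols if c not in to_drop]
    return retained, V, report
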
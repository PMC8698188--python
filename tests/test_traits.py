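"""Trait derivation, specialization index and the association screen."""

import numpy as np
import pandas as pd
import pytest

from avitrend.traits import (
    REFERENCE_QUARTILES,
    assign_diet,
    assign_landscape_type,
    assign_nest_type,
    categorize_by_quartiles,
    compute_specialization,
    cramers_v,
    derive_numeric_traits,
    derive_trait_table,
    screen_trait_associations,
)


class TestNumericTraits:
    def test_dispersal_ratio_cube_root(self):
        raw = pd.DataFrame({
            "wing_length": [100.0], "body_mass": [27.0], "clutch_size": [4.0],
            "broods_per_year": [1.0], "incubation_days": [14.0],
        })
        out = derive_numeric_traits(raw)
        assert out["dispersal_ratio"].iloc[0] == pytest.approx(100.0 / 3.0)

    def test_annual_fecundity_product(self):
        raw = pd.DataFrame({
            "wing_length": [80.0], "body_mass": [20.0], "clutch_size": [5.0],
            "broods_per_year": [2.0], "incubation_days": [12.0],
        })
        assert derive_numeric_traits(raw)["annual_fecundity"].iloc[0] == 10.0

    def test_brood_parasite_forced_to_one_brood(self):
        raw = pd.DataFrame({
            "wing_length": [220.0], "body_mass": [110.0], "clutch_size": [9.0],
            "broods_per_year": [3.0], "incubation_days": [12.0],
            "brood_parasite": [True],
        })
        assert derive_numeric_traits(raw)["annual_fecundity"].iloc[0] == 9.0

    def test_non_positive_rejected(self):
        raw = pd.DataFrame({
            "wing_length": [0.0], "body_mass": [20.0], "clutch_size": [5.0],
            "broods_per_year": [2.0], "incubation_days": [12.0],
        })
        with pytest.raises(ValueError, match="wing_length"):
            derive_numeric_traits(raw)


class TestQuartileCategories:
    def test_published_cutoffs_boundaries_inclusive(self):
        """<= Q1 is low and >= Q3 is high with the published cut-offs."""
        classes, _ = categorize_by_quartiles(
            pd.Series([28.0, 28.278, 30.0, 33.737, 35.0]),
            quartiles=REFERENCE_QUARTILES["dispersal_ratio"],
        )
        assert classes.tolist() == ["low", "low", "intermediate", "high", "high"]
        af, _ = categorize_by_quartiles(
            pd.Series([10.625]), quartiles=REFERENCE_QUARTILES["annual_fecundity"]
        )
        assert af.iloc[0] == "high"

    def test_quantile_oracle_on_1_to_100(self):
        classes, (q1, q3) = categorize_by_quartiles(np.arange(1, 101, dtype=float))
        counts = pd.Series(classes).value_counts()
        assert q1 == pytest.approx(np.quantile(np.arange(1, 101), 0.25))
        assert counts["low"] == 25
        assert counts["high"] == 25
        assert counts["intermediate"] == 50

    def test_degenerate_values_all_low(self):
        with pytest.warns(UserWarning, match="degenerate"):
            classes, _ = categorize_by_quartiles(np.ones(10))
        assert set(classes) == {"low"}


class TestDietAndHabitat:
    @pytest.mark.parametrize(
        "fracs,expected",
        [
            ({"vertebrates": 0.0, "plants": 0.1, "invertebrates": 0.75, "other": 0.15}, "invertebrates"),
            ({"vertebrates": 0.1, "plants": 0.6, "invertebrates": 0.3, "other": 0.0}, "omnivores"),
            ({"vertebrates": 0.70, "plants": 0.1, "invertebrates": 0.2, "other": 0.0}, "vertebrates"),
            ({"vertebrates": 0.0, "plants": 0.85, "invertebrates": 0.1, "other": 0.05}, "plant-eaters"),
        ],
    )
    def test_diet_70_percent_rule(self, fracs, expected):
        assert assign_diet(fracs) == expected

    def test_diet_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            assign_diet({"vertebrates": 0.5, "plants": 0.1,
                         "invertebrates": 0.1, "other": 0.1})

    @pytest.mark.parametrize(
        "nest,expected",
        [
            ("open-arboreal", "elevated-nesters"),
            ("closed-arboreal", "elevated-nesters"),
            ("ground", "ground-nesters"),
            ("ground-closer", "ground-nesters"),
            ("hole", "hole-nesters"),
        ],
    )
    def test_nest_reclassification(self, nest, expected):
        assert assign_nest_type(nest) == expected

    @pytest.mark.parametrize(
        "medians,expected",
        [
            ({"cover_forest": 0.6, "cover_agricultural": 0.2}, "woodland"),
            ({"cover_forest": 0.4, "cover_agricultural": 0.45}, "several"),
            ({"cover_agricultural": 0.50, "cover_forest": 0.3}, "several"),  # strict
            ({"cover_agricultural": 0.51}, "farmland"),
            ({"cover_natural_open": 0.7}, "natural open-habitat"),
        ],
    )
    def test_landscape_50_percent_rule(self, medians, expected):
        assert assign_landscape_type(medians) == expected


class TestSpecialization:
    def test_full_generalist_is_zero(self):
        ssi, si = compute_specialization({"a": np.ones(5), "b": np.ones(3)})
        assert ssi == {"a": 0.0, "b": 0.0}
        assert si == 0.0

    @pytest.mark.parametrize("k", [2, 4, 7])
    def test_single_category_closed_form(self, k):
        """Using 1 of K categories gives SSI = sqrt(K - 1)."""
        u = np.zeros(k)
        u[0] = 1
        ssi, _ = compute_specialization({"axis": u})
        assert ssi["axis"] == pytest.approx(np.sqrt(k - 1))

    def test_si_is_mean_of_axes(self):
        usage = {f"ax{i}": np.ones(3) for i in range(4)}
        u = np.zeros(26)
        u[0] = 1  # SSI = 5
        usage["ax4"] = u
        _, si = compute_specialization(usage)
        assert si == pytest.approx(1.0)

    def test_permutation_invariance(self):
        u = np.array([1, 0, 1, 0, 0])
        s1, _ = compute_specialization({"a": u})
        s2, _ = compute_specialization({"a": u[::-1]})
        assert s1["a"] == pytest.approx(s2["a"])

    def test_zero_usage_rejected(self):
        with pytest.raises(ValueError, match="no category"):
            compute_specialization({"a": np.zeros(4)})


class TestAssociationScreen:
    def test_hand_computed_2x2(self):
        """[[8,2],[2,8]]: chi2 = 7.2, n = 20, V = 0.6 (all expected = 5)."""
        assert cramers_v([[8, 2], [2, 8]]) == pytest.approx(0.6)

    def test_chi2_path_for_expected_at_least_5(self):
        df = pd.DataFrame({
            "t1": ["a"] * 10 + ["b"] * 10,
            "t2": ["x"] * 8 + ["y"] * 2 + ["x"] * 2 + ["y"] * 8,
        })
        retained, V, report = screen_trait_associations(df, columns=["t1", "t2"])
        row = report.iloc[0]
        assert row["test"] == "chi2"
        assert row["cramers_v"] == pytest.approx(0.6)

    def test_fisher_for_small_expected_2x2(self):
        df = pd.DataFrame({
            "t1": ["a"] * 4 + ["b"] * 4,
            "t2": ["x", "x", "x", "y", "y", "y", "y", "x"],
        })
        _, _, report = screen_trait_associations(df, columns=["t1", "t2"])
        assert report.iloc[0]["test"] == "fisher"

    def test_duplicated_trait_flagged(self):
        rng = np.random.default_rng(3)
        t = rng.choice(["a", "b", "c"], 60)
        df = pd.DataFrame({"t1": t, "t2": t, "t3": rng.choice(["x", "y"], 60)})
        retained, V, report = screen_trait_associations(df)
        assert V.loc["t1", "t2"] == pytest.approx(1.0)
        pair = report[(report.trait_a == "t1") & (report.trait_b == "t2")]
        assert bool(pair["flagged"].iloc[0])
        assert ("t1" in retained) != ("t2" in retained)  # exactly one dropped

    def test_independent_traits_retained(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({
            "t1": rng.choice(["a", "b", "c"], 500),
            "t2": rng.choice(["x", "y"], 500),
        })
        retained, V, report = screen_trait_associations(df)
        assert V.loc["t1", "t2"] < 0.15
        assert retained == ["t1", "t2"]

    def test_v_matrix_symmetric_in_unit_interval(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({
            "t1": rng.choice(["a", "b"], 100),
            "t2": rng.choice(["x", "y", "z"], 100),
            "t3": rng.choice(["u", "v"], 100),
        })
        _, V, _ = screen_trait_associations(df)
        assert np.allclose(V.to_numpy(), V.to_numpy().T)
        assert ((V.to_numpy() >= -1e-12) & (V.to_numpy() <= 1 + 1e-12)).all()


class TestDeriveTraitTable:
    def test_each_species_gets_one_level_per_trait(self):
        from avitrend.synthetic import random_species_specs, generate_trait_table

        specs = random_species_specs(
            24, seed=3, group_slopes={"farmland": -0.02, "woodland": 0.01}
        )
        raw = generate_trait_table(specs)
        derived = derive_trait_table(raw)
        for col in ("migration", "dispersal_ratio_class", "annual_fecundity_class",
                    "incubation_period_class", "diet_class", "nest_class",
                    "landscape_class", "specialization_class"):
            assert derived[col].notna().all()
        # pinned group covers map onto the right landscape class
        farm = raw["group"] == "farmland"
        assert (derived.loc[farm, "landscape_class"] == "farmland").all()
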
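"""Synthetic survey generator: placement, count processes, traits, truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from avitrend.synthetic import (
    RegionSpec,
    SpeciesSimSpec,
    SyntheticLandscape,
    generate_sites,
    generate_trait_table,
    random_species_specs,
    simulate_counts,
)


class TestSitePlacement:
    def test_uniform_sampling_counts_and_spacing(self, small_sites, small_region):
        sites, _ = small_sites
        assert len(sites) == 60 * len(small_region.survey_years)
        for _, grp in sites.groupby("year"):
            assert pdist(grp[["x", "y"]].to_numpy()).min() >= 500.0

    def test_uniform_sampling_has_stable_covariate_means(self, small_sites):
        """Without bias the surveyed covariate distribution is year-stationary."""
        sites, _ = small_sites
        yearly = sites.groupby("year")["forest_2500"].mean()
        overall_sd = sites["forest_2500"].std() / np.sqrt(60)
        assert yearly.max() - yearly.min() < 6 * overall_sd

    def test_forest_bias_shifts_surveyed_covariates(self):
        """Weighting later epochs toward forest raises the surveyed forest mean."""
        region = RegionSpec(extent=(0, 0, 25_000.0, 25_000.0),
                            survey_years=list(range(2000, 2010)))

        def bias(year, cov):
            if year < 2005:
                return np.ones(len(cov))
            return 0.01 + cov["forest_2500"].to_numpy() ** 4

        sites, _ = generate_sites(region, n_per_year=60, bias=bias, seed=8)
        early = sites[sites.year < 2005]["forest_2500"].mean()
        late = sites[sites.year >= 2005]["forest_2500"].mean()
        assert late > early

    def test_packing_capacity_guard(self):
        """10 km x 10 km at 500 m spacing caps near 441 sites; 500 must fail."""
        region = RegionSpec(extent=(0, 0, 10_000.0, 10_000.0),
                            survey_years=[2000, 2001])
        assert region.packing_capacity() == 441
        with pytest.raises(ValueError, match="infeasible"):
            generate_sites(region, n_per_year=500, seed=0)

    def test_seed_reproducibility(self, small_region):
        s1, _ = generate_sites(small_region, n_per_year=20, seed=5)
        s2, _ = generate_sites(small_region, n_per_year=20, seed=5)
        pd.testing.assert_frame_equal(s1, s2)

    def test_landcover_fractions_valid(self, small_sites):
        sites, _ = small_sites
        lc = sites[[f"lc{i:02d}" for i in range(1, 18)]].to_numpy()
        assert (lc >= 0).all() and (lc <= 1).all()
        assert (lc.sum(axis=1) <= 1 + 1e-9).all()
        asp = sites["aspect_sin"] ** 2 + sites["aspect_cos"] ** 2
        assert np.allclose(asp, 1.0)


def _fixed_sites(n, elevation=500.0, urban=0.3, forest=0.4, years=(2000,)):
    reps = n // len(years)
    return pd.DataFrame({
        "site_id": [f"S{i}" for i in range(reps * len(years))],
        "year": np.repeat(list(years), reps),
        "elevation": elevation, "urban_2500": urban, "forest_2500": forest,
    })


class TestCountProcesses:
    def test_zip_with_zero_mass_off_is_poisson(self):
        """pi = 0 collapses ZIP onto Poisson: dispersion ratio near 1."""
        sites = _fixed_sites(10_000)
        spec = SpeciesSimSpec(species_id="s", family="ZIP", baseline_log_mean=1.0,
                              zi_coefficients=(-30.0, 0.0, 0.0, 0.0))
        counts, _ = simulate_counts(sites, [spec], seed=1)
        y = counts["individuals"].to_numpy()
        ratio = y.var() / y.mean()
        # dispersion-ratio null band at alpha = 0.01 (chi2 approximation)
        half = 2.576 * np.sqrt(2.0 / len(y))
        assert 1 - half <= ratio <= 1 + half

    def test_nb_large_dispersion_approaches_poisson(self):
        sites = _fixed_sites(10_000)
        spec = SpeciesSimSpec(species_id="s", family="NB", baseline_log_mean=1.0,
                              nb_dispersion=1e6)
        counts, _ = simulate_counts(sites, [spec], seed=2)
        y = counts["individuals"].to_numpy()
        assert y.var() / y.mean() == pytest.approx(1.0, abs=0.05)

    def test_nb_variance_matches_nb2_form(self):
        """Empirical variance tracks mu + mu^2/k."""
        sites = _fixed_sites(20_000)
        k = 2.0
        spec = SpeciesSimSpec(species_id="s", family="NB", baseline_log_mean=1.2,
                              nb_dispersion=k)
        counts, _ = simulate_counts(sites, [spec], seed=3)
        y = counts["individuals"].to_numpy()
        mu = np.exp(1.2)
        assert y.var() == pytest.approx(mu + mu**2 / k, rel=0.1)

    def test_zinb_zero_fraction_closed_form(self):
        """Zero mass equals pi + (1 - pi) * NB(0) at fixed covariates."""
        sites = _fixed_sites(10_000)
        k, mu = 1.5, np.exp(1.0)
        c0 = -0.4
        spec = SpeciesSimSpec(species_id="s", family="ZINB", baseline_log_mean=1.0,
                              nb_dispersion=k, zi_coefficients=(c0, 0.0, 0.0, 0.0))
        counts, _ = simulate_counts(sites, [spec], seed=4)
        y = counts["individuals"].to_numpy()
        pi = 1 / (1 + np.exp(-c0))  # covariate terms vanish at fixed covariates
        nb_zero = (k / (k + mu)) ** k
        expect = pi + (1 - pi) * nb_zero
        mc_se = np.sqrt(expect * (1 - expect) / len(y))
        assert abs((y == 0).mean() - expect) < 3.5 * mc_se

    def test_gregarious_individuals_consistent_with_cf(self):
        sites = _fixed_sites(5000)
        spec = SpeciesSimSpec(species_id="s", family="P", baseline_log_mean=0.5,
                              cf=11)
        counts, _ = simulate_counts(sites, [spec], seed=5)
        ind = counts["individuals"].to_numpy()
        pairs = -(-ind // 11)
        # individuals always lie in the band that ceiling-divides back
        assert np.all((ind == 0) | ((pairs - 1) * 11 < ind))
        assert np.all(ind <= pairs * 11)
        assert ind.max() > 11  # multiple pairs occur at this abundance

    def test_non_finite_predictor_reported(self):
        sites = _fixed_sites(10)
        spec = SpeciesSimSpec(species_id="bad", family="P",
                              baseline_log_mean=0.0,
                              covariate_effects={"elevation": np.inf})
        with pytest.raises(FloatingPointError, match="bad"):
            simulate_counts(sites, [spec], seed=0)

    def test_truth_record_tracks_trend_and_family(self):
        sites = _fixed_sites(400, years=(2000, 2001, 2002, 2003))
        spec = SpeciesSimSpec(species_id="s", family="P", baseline_log_mean=0.0,
                              true_log_trend=-0.05)
        counts, truth = simulate_counts(sites, [spec], seed=6)
        assert truth.family["s"] == "P"
        assert truth.true_log_trend["s"] == -0.05
        idx = truth.yearly_index["s"]
        years = sorted(idx)
        ratios = [idx[b] / idx[a] for a, b in zip(years, years[1:])]
        assert np.allclose(ratios, np.exp(-0.05), rtol=1e-9)


class TestTraitTable:
    def test_raw_values_pass_through(self):
        specs = random_species_specs(3, seed=1)
        specs[0].traits["wing_length"] = 100.0
        specs[0].traits["body_mass"] = 27.0
        table = generate_trait_table(specs)
        assert table.loc[0, "wing_length"] == 100.0
        assert table.loc[0, "body_mass"] == 27.0

    def test_missing_trait_is_error(self):
        specs = random_species_specs(2, seed=2)
        del specs[1].traits["clutch_size"]
        with pytest.raises(ValueError, match="clutch_size"):
            generate_trait_table(specs)

    def test_group_slopes_equal_configured_values(self):
        """With zero species-level spread, group trends are exact."""
        specs = random_species_specs(
            20, seed=3, group_slopes={"farmland": -0.02, "woodland": 0.01},
            slope_sd=0.0, covariate_cols=[],
        )
        sites = _fixed_sites(200, years=(2000, 2001))
        _, truth = simulate_counts(sites, specs, seed=1)
        slopes = pd.Series(truth.true_log_trend)
        groups = pd.Series(truth.group)
        assert (slopes[groups == "farmland"] == -0.02).all()
        assert (slopes[groups == "woodland"] == 0.01).all()

    def test_independent_categorical_traits_uncorrelated(self):
        """Traits generated independently show near-zero Cramer's V."""
        from avitrend.traits import cramers_v

        specs = random_species_specs(400, seed=4)
        table = generate_trait_table(specs)
        tab = pd.crosstab(table["migration"], table["nest_raw"]).to_numpy()
        assert cramers_v(tab) < 0.12


class TestLandscape:
    def test_snapshot_table_changes_over_decades(self, small_region):
        land = SyntheticLandscape(small_region, seed=0)
        snaps = land.snapshot_table(years=[1980, 2000, 2018])
        assert len(snaps) == 3
        # urban class drifts upward by construction
        assert snaps["lc01"].iloc[-1] > snaps["lc01"].iloc[0]

    def test_covariates_deterministic(self, small_region):
        land = SyntheticLandscape(small_region, seed=3)
        xy = np.array([[1000.0, 2000.0], [5000.0, 9000.0]])
        c1 = land.covariates(xy, 2005)
        c2 = land.covariates(xy, 2005)
        pd.testing.assert_frame_equal(c1, c2)
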
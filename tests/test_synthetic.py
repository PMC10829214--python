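"""The synthetic-cohort generator: determinism, bounds, and the planted
statistical structure each downstream stage relies on."""

import warnings

import numpy as np
import pandas as pd
import pytest

from adipoage.synthetic import (
    PhenotypeParams,
    ProportionModel,
    random_profiles,
    simulate_bulk_mixture,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_single_cell,
    tetrachoric_correlation,
)


class TestGenotypes:
    def test_deterministic_given_seed(self, tiny_layout):
        a = simulate_genotypes(50, tiny_layout, seed=5)
        b = simulate_genotypes(50, tiny_layout, seed=5)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_dosage_bounds_and_af_reproducible(self, tiny_geno):
        d = tiny_geno.dosages
        assert np.nanmin(d) >= 0 and np.nanmax(d) <= 2
        af = tiny_geno.empirical_af()
        np.testing.assert_allclose(af, np.nanmean(d, axis=0) / 2)

    def test_positions_strictly_increasing_within_chrom(self, tiny_geno):
        for _, grp in tiny_geno.variants.groupby("chrom"):
            assert np.all(np.diff(grp["pos"]) > 0)

    def test_zero_ld_gives_independent_variants(self, tiny_layout):
        g = simulate_genotypes(2000, tiny_layout, variants_per_kb=0.01, ld_rho=0.0,
                               seed=7)
        d = g.dosages
        c = np.corrcoef(d.T)
        off = np.abs(c[np.triu_indices_from(c, k=1)])
        # mean |r| for independent pairs is ~ sqrt(2/pi)/sqrt(n); allow 3 SE
        n = d.shape[0]
        expected = np.sqrt(2 / np.pi) / np.sqrt(n)
        se = np.sqrt((1 - 2 / np.pi) / n) / np.sqrt(off.size)
        assert abs(off.mean() - expected) < 3 * se

    def test_adjacent_pair_correlation_matches_tetrachoric_oracle(self, tiny_layout):
        """Empirical dosage correlation of within-block neighbours agrees
        with the bivariate-normal orthant-probability computation."""
        rho = 0.8
        g = simulate_genotypes(5000, tiny_layout, variants_per_kb=0.02,
                               ld_block_kb=500, ld_rho=rho, seed=8)
        v = g.variants
        d = g.dosages
        diffs = []
        for j in range(1, g.n_variants):
            if v["ld_block"][j] != v["ld_block"][j - 1]:
                continue
            emp = np.corrcoef(d[:, j - 1], d[:, j])[0, 1]
            oracle = tetrachoric_correlation(v["maf"][j - 1], v["maf"][j], rho)
            diffs.append(emp - oracle)
        assert len(diffs) > 10
        assert np.max(np.abs(diffs)) < 0.05

    def test_parameter_validation(self, tiny_layout):
        with pytest.raises(ValueError, match="ld_rho"):
            simulate_genotypes(10, tiny_layout, ld_rho=1.0)
        import adipoage.synthetic as syn

        empty = syn.GenomeLayout(genes=tiny_layout.genes.iloc[:0],
                                 chrom_lengths=tiny_layout.chrom_lengths)
        with pytest.raises(ValueError, match="layout"):
            simulate_genotypes(10, empty)


class TestPhenotypes:
    def test_degenerate_model_is_affine_in_age_and_sex(self, tiny_geno, tiny_layout):
        params = PhenotypeParams(h2_main=0.0, gamma_interaction=0.0, noise_sd=0.0,
                                 n_pcs=0, pc_effect=0.0)
        cohort, _ = simulate_phenotypes(tiny_geno, tiny_layout, ["G0000"], params,
                                        seed=1)
        age_c = cohort["age"] - cohort["age"].mean()
        pred = (
            params.bmi_intercept
            + params.beta_age * age_c
            + params.sex_effect * (cohort["sex"] == "male")
            + 0.1 * cohort["center"].str[1].astype(int)
            + 0.05 * cohort["array"].str[1].astype(int)
        )
        np.testing.assert_allclose(cohort["bmi"], pred, atol=1e-10)

    def test_variance_close_to_generative_budget(self, tiny_layout):
        """Sample variance tracks the analytic component sum of the stated
        generative formula (Monte-Carlo oracle at large n)."""
        g = simulate_genotypes(50_000, tiny_layout, variants_per_kb=0.01, seed=9)
        params = PhenotypeParams(h2_main=0.25, gamma_interaction=0.0)
        cohort, _ = simulate_phenotypes(g, tiny_layout, ["G0000"], params, seed=2)
        age_var = (params.age_dist[1] - params.age_dist[0]) ** 2 / 12
        analytic = (
            params.h2_main * params.var_scale
            + params.beta_age**2 * age_var
            + params.sex_effect**2 * 0.25
            + params.n_pcs * params.pc_effect**2
            + 0.1**2 * np.var([0, 1, 2])
            + 0.05**2 * 0.25
            + params.noise_sd**2
        )
        assert cohort["bmi"].var() == pytest.approx(analytic, rel=0.05)

    def test_interaction_signal_present_when_planted(self, tiny_layout):
        g = simulate_genotypes(10_000, tiny_layout, variants_per_kb=0.02, seed=10)
        params = PhenotypeParams(gamma_interaction=0.3)
        cohort, prov = simulate_phenotypes(g, tiny_layout, ["G0002", "G0009"], params,
                                           seed=3)
        from scipy.stats import pearsonr

        age_c = cohort["age"] - cohort["age"].mean()
        x = age_c * prov.burden
        r, p = pearsonr(x, cohort["bmi"])
        assert r > 0 and p < 0.01

    def test_empty_cis_window_raises_with_gene_names(self, tiny_layout):
        g = simulate_genotypes(100, tiny_layout, variants_per_kb=0.05, seed=11)
        # shrink the flank so a window can be empty
        params = PhenotypeParams(cis_flank=1, gamma_interaction=-0.1)
        sparse = g.subset_variants(np.arange(3))  # only 3 variants remain
        with pytest.raises(ValueError, match="G0015"):
            simulate_phenotypes(sparse, tiny_layout, ["G0015"], params, seed=4)

    def test_split_assignment_partitions_and_preserves_sex_ratio(self, tiny_geno,
                                                                 tiny_layout):
        cohort, _ = simulate_phenotypes(tiny_geno, tiny_layout, ["G0000"],
                                        PhenotypeParams(), seed=5)
        assert set(cohort["split"]) == {"base", "test"}
        test = cohort[cohort["split"] == "test"]
        assert set(test["test_half"]) == {"A", "B"}
        assert (cohort.loc[cohort["split"] == "base", "test_half"] == "none").all()
        ratio_all = (cohort["sex"] == "male").mean()
        ratio_test = (test["sex"] == "male").mean()
        assert abs(ratio_all - ratio_test) < 0.02


class TestSingleCell:
    def test_cell_bookkeeping(self):
        profiles = random_profiles(30, seed=31)
        sc = simulate_single_cell(6, profiles, ProportionModel(),
                                  cells_per_individual=1000, seed=32)
        counts_per_ind = sc.cell_meta.groupby("individual_id").size()
        assert (counts_per_ind == 1000).all()
        assert sc.counts.min() >= 0
        assert np.issubdtype(sc.counts.dtype, np.integer)
        assert sc.cell_meta["cell_type"].isin(profiles.columns).all()

    def test_null_model_has_no_age_dependence(self):
        """With no planted slope, lean-stratum young-vs-old p-values are not
        systematically small across seeds."""
        from adipoage.deconvolve import sc_proportions
        from adipoage.stats import rank_sum

        profiles = random_profiles(20, seed=33)
        pm = ProportionModel(age_slope_on_aspc=0.0, obese_offset=0.0)
        pvals = []
        for seed in range(12):
            sc = simulate_single_cell(24, profiles, pm, cells_per_individual=200,
                                      seed=100 + seed)
            props = sc_proportions(sc)
            ind = sc.individuals.set_index("individual_id")
            young = ind["age"] < ind["age"].median()
            p = rank_sum(props.loc[young.values, "ASPC"],
                         props.loc[~young.values, "ASPC"])[1]
            pvals.append(p)
        assert np.median(pvals) > 0.05

    def test_proportion_clipping_warns(self):
        profiles = random_profiles(10, seed=34)
        pm = ProportionModel(age_slope_on_aspc=0.05)  # extreme slope
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            simulate_single_cell(10, profiles, pm, cells_per_individual=50, seed=35)
        assert any("clipped" in str(w.message) for w in caught)

    def test_deterministic(self):
        profiles = random_profiles(15, seed=36)
        a = simulate_single_cell(5, profiles, ProportionModel(), seed=37)
        b = simulate_single_cell(5, profiles, ProportionModel(), seed=37)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestOpenChromatin:
    def test_intervals_sorted_nonoverlapping_and_cover_picked_variants(self, tiny_geno):
        from adipoage.prs import variants_in_intervals
        from adipoage.synthetic import simulate_open_chromatin

        bed = simulate_open_chromatin(tiny_geno, coverage=0.4, seed=50)
        for _, grp in bed.groupby("chrom"):
            assert (grp["start"] < grp["end"]).all()
            assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()
        inside = variants_in_intervals(tiny_geno.variants, bed)
        frac = inside.mean()
        assert 0.25 < frac < 0.75  # roughly the requested coverage
        full = simulate_open_chromatin(tiny_geno, coverage=1.0, seed=51)
        assert variants_in_intervals(tiny_geno.variants, full).all()

    def test_invalid_coverage_rejected(self, tiny_geno):
        from adipoage.synthetic import simulate_open_chromatin

        with pytest.raises(ValueError):
            simulate_open_chromatin(tiny_geno, coverage=0.0)


class TestBulkMixture:
    def test_pure_mixtures_proportional_to_reference_columns(self):
        profiles = random_profiles(40, seed=41)
        eye = pd.DataFrame(np.eye(5), index=[f"S{i}" for i in range(5)],
                           columns=profiles.columns)
        bulk = simulate_bulk_mixture(profiles, eye, noise_cv=0.0, seed=42)
        for i, ct in enumerate(profiles.columns):
            col = bulk.values.iloc[:, i].to_numpy()
            ref = profiles[ct].to_numpy()
            ratio = col[ref > 0] / ref[ref > 0]
            np.testing.assert_allclose(ratio, ratio[0])

    def test_noise_increases_recovery_error(self):
        """Paired simulation: deconvolution error grows with noise level."""
        from adipoage.deconvolve import CellTypeReference, estimate_proportions

        profiles = random_profiles(200, seed=43)
        rng = np.random.default_rng(44)
        P = rng.dirichlet(np.ones(5) * 3.0, size=60)
        props = pd.DataFrame(P, index=[f"S{i}" for i in range(60)],
                             columns=profiles.columns)
        errs = {}
        for cv in (0.05, 0.2):
            bulk = simulate_bulk_mixture(profiles, props, noise_cv=cv, seed=45)
            ref = CellTypeReference(profile=profiles, sc_proportions=props.iloc[:0],
                                    pseudobulk=profiles.iloc[:, :0])
            est = estimate_proportions(bulk, ref)
            errs[cv] = np.abs(est.to_numpy() - P).mean()
        assert errs[0.2] > errs[0.05]

    def test_negative_noise_rejected(self):
        profiles = random_profiles(10, seed=46)
        props = pd.DataFrame([[0.2, 0.2, 0.2, 0.2, 0.2]], index=["S0"],
                             columns=profiles.columns)
        with pytest.raises(ValueError, match="noise_cv"):
            simulate_bulk_mixture(profiles, props, noise_cv=-0.1)
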
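"""Cis-windows, LD clumping, penalized summary-statistic fitting, scoring
and split-validation."""

import numpy as np
import pandas as pd
import pytest

from adipoage.prs import (
    PRSWeights,
    build_cis_windows,
    build_ld_reference,
    fit_lassosum,
    lasso_objective,
    ld_clump,
    marginal_correlations,
    merge_intervals,
    score_individuals,
    split_validate_score,
    variance_explained,
    variants_in_intervals,
)
from conftest import make_genotype_matrix


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand",
                                       "tss"])


class TestCisWindows:
    def test_nearby_genes_merge_into_one_interval(self):
        genes = _genes([
            ("a", "chr1", 1_000_000, 1_010_000, "+", 1_000_000),
            ("b", "chr1", 1_110_000, 1_120_000, "+", 1_110_000),
        ])
        iv = build_cis_windows(genes, ["a", "b"], flank=500_000)
        assert len(iv.intervals) == 1

    def test_sex_chromosome_gene_dropped(self):
        genes = _genes([
            ("a", "chr1", 1_000_000, 1_010_000, "+", 1_000_000),
            ("x", "chrX", 1_000_000, 1_010_000, "+", 1_000_000),
        ])
        iv = build_cis_windows(genes, ["a", "x"], autosomal_only=True)
        assert iv.dropped_genes == ["x"] and iv.retained_genes == ["a"]
        with pytest.raises(ValueError):
            build_cis_windows(genes, ["x"], autosomal_only=True)

    def test_merged_coverage_matches_boolean_mask_oracle(self):
        """Merged window coverage equals a brute-force per-base union on a
        10-Mb toy chromosome, over random gene sets."""
        rng = np.random.default_rng(0)
        L = 10_000_000
        rows = []
        for i in range(50):
            s = int(rng.integers(1, L - 200_000))
            rows.append((f"g{i}", "chr1", s, s + int(rng.integers(1000, 100_000)),
                         "+", s))
        genes = _genes(rows)
        for trial in range(3):
            sub = list(rng.choice(genes["gene_id"], size=12, replace=False))
            iv = build_cis_windows(genes, sub, flank=500_000)
            covered = sum(
                min(e, L) - max(s, 0) for s, e in
                zip(iv.intervals["start"], iv.intervals["end"].clip(upper=L))
            )
            mask = np.zeros(L, dtype=bool)
            gsub = genes.set_index("gene_id").loc[sub]
            for _, g in gsub.iterrows():
                lo = max(0, g["start"] - 1 - 500_000)
                hi = min(L, g["end"] + 500_000)
                mask[lo:hi] = True
            assert covered == int(mask.sum())

    def test_interval_membership_convention_at_boundaries(self):
        """1-based position p is inside half-open [s, e) iff s < p <= e."""
        variants = pd.DataFrame(
            {"variant_id": ["v1", "v2", "v3", "v4"], "chrom": "chr1",
             "pos": [100, 101, 200, 201]}
        )
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        mask = variants_in_intervals(variants, iv)
        assert list(mask) == [False, True, True, False]

    def test_merge_intervals_idempotent(self):
        df = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [10, 5, 50], "end": [20, 12, 60]}
        )
        once = merge_intervals(df)
        twice = merge_intervals(once)
        pd.testing.assert_frame_equal(once, twice)


def _summary_for(geno, pvals, betas=None):
    m = geno.n_variants
    betas = betas if betas is not None else np.ones(m) * 0.1
    return pd.DataFrame(
        {
            "SNP": geno.variants["variant_id"],
            "CHR": geno.variants["chrom"],
            "BP": geno.variants["pos"],
            "A1": geno.variants["alt_allele"],
            "A2": geno.variants["ref_allele"],
            "BETA": betas,
            "SE": np.full(m, 0.05),
            "P": pvals,
            "N": 1000,
            "MAF": geno.variants["maf"],
            "INFO": 1.0,
        }
    )


def oracle_clump(summary, geno, r2_cut, window):
    """O(m^2) re-scan greedy oracle: recompute all pairwise r^2 each step."""
    d = geno.dosages.copy()
    d = np.where(np.isnan(d), np.nanmean(d, axis=0), d)
    pos = geno.variants.set_index("variant_id")["pos"]
    chrom = geno.variants.set_index("variant_id")["chrom"]
    vmap = {v: i for i, v in enumerate(geno.variants["variant_id"])}
    remaining = summary.sort_values(["P", "SNP"], kind="mergesort")["SNP"].tolist()
    kept = []
    while remaining:
        idx = remaining.pop(0)
        kept.append(idx)
        survivors = []
        for v in remaining:
            if chrom[v] == chrom[idx] and abs(pos[v] - pos[idx]) <= window:
                r = np.corrcoef(d[:, vmap[idx]], d[:, vmap[v]])[0, 1]
                if r**2 >= r2_cut:
                    continue
            survivors.append(v)
        remaining = survivors
    return kept


class TestClump:
    def test_perfectly_correlated_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(1)
        a = rng.binomial(2, 0.3, size=(200, 1)).astype(float)
        geno = make_genotype_matrix(np.hstack([a, a]), pos=[1000, 11_000])
        summary = _summary_for(geno, [0.04, 0.001])
        kept = ld_clump(summary, geno, r2_cut=0.1, window=250_000)
        assert kept == [geno.variants["variant_id"][1]]

    def test_independent_variants_all_retained(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.3, size=(500, 8)).astype(float)
        geno = make_genotype_matrix(d, spacing=500_000)  # outside any window
        summary = _summary_for(geno, rng.uniform(size=8))
        kept = ld_clump(summary, geno, r2_cut=0.1, window=250_000)
        assert sorted(kept) == sorted(summary["SNP"])

    def test_matches_rescan_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for trial in range(25):
            n, m = 120, 50
            base = rng.binomial(2, 0.3, size=(n, m)).astype(float)
            # induce blocks of correlation by copying neighbours with noise
            for j in range(1, m):
                if rng.random() < 0.5:
                    flip = rng.random(n) < 0.1
                    base[:, j] = np.where(flip, rng.binomial(2, 0.3, n), base[:, j - 1])
            pos = np.sort(rng.choice(np.arange(1, 2_000_000), size=m, replace=False))
            geno = make_genotype_matrix(base, pos=pos)
            summary = _summary_for(geno, rng.uniform(size=m))
            ours = ld_clump(summary, geno, r2_cut=0.1, window=250_000)
            ref = oracle_clump(summary, geno, r2_cut=0.1, window=250_000)
            assert ours == ref

    def test_empty_input_empty_output(self):
        geno = make_genotype_matrix(np.zeros((10, 0)))
        assert ld_clump(_summary_for(geno, []), geno) == []


class TestLassosum:
    def _identity_fixture(self, m=25, seed=4):
        rng = np.random.default_rng(seed)
        d = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(300, m)).astype(float)
        geno = make_genotype_matrix(d, spacing=300_000)
        geno.variants["ld_block"] = np.arange(m)  # one variant per block
        betas = rng.normal(0, 0.2, m)
        summary = _summary_for(geno, rng.uniform(size=m), betas=betas)
        return geno, summary

    def test_identity_ld_equals_soft_threshold_closed_form(self):
        geno, summary = self._identity_fixture()
        ld = build_ld_reference(geno)
        for lam in (0.005, 0.02, 0.08):
            (res,) = fit_lassosum(summary, ld, lambda_grid=[lam], s_grid=[1.0])
            r = marginal_correlations(summary)
            expected = np.sign(r) * np.clip(np.abs(r) - lam, 0.0, None)
            np.testing.assert_allclose(res.table["WEIGHT"], expected, atol=1e-10)

    def test_large_lambda_shrinks_everything_to_zero(self):
        geno, summary = self._identity_fixture()
        ld = build_ld_reference(geno)
        lam = np.abs(marginal_correlations(summary)).max() * 1.01
        (res,) = fit_lassosum(summary, ld, lambda_grid=[lam], s_grid=[0.5])
        assert res.n_active == 0

    def test_kkt_satisfied_on_block_ld(self, tiny_geno):
        rng = np.random.default_rng(5)
        m = tiny_geno.n_variants
        summary = _summary_for(tiny_geno, rng.uniform(size=m),
                               betas=rng.normal(0, 0.2, m))
        ld = build_ld_reference(tiny_geno)
        for res in fit_lassosum(summary, ld, lambda_grid=[0.01, 0.05], s_grid=[0.5, 0.9]):
            assert res.converged
            assert res.kkt <= 1e-6

    def test_objective_matches_sklearn_lasso_oracle(self):
        """30-variant block, s = 0.5, lambda = 0.01: the coordinate-descent
        solution's objective agrees with an off-the-shelf convex solver on
        the same quadratic program."""
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(6)
        n, m = 400, 30
        d = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        for j in range(1, m):  # correlated block
            mix = rng.random(n) < 0.6
            d[:, j] = np.where(mix, d[:, j - 1], d[:, j])
        geno = make_genotype_matrix(d, spacing=1000)
        geno.variants["ld_block"] = 0
        summary = _summary_for(geno, rng.uniform(size=m), betas=rng.normal(0, 0.2, m))
        ld = build_ld_reference(geno)
        s, lam = 0.5, 0.01
        (res,) = fit_lassosum(summary, ld, lambda_grid=[lam], s_grid=[s])
        B = (1 - s) * ld.R[0] + s * np.eye(m)
        r = marginal_correlations(summary)
        # map onto sklearn's (1/2n)||y - Xw||^2 + alpha ||w||_1 with X'X = B
        L = np.linalg.cholesky(B)
        X = L.T
        y = np.linalg.solve(L, r)
        sk = Lasso(alpha=lam / m, fit_intercept=False, tol=1e-14, max_iter=1_000_000)
        sk.fit(X, y)
        ours = lasso_objective(res.table["WEIGHT"].to_numpy(), B, r, lam)
        ref = lasso_objective(sk.coef_, B, r, lam)
        assert abs(ours - ref) < 1e-8

    def test_active_set_monotone_in_lambda_on_identity_ld(self):
        geno, summary = self._identity_fixture(m=40, seed=7)
        ld = build_ld_reference(geno)
        fits = fit_lassosum(summary, ld, lambda_grid=[0.05, 0.01], s_grid=[1.0])
        by_lam = {f.lam: set(f.table.loc[f.table["WEIGHT"] != 0, "SNP"]) for f in fits}
        assert by_lam[0.05] <= by_lam[0.01]


class TestScoring:
    def test_score_is_centered_dot_product(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.4, size=(50, 4)).astype(float)
        geno = make_genotype_matrix(d)
        w = pd.DataFrame(
            {"SNP": geno.variants["variant_id"], "A1": "G", "WEIGHT": [0.5, -0.2, 0.0, 1.0]}
        )
        score = score_individuals(geno, w)
        af = d.mean(axis=0) / 2
        expected = (d - 2 * af) @ np.array([0.5, -0.2, 0.0, 1.0])
        np.testing.assert_allclose(score, expected, atol=1e-12)

    def test_allele_flip_leaves_scores_unchanged(self):
        rng = np.random.default_rng(9)
        d = rng.binomial(2, 0.3, size=(80, 3)).astype(float)
        geno = make_genotype_matrix(d)
        w = pd.DataFrame(
            {"SNP": geno.variants["variant_id"], "A1": "G", "WEIGHT": [0.4, -0.1, 0.7]}
        )
        flipped = w.copy()
        flipped.loc[1, "A1"] = "A"
        flipped.loc[1, "WEIGHT"] = -w.loc[1, "WEIGHT"]
        np.testing.assert_allclose(
            score_individuals(geno, w), score_individuals(geno, flipped), atol=1e-12
        )


def _test_cohort(geno, trait, seed=0):
    rng = np.random.default_rng(seed)
    n = geno.n_individuals
    half = np.where(np.arange(n) % 2 == 0, "A", "B")
    return pd.DataFrame(
        {
            "individual_id": geno.individual_ids,
            "age": rng.uniform(25, 73, n),
            "sex": rng.choice(["male", "female"], n),
            "bmi": trait,
            "split": "test",
            "test_half": half,
        }
    )


class TestSplitValidation:
    def test_single_candidate_passthrough(self):
        rng = np.random.default_rng(10)
        d = rng.binomial(2, 0.3, size=(60, 5)).astype(float)
        geno = make_genotype_matrix(d)
        w = PRSWeights(
            table=pd.DataFrame({"SNP": geno.variants["variant_id"], "A1": "G",
                                "WEIGHT": rng.normal(size=5)}),
            method="lassosum", lam=0.01, s=0.5, converged=True, kkt=0.0,
        )
        trait = rng.normal(27, 4, 60)
        sv = split_validate_score([w], geno, _test_cohort(geno, trait))
        raw = score_individuals(geno, w.table)
        for h in ("A", "B"):
            sub = sv.scores[sv.scores["half"] == h]
            idx = [geno.individual_ids.index(i) for i in sub["individual_id"]]
            expect = (raw[idx] - raw[idx].mean()) / raw[idx].std()
            np.testing.assert_allclose(sub["score"], expect, atol=1e-10)
        assert abs(sv.scores["score"].mean()) < 1e-8

    def test_planted_candidate_selected(self):
        wins = 0
        n_seeds = 15
        for seed in range(n_seeds):
            rng = np.random.default_rng(2000 + seed)
            n, m = 4000, 40
            d = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
            geno = make_genotype_matrix(d, spacing=100_000)
            gstd = (d - d.mean(0)) / d.std(0)
            b = rng.normal(size=m)
            g = gstd @ b
            g = g / g.std()
            h2 = 0.3
            trait = np.sqrt(h2) * g + rng.normal(size=n) * np.sqrt(1 - h2)
            planted = PRSWeights(
                table=pd.DataFrame({"SNP": geno.variants["variant_id"], "A1": "G",
                                    "WEIGHT": b / d.std(0)}),
                method="lassosum", lam=0.0, s=1.0, converged=True, kkt=0.0,
            )
            decoys = [
                PRSWeights(
                    table=pd.DataFrame({"SNP": geno.variants["variant_id"], "A1": "G",
                                        "WEIGHT": rng.permutation(b) / d.std(0)}),
                    method="lassosum", lam=lam, s=1.0, converged=True, kkt=0.0,
                )
                for lam in (0.01, 0.02)
            ]
            sv = split_validate_score([planted, *decoys], geno,
                                      _test_cohort(geno, trait, seed=seed))
            wins += int(sv.chosen["A"]["index"] == 0 and sv.chosen["B"]["index"] == 0)
        assert wins >= 0.9 * n_seeds

    def test_zero_trait_variance_errors(self):
        rng = np.random.default_rng(11)
        d = rng.binomial(2, 0.3, size=(20, 2)).astype(float)
        geno = make_genotype_matrix(d)
        w = PRSWeights(
            table=pd.DataFrame({"SNP": geno.variants["variant_id"], "A1": "G",
                                "WEIGHT": [1.0, 0.5]}),
            method="lassosum", lam=0.01, s=0.5, converged=True, kkt=0.0,
        )
        with pytest.raises(ValueError, match="variance"):
            split_validate_score([w], geno, _test_cohort(geno, np.full(20, 27.0)))


class TestVarianceExplained:
    def test_perfect_score(self):
        df = pd.DataFrame({"individual_id": [f"I{i}" for i in range(20)],
                           "score": np.arange(20.0)})
        cohort = pd.DataFrame({"individual_id": df["individual_id"],
                               "bmi": np.arange(20.0) * 2 + 5})
        assert variance_explained(df, cohort) == pytest.approx(1.0)

    def test_independent_score_near_zero(self):
        rng = np.random.default_rng(12)
        n = 4000
        df = pd.DataFrame({"individual_id": [f"I{i}" for i in range(n)],
                           "score": rng.normal(size=n)})
        cohort = pd.DataFrame({"individual_id": df["individual_id"],
                               "bmi": rng.normal(27, 4, n)})
        assert variance_explained(df, cohort) < (3 / np.sqrt(n)) ** 2

    def test_matches_generative_r2(self):
        rng = np.random.default_rng(13)
        n, h2 = 10_000, 0.25
        s = rng.normal(size=n)
        trait = np.sqrt(h2) * s + rng.normal(size=n) * np.sqrt(1 - h2)
        df = pd.DataFrame({"individual_id": [f"I{i}" for i in range(n)], "score": s})
        cohort = pd.DataFrame({"individual_id": df["individual_id"], "bmi": trait})
        assert variance_explained(df, cohort) == pytest.approx(h2, abs=0.03)

    def test_too_few_individuals_errors(self):
        df = pd.DataFrame({"individual_id": ["a", "b"], "score": [1.0, 2.0]})
        cohort = pd.DataFrame({"individual_id": ["a", "b"], "bmi": [20.0, 30.0]})
        with pytest.raises(ValueError):
            variance_explained(df, cohort)
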
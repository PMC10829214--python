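"""Genotype quality control and per-variant association testing.

QC mirrors standard biobank practice: variants are dropped for missingness,
low minor-allele frequency, or Hardy-Weinberg disequilibrium; individuals
for genotype missingness or outlying heterozygosity.  Association uses
ordinary least squares of the (within-stratum inverse-normal-transformed)
trait on dosage plus covariates — the correct desk-scale analogue of a
mixed-model GWAS for unrelated, unstructured synthetic cohorts.

The per-variant regression is computed by the Frisch-Waugh projection:
trait and dosages are residualised on the covariate design once, then each
variant's slope, standard error and two-sided t-test follow from simple
regression on the residuals with the full model's degrees of freedom.  This
is algebraically identical to the joint OLS fit and vectorises across
variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import inverse_normal_transform
from .synthetic import GenotypeMatrix


@dataclass
class QCThresholds:
    miss_var: float = 0.01
    maf: float = 0.01
    hwe_p: float = 1e-6
    miss_ind: float = 0.01
    het_sd: float = 3.0


@dataclass
class QCLog:
    variants_missingness: int = 0
    variants_maf: int = 0
    variants_hwe: int = 0
    individuals_missingness: int = 0
    individuals_heterozygosity: int = 0
    details: dict = field(default_factory=dict)


def hwe_chisq(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """1-df chi-square Hardy-Weinberg test from genotype counts."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 0.0, 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
    stat = float(terms.sum())
    return stat, float(sps.chi2.sf(stat, 1))


def qc_filter(
    geno: GenotypeMatrix,
    cohort: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, QCLog]:
    """Apply variant- and individual-level QC; returns filtered copies and a log.

    Variant filters (on hard-called genotypes where genotype classes are
    needed): missingness >= ``miss_var``, folded MAF < ``maf``, HWE exact
    chi-square p < ``hwe_p``.  Individual filters: genotype missingness >
    ``miss_ind``, heterozygosity beyond ``het_sd`` SDs of the cohort mean.
    """
    th = thresholds or QCThresholds()
    log = QCLog()
    d = geno.dosages
    n, m = d.shape
    hard = np.round(d)

    miss = np.mean(np.isnan(d), axis=0)
    af = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(af, 1 - af)
    hwe_p = np.ones(m)
    for j in range(m):
        g = hard[:, j]
        g = g[~np.isnan(g)]
        n_bb = int((g == 2).sum())  # alt hom
        n_ab = int((g == 1).sum())
        n_aa = int((g == 0).sum())
        hwe_p[j] = hwe_chisq(n_aa, n_ab, n_bb)[1]

    drop_miss = miss >= th.miss_var
    drop_maf = maf < th.maf
    drop_hwe = hwe_p < th.hwe_p
    keep_var = ~(drop_miss | drop_maf | drop_hwe)
    log.variants_missingness = int(drop_miss.sum())
    log.variants_maf = int((drop_maf & ~drop_miss).sum())
    log.variants_hwe = int((drop_hwe & ~drop_miss & ~drop_maf).sum())
    if not keep_var.any():
        raise ValueError("all variants removed by QC")

    ind_miss = np.mean(np.isnan(d[:, keep_var]), axis=1)
    het = np.nanmean(hard[:, keep_var] == 1, axis=1)
    het_mu, het_sd = het.mean(), het.std()
    drop_ind_miss = ind_miss > th.miss_ind
    if het_sd > 0:
        drop_ind_het = np.abs(het - het_mu) > th.het_sd * het_sd
    else:
        drop_ind_het = np.zeros(n, dtype=bool)
    keep_ind = ~(drop_ind_miss | drop_ind_het)
    log.individuals_missingness = int(drop_ind_miss.sum())
    log.individuals_heterozygosity = int((drop_ind_het & ~drop_ind_miss).sum())

    out_geno = geno.subset_variants(np.where(keep_var)[0]).subset_individuals(
        np.where(keep_ind)[0]
    )
    kept_ids = set(out_geno.individual_ids)
    out_cohort = cohort.loc[cohort["individual_id"].isin(kept_ids)].reset_index(drop=True)
    log.details = {
        "variants_kept": int(keep_var.sum()),
        "individuals_kept": int(keep_ind.sum()),
    }
    return out_geno, out_cohort, log


def build_covariate_design(
    cohort: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate columns; categorical columns are one-hot coded
    (first level dropped)."""
    cols = [np.ones(len(cohort))]
    names = ["intercept"]
    for c in covariates:
        col = cohort[c]
        if col.dtype.kind in "fiu":
            cols.append(col.to_numpy().astype(float))
            names.append(c)
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy().astype(float))
                names.append(dc)
    return np.column_stack(cols), names


def run_gwas(
    geno: GenotypeMatrix,
    cohort: pd.DataFrame,
    trait: str = "bmi",
    covariates: list[str] | None = None,
    sex_stratum: str = "all",
    adjust_age: bool = False,
    maf_min: float = 0.01,
    info_min: float = 0.8,
) -> pd.DataFrame:
    """Per-variant OLS association scan.

    The trait is inverse-normal transformed within the analysis stratum.
    Covariates (plus centered age and age^2 when ``adjust_age``) are
    projected out of trait and dosages; per-variant beta, SE and two-sided
    t-test p follow.  Monomorphic variants are emitted with beta 0, p 1 and
    a flag.  The post-filter removes variants with MAF < ``maf_min`` or
    INFO < ``info_min``.

    Returns the summary-statistics table with columns SNP, CHR, BP, A1
    (effect allele = alt), A2, BETA, SE, P, N, MAF, INFO.
    """
    covariates = covariates if covariates is not None else []
    cohort = cohort.reset_index(drop=True)
    if sex_stratum != "all":
        keep = cohort["sex"] == sex_stratum
        cohort = cohort.loc[keep].reset_index(drop=True)
        id_index = {iid: i for i, iid in enumerate(geno.individual_ids)}
        geno = geno.subset_individuals([id_index[i] for i in cohort["individual_id"]])
    n = len(cohort)
    y = inverse_normal_transform(cohort[trait].to_numpy())

    X, names = build_covariate_design(cohort, covariates)
    if adjust_age:
        age_c = cohort["age"].to_numpy() - cohort["age"].mean()
        X = np.column_stack([X, age_c, age_c**2])
        names += ["age", "age2"]
    q, r = np.linalg.qr(X)
    if np.any(np.abs(np.diag(r)) <= max(X.shape) * np.finfo(float).eps * np.abs(np.diag(r)).max()):
        bad = names[int(np.argmin(np.abs(np.diag(r))))]
        raise ValueError(f"covariate design rank-deficient; collinear column: {bad}")

    d = geno.dosages
    col_mean = np.nanmean(d, axis=0)
    d_filled = np.where(np.isnan(d), col_mean[None, :], d)
    # project out covariates from trait and dosages
    y_res = y - q @ (q.T @ y)
    g_res = d_filled - q @ (q.T @ d_filled)

    gg = np.einsum("ij,ij->j", g_res, g_res)
    gy = g_res.T @ y_res
    mono = gg <= 1e-12
    gg_safe = np.where(mono, 1.0, gg)
    beta = gy / gg_safe
    df = n - X.shape[1] - 1
    rss = (y_res @ y_res) - beta * gy
    rss = np.clip(rss, 0.0, None)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / gg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * sps.t.sf(np.abs(tstat), df)
    beta = np.where(mono, 0.0, beta)
    se = np.where(mono, np.nan, se)
    pvals = np.where(mono, 1.0, pvals)

    af = col_mean / 2.0
    maf = np.minimum(af, 1 - af)
    v = geno.variants
    out = pd.DataFrame(
        {
            "SNP": v["variant_id"],
            "CHR": v["chrom"],
            "BP": v["pos"],
            "A1": v["alt_allele"],
            "A2": v["ref_allele"],
            "BETA": beta,
            "SE": se,
            "P": np.clip(pvals, np.finfo(float).tiny, 1.0),
            "N": n,
            "MAF": maf,
            "INFO": v["info"],
            "MONOMORPHIC": mono,
        }
    )
    out = out.loc[(out["MAF"] >= maf_min) & (out["INFO"] >= info_min)]
    return out.reset_index(drop=True)
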
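"""PRS-by-age and variant-by-age interaction testing on BMI.

The phenotype is first residualised on technical/genetic covariates and
inverse-normal transformed.  Analysis groups follow standard BMI classes,
optionally frequency-matched by (sex, age-year) cells so the normal-BMI and
obese groups share identical age histograms.  The headline model is

    adjusted BMI ~ age + PRS + PRS x age

fit by OLS with Wald t tests (n - 4 residual df); the single-variant scan
applies the same model per variant after a filter cascade (cis-region
membership, nominal GWAS significance, LD clumping, open-chromatin overlap)
with Bonferroni correction over the variants actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import build_covariate_design
from .prs import IntervalSet, ld_clump, variants_in_intervals
from .stats import OLSFit, inverse_normal_transform, ols_fit
from .synthetic import GenotypeMatrix


def adjust_phenotype(
    cohort: pd.DataFrame, trait: str = "bmi", covariates: list[str] | None = None
) -> np.ndarray:
    """OLS residuals of the trait on the covariates, inverse-normal
    transformed.  With no covariates this reduces to the transform of the
    raw trait.  Exactly collinear traits leave constant residuals, on which
    the transform raises."""
    y = cohort[trait].to_numpy().astype(float)
    scale = y.std()
    if covariates:
        X, _ = build_covariate_design(cohort, covariates)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        y = y - X @ beta
        if scale > 0 and y.std() < 1e-10 * scale:
            raise ValueError(
                "residuals are constant (trait exactly linear in covariates); "
                "inverse-normal transform undefined"
            )
    return inverse_normal_transform(y)


@dataclass
class MatchedCohort:
    """Frequency-matched normal/obese contrast: retained ids and per-cell
    counts (equal across groups by construction)."""

    individual_ids: list[str]
    cell_counts: pd.DataFrame  # sex, age_year, n_per_group
    dropped_cells: int = 0


def classify_and_match(
    cohort: pd.DataFrame,
    bmi_cuts: tuple[float, float] = (25.0, 30.0),
    match: bool = True,
    seed: int = 0,
) -> tuple[pd.Series, MatchedCohort | None]:
    """Assign BMI classes and optionally frequency-match normal vs obese.

    Classes: normal < ``bmi_cuts[0]`` <= overweight < ``bmi_cuts[1]`` <=
    obese (the obesity boundary is inclusive).  Matching down-samples,
    within each (sex, floor(age)) cell, the larger of the normal/obese
    groups to the smaller's count (seeded, without replacement); cells with
    one side empty are dropped from both.  Overweight individuals never
    enter the matched contrast.
    """
    labels = pd.Series("overweight", index=cohort.index, dtype=object)
    labels[cohort["bmi"] < bmi_cuts[0]] = "normal"
    labels[cohort["bmi"] >= bmi_cuts[1]] = "obese"
    if not match:
        return labels, None
    rng = np.random.default_rng(seed)
    age_year = np.floor(cohort["age"]).astype(int)
    keep_ids: list[str] = []
    cells = []
    dropped = 0
    for (sex, ay), grp in cohort.groupby([cohort["sex"], age_year], observed=True):
        normal = grp.index[labels.loc[grp.index] == "normal"]
        obese = grp.index[labels.loc[grp.index] == "obese"]
        k = min(len(normal), len(obese))
        if k == 0:
            if len(normal) or len(obese):
                dropped += 1
            continue
        sel_n = rng.choice(normal, size=k, replace=False) if len(normal) > k else normal
        sel_o = rng.choice(obese, size=k, replace=False) if len(obese) > k else obese
        keep_ids.extend(cohort.loc[sel_n, "individual_id"])
        keep_ids.extend(cohort.loc[sel_o, "individual_id"])
        cells.append({"sex": sex, "age_year": ay, "n_per_group": k})
    matched = MatchedCohort(
        individual_ids=keep_ids,
        cell_counts=pd.DataFrame(cells, columns=["sex", "age_year", "n_per_group"]),
        dropped_cells=dropped,
    )
    return labels, matched


@dataclass
class InteractionFit:
    """Coefficients and Wald tests for one interaction model."""

    terms: pd.DataFrame  # term, beta, se, z, p
    n: int
    stratum: str = "all"
    variant_id: str | None = None

    @property
    def interaction(self) -> dict:
        return self.terms.loc[self.terms["term"] == "interaction"].iloc[0].to_dict()


def _interaction_ols(
    y: np.ndarray, age: np.ndarray, x: np.ndarray, stratum: str,
    x_name: str = "prs", center_age: bool = True, standardize_x: bool = True,
) -> InteractionFit:
    age_t = age - age.mean() if center_age else age.astype(float)
    xt = x.astype(float)
    if standardize_x:
        sd = xt.std()
        if sd == 0:
            raise ValueError(f"degenerate term: {x_name} is constant")
        xt = (xt - xt.mean()) / sd
    if np.std(age_t) == 0:
        raise ValueError("degenerate term: age is constant")
    X = np.column_stack([np.ones(len(y)), age_t, xt, age_t * xt])
    fit: OLSFit = ols_fit(X, y, names=["intercept", "age", x_name, "interaction"])
    terms = pd.DataFrame(
        {
            "term": fit.names,
            "beta": fit.beta,
            "se": fit.se,
            "z": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return InteractionFit(terms=terms, n=len(y), stratum=stratum)


def test_prs_age_interaction(
    adj_bmi: np.ndarray,
    age: np.ndarray,
    prs: np.ndarray,
    subset: np.ndarray | None = None,
    stratum: str = "all",
) -> InteractionFit:
    """OLS of adjusted BMI on centered age, standardized PRS and their
    product; the interaction coefficient's Wald test is the headline."""
    adj_bmi = np.asarray(adj_bmi, dtype=float)
    age = np.asarray(age, dtype=float)
    prs = np.asarray(prs, dtype=float)
    if subset is not None:
        subset = np.asarray(subset)
        adj_bmi, age, prs = adj_bmi[subset], age[subset], prs[subset]
    if len(adj_bmi) < 10:
        raise ValueError("need at least 10 individuals")
    return _interaction_ols(adj_bmi, age, prs, stratum, x_name="prs")


@dataclass
class AttritionLog:
    """Per-filter candidate counts for the single-variant scan."""

    start: int = 0
    in_regions: int = 0
    nominal_p: int = 0
    clumped: int = 0
    open_chromatin: int = 0
    tested: int = 0
    counts: dict = field(default_factory=dict)


def _in_bed_intervals(variants: pd.DataFrame, bed: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(variants), dtype=bool)
    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].to_numpy()
    for _, iv in bed.iterrows():
        mask |= (chrom == iv["chrom"]) & (iv["start"] < pos) & (pos <= iv["end"])
    return mask


def variant_interaction_scan(
    summary: pd.DataFrame,
    geno: GenotypeMatrix,
    adj_bmi: np.ndarray,
    age: np.ndarray,
    atac: pd.DataFrame,
    regions: IntervalSet,
    r2_cut: float = 0.1,
    window: int = 250_000,
    subset: np.ndarray | None = None,
    nominal_p: float = 0.05,
    alpha: float = 0.05,
) -> tuple[list[InteractionFit], AttritionLog]:
    """Variant-by-age interaction scan over the filter cascade.

    Candidates are summary variants that (1) lie inside ``regions``,
    (2) reach nominal significance in the (non-age-adjusted) GWAS,
    (3) survive greedy LD clumping, and (4) land inside an open-chromatin
    interval (``atac``: BED-convention chrom/start/end, 0-based half-open).
    Each candidate is coded as copies of the allele positively associated
    with BMI and fitted with the interaction OLS; Bonferroni significance
    is reported over the variants actually tested.  An empty cascade
    returns an empty list plus the attrition counts.
    """
    log = AttritionLog(start=len(summary))
    vmeta = geno.variants.set_index("variant_id")
    sm = summary.copy()
    sm["pos"] = vmeta.loc[sm["SNP"], "pos"].to_numpy()
    sm["chrom"] = vmeta.loc[sm["SNP"], "chrom"].to_numpy()

    in_reg = variants_in_intervals(sm, regions.intervals)
    sm = sm.loc[in_reg]
    log.in_regions = len(sm)
    sm = sm.loc[sm["P"] < nominal_p]
    log.nominal_p = len(sm)
    kept = ld_clump(sm, geno, r2_cut=r2_cut, window=window, p_index=1.0) if len(sm) else []
    sm = sm.set_index("SNP").loc[kept].reset_index()
    log.clumped = len(sm)
    if len(sm):
        in_atac = _in_bed_intervals(sm, atac)
        sm = sm.loc[in_atac]
    log.open_chromatin = len(sm)

    adj_bmi = np.asarray(adj_bmi, dtype=float)
    age = np.asarray(age, dtype=float)
    if subset is not None:
        subset = np.asarray(subset)
        adj_bmi, age = adj_bmi[subset], age[subset]
    fits: list[InteractionFit] = []
    vmap = {vid: i for i, vid in enumerate(geno.variants["variant_id"])}
    for _, row in sm.iterrows():
        j = vmap[row["SNP"]]
        d = geno.dosages[:, j]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        if subset is not None:
            d = d[subset]
        if row["BETA"] < 0:  # count copies of the BMI-increasing allele
            d = 2.0 - d
        fit = _interaction_ols(
            adj_bmi, age, d, stratum="scan", x_name="variant", standardize_x=False
        )
        fit.variant_id = row["SNP"]
        fits.append(fit)
    log.tested = len(fits)
    log.counts = {
        "start": log.start,
        "in_regions": log.in_regions,
        "nominal_p": log.nominal_p,
        "clumped": log.clumped,
        "open_chromatin": log.open_chromatin,
        "tested": log.tested,
    }
    if fits:
        m = len(fits)
        for f in fits:
            p = f.interaction["p"]
            f.terms.attrs["p_bonferroni"] = min(1.0, p * m)
            f.terms.attrs["significant_nominal"] = p < nominal_p
            f.terms.attrs["significant_adjusted"] = p * m < alpha
    return fits, log
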
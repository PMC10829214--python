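"""Reference-based cell-type deconvolution of bulk expression and
stratified proportion comparisons.

The decomposition follows the Bisque-style, simplified skeleton: a
pseudobulk reference profile is trained from annotated single-cell data,
optionally rescaled gene-by-gene using samples present in both the
single-cell and bulk data, and each bulk sample is decomposed by
non-negative least squares with the proportions renormalised to the
simplex.  Stratified young-vs-old comparisons use the two-sided Wilcoxon
rank-sum test, reporting the Mann-Whitney U of the first group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import nnls

from .stats import rank_sum
from .synthetic import BulkExpression, SingleCellDataset


@dataclass
class CellTypeReference:
    """Pseudobulk reference: genes x cell-types profile, per-donor observed
    single-cell type fractions, and an optional per-gene linear transform
    mapping bulk onto the reference scale."""

    profile: pd.DataFrame
    sc_proportions: pd.DataFrame
    pseudobulk: pd.DataFrame  # genes x sc-individuals CPM, for overlap fitting
    transform: pd.DataFrame | None = None  # columns slope, intercept


def sc_proportions(sc: SingleCellDataset) -> pd.DataFrame:
    """Observed cell-type fractions per single-cell donor (rows sum to 1)."""
    tab = pd.crosstab(sc.cell_meta["individual_id"], sc.cell_meta["cell_type"])
    tab = tab.reindex(sc.individuals["individual_id"], fill_value=0)
    return tab.div(tab.sum(axis=1), axis=0)


def _cpm_columns(mat: np.ndarray) -> np.ndarray:
    totals = mat.sum(axis=0).astype(float)
    totals[totals == 0] = 1.0
    return mat * (1e6 / totals[None, :])


def build_reference(sc: SingleCellDataset) -> CellTypeReference:
    """Train the pseudobulk reference profile from annotated single-cell data.

    Z[g, t] is the mean CPM-normalised expression of gene g over all cells
    of type t pooled across donors; genes never detected in the single-cell
    data are dropped.  The per-donor observed type fractions and per-donor
    pseudobulk CPM profiles are recorded for the overlap transform.
    """
    types = sc.cell_types
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    norm = _cpm_columns(sc.counts.astype(float))
    labels = sc.cell_meta["cell_type"].to_numpy()
    cols = {}
    for ct in types:
        mask = labels == ct
        if mask.sum() == 0:
            raise ValueError(f"cell type {ct} has zero cells")
        cols[ct] = norm[:, mask].mean(axis=1)
    profile = pd.DataFrame(cols, index=sc.gene_ids)
    detected = profile.sum(axis=1) > 0
    profile = profile.loc[detected]

    indiv = sc.cell_meta["individual_id"].to_numpy()
    pb = {}
    for iid in sc.individuals["individual_id"]:
        mask = indiv == iid
        pb[iid] = sc.counts[:, mask].sum(axis=1)
    pseudobulk = pd.DataFrame(pb, index=sc.gene_ids).loc[detected.index[detected]]
    pseudobulk = pd.DataFrame(
        _cpm_columns(pseudobulk.to_numpy().astype(float)),
        index=pseudobulk.index,
        columns=pseudobulk.columns,
    )
    return CellTypeReference(
        profile=profile, sc_proportions=sc_proportions(sc), pseudobulk=pseudobulk
    )


def estimate_proportions(
    bulk: BulkExpression,
    reference: CellTypeReference,
    overlap_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Decompose bulk samples into cell-type proportions.

    Bulk values are CPM-normalised and restricted to genes shared with the
    reference.  When ``overlap_ids`` names samples present in both the bulk
    and the single-cell data, a per-gene least-squares line from pseudobulk
    (predictor) to observed bulk (response) over those samples is inverted
    to map bulk expression onto the reference scale; genes with non-positive
    slope or fewer than 3 overlap points fall back to mean/variance
    matching.  Each sample is then solved by NNLS and renormalised to the
    simplex.
    """
    cpm = bulk.to_cpm().values
    shared = cpm.index.intersection(reference.profile.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} genes shared between bulk and reference")
    B = cpm.loc[shared].to_numpy().astype(float)
    Z = reference.profile.loc[shared].to_numpy()

    if overlap_ids:
        pb = reference.pseudobulk.loc[shared]
        usable = [s for s in overlap_ids if s in pb.columns and s in cpm.columns]
        X = pb[usable].to_numpy() if usable else np.empty((len(shared), 0))
        Y = cpm.loc[shared, usable].to_numpy() if usable else np.empty((len(shared), 0))
        slope = np.ones(len(shared))
        intercept = np.zeros(len(shared))
        if X.shape[1] >= 3:
            xm = X.mean(axis=1)
            ym = Y.mean(axis=1)
            sxx = ((X - xm[:, None]) ** 2).sum(axis=1)
            sxy = ((X - xm[:, None]) * (Y - ym[:, None])).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                b1 = np.where(sxx > 0, sxy / sxx, 0.0)
            ok = b1 > 0
            slope[ok] = b1[ok]
            intercept[ok] = ym[ok] - b1[ok] * xm[ok]
            # fallback: match first two moments of pseudobulk for the rest
            xs = X.std(axis=1)
            ys = Y.std(axis=1)
            fb = ~ok
            with np.errstate(divide="ignore", invalid="ignore"):
                s_fb = np.where(ys > 0, xs / ys, 1.0)
            slope_inv_fb = np.where(s_fb > 0, s_fb, 1.0)
            slope[fb] = np.where(slope_inv_fb[fb] > 0, 1.0 / slope_inv_fb[fb], 1.0)
            intercept[fb] = ym[fb] - slope[fb] * xm[fb]
        # invert the bulk = slope * reference + intercept relation
        B = (B - intercept[:, None]) / slope[:, None]
        B = np.clip(B, 0.0, None)

    props = np.zeros((B.shape[1], Z.shape[1]))
    for s in range(B.shape[1]):
        b = B[:, s]
        if not np.any(b > 0):
            raise ValueError(f"all-zero bulk sample: {cpm.columns[s]}")
        p, _ = nnls(Z, b)
        tot = p.sum()
        if tot == 0:
            raise ValueError(f"NNLS returned the zero vector for sample {cpm.columns[s]}")
        props[s] = p / tot
    return pd.DataFrame(props, index=cpm.columns, columns=reference.profile.columns)


def bmi_class(bmi) -> pd.Series:
    """Standard BMI classes: normal < 25, 25 <= overweight < 30, obese >= 30."""
    bmi = pd.Series(bmi)
    out = pd.Series("overweight", index=bmi.index, dtype=object)
    out[bmi < 25] = "normal"
    out[bmi >= 30] = "obese"
    return out


@dataclass
class ComparisonResult:
    """One stratum's young-vs-old Wilcoxon comparison of proportions."""

    stratum: str
    n_group1: int
    n_group2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    w_statistic: float
    p: float
    testable: bool = True


def compare_proportions(
    props: pd.DataFrame,
    cell_type: str,
    strata: pd.Series,
    contrast: pd.Series,
    downsample_seed: int | None = None,
) -> list[ComparisonResult]:
    """Two-sided Wilcoxon comparisons of one cell type's proportions.

    Within each level of ``strata`` (e.g. BMI class), compares proportions
    across the two levels of ``contrast`` (e.g. young vs old; levels are
    taken in sorted order, group 1 first).  ``downsample_seed`` optionally
    equalises group sizes by seeded down-sampling before testing.  Groups
    with fewer than 2 members are flagged untestable.
    """
    frac = props[cell_type]
    strata = strata.reindex(frac.index)
    contrast = contrast.reindex(frac.index)
    levels = sorted(contrast.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"contrast must have exactly 2 levels, got {levels}")
    rng = np.random.default_rng(downsample_seed) if downsample_seed is not None else None
    results = []
    for stratum in sorted(strata.dropna().unique()):
        mask = strata == stratum
        g1 = frac[mask & (contrast == levels[0])].to_numpy()
        g2 = frac[mask & (contrast == levels[1])].to_numpy()
        if rng is not None and len(g1) != len(g2) and min(len(g1), len(g2)) > 0:
            k = min(len(g1), len(g2))
            if len(g1) > k:
                g1 = rng.choice(g1, size=k, replace=False)
            else:
                g2 = rng.choice(g2, size=k, replace=False)
        if len(g1) < 2 or len(g2) < 2:
            results.append(
                ComparisonResult(str(stratum), len(g1), len(g2), np.nan, np.nan, np.nan,
                                 np.nan, np.nan, np.nan, testable=False)
            )
            continue
        w, p = rank_sum(g1, g2)
        results.append(
            ComparisonResult(
                stratum=str(stratum),
                n_group1=len(g1),
                n_group2=len(g2),
                mean1=float(g1.mean()),
                mean2=float(g2.mean()),
                sd1=float(g1.std(ddof=1)),
                sd2=float(g2.std(ddof=1)),
                w_statistic=w,
                p=p,
            )
        )
    return results


def partial_spearman(
    x, y, covariates: pd.DataFrame | None = None
) -> tuple[float, float]:
    """Spearman correlation of ``x`` and ``y``, optionally residualised on
    covariates (each variable OLS-residualised before ranking).  Thin helper
    for relating estimated proportions to body-composition phenotypes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is not None and covariates.shape[1] > 0:
        C = np.column_stack([np.ones(len(x)), covariates.to_numpy().astype(float)])
        x = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
        y = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
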
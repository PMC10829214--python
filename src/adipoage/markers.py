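"""Cell-type marker discovery and age differential expression in ASPCs.

Marker genes are called one-vs-rest per cell type with a two-sided Wilcoxon
rank-sum test on log-normalised expression, keeping upregulated genes that
clear a fold-change and expression-fraction filter at a Bonferroni-adjusted
p < 0.05.  Markers of the focal type (ASPCs) that also mark another type are
removed to give the unique marker set.  Age differential expression then
compares expression across ASPC cells of donors split by an age cut.

Normalisation follows the common single-cell convention: UMI counts scaled
to a fixed total per cell (default 1000) then log1p-transformed, so marker
calling is invariant to per-cell library-size rescaling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import adjust_pvalues, rank_sum
from .synthetic import SingleCellDataset

_LOG2FC_PSEUDO = 0.01


def lognormalize(counts: np.ndarray, scale: float = 1000.0) -> np.ndarray:
    """Per-cell total-count scaling to ``scale`` followed by log1p."""
    totals = counts.sum(axis=0).astype(float)
    totals[totals == 0] = 1.0
    return np.log1p(counts * (scale / totals[None, :]))


def _log2fc(mean_in: np.ndarray, mean_out: np.ndarray) -> np.ndarray:
    return np.log2((mean_in + _LOG2FC_PSEUDO) / (mean_out + _LOG2FC_PSEUDO))


def find_cell_type_markers(
    sc: SingleCellDataset,
    min_log2fc: float = 0.25,
    min_pct: float = 0.1,
    adjust: str = "bonferroni",
    alpha: float = 0.05,
    n_tests: str = "all",
) -> pd.DataFrame:
    """One-vs-rest upregulated marker genes per cell type.

    Returns a table with columns gene_id, cell_type, log2fc, pct_in,
    pct_out, p, p_adj, keeping genes with positive log2fc >= ``min_log2fc``,
    expressed in >= ``min_pct`` of in-type cells, and adjusted p < ``alpha``.
    The Bonferroni denominator (``n_tests``) defaults to all genes in the
    dataset per comparison — the convention of the standard discovery tools,
    which also absorbs the selection bias of the fold-change prefilter —
    with "tested" (genes passing the prefilters) available.
    """
    types = sc.cell_types
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    norm = lognormalize(sc.counts)
    labels = sc.cell_meta["cell_type"].to_numpy()
    rows = []
    for ct in types:
        in_mask = labels == ct
        if in_mask.sum() < 3:
            warnings.warn(f"cell type {ct} has < 3 cells; skipped", stacklevel=2)
            continue
        xin = norm[:, in_mask]
        xout = norm[:, ~in_mask]
        pct_in = (xin > 0).mean(axis=1)
        pct_out = (xout > 0).mean(axis=1)
        # fold change on the linear normalized scale (ranks are unaffected)
        lfc = _log2fc(np.expm1(xin).mean(axis=1), np.expm1(xout).mean(axis=1))
        test_idx = np.where((lfc >= min_log2fc) & (pct_in >= min_pct))[0]
        if test_idx.size == 0:
            continue
        pvals = np.array([rank_sum(xin[g], xout[g])[1] for g in test_idx])
        if adjust == "bonferroni" and n_tests == "all":
            padj = np.minimum(pvals * norm.shape[0], 1.0)
        else:
            padj = adjust_pvalues(pvals, method=adjust)
        for g, p, pa in zip(test_idx, pvals, padj):
            if pa < alpha:
                rows.append(
                    {
                        "gene_id": sc.gene_ids[g],
                        "cell_type": ct,
                        "log2fc": float(lfc[g]),
                        "pct_in": float(pct_in[g]),
                        "pct_out": float(pct_out[g]),
                        "p": float(p),
                        "p_adj": float(pa),
                    }
                )
    cols = ["gene_id", "cell_type", "log2fc", "pct_in", "pct_out", "p", "p_adj"]
    return pd.DataFrame(rows, columns=cols)


def unique_markers(markers: pd.DataFrame, focal_type: str = "ASPC") -> list[str]:
    """Focal-type markers minus genes marking any other type, by ascending p."""
    if markers.empty:
        raise ValueError("marker table is empty")
    available = sorted(markers["cell_type"].unique())
    if focal_type not in available:
        raise ValueError(f"cell type {focal_type!r} absent; available: {available}")
    focal = markers.loc[markers["cell_type"] == focal_type].sort_values("p", kind="mergesort")
    shared = set(markers.loc[markers["cell_type"] != focal_type, "gene_id"])
    return [g for g in focal["gene_id"] if g not in shared]


def _age_groups(ages: pd.Series, age_cut) -> tuple[pd.Index, pd.Index]:
    """Donor ids below/above the cut; 'median' and 'quartiles' modes mirror
    the cohort-specific groupings (young = at or below the lower cut, old =
    strictly above the upper cut)."""
    if age_cut == "median":
        lo = hi = ages.median()
    elif age_cut == "quartiles":
        lo = ages.quantile(0.25)
        hi = ages.quantile(0.75)
    else:
        lo = hi = float(age_cut)
    young = ages.index[ages <= lo]
    old = ages.index[ages > hi]
    return young, old


def test_age_de(
    sc: SingleCellDataset,
    genes: list[str],
    age_cut="median",
    cell_type: str = "ASPC",
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Wilcoxon rank-sum age differential expression across cells of one type.

    Cells (not donors) are the sampling unit; donors are classed young/old
    by ``age_cut`` (a year value, 'median', or 'quartiles' which contrasts
    the lowest vs highest age quartile).  Returns gene_id, mean_young,
    mean_old, log2fc (old vs young), p, p_adj, direction.
    """
    if len(genes) == 0:
        return pd.DataFrame(
            columns=["gene_id", "mean_young", "mean_old", "log2fc", "p", "p_adj", "direction"]
        )
    ages = sc.individuals.set_index("individual_id")["age"]
    young_ids, old_ids = _age_groups(ages, age_cut)
    labels = sc.cell_meta["cell_type"].to_numpy()
    indiv = sc.cell_meta["individual_id"].to_numpy()
    ct_mask = labels == cell_type
    young_mask = ct_mask & np.isin(indiv, young_ids)
    old_mask = ct_mask & np.isin(indiv, old_ids)
    n_young = len(set(indiv[young_mask]))
    n_old = len(set(indiv[old_mask]))
    if n_young < 2 or n_old < 2:
        raise ValueError(
            f"both age groups need >= 2 donors with {cell_type} cells "
            f"(young={n_young}, old={n_old})"
        )
    norm = lognormalize(sc.counts)
    gidx = {g: i for i, g in enumerate(sc.gene_ids)}
    rows = []
    for g in genes:
        i = gidx[g]
        xy = norm[i, young_mask]
        xo = norm[i, old_mask]
        _, p = rank_sum(xo, xy)
        my, mo = float(np.expm1(xy).mean()), float(np.expm1(xo).mean())
        lfc = float(_log2fc(np.array(mo), np.array(my)))
        rows.append(
            {
                "gene_id": g,
                "mean_young": my,
                "mean_old": mo,
                "log2fc": lfc,
                "p": p,
                "direction": "up" if lfc >= 0 else "down",
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), method=adjust)
    return out[["gene_id", "mean_young", "mean_old", "log2fc", "p", "p_adj", "direction"]]
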
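"""Polygenic risk scores from GWAS summary statistics.

Implements the summary-statistic penalized-regression approach: per-variant
marginal correlations are derived from beta/SE/N, and lasso weights are
fitted by blockwise coordinate descent against a shrunken block-diagonal LD
matrix ``(1-s) R + s I`` over a grid of penalty (lambda) and shrinkage (s)
values.  Regional scores restrict candidate variants to merged cis-windows
(gene body +/- flank) before fitting.  Split-validation tunes the grid on
one half of held-out data and applies it to the other, standardising each
half before combination.  Greedy LD clumping (r^2 cutoff within a window)
is provided for the single-variant pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import GenomeLayout, GenotypeMatrix

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


DEFAULT_LAMBDA_GRID = tuple(np.geomspace(0.001, 0.1, 20))
DEFAULT_S_GRID = (0.2, 0.5, 0.9, 1.0)


# ---------------------------------------------------------------------------
# cis-windows


@dataclass
class IntervalSet:
    """Sorted, merged genomic intervals (0-based half-open) with provenance."""

    intervals: pd.DataFrame  # chrom, start, end
    retained_genes: list[str] = field(default_factory=list)
    dropped_genes: list[str] = field(default_factory=list)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping/touching half-open intervals per chromosome."""
    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur_s, cur_e = None, None
        for _, r in grp.iterrows():
            s, e = int(r["start"]), int(r["end"])
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def build_cis_windows(
    layout: GenomeLayout | pd.DataFrame,
    gene_set: list[str],
    flank: int = 500_000,
    autosomal_only: bool = True,
) -> IntervalSet:
    """Merged cis-windows (gene body +/- ``flank``) for a gene set.

    Sex-chromosome genes are dropped when ``autosomal_only`` and recorded in
    the provenance.  Intervals are 0-based half-open, clipped at zero.
    """
    genes = layout.genes if isinstance(layout, GenomeLayout) else layout
    sub = genes.set_index("gene_id")
    missing = [g for g in gene_set if g not in sub.index]
    if missing:
        raise ValueError(f"genes absent from annotation: {missing}")
    retained, dropped, rows = [], [], []
    for g in gene_set:
        r = sub.loc[g]
        if autosomal_only and r["chrom"] in ("chrX", "chrY"):
            dropped.append(g)
            continue
        retained.append(g)
        start = max(0, int(r["start"]) - 1 - flank)
        end = int(r["end"]) + flank
        rows.append((r["chrom"], start, end))
    if not rows:
        raise ValueError("no genes remain after the autosomal filter")
    merged = merge_intervals(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    return IntervalSet(intervals=merged, retained_genes=retained, dropped_genes=dropped)


def variants_in_intervals(variants: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask: 1-based position p lies in half-open [s, e) iff s < p <= e."""
    mask = np.zeros(len(variants), dtype=bool)
    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].to_numpy()
    for _, iv in intervals.iterrows():
        mask |= (chrom == iv["chrom"]) & (iv["start"] < pos) & (pos <= iv["end"])
    return mask


# ---------------------------------------------------------------------------
# LD clumping


def ld_clump(
    summary: pd.DataFrame,
    geno_ref: GenotypeMatrix,
    r2_cut: float = 0.1,
    window: int = 250_000,
    p_index: float = 1.0,
) -> list[str]:
    """Greedy LD clumping: repeatedly take the most significant unclumped
    variant (p < ``p_index``) as an index and remove variants within
    +/- ``window`` bp whose dosage r^2 with it is >= ``r2_cut``.  Returns
    index variants sorted by p."""
    if summary.empty:
        return []
    vmap = {vid: i for i, vid in enumerate(geno_ref.variants["variant_id"])}
    snps = summary["SNP"].to_numpy()
    absent = [s for s in snps if s not in vmap]
    if absent:
        raise ValueError(f"summary variants absent from LD reference: {absent[:5]}")
    cand = summary.loc[summary["P"] < p_index].sort_values(
        ["P", "SNP"], kind="mergesort"
    )
    if cand.empty:
        return []
    idx = np.array([vmap[s] for s in cand["SNP"]])
    d = geno_ref.dosages[:, idx]
    d = np.where(np.isnan(d), np.nanmean(d, axis=0), d)
    d = d - d.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", d, d))
    norms[norms == 0] = 1.0
    d = d / norms
    pos = geno_ref.variants["pos"].to_numpy()[idx]
    chrom = geno_ref.variants["chrom"].to_numpy()[idx]
    snp_ids = cand["SNP"].to_numpy()

    alive = np.ones(len(idx), dtype=bool)
    keep = []
    for i in range(len(idx)):
        if not alive[i]:
            continue
        keep.append(snp_ids[i])
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        near[i] = False
        if near.any():
            r2 = (d[:, near].T @ d[:, i]) ** 2
            kill = np.where(near)[0][r2 >= r2_cut]
            alive[kill] = False
        alive[i] = False
    return keep


# ---------------------------------------------------------------------------
# LD reference and lassosum-style fitting


@dataclass
class LDReference:
    """Block-diagonal LD: per-block variant ids and correlation matrices."""

    variant_ids: list[str]
    blocks: list[np.ndarray]  # index arrays into variant_ids
    R: list[np.ndarray]

    def subset(self, keep_ids: list[str]) -> "LDReference":
        keep = set(keep_ids)
        new_ids: list[str] = []
        new_blocks, new_R = [], []
        vid = np.asarray(self.variant_ids)
        for b, R in zip(self.blocks, self.R):
            sel = np.array([k for k, i in enumerate(b) if vid[i] in keep], dtype=int)
            if sel.size == 0:
                continue
            start = len(new_ids)
            new_ids.extend(vid[b[sel]])
            new_blocks.append(np.arange(start, start + sel.size))
            new_R.append(R[np.ix_(sel, sel)])
        return LDReference(new_ids, new_blocks, new_R)


def build_ld_reference(geno: GenotypeMatrix) -> LDReference:
    """Empirical block correlation matrices from a genotype panel, with
    block boundaries at the simulator's LD blocks."""
    d = geno.dosages
    d = np.where(np.isnan(d), np.nanmean(d, axis=0), d)
    d = d - d.mean(axis=0)
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    d = d / sd
    blocks_col = geno.variants["ld_block"].to_numpy()
    vids = geno.variants["variant_id"].tolist()
    blocks, mats = [], []
    for b in np.unique(blocks_col):
        idx = np.where(blocks_col == b)[0]
        sub = d[:, idx]
        R = (sub.T @ sub) / sub.shape[0]
        np.fill_diagonal(R, 1.0)
        blocks.append(idx)
        mats.append(R)
    return LDReference(vids, blocks, mats)


def marginal_correlations(summary: pd.DataFrame) -> np.ndarray:
    """Sign-preserving transform of the per-variant t statistic:
    r_j = beta_j / sqrt(beta_j^2 + (n - 2) se_j^2)."""
    beta = summary["BETA"].to_numpy().astype(float)
    se = summary["SE"].to_numpy().astype(float)
    n = summary["N"].to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = beta / np.sqrt(beta**2 + (n - 2) * se**2)
    return np.nan_to_num(r, nan=0.0)


@njit(cache=True)
def _cd_block(B, r, lam, w, max_sweeps, eps):  # pragma: no cover - numba kernel
    m = r.shape[0]
    viol = 0.0
    for sweep in range(max_sweeps):
        for j in range(m):
            g = r[j] - np.dot(B[j], w) + B[j, j] * w[j]
            if g > lam:
                w[j] = (g - lam) / B[j, j]
            elif g < -lam:
                w[j] = (g + lam) / B[j, j]
            else:
                w[j] = 0.0
        viol = 0.0
        for j in range(m):
            gr = np.dot(B[j], w) - r[j]
            if w[j] > 0.0:
                v = abs(gr + lam)
            elif w[j] < 0.0:
                v = abs(gr - lam)
            else:
                v = abs(gr) - lam
                if v < 0.0:
                    v = 0.0
            if v > viol:
                viol = v
        if viol <= eps:
            return viol, sweep + 1
    return viol, -max_sweeps


def _cd_block_py(B, r, lam, w, max_sweeps, eps):
    """Pure-numpy fallback with identical semantics to the numba kernel."""
    m = r.shape[0]
    viol = 0.0
    for sweep in range(max_sweeps):
        for j in range(m):
            g = r[j] - B[j] @ w + B[j, j] * w[j]
            if g > lam:
                w[j] = (g - lam) / B[j, j]
            elif g < -lam:
                w[j] = (g + lam) / B[j, j]
            else:
                w[j] = 0.0
        grad = B @ w - r
        v_active = np.abs(grad + lam * np.sign(w))
        v_zero = np.clip(np.abs(grad) - lam, 0.0, None)
        viol = float(np.max(np.where(w != 0, v_active, v_zero))) if m else 0.0
        if viol <= eps:
            return viol, sweep + 1
    return viol, -max_sweeps


_cd = _cd_block if _HAVE_NUMBA else _cd_block_py


@dataclass
class PRSWeights:
    """Fitted per-variant weights at one (lambda, s) grid point."""

    table: pd.DataFrame  # SNP, A1, WEIGHT
    method: str
    lam: float
    s: float
    converged: bool
    kkt: float

    @property
    def n_active(self) -> int:
        return int((self.table["WEIGHT"] != 0).sum())


def lasso_objective(w: np.ndarray, B: np.ndarray, r: np.ndarray, lam: float) -> float:
    """0.5 w'Bw - r'w + lam*||w||_1, the quadratic whose stationarity the
    coordinate descent solves."""
    return float(0.5 * w @ B @ w - r @ w + lam * np.abs(w).sum())


def fit_lassosum(
    summary: pd.DataFrame,
    ld: LDReference,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    s_grid=DEFAULT_S_GRID,
    max_sweeps: int = 500,
    eps: float = 1e-9,
) -> list[PRSWeights]:
    """Blockwise coordinate descent over the (lambda, s) grid.

    Solves, per block, the lasso whose stationarity condition is
    ``w_j <- soft(r_j - sum_{k != j} B_jk w_k, lam) / B_jj`` with the
    blended LD matrix ``B = (1-s) R + s I`` (unit diagonal, so B_jj = 1).
    Convergence is declared when the KKT violation falls below ``eps``;
    warm starts are used along the descending lambda path.  Non-converged
    fits are flagged but retained.
    """
    sm = summary.set_index("SNP")
    order = [v for v in ld.variant_ids if v in sm.index]
    if len(order) != len(ld.variant_ids):
        ld = ld.subset(order)
    sm = sm.loc[ld.variant_ids]
    r_all = marginal_correlations(sm.reset_index())
    a1 = sm["A1"].to_numpy()

    results = []
    lambdas = sorted(lambda_grid, reverse=True)
    for s in s_grid:
        if not (0.0 < s <= 1.0):
            raise ValueError("s must lie in (0, 1]")
        w_state = [np.zeros(len(b)) for b in ld.blocks]
        B_blocks = [(1.0 - s) * R + s * np.eye(len(R)) for R in ld.R]
        for lam in lambdas:
            ok = True
            worst = 0.0
            for bi, (b, B) in enumerate(zip(ld.blocks, B_blocks)):
                rb = np.ascontiguousarray(r_all[b])
                viol, sweeps = _cd(B, rb, float(lam), w_state[bi], max_sweeps, eps)
                worst = max(worst, viol)
                if sweeps < 0:
                    ok = False
            w_full = np.empty(len(ld.variant_ids))
            for b, wb in zip(ld.blocks, w_state):
                w_full[b] = wb
            table = pd.DataFrame({"SNP": ld.variant_ids, "A1": a1, "WEIGHT": w_full})
            results.append(
                PRSWeights(table=table, method="lassosum", lam=float(lam), s=float(s),
                           converged=ok, kkt=worst)
            )
    return results


# ---------------------------------------------------------------------------
# scoring and split-validation


def score_individuals(geno: GenotypeMatrix, weights: pd.DataFrame) -> np.ndarray:
    """Allele-frequency-centered weighted dosage sum.

    Dosages are counted on each weight's effect allele and centered at twice
    the effect-allele frequency, which makes the score exactly invariant to
    flipping a variant's coded allele in the weight file (beta -> -beta).
    """
    v = geno.variants.set_index("variant_id")
    vmap = {vid: i for i, vid in enumerate(geno.variants["variant_id"])}
    score = np.zeros(geno.n_individuals)
    af_all = geno.empirical_af()
    for _, row in weights.iterrows():
        if row["WEIGHT"] == 0 or row["SNP"] not in vmap:
            continue
        j = vmap[row["SNP"]]
        d = geno.dosages[:, j]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        meta = v.loc[row["SNP"]]
        if row["A1"] == meta["alt_allele"]:
            eff, af = d, af_all[j]
        elif row["A1"] == meta["ref_allele"]:
            eff, af = 2.0 - d, 1.0 - af_all[j]
        else:
            raise ValueError(f"effect allele of {row['SNP']} matches neither allele")
        score += row["WEIGHT"] * (eff - 2.0 * af)
    return score


def _score_matrix(geno: GenotypeMatrix, candidates: list[PRSWeights]) -> np.ndarray:
    """Vectorised scores for all candidates (columns) at once."""
    d = geno.dosages
    d = np.where(np.isnan(d), np.nanmean(d, axis=0), d)
    af = d.mean(axis=0) / 2.0
    centered = d - 2.0 * af
    vmap = {vid: i for i, vid in enumerate(geno.variants["variant_id"])}
    alt = geno.variants["alt_allele"].to_numpy()
    W = np.zeros((geno.n_variants, len(candidates)))
    for c, cand in enumerate(candidates):
        t = cand.table
        for snp, a1, w in zip(t["SNP"], t["A1"], t["WEIGHT"]):
            if w == 0 or snp not in vmap:
                continue
            j = vmap[snp]
            W[j, c] = w if a1 == alt[j] else -w
    return centered @ W


@dataclass
class ScoreVector:
    """Per-individual standardized scores with test-half labels and the
    tuning chosen on each training half."""

    scores: pd.DataFrame  # individual_id, score, half
    chosen: dict  # half -> {"lambda": .., "s": ..}
    standardized: bool = True


def split_validate_score(
    candidates: list[PRSWeights],
    geno_test: GenotypeMatrix,
    cohort: pd.DataFrame,
    trait: str = "bmi",
) -> ScoreVector:
    """Half-sample tuning: for each test half, pick the candidate whose score
    best correlates with the trait on that half, apply it to the other half,
    z-standardise each applied half separately and concatenate."""
    if not candidates:
        raise ValueError("no candidate weight sets supplied")
    test = cohort.loc[cohort["split"] == "test"]
    id_index = {iid: i for i, iid in enumerate(geno_test.individual_ids)}
    rows = {h: test.loc[test["test_half"] == h] for h in ("A", "B")}
    if rows["A"].empty or rows["B"].empty:
        raise ValueError("test cohort must carry non-empty A/B half labels")
    sub_idx = {h: np.array([id_index[i] for i in rows[h]["individual_id"]]) for h in rows}
    S = _score_matrix(geno_test, candidates)

    chosen = {}
    out = []
    for train_h, apply_h in (("A", "B"), ("B", "A")):
        y = rows[train_h][trait].to_numpy().astype(float)
        if np.std(y) == 0:
            raise ValueError(f"trait has zero variance in half {train_h}")
        sc = S[sub_idx[train_h]]
        yc = y - y.mean()
        scc = sc - sc.mean(axis=0)
        denom = np.sqrt((yc @ yc) * np.einsum("ij,ij->j", scc, scc))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, (scc.T @ yc) / denom, -np.inf)
        best = int(np.argmax(corr))
        chosen[train_h] = {"lambda": candidates[best].lam, "s": candidates[best].s,
                           "index": best}
        applied = S[sub_idx[apply_h], best]
        sd = applied.std()
        applied = (applied - applied.mean()) / (sd if sd > 0 else 1.0)
        out.append(
            pd.DataFrame(
                {
                    "individual_id": rows[apply_h]["individual_id"].to_numpy(),
                    "score": applied,
                    "half": apply_h,
                }
            )
        )
    scores = pd.concat(out, ignore_index=True)
    return ScoreVector(scores=scores, chosen=chosen)


def variance_explained(score: ScoreVector | pd.DataFrame, cohort: pd.DataFrame,
                       trait: str = "bmi") -> float:
    """Squared Pearson correlation between score and trait on scored individuals."""
    df = score.scores if isinstance(score, ScoreVector) else score
    merged = df.merge(cohort[["individual_id", trait]], on="individual_id")
    if len(merged) < 3:
        raise ValueError("need at least 3 scored individuals")
    r = np.corrcoef(merged["score"], merged[trait])[0, 1]
    return float(r**2)
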
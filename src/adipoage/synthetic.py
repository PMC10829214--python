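"""Synthetic cohort generator.

Produces every input the downstream analysis consumes — LD-blocked biallelic
dosages, an age/sex/BMI phenotype with a genotype-by-age interaction confined
to the cis-windows of a designated gene set, cell-type-annotated single-cell
counts whose ASPC fraction declines with age only in low-BMI individuals, and
bulk mixtures of the single-cell profiles — so the full pipeline is testable
offline.

Every simulator is a pure function of its parameters and seed.  Provenance
objects record the planted truth (causal variants, true interaction
coefficient, per-individual proportions) so recovery tests can check against
it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

CELL_TYPES = ["adipocyte", "ASPC", "myeloid", "vascular", "Tcell"]

# ---------------------------------------------------------------------------
# genome layout


@dataclass
class GenomeLayout:
    """Gene annotation plus chromosome lengths.

    ``genes`` columns: gene_id, chrom, start, end (1-based inclusive),
    strand, tss.  ``chrom_lengths`` maps chromosome name to length in bp.
    Sex chromosomes are any chromosome named 'chrX' or 'chrY'.
    """

    genes: pd.DataFrame
    chrom_lengths: dict[str, int]

    def autosomal_genes(self) -> pd.DataFrame:
        mask = ~self.genes["chrom"].isin(["chrX", "chrY"])
        return self.genes.loc[mask]


def random_gene_table(
    chrom_lengths: dict[str, int],
    genes_per_chrom: dict[str, int],
    seed: int,
    gene_length: tuple[int, int] = (5_000, 100_000),
) -> GenomeLayout:
    """Place non-overlapping genes uniformly along each chromosome."""
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for chrom, length in chrom_lengths.items():
        n = genes_per_chrom.get(chrom, 0)
        if n == 0:
            continue
        # anchor gene starts on an even grid, jitter within the slot
        slot = length // (n + 1)
        for i in range(n):
            glen = int(rng.integers(gene_length[0], gene_length[1] + 1))
            start = (i + 1) * slot - glen // 2 + int(rng.integers(-slot // 4, slot // 4 + 1))
            start = max(1, min(start, length - glen))
            strand = "+" if rng.random() < 0.5 else "-"
            end = start + glen - 1
            rows.append(
                {
                    "gene_id": f"G{idx:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "tss": start if strand == "+" else end,
                }
            )
            idx += 1
    genes = pd.DataFrame(rows)
    return GenomeLayout(genes=genes, chrom_lengths=dict(chrom_lengths))


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant metadata.

    ``dosages`` holds alt-allele counts in [0, 2]; missing entries are NaN.
    ``variants`` columns: variant_id, chrom, pos (1-based), ref_allele,
    alt_allele, maf, info, missing_rate, ld_block.
    """

    dosages: np.ndarray
    individual_ids: list[str]
    variants: pd.DataFrame

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def empirical_af(self) -> np.ndarray:
        """Alt-allele frequency per variant, ignoring missing entries."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.individual_ids),
            self.variants.iloc[idx].reset_index(drop=True),
        )

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[idx, :],
            [self.individual_ids[i] for i in idx],
            self.variants.copy(),
        )


def simulate_genotypes(
    n_individuals: int,
    layout: GenomeLayout,
    variants_per_kb: float = 0.3,
    ld_block_kb: float = 100.0,
    ld_rho: float = 0.7,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    missing_rate: float = 0.0,
    info_value: float = 1.0,
) -> GenotypeMatrix:
    """Gaussian-copula haplotypes with AR(1) latent correlation inside
    fixed-length LD blocks.

    Each individual's dosage is the sum of two independent haplotypes; a
    haplotype carries the alt allele at variant j when its latent normal
    falls below ``Phi^{-1}(maf_j)``.  Within a block, adjacent latent values
    have correlation ``ld_rho``; across blocks (and chromosomes) they are
    independent, so the realised allele correlation is the tetrachoric value
    implied by the copula thresholds.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if layout.genes.empty:
        raise ValueError("empty genome layout")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must lie in [0, 1)")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a sub-interval of (0, 0.5]")
    rng = np.random.default_rng(seed)

    var_rows = []
    block_global = 0
    chrom_positions: dict[str, np.ndarray] = {}
    for chrom, length in layout.chrom_lengths.items():
        n_var = max(1, int(round(length / 1000.0 * variants_per_kb)))
        # rejection-free distinct positions without materialising the genome
        pos = np.unique(rng.integers(1, length + 1, size=int(n_var * 1.1) + 16))
        while pos.size < n_var:
            pos = np.unique(
                np.concatenate([pos, rng.integers(1, length + 1, size=n_var)])
            )
        pos = np.sort(rng.permutation(pos)[:n_var])
        chrom_positions[chrom] = pos
        block_ids = pos // int(ld_block_kb * 1000)
        # remap to globally unique consecutive block indices
        _, local = np.unique(block_ids, return_inverse=True)
        for p, b in zip(pos, local):
            var_rows.append(
                {
                    "variant_id": f"{chrom}:{p}",
                    "chrom": chrom,
                    "pos": int(p),
                    "ref_allele": "A",
                    "alt_allele": "G",
                    "ld_block": block_global + int(b),
                }
            )
        block_global += int(local.max()) + 1
    variants = pd.DataFrame(var_rows)
    m = len(variants)
    mafs = rng.uniform(lo, hi, size=m)
    variants["maf"] = mafs
    variants["info"] = info_value
    variants["missing_rate"] = missing_rate

    thresholds = sps.norm.ppf(mafs)
    blocks = variants["ld_block"].to_numpy()
    dosage = np.zeros((n_individuals, m), dtype=float)
    for _hap in range(2):
        z = rng.standard_normal((n_individuals, m))
        scale = np.sqrt(1.0 - ld_rho**2)
        for j in range(1, m):
            if blocks[j] == blocks[j - 1]:
                z[:, j] = ld_rho * z[:, j - 1] + scale * z[:, j]
        dosage += (z < thresholds[None, :]).astype(float)

    if missing_rate > 0:
        mask = rng.random((n_individuals, m)) < missing_rate
        dosage[mask] = np.nan

    ids = [f"I{i:05d}" for i in range(n_individuals)]
    return GenotypeMatrix(dosage, ids, variants)


def tetrachoric_correlation(maf1: float, maf2: float, rho: float) -> float:
    """Allele correlation implied by the copula for adjacent variants.

    Oracle-style closed form: the orthant probability
    ``P(Z1 < t1, Z2 < t2)`` under a bivariate normal with correlation
    ``rho`` gives the joint allele probability, from which the Pearson
    correlation of the two Bernoulli alleles follows.
    """
    t1, t2 = sps.norm.ppf(maf1), sps.norm.ppf(maf2)
    p11 = sps.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([t1, t2])
    num = p11 - maf1 * maf2
    den = np.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2))
    return float(num / den)


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class PhenotypeParams:
    """Generative parameters for the BMI-like phenotype.

    ``h2_main`` is the fraction of ``var_scale`` (the target phenotypic
    variance, kg^2/m^4) contributed by additive main effects.
    ``gamma_interaction`` multiplies centered age times the standardized
    regional genetic score (kg/m^2 per year per SD).
    """

    h2_main: float = 0.25
    n_causal_main: int = 80
    gamma_interaction: float = 0.0
    age_dist: tuple[float, float] = (25.0, 73.0)
    sex_effect: float = 1.0
    noise_sd: float = 4.0
    beta_age: float = 0.05
    var_scale: float = 25.0
    bmi_intercept: float = 27.0
    n_pcs: int = 4
    pc_effect: float = 0.1
    cis_flank: int = 500_000


@dataclass
class PhenotypeProvenance:
    """Planted truth recorded for recovery tests."""

    causal_variant_ids: list[str]
    causal_effects: np.ndarray
    interaction_variant_ids: list[str]
    interaction_weights: np.ndarray
    gamma_interaction: float
    target_genes: list[str]
    burden: np.ndarray
    seed: int


def _standardize_dosages(d: np.ndarray) -> np.ndarray:
    filled = np.where(np.isnan(d), np.nanmean(d, axis=0), d)
    mu = filled.mean(axis=0)
    sd = filled.std(axis=0)
    sd[sd == 0] = 1.0
    return (filled - mu) / sd


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    layout: GenomeLayout,
    target_set: list[str],
    params: PhenotypeParams,
    seed: int = 0,
) -> tuple[pd.DataFrame, PhenotypeProvenance]:
    """Generate the cohort table with a planted genotype-by-age interaction.

    BMI = intercept + additive main effects (causal variants sampled
    genome-wide, scaled to heritability ``h2_main``) + age main effect +
    ``gamma_interaction`` * centered age * standardized regional genetic
    score of the causal variants inside the target genes' cis-windows + sex
    effect + small PC/center/array effects + Gaussian noise.

    Raises if any target gene's cis-window contains zero variants (naming
    the empty genes).
    """
    rng = np.random.default_rng(seed)
    p = params
    genes = layout.genes.set_index("gene_id")
    missing = [g for g in target_set if g not in genes.index]
    if missing:
        raise ValueError(f"target genes absent from layout: {missing}")

    n = genotypes.n_individuals
    m = genotypes.n_variants
    gstd = _standardize_dosages(genotypes.dosages)

    n_causal = min(p.n_causal_main, m)
    causal_idx = np.sort(rng.choice(m, size=n_causal, replace=False))
    raw_effects = rng.standard_normal(n_causal)
    genetic = gstd[:, causal_idx] @ raw_effects
    target_sd = np.sqrt(p.h2_main * p.var_scale)
    emp_sd = genetic.std()
    if p.h2_main > 0 and emp_sd > 0:
        scale = target_sd / emp_sd
    else:
        scale = 0.0
    effects = raw_effects * scale
    genetic = genetic * scale

    # interaction burden: main-effect-weighted score of causal variants
    # inside the target cis-windows (falls back to unit weights when no
    # main effects were generated)
    vpos = genotypes.variants["pos"].to_numpy()
    vchrom = genotypes.variants["chrom"].to_numpy()
    in_window = np.zeros(m, dtype=bool)
    empty = []
    for g in target_set:
        row = genes.loc[g]
        lo = max(0, int(row["start"]) - p.cis_flank)
        hi = int(row["end"]) + p.cis_flank
        mask = (vchrom == row["chrom"]) & (vpos >= lo) & (vpos < hi)
        if not mask.any():
            empty.append(g)
        in_window |= mask
    if empty:
        raise ValueError(f"cis-windows contain zero variants for genes: {empty}")
    inter_mask = np.zeros(m, dtype=bool)
    inter_mask[causal_idx] = True
    inter_mask &= in_window
    inter_idx = np.where(inter_mask)[0]
    if p.gamma_interaction != 0 and inter_idx.size == 0:
        raise ValueError("no causal variants fall inside the target cis-windows")
    if inter_idx.size:
        w = effects[np.isin(causal_idx, inter_idx)]
        if np.all(w == 0):
            w = np.ones(inter_idx.size)
        burden = gstd[:, inter_idx] @ w
        bsd = burden.std()
        burden = burden / bsd if bsd > 0 else burden
    else:
        w = np.zeros(0)
        burden = np.zeros(n)

    age = rng.uniform(p.age_dist[0], p.age_dist[1], size=n)
    age_c = age - age.mean()
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    pcs = rng.standard_normal((n, p.n_pcs))
    center = rng.integers(0, 3, size=n)
    array = rng.integers(0, 2, size=n)

    bmi = (
        p.bmi_intercept
        + genetic
        + p.beta_age * age_c
        + p.gamma_interaction * age_c * burden
        + p.sex_effect * (sex == "male")
        + pcs @ np.full(p.n_pcs, p.pc_effect)
        + 0.1 * center
        + 0.05 * array
        + rng.normal(0.0, p.noise_sd, size=n)
    )

    cohort = pd.DataFrame(
        {
            "individual_id": genotypes.individual_ids,
            "age": age,
            "sex": sex,
            "bmi": bmi,
        }
    )
    for k in range(p.n_pcs):
        cohort[f"pc{k + 1}"] = pcs[:, k]
    cohort["center"] = pd.Categorical([f"c{c}" for c in center])
    cohort["array"] = pd.Categorical([f"a{a}" for a in array])
    cohort = assign_splits(cohort, seed=int(rng.integers(0, 2**31 - 1)))

    prov = PhenotypeProvenance(
        causal_variant_ids=genotypes.variants["variant_id"].iloc[causal_idx].tolist(),
        causal_effects=effects,
        interaction_variant_ids=genotypes.variants["variant_id"].iloc[inter_idx].tolist(),
        interaction_weights=np.asarray(w),
        gamma_interaction=p.gamma_interaction,
        target_genes=list(target_set),
        burden=burden,
        seed=seed,
    )
    return cohort, prov


def assign_splits(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Assign base/test splits and A/B test halves, stratified by sex.

    Stratification preserves the male:female ratio across splits, as the
    split-validation contract requires.
    """
    rng = np.random.default_rng(seed)
    cohort = cohort.copy()
    cohort["split"] = "base"
    cohort["test_half"] = "none"
    for _sex, idx in cohort.groupby("sex", observed=True).groups.items():
        idx = np.asarray(idx)
        perm = rng.permutation(idx)
        half = len(perm) // 2
        test_ids = perm[half:]
        cohort.loc[test_ids, "split"] = "test"
        sub = rng.permutation(test_ids)
        cohort.loc[sub[: len(sub) // 2], "test_half"] = "A"
        cohort.loc[sub[len(sub) // 2 :], "test_half"] = "B"
    return cohort


# ---------------------------------------------------------------------------
# single-cell


@dataclass
class ProportionModel:
    """Cell-type proportion model: the ASPC fraction declines linearly with
    age in individuals below the BMI gate and sits at a constant lower level
    (no age term) above it."""

    base_props: dict[str, float] = field(
        default_factory=lambda: {
            "adipocyte": 0.45,
            "ASPC": 0.20,
            "myeloid": 0.15,
            "vascular": 0.12,
            "Tcell": 0.08,
        }
    )
    age_slope_on_aspc: float = 0.002
    bmi_gate: float = 30.0
    obese_offset: float = 0.05
    age_mid: float = 49.0


@dataclass
class SingleCellDataset:
    """Genes x cells integer counts with cell and individual metadata."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame  # cell_id, individual_id, cell_type
    individuals: pd.DataFrame  # individual_id, age, sex, bmi
    true_proportions: pd.DataFrame | None = None  # planted per-individual props

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.cell_meta["cell_type"].unique())


def default_sc_individuals(n_individuals: int, seed: int) -> pd.DataFrame:
    """Donor table for the single-cell fixture: ages uniform 25-73 years,
    alternating sex, half below-gate BMI (20-24.5) and half obese (30-38)."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(25.0, 73.0, size=n_individuals)
    sex = np.where(np.arange(n_individuals) % 2 == 0, "female", "male")
    lean = np.arange(n_individuals) < n_individuals // 2
    bmi = np.where(
        lean,
        rng.uniform(20.0, 24.5, size=n_individuals),
        rng.uniform(30.0, 38.0, size=n_individuals),
    )
    return pd.DataFrame(
        {
            "individual_id": [f"D{i:03d}" for i in range(n_individuals)],
            "age": age,
            "sex": sex,
            "bmi": bmi,
        }
    )


def random_profiles(
    n_genes: int,
    seed: int,
    cell_types: list[str] | None = None,
    markers_per_type: int = 10,
    marker_fold: float = 8.0,
    base_mean: float = 1.0,
) -> pd.DataFrame:
    """Genes x cell-types mean-expression matrix with planted markers.

    The first ``markers_per_type`` genes of each consecutive gene stripe are
    elevated ``marker_fold``-fold in one cell type, giving marker calling
    real structure; remaining genes share a lognormal baseline across types.
    """
    cell_types = cell_types or CELL_TYPES
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=np.log(base_mean), sigma=0.6, size=n_genes)
    prof = np.tile(base[:, None], (1, len(cell_types)))
    for t, _ct in enumerate(cell_types):
        lo = t * markers_per_type
        hi = min(lo + markers_per_type, n_genes)
        prof[lo:hi, t] *= marker_fold
    genes = [f"ENSG{i:05d}" for i in range(n_genes)]
    return pd.DataFrame(prof, index=genes, columns=cell_types)


def simulate_single_cell(
    n_individuals: int,
    profiles: pd.DataFrame,
    proportion_model: ProportionModel,
    cells_per_individual: int = 300,
    age_de_genes: dict[str, float] | None = None,
    seed: int = 0,
    individuals: pd.DataFrame | None = None,
    age_half_range: float = 24.0,
) -> SingleCellDataset:
    """Multinomial cell-type composition + Poisson per-cell counts.

    ``age_de_genes`` maps gene id -> log2 fold change across the donor age
    span: a gene's ASPC-cell mean is multiplied by ``2**(lfc * z)`` where
    ``z = (age - age_mid) / age_half_range``, so donors one half-range above
    the midpoint express ``2**lfc``-fold more than the midpoint donor and
    young/old donor groups differ by about ``2**lfc``-fold.  The effect is
    restricted to ASPC cells.
    """
    pm = proportion_model
    rng = np.random.default_rng(seed)
    if individuals is None:
        individuals = default_sc_individuals(n_individuals, seed=int(rng.integers(2**31 - 1)))
    cell_types = list(profiles.columns)
    base = np.array([pm.base_props[t] for t in cell_types])
    if not np.isclose(base.sum(), 1.0):
        raise ValueError("base proportions must sum to 1")
    if (profiles.to_numpy() < 0).any():
        raise ValueError("profiles must be non-negative")
    aspc_col = cell_types.index("ASPC")
    age_de_genes = age_de_genes or {}

    counts_blocks = []
    meta_rows = []
    true_props = []
    profile_mat = profiles.to_numpy()
    gene_index = {g: i for i, g in enumerate(profiles.index)}
    for _, ind in individuals.iterrows():
        props = base.copy()
        if ind["bmi"] < pm.bmi_gate:
            target = pm.base_props["ASPC"] - pm.age_slope_on_aspc * (ind["age"] - pm.age_mid)
        else:
            target = pm.base_props["ASPC"] - pm.obese_offset
        if not (0.0 <= target <= 1.0):
            warnings.warn(
                f"ASPC proportion {target:.3f} clipped to [0, 1] for {ind['individual_id']}",
                stacklevel=2,
            )
            target = float(np.clip(target, 0.0, 1.0))
        props[aspc_col] = target
        others = [i for i in range(len(cell_types)) if i != aspc_col]
        props[others] = base[others] * (1.0 - target) / base[others].sum()
        true_props.append(props)

        type_counts = rng.multinomial(cells_per_individual, props)
        z = (ind["age"] - pm.age_mid) / age_half_range
        for t, ct in enumerate(cell_types):
            nc = type_counts[t]
            if nc == 0:
                continue
            lam = profile_mat[:, t].copy()
            if ct == "ASPC":
                for g, lfc in age_de_genes.items():
                    lam[gene_index[g]] *= 2.0 ** (lfc * z)
            block = rng.poisson(lam[:, None], size=(len(lam), nc))
            counts_blocks.append(block)
            for _c in range(nc):
                meta_rows.append((ind["individual_id"], ct))

    counts = np.concatenate(counts_blocks, axis=1).astype(np.int32)
    cell_ids = [f"CELL{i:06d}" for i in range(counts.shape[1])]
    cell_meta = pd.DataFrame(meta_rows, columns=["individual_id", "cell_type"])
    cell_meta.insert(0, "cell_id", cell_ids)
    tp = pd.DataFrame(
        true_props, index=individuals["individual_id"].tolist(), columns=cell_types
    )
    return SingleCellDataset(
        counts=counts,
        gene_ids=list(profiles.index),
        cell_ids=cell_ids,
        cell_meta=cell_meta,
        individuals=individuals.reset_index(drop=True),
        true_proportions=tp,
    )


# ---------------------------------------------------------------------------
# open chromatin


def simulate_open_chromatin(
    geno: GenotypeMatrix,
    coverage: float = 0.5,
    peak_halfwidth: int = 1_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic accessible-chromatin intervals (BED convention: 0-based
    half-open, sorted, non-overlapping).

    Peaks of +/- ``peak_halfwidth`` bp are centred on a random ``coverage``
    fraction of variant positions, then merged — a regulatory-filter
    stand-in that guarantees a known subset of variants lands inside open
    chromatin.
    """
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    v = geno.variants
    pick = rng.random(len(v)) < coverage
    rows = [
        (c, max(0, p - 1 - peak_halfwidth), p + peak_halfwidth)
        for c, p in zip(v.loc[pick, "chrom"], v.loc[pick, "pos"])
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    from .prs import merge_intervals  # local import: prs has no synthetic dep

    return merge_intervals(df) if not df.empty else df


# ---------------------------------------------------------------------------
# bulk mixtures


@dataclass
class BulkExpression:
    """Genes x samples expression, raw counts or CPM."""

    values: pd.DataFrame
    normalization: str = "counts"  # counts | cpm

    def to_cpm(self) -> "BulkExpression":
        if self.normalization == "cpm":
            return self
        totals = self.values.sum(axis=0)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0].tolist()
            raise ValueError(f"all-zero bulk sample(s): {bad}")
        return BulkExpression(self.values * 1e6 / totals, "cpm")


def simulate_bulk_mixture(
    reference_profiles: pd.DataFrame,
    proportions: pd.DataFrame,
    library_size: int = 1_000_000,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> BulkExpression:
    """Bulk samples as noisy mixtures of cell-type reference profiles.

    Expected expression per sample is ``Z @ p`` scaled to ``library_size``,
    with multiplicative log-normal noise of coefficient of variation
    ``noise_cv`` (mean-one, so expectations are preserved).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    P = proportions.to_numpy()
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("proportion rows must sum to 1")
    rng = np.random.default_rng(seed)
    Z = reference_profiles[proportions.columns].to_numpy()
    expected = Z @ P.T  # genes x samples
    col_totals = expected.sum(axis=0)
    col_totals[col_totals == 0] = 1.0
    expected = expected * (library_size / col_totals)
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=expected.shape)
        expected = expected * noise
    values = pd.DataFrame(
        expected, index=reference_profiles.index, columns=proportions.index
    )
    return BulkExpression(values=values, normalization="counts")
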
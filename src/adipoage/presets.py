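"""Default study presets: the synthetic conditions under which the whole
pipeline is exercised.

One genome layout (two 20-Mb autosomes plus a 6-Mb sex chromosome carrying
78 genes) and one cohort scale (2,400 individuals split half base / half
test) serve as the standard desk-scale study; the single-cell preset is a
40-donor, 120-gene fixture with the lean-only ASPC age decline.  The
planted PRS-by-age interaction strength ``DEFAULT_GAMMA`` was calibrated so
that one replicate of the full pipeline yields an interaction Wald p on the
order of 1e-2, the regime in which the permutation analysis is informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas import run_gwas
from .interaction import adjust_phenotype
from .permutation import PRSConfig
from .synthetic import (
    GenomeLayout,
    GenotypeMatrix,
    PhenotypeParams,
    PhenotypeProvenance,
    ProportionModel,
    SingleCellDataset,
    random_gene_table,
    random_profiles,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_single_cell,
)

_LAYOUT_SEED = 20240131  # the genome layout is a fixed map, not a random draw
DEFAULT_GAMMA = -0.08  # kg/m^2 per year per SD of the regional genetic score
GWAS_COVARIATES = ["sex", "pc1", "pc2", "pc3", "pc4", "center", "array"]
ADJUST_COVARIATES = ["pc1", "pc2", "pc3", "pc4", "center", "array", "sex"]


def default_layout() -> GenomeLayout:
    return random_gene_table(
        chrom_lengths={"chr1": 20_000_000, "chr2": 20_000_000, "chrX": 6_000_000},
        genes_per_chrom={"chr1": 36, "chr2": 36, "chrX": 6},
        seed=_LAYOUT_SEED,
    )


def default_target_genes(layout: GenomeLayout | None = None, size: int = 6) -> list[str]:
    """The designated age-DE-like gene set: a fixed, well-spread autosomal
    subset of the default layout."""
    layout = layout or default_layout()
    pool = layout.autosomal_genes()["gene_id"].to_numpy()
    rng = np.random.default_rng(_LAYOUT_SEED + 1)
    return sorted(rng.choice(pool, size=size, replace=False))


@dataclass
class StudyData:
    """One simulated replicate of the genetic study, GWAS already run."""

    layout: GenomeLayout
    geno: GenotypeMatrix
    cohort: pd.DataFrame
    provenance: PhenotypeProvenance
    target_genes: list[str]
    summary: pd.DataFrame
    adj_bmi: np.ndarray
    prs_config: PRSConfig

    @property
    def geno_base(self) -> GenotypeMatrix:
        return self._split_geno("base")

    @property
    def geno_test(self) -> GenotypeMatrix:
        return self._split_geno("test")

    def _split_geno(self, split: str) -> GenotypeMatrix:
        idx = np.where((self.cohort["split"] == split).to_numpy())[0]
        return self.geno.subset_individuals(idx)


def simulate_study(
    seed: int,
    n_individuals: int = 2_400,
    gamma: float = DEFAULT_GAMMA,
    layout: GenomeLayout | None = None,
    target_genes: list[str] | None = None,
    variants_per_kb: float = 0.04,
    ld_block_kb: float = 200.0,
    ld_rho: float = 0.7,
    h2_main: float = 0.25,
    n_causal_main: int = 80,
    run_base_gwas: bool = True,
) -> StudyData:
    """Simulate one replicate of the default study and run the base GWAS.

    The phenotype carries genome-wide additive main effects (h2 = 0.25 of a
    25 kg^2/m^4 variance scale over 80 causal variants) and an age
    interaction confined to the cis-windows of the target gene set.  The
    base-split GWAS is non-age-adjusted (the configuration from which the
    PRS is built) and the adjusted phenotype residualises on PCs, center,
    array and sex before the inverse-normal transform.
    """
    layout = layout or default_layout()
    target_genes = target_genes or default_target_genes(layout)
    rng = np.random.default_rng(seed)
    geno = simulate_genotypes(
        n_individuals,
        layout,
        variants_per_kb=variants_per_kb,
        ld_block_kb=ld_block_kb,
        ld_rho=ld_rho,
        seed=int(rng.integers(2**31 - 1)),
    )
    params = PhenotypeParams(
        h2_main=h2_main,
        n_causal_main=n_causal_main,
        gamma_interaction=gamma,
    )
    cohort, prov = simulate_phenotypes(
        geno, layout, target_genes, params, seed=int(rng.integers(2**31 - 1))
    )
    summary = None
    if run_base_gwas:
        base_idx = np.where((cohort["split"] == "base").to_numpy())[0]
        summary = run_gwas(
            geno.subset_individuals(base_idx),
            cohort.loc[cohort["split"] == "base"],
            trait="bmi",
            covariates=GWAS_COVARIATES,
            adjust_age=False,
        )
    adj_bmi = adjust_phenotype(cohort, "bmi", ADJUST_COVARIATES)
    cfg = PRSConfig(genes=layout.genes)
    return StudyData(
        layout=layout,
        geno=geno,
        cohort=cohort,
        provenance=prov,
        target_genes=target_genes,
        summary=summary,
        adj_bmi=adj_bmi,
        prs_config=cfg,
    )


def default_sc_profiles(n_genes: int = 120, seed: int = _LAYOUT_SEED + 2) -> pd.DataFrame:
    return random_profiles(n_genes, seed=seed, markers_per_type=12, marker_fold=8.0)


def simulate_sc_study(
    seed: int,
    n_individuals: int = 40,
    cells_per_individual: int = 300,
    profiles: pd.DataFrame | None = None,
    age_de_genes: dict[str, float] | None = None,
) -> SingleCellDataset:
    """The default single-cell fixture: lean-only ASPC age decline
    (slope 0.002 per year below BMI 30, constant 0.05 deficit above)."""
    profiles = profiles if profiles is not None else default_sc_profiles()
    return simulate_single_cell(
        n_individuals,
        profiles,
        ProportionModel(),
        cells_per_individual=cells_per_individual,
        age_de_genes=age_de_genes,
        seed=seed,
    )
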
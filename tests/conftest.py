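import numpy as np
import pandas as pd
import pytest

from adipoage.synthetic import (
    GenomeLayout,
    GenotypeMatrix,
    ProportionModel,
    random_gene_table,
    random_profiles,
    simulate_genotypes,
    simulate_single_cell,
)


@pytest.fixture(scope="session")
def tiny_layout() -> GenomeLayout:
    return random_gene_table(
        chrom_lengths={"chr1": 5_000_000, "chr2": 5_000_000, "chrX": 2_000_000},
        genes_per_chrom={"chr1": 8, "chr2": 8, "chrX": 2},
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_geno(tiny_layout) -> GenotypeMatrix:
    return simulate_genotypes(
        400, tiny_layout, variants_per_kb=0.05, ld_block_kb=100, ld_rho=0.6, seed=12
    )


@pytest.fixture(scope="session")
def small_sc():
    profiles = random_profiles(60, seed=21, markers_per_type=6, marker_fold=10.0,
                               base_mean=2.0)
    return simulate_single_cell(
        20, profiles, ProportionModel(), cells_per_individual=150, seed=22
    )


def make_genotype_matrix(dosages: np.ndarray, chrom="chr1", pos=None,
                         spacing=10_000) -> GenotypeMatrix:
    """Hand-built GenotypeMatrix for tests that don't need the copula."""
    n, m = dosages.shape
    pos = np.asarray(pos) if pos is not None else (np.arange(m) + 1) * spacing
    af = np.nanmean(dosages, axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "variant_id": [f"{chrom}:{p}" for p in pos],
            "chrom": chrom,
            "pos": pos,
            "ref_allele": "A",
            "alt_allele": "G",
            "maf": np.minimum(af, 1 - af),
            "info": 1.0,
            "missing_rate": np.mean(np.isnan(dosages), axis=0),
            "ld_block": pos // 250_000,
        }
    )
    ids = [f"I{i:05d}" for i in range(n)]
    return GenotypeMatrix(dosages.astype(float), ids, variants)
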
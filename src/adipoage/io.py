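"""Readers and writers for the pipeline's on-disk formats.

Plain-text TSV carriers for dosages, phenotypes, gene annotations, summary
statistics, PRS weights and scores; BED (0-based half-open) for interval
sets; MatrixMarket + barcodes/features for single-cell counts; and a
minimal PLINK BED/BIM/FAM codec (SNP-major, 2-bit codes, genotypes
hard-called on write — the dosage TSV writer preserves fractional values).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .synthetic import BulkExpression, GenotypeMatrix, SingleCellDataset

# ---------------------------------------------------------------------------
# TSV carriers


def write_dosage_tsv(geno: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    geno.variants.to_csv(prefix.with_suffix(".variants.tsv"), sep="\t", index=False)
    df = pd.DataFrame(
        geno.dosages, index=geno.individual_ids, columns=geno.variants["variant_id"]
    )
    df.to_csv(prefix.with_suffix(".dosages.tsv"), sep="\t", index_label="individual_id")


def read_dosage_tsv(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    variants = pd.read_csv(prefix.with_suffix(".variants.tsv"), sep="\t")
    df = pd.read_csv(prefix.with_suffix(".dosages.tsv"), sep="\t", index_col=0)
    return GenotypeMatrix(df.to_numpy().astype(float), list(df.index), variants)


def write_phenotypes(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    genes[["gene_id", "chrom", "start", "end", "strand"]].to_csv(
        path, sep="\t", index=False
    )


def read_gene_table(path: str | Path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t")
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])
    return genes


def write_bed_intervals(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])


def write_summary_stats(summary: pd.DataFrame, path: str | Path) -> None:
    cols = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N", "MAF", "INFO"]
    summary[cols].to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_weights(weights, path: str | Path) -> None:
    t = weights.table.copy()
    t["METHOD"] = weights.method
    t["LAMBDA"] = weights.lam
    t["S"] = weights.s
    t.to_csv(path, sep="\t", index=False)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    out = scores.rename(columns={"individual_id": "IID", "score": "SCORE", "half": "HALF"})
    out.to_csv(path, sep="\t", index=False)


def write_bulk_tsv(bulk: BulkExpression, path: str | Path) -> None:
    bulk.values.to_csv(path, sep="\t", index_label="gene_id")


def read_bulk_tsv(path: str | Path, normalization: str = "counts") -> BulkExpression:
    return BulkExpression(pd.read_csv(path, sep="\t", index_col=0), normalization)


# ---------------------------------------------------------------------------
# single-cell MTX


def write_single_cell(sc: SingleCellDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(sc.counts))
    pd.Series(sc.gene_ids).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(sc.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    sc.cell_meta.to_csv(outdir / "cell_metadata.tsv", sep="\t", index=False)
    sc.individuals.to_csv(outdir / "individuals.tsv", sep="\t", index=False)


def read_single_cell(outdir: str | Path) -> SingleCellDataset:
    outdir = Path(outdir)
    counts = np.asarray(spio.mmread(outdir / "matrix.mtx").todense()).astype(np.int32)
    genes = pd.read_csv(outdir / "features.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(outdir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    cell_meta = pd.read_csv(outdir / "cell_metadata.tsv", sep="\t")
    individuals = pd.read_csv(outdir / "individuals.tsv", sep="\t")
    return SingleCellDataset(counts, genes, cells, cell_meta, individuals)


# ---------------------------------------------------------------------------
# PLINK BED/BIM/FAM

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit codes: 00 hom A1, 01 missing, 10 het, 11 hom A2; A1 = alt allele here
_CODE_FOR_ALT_COUNT = {2: 0b00, 1: 0b10, 0: 0b11}
_ALT_COUNT_FOR_CODE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Hard-call dosages (rounded; NaN -> missing) and write BED/BIM/FAM."""
    prefix = Path(prefix)
    n = geno.n_individuals
    hard = np.round(geno.dosages)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(geno.n_variants):
            col = hard[:, j]
            byts = bytearray((n + 3) // 4)
            for i in range(n):
                g = col[i]
                code = 0b01 if np.isnan(g) else _CODE_FOR_ALT_COUNT[int(g)]
                byts[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(byts))
    bim = geno.variants[["chrom", "variant_id", "pos", "alt_allele", "ref_allele"]].copy()
    bim.insert(2, "cm", 0)
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", index=False, header=False)
    fam = pd.DataFrame(
        {
            "fid": geno.individual_ids,
            "iid": geno.individual_ids,
            "pid": 0,
            "mid": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", index=False, header=False)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep="\t",
        header=None,
        names=["chrom", "variant_id", "cm", "pos", "alt_allele", "ref_allele"],
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep="\t", header=None)
    ids = fam[1].astype(str).tolist()
    n, m = len(ids), len(bim)
    dos = np.empty((n, m))
    with open(prefix.with_suffix(".bed"), "rb") as fh:
        if fh.read(3) != _BED_MAGIC:
            raise ValueError("not a SNP-major PLINK BED file")
        nbytes = (n + 3) // 4
        for j in range(m):
            raw = fh.read(nbytes)
            for i in range(n):
                code = (raw[i // 4] >> (2 * (i % 4))) & 0b11
                dos[i, j] = _ALT_COUNT_FOR_CODE[code]
    variants = bim[["variant_id", "chrom", "pos", "ref_allele", "alt_allele"]].copy()
    af = np.nanmean(dos, axis=0) / 2.0
    variants["maf"] = np.minimum(af, 1 - af)
    variants["info"] = 1.0
    variants["missing_rate"] = np.mean(np.isnan(dos), axis=0)
    variants["ld_block"] = 0
    return GenotypeMatrix(dos, ids, variants)
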
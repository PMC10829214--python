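"""Generate a synthetic study cohort and write its inputs to disk.

Builds the default two-autosome genome, simulates LD-blocked genotypes and
a BMI-like phenotype with a planted gene-by-age interaction, and writes
PLINK/TSV/BED files under ./scratch_example/.
"""

from pathlib import Path

from adipoage import io as aio
from adipoage.presets import simulate_study
from adipoage.synthetic import simulate_open_chromatin

out = Path("scratch_example")
out.mkdir(exist_ok=True)

study = simulate_study(seed=1)
aio.write_plink(study.geno, out / "cohort")
aio.write_phenotypes(study.cohort, out / "phenotypes.tsv")
aio.write_gene_table(study.layout.genes, out / "genes.tsv")
aio.write_summary_stats(study.summary, out / "gwas_base.tsv")
atac = simulate_open_chromatin(study.geno, coverage=0.5, seed=2)
aio.write_bed_intervals(atac, out / "open_chromatin.bed")

print(f"individuals:         {study.geno.n_individuals}")
print(f"variants:            {study.geno.n_variants}")
print(f"genes:               {len(study.layout.genes)}")
print(f"target gene set:     {study.target_genes}")
print(f"planted interaction: {study.provenance.gamma_interaction} kg/m^2 per year per SD")
print(f"causal variants in target cis-windows: "
      f"{len(study.provenance.interaction_variant_ids)}")
# The target gene set carries the planted age interaction; everything else
# is background polygenic signal.
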
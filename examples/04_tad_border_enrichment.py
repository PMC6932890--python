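"""Test whether non-coding SNPs pile up in TAD border regions.

Border cores are widened by 100 bp on each side; the observed non-coding
SNP count inside them is compared with the average over 100 matched random
border sets (same chromosome, same core widths, never overlapping a real
border region) using Fisher's exact test.
"""

from coloc_longevity import (
    SimulationConfig,
    classify_coding,
    gene_border_proximity,
    simulate_annotations,
    simulate_gwas_tables,
    tad_enrichment_test,
)

config = SimulationConfig(
    seed=7,
    chromosomes=(("2L", 3_000_000), ("2R", 3_000_000), ("X", 3_000_000)),
    n_snps_synthetic=1_000,
    n_snps_dgrp=30_000,
    n_borders=150,
    n_genes=300,
    border_rate_multiplier=2.0,  # planted: borders carry twice the SNP density
)
layout = config.layout()
borders, genes = simulate_annotations(layout, config)
_, dgrp = simulate_gwas_tables(layout, config)
dgrp = classify_coding(dgrp, genes)
noncoding = dgrp[~dgrp["coding"]]
print(f"{len(noncoding)} non-coding SNPs of {len(dgrp)} total")

result, regions = tad_enrichment_test(
    noncoding, borders, layout, reps=100, seed=config.seed, sided="greater"
)
mutated = sum(1 for r in regions if r.mutated)
print(f"observed in borders: {result.obs_in}  "
      f"expected from matched controls: {result.ctrl_in}")
print(f"mutated borders (>=1 SNP): {mutated}/{len(regions)}")
print(f"odds ratio {result.odds_ratio:.2f}, one-sided Fisher p = {result.pvalue:.3g}")
print("A p-value this small says border regions hold far more non-coding "
      "SNPs than matched random intervals — the planted 2x density.")

fine = config.fine_layout()
prox = gene_border_proximity(genes, regions, fine)
counts = prox["border_class"].value_counts().to_dict()
print("genes by nearby-border status (30-kb windows):", counts)
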
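"""Assign long-range candidate target genes to non-coding SNPs at 10 kb.

For each 10-Kb bin harboring non-coding SNPs, find the intra-chromosomal
bin it contacts most strongly.  Usually that is an adjacent bin; when the
strongest interactor is farther away the pair is a candidate regulatory
loop, and the genes in the partner bin are candidate targets of the SNPs.
"""

from coloc_longevity import (
    SimulationConfig,
    assign_bins,
    classify_coding,
    rank_long_range_pairs,
    simulate_annotations,
    simulate_fine_contacts,
    simulate_gwas_tables,
    strongest_interactor,
)

config = SimulationConfig(
    seed=7,
    chromosomes=(("2L", 3_000_000), ("2R", 3_000_000), ("X", 3_000_000)),
    n_snps_synthetic=10_000,
    n_snps_dgrp=1_000,
    n_borders=150,
    n_genes=300,
)
layout, fine = config.layout(), config.fine_layout()
contacts = simulate_fine_contacts(fine, config)
_, genes = simulate_annotations(layout, config)
syn, _ = simulate_gwas_tables(layout, config)
syn = classify_coding(syn, genes)
noncoding = assign_bins(syn[~syn["coding"]], fine)

some_bin = int(noncoding["bin"].iloc[0])
hit = strongest_interactor(some_bin, contacts)
print(f"bin {some_bin}: strongest interactor {hit[0]} "
      f"({abs(hit[0] - some_bin) * 10} kb away, f = {hit[1]:.1f})")

seeds = {int(b): list(g) for b, g in noncoding.groupby("bin")["id"].agg(list).items()}
pairs = rank_long_range_pairs(seeds, contacts, min_distance=2, top_k=10, genes=genes)
print(f"\ntop {len(pairs)} long-range pairs (planted loops sit at 50 and 100 kb):")
for p in pairs:
    targets = ",".join(p.genes_in_target) or "(gene-less)"
    print(f"  bin {p.snp_bin} -> bin {p.target_bin}  "
          f"{p.distance_bp // 1000:>3d} kb  f={p.frequency:.0f}  genes: {targets}")
print("Gene-less target bins mirror the real observation that some of the "
      "strongest long-range partners contain no annotated gene.")
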
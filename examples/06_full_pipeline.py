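"""Run the whole analysis end to end and write every report.

One call generates the inputs, filters both GWAS tables, builds and extends
both networks, detects communities, tests TAD-border enrichment, ranks
long-range target pairs, and writes cluster reports plus a run manifest.
Rerunning with the same seed reproduces every output byte for byte.
"""

import json
from pathlib import Path

from coloc_longevity import PipelineSettings, SimulationConfig, run_all

config = SimulationConfig(
    seed=7,
    chromosomes=(("2L", 3_000_000), ("2R", 3_000_000), ("X", 3_000_000)),
    n_snps_synthetic=10_000,
    n_snps_dgrp=20_000,
    n_borders=150,
    n_genes=300,
)
settings = PipelineSettings(q=0.99, d_cut=7.9, alpha=0.05, resolution=0.1, reps=100)

result = run_all(config, settings, outdir="example_results")
for name, ds in result.datasets.items():
    print(f"{name}: original {ds.original.n_nodes} nodes -> "
          f"extended {ds.extended.n_nodes} nodes in {len(ds.components)} "
          f"component(s), {ds.partition.n_communities} communities")
common, span = result.shared_original
print(f"networks share {len(common)} original nodes covering {span:.2f} Mb")
print(f"TAD border enrichment: p = {result.tad.pvalue:.3g} ({result.tad.sided})")
print(f"long-range pairs reported: "
      f"{ {k: len(v) for k, v in result.target_pairs.items()} }")

manifest = json.loads(Path("example_results/manifest.json").read_text())
print("outputs in example_results/, manifest config hash:", manifest["config_hash"])
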
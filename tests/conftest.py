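import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from coloc_longevity import ContactMatrix, ThresholdSet, make_genome_layout
from coloc_longevity.simulate import SimulationConfig

# compact two-chromosome genome used by most unit tests: 10 + 6 bins at 80 kb
SMALL_CHROMS = (("A", 800_000), ("B", 480_000))

# four 3-Mb chromosomes for simulation-based tests (150 bins at 80 kb,
# 1,200 bins at 10 kb — large enough for planted structure, fast to generate)
SIM_CHROMS = (
    ("2L", 3_000_000),
    ("2R", 3_000_000),
    ("3L", 3_000_000),
    ("X", 3_000_000),
)


@pytest.fixture
def small_layout():
    return make_genome_layout(SMALL_CHROMS, 80_000)


@pytest.fixture
def sim_config():
    """Scaled-down generator config preserving the default structure."""
    return SimulationConfig(
        seed=0,
        chromosomes=SIM_CHROMS,
        n_snps_synthetic=10_000,
        n_snps_dgrp=20_000,
        n_borders=200,
        n_genes=300,
        n_extra_signal_bins=10,
    )


def contact_matrix_from_entries(layout, entries):
    """Build a ContactMatrix from {(bin_i, bin_j): f} (1-based, symmetrized)."""
    n = layout.n_bins
    m = np.zeros((n, n))
    for (i, j), f in entries.items():
        m[i - 1, j - 1] = f
        m[j - 1, i - 1] = f
    return ContactMatrix(layout, m)


def flat_thresholds(layout, tau, tau_inter=None):
    """A ThresholdSet with one intra threshold for every pooled chromosome."""
    return ThresholdSet(
        q=0.99,
        intra={name: tau for name in layout.pooled_names},
        inter=tau if tau_inter is None else tau_inter,
    )


def snp_frame(rows, n_founders=0):
    """SNP table from (chrom, pos, id[, extra dict]) tuples."""
    recs = []
    for row in rows:
        chrom, pos, sid = row[:3]
        rec = {"chrom": chrom, "pos": pos, "id": sid, "dataset": "test"}
        if len(row) > 3:
            rec.update(row[3])
        recs.append(rec)
    return pd.DataFrame(recs)


def gene_frame(rows):
    """Gene table from (chrom, start, end, gene_id[, phenotype[, go_terms]])."""
    recs = []
    for row in rows:
        chrom, start, end, gid = row[:4]
        recs.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "gene_id": gid,
                "phenotype": row[4] if len(row) > 4 else "none",
                "go_terms": row[5] if len(row) > 5 else "",
            }
        )
    return pd.DataFrame(recs)
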
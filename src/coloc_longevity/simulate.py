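"""Synthetic pipeline inputs with planted, recoverable signal.

Every input the analysis consumes — contact matrices, the two GWAS SNP
tables, TAD borders and the gene annotation table — can be generated here
with the statistical structure the analysis assumes:

* **Contacts** follow a power-law distance decay,
  ``E[f] = C * (1 + d) ** -decay`` for intra-chromosomal bin distance ``d``
  with multiplicative log-normal noise, so adjacent bins interact most
  strongly and the upper tail is heavy enough for top-1% thresholding.
  Inter-chromosomal contacts are a low constant baseline with the same
  noise.  *Planted modules* (small sets of bins) have their pairwise
  contacts boosted multiplicatively, making them recoverable as network
  communities.
* **Synthetic-style SNPs** carry per-founder haplotype frequencies for an
  old and a young group.  The null divergence is a zero-sum Gaussian
  perturbation of a shared Dirichlet base, so the null distribution of the
  D statistic is known in closed form
  (``D = 100 * sigma * sqrt(chi2(n-1) / n)``); SNPs in *planted signal
  bins* get an additional alternating per-founder shift pushing expected D
  well past the 7.9 significance cut.
* **DGRP-style SNPs** carry uniform(0, 1) p-values off-plant and p-values
  suppressed below the Bonferroni cut inside planted bins.
* **Borders** are disjoint core intervals (flanked regions disjoint too);
  non-coding SNP density inside them can be multiplied to plant border
  enrichment.  **Genes** are intervals with phenotype flags and flat GO
  terms; a planted "longevity" term is concentrated in the planted module
  bins.

All generators draw from independent RNG substreams derived from the master
seed, so outputs are byte-identical for a fixed seed and adding one
generator never perturbs another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .contacts import ContactMatrix
from .layout import DM3_LIKE_CHROMOSOMES, GenomeLayout, make_genome_layout

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_contact_matrix",
    "simulate_fine_contacts",
    "simulate_gwas_tables",
    "simulate_annotations",
    "write_simulation",
]

# RNG substream tags (second word of the seed sequence)
_STREAM_CONTACTS = 1
_STREAM_FINE = 2
_STREAM_BORDERS = 3
_STREAM_GENES = 4
_STREAM_SYN = 5
_STREAM_DGRP = 6
_STREAM_EXTRA_BINS = 7


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic-data generator.

    Defaults describe the standard study conditions: a fly-like six-arm
    genome binned at 80 Kb (1,503 bins), eight founder haplotypes, two GWAS
    tables at a 1:2 size ratio, 2,847 TAD borders, and planted contact
    modules / significant bins / enriched borders / long-range pairs strong
    enough to be recovered by the downstream analysis.
    """

    seed: int = 0
    chromosomes: tuple[tuple[str, int], ...] = DM3_LIKE_CHROMOSOMES
    bin_size: int = 80_000
    fine_bin_size: int = 10_000

    # GWAS tables
    n_founders: int = 8
    n_snps_synthetic: int = 100_000
    n_snps_dgrp: int = 200_000
    base_concentration: float = 20.0  # Dirichlet concentration of founder freqs
    frequency_noise_sd: float = 0.03  # sigma of the null zero-sum divergence
    effect_size: float = 0.12  # planted per-founder frequency shift
    alpha: float = 0.05

    # planted signal bins (None -> module bins + n_extra_signal_bins random)
    planted_signal_bins: tuple[int, ...] | None = None
    n_extra_signal_bins: int = 25

    # contacts
    contact_scale: float = 1000.0
    decay_exponent: float = 1.0
    inter_baseline: float = 1.0
    contact_noise_sd: float = 0.5  # log-normal sigma; 0 disables noise
    planted_modules: tuple[tuple[int, ...], ...] | None = None  # None -> defaults
    n_modules: int = 3
    module_size: int = 5
    module_boost: float = 20.0

    # fine (10-Kb) contacts
    fine_band_bins: int = 50
    planted_longrange_pairs: tuple[tuple[int, int], ...] | None = None  # fine bins
    longrange_boost: float = 20.0
    snps_per_longrange_bin: int = 3

    # borders and genes
    n_borders: int = 2847
    border_width_range: tuple[int, int] = (200, 1000)
    border_flank: int = 100
    border_rate_multiplier: float = 2.0  # SNP density multiplier inside borders
    n_genes: int = 3000
    gene_log_length: tuple[float, float] = (8.5, 1.0)  # lognormal mu, sigma of bp
    n_go_terms: int = 30
    go_terms_per_gene: float = 2.0
    planted_go_term: str = "longevity regulation"

    def layout(self) -> GenomeLayout:
        return make_genome_layout(self.chromosomes, self.bin_size)

    def fine_layout(self) -> GenomeLayout:
        return make_genome_layout(self.chromosomes, self.fine_bin_size)

    # -- resolved planted structure -------------------------------------

    def resolved_modules(self, layout: GenomeLayout) -> tuple[tuple[int, ...], ...]:
        """Planted contact modules: runs of consecutive bins, one per module.

        If not given explicitly, modules are placed deterministically at
        40% of the length of successive chromosomes (wrapping around),
        skipping chromosomes too short to hold a module.
        """
        if self.planted_modules is not None:
            for mod in self.planted_modules:
                for b in mod:
                    if not 1 <= b <= layout.n_bins:
                        raise ValueError(f"planted module bin {b} outside layout")
            return self.planted_modules
        mods: list[tuple[int, ...]] = []
        eligible = [
            c for c in layout.chrom_names if layout.chrom_bin_count(c) >= 3 * self.module_size
        ]
        if not eligible:
            return ()
        for k in range(self.n_modules):
            chrom = eligible[k % len(eligible)]
            first, last = layout.chrom_bin_range(chrom)
            anchor = first + int(0.4 * (last - first)) + (k // len(eligible)) * (
                2 * self.module_size
            )
            mod = tuple(range(anchor, anchor + self.module_size))
            if mod[-1] > last:
                mod = tuple(range(last - self.module_size + 1, last + 1))
            mods.append(mod)
        return tuple(mods)

    def resolved_signal_bins(self, layout: GenomeLayout) -> tuple[int, ...]:
        """Bins whose SNPs carry planted association signal.

        Defaults to the planted module bins plus ``n_extra_signal_bins``
        additional bins drawn (reproducibly) at random outside the modules.
        """
        if self.planted_signal_bins is not None:
            return tuple(sorted(set(self.planted_signal_bins)))
        module_bins = {b for mod in self.resolved_modules(layout) for b in mod}
        # keep planted long-range loci out of the random extras: their source
        # bins are planted separately and their target bins must stay free of
        # significant SNPs to remain "novel" regions
        fine = self.fine_layout()
        excluded = set(module_bins)
        for src, dst in self.resolved_longrange_pairs(fine):
            for fb in (src, dst):
                chrom, start, _ = fine.bin_interval(fb)
                excluded.add(layout.bin_of(chrom, start + 1))
        rng = np.random.default_rng([self.seed, _STREAM_EXTRA_BINS])
        pool = np.setdiff1d(np.arange(1, layout.n_bins + 1), sorted(excluded))
        k = min(self.n_extra_signal_bins, pool.size)
        extra = rng.choice(pool, size=k, replace=False)
        return tuple(sorted(module_bins | set(int(b) for b in extra)))

    def resolved_longrange_pairs(
        self, fine_layout: GenomeLayout
    ) -> tuple[tuple[int, int], ...]:
        """Planted (snp_bin, target_bin) pairs in the fine layout.

        Defaults to two pairs per sufficiently long chromosome: one with the
        target 5 bins away (50 Kb) and one 10 bins away (100 Kb), mirroring
        the long-range exceptions seen in real fine-scale contact maps.
        """
        if self.planted_longrange_pairs is not None:
            return self.planted_longrange_pairs
        pairs: list[tuple[int, int]] = []
        for chrom in fine_layout.chrom_names:
            first, last = fine_layout.chrom_bin_range(chrom)
            n = last - first + 1
            if n < 200:
                continue
            src1 = first + int(0.3 * n)
            src2 = first + int(0.6 * n)
            pairs.append((src1, src1 + 5))
            pairs.append((src2, src2 + 10))
        return tuple(pairs)


# ---------------------------------------------------------------------------
# contacts


def simulate_contact_matrix(
    layout: GenomeLayout, config: SimulationConfig
) -> ContactMatrix:
    """Genome-wide (intra + inter) contact matrix with planted modules.

    Intra-chromosomal expectation decays as ``C * (1 + d) ** -decay`` with
    bin distance ``d``; inter-chromosomal expectation is the low
    ``inter_baseline``.  Multiplicative log-normal noise is applied
    symmetrically.  Pairwise contacts within each planted module are
    multiplied by ``module_boost``.  Self-contacts are generated (strongest
    of all) but are excluded downstream from threshold computations.

    Intended for coarse layouts; the matrix is dense internally.
    """
    n = layout.n_bins
    rng = np.random.default_rng([config.seed, _STREAM_CONTACTS])
    chrom_idx = layout.bin_chrom_array()
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    same = chrom_idx[:, None] == chrom_idx[None, :]
    expected = np.where(
        same,
        config.contact_scale * (1.0 + d) ** (-config.decay_exponent),
        config.inter_baseline,
    )
    if config.contact_noise_sd > 0:
        z = rng.standard_normal((n, n))
        z = np.triu(z, k=0)
        z = z + np.triu(z, k=1).T  # symmetric noise field
        expected = expected * np.exp(config.contact_noise_sd * z)
    for mod in config.resolved_modules(layout):
        mb = np.asarray(mod, dtype=int) - 1
        sub = np.ix_(mb, mb)
        boost = np.full((len(mb), len(mb)), config.module_boost)
        np.fill_diagonal(boost, 1.0)
        expected[sub] = expected[sub] * boost
    return ContactMatrix(layout, expected)


def simulate_fine_contacts(
    fine_layout: GenomeLayout, config: SimulationConfig
) -> ContactMatrix:
    """Intra-chromosomal banded contact map at fine (10-Kb) resolution.

    Contacts are generated within ``fine_band_bins`` of the diagonal with
    the same decay/noise model as the coarse matrix (fine-scale maps are
    intra-only, and contacts beyond the band are negligible under the
    decay).  Planted long-range pairs are then set to
    ``longrange_boost * contact_scale``, far above any in-band value, so
    each planted source bin's strongest interactor is its planted target.
    """
    rng = np.random.default_rng([config.seed, _STREAM_FINE])
    n = fine_layout.n_bins
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for chrom in fine_layout.chrom_names:
        first, last = fine_layout.chrom_bin_range(chrom)
        nc = last - first + 1
        for d in range(1, min(config.fine_band_bins, nc - 1) + 1):
            m = nc - d
            base = config.contact_scale * (1.0 + d) ** (-config.decay_exponent)
            f = base * np.exp(config.contact_noise_sd * rng.standard_normal(m))
            i = np.arange(first - 1, first - 1 + m)
            rows.append(i)
            cols.append(i + d)
            vals.append(f)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    v = np.concatenate(vals)
    upper = sparse.coo_array((v, (r, c)), shape=(n, n)).tolil()
    for src, dst in config.resolved_longrange_pairs(fine_layout):
        if not 1 <= src <= n or not 1 <= dst <= n:
            raise ValueError(f"planted long-range pair ({src}, {dst}) outside layout")
        i, j = min(src, dst) - 1, max(src, dst) - 1
        upper[i, j] = config.longrange_boost * config.contact_scale
    upper = upper.tocsr()
    full = upper + sparse.triu(upper, k=1).T
    return ContactMatrix(fine_layout, full)


# ---------------------------------------------------------------------------
# borders (shared between the annotation and GWAS generators)


def _simulate_border_cores(layout: GenomeLayout, config: SimulationConfig) -> pd.DataFrame:
    """Disjoint border core intervals; even the flanked regions are disjoint.

    Uses its own RNG substream so the GWAS generator can re-derive the same
    borders when planting SNP enrichment inside them.
    """
    rng = np.random.default_rng([config.seed, _STREAM_BORDERS])
    glen = layout.genome_length
    counts = []
    for _, length in layout.chromosomes:
        counts.append(int(round(config.n_borders * length / glen)))
    # fix rounding drift on the largest chromosome
    drift = config.n_borders - sum(counts)
    counts[int(np.argmax([l for _, l in layout.chromosomes]))] += drift

    pad = 2 * config.border_flank + 1
    w0, w1 = config.border_width_range
    rows = []
    bid = 1
    for (chrom, length), n_c in zip(layout.chromosomes, counts):
        if n_c <= 0:
            continue
        widths = rng.integers(w0, w1 + 1, size=n_c)
        slack = length - int(widths.sum()) - n_c * pad
        if slack <= 0:
            raise ValueError(f"chromosome {chrom} too short for {n_c} borders")
        # classic spacing construction: sorted uniform gaps keep intervals disjoint
        gaps = np.sort(rng.integers(0, slack, size=n_c))
        starts = gaps + np.concatenate(([0], np.cumsum(widths[:-1] + pad))) + pad // 2
        for s, w in zip(starts, widths):
            rows.append((chrom, int(s), int(s + w), bid))
            bid += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "border_id"])


# ---------------------------------------------------------------------------
# GWAS tables


def _uniform_positions(
    rng: np.random.Generator, layout: GenomeLayout, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """k genome-wide uniform positions -> (chrom index array, 1-based pos array)."""
    lengths = np.array([l for _, l in layout.chromosomes], dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(lengths)))
    g = rng.integers(0, cum[-1], size=k)
    ci = np.searchsorted(cum, g, side="right") - 1
    pos = g - cum[ci] + 1
    return ci, pos


def _extra_border_positions(
    rng: np.random.Generator,
    layout: GenomeLayout,
    borders: pd.DataFrame,
    n_snps: int,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Extra SNP positions planted uniformly inside flanked border regions.

    The expected extra count is ``(multiplier - 1) * n_snps * footprint /
    genome``, which raises the SNP rate inside borders to ``multiplier``
    times the background rate.
    """
    if config.border_rate_multiplier <= 1.0 or borders.empty:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    flank = config.border_flank
    starts = np.maximum(borders["start"].to_numpy() - flank, 0)
    chrom_len = np.array(
        [layout.chrom_length(c) for c in borders["chrom"]], dtype=np.int64
    )
    ends = np.minimum(borders["end"].to_numpy() + flank, chrom_len)
    widths = ends - starts
    footprint = int(widths.sum())
    expected = (config.border_rate_multiplier - 1.0) * n_snps * footprint / layout.genome_length
    k = rng.poisson(expected)
    if k == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    which = rng.choice(len(borders), size=k, p=widths / footprint)
    offs = rng.integers(0, widths[which])
    pos = starts[which] + offs + 1  # 1-based
    ci = np.array(
        [layout.chrom_index(c) for c in borders["chrom"].to_numpy()[which]],
        dtype=np.int64,
    )
    return ci, pos


def _longrange_seed_positions(
    layout: GenomeLayout, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """A few SNPs inside each planted long-range source bin (deterministic)."""
    fine = config.fine_layout()
    cis, poss = [], []
    for src, _dst in config.resolved_longrange_pairs(fine):
        chrom, start, end = fine.bin_interval(src)
        ci = layout.chrom_index(chrom)
        for k in range(config.snps_per_longrange_bin):
            frac = (k + 1) / (config.snps_per_longrange_bin + 1)
            cis.append(ci)
            poss.append(start + int(frac * (end - start)) + 1)
    return np.array(cis, dtype=np.int64), np.array(poss, dtype=np.int64)


def simulate_gwas_tables(
    layout: GenomeLayout, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the synthetic-style and DGRP-style SNP tables.

    Both tables place SNPs uniformly over the genome, add extra SNPs inside
    (flanked) TAD borders at ``border_rate_multiplier`` times the background
    rate, and seed each planted long-range source bin with a few SNPs.

    Synthetic-style rows carry old/young per-founder haplotype frequencies
    (columns ``h_O_j`` / ``h_Y_j``, each vector summing to 1).  Off-plant,
    old and young frequencies differ by a zero-sum Gaussian perturbation of
    scale ``frequency_noise_sd``; in planted signal bins an alternating
    ``±effect_size`` shift is added so expected D clears 7.9.  Frequencies
    pushed outside [0, 1] are clipped and the vector renormalized (counted
    in the log).

    DGRP-style rows carry p-values: uniform(0, 1) off-plant, scaled below
    the fine-scale Bonferroni cut in planted bins (hence below the coarse
    cut as well).
    """
    if config.n_founders < 2:
        raise ValueError("need at least two founder haplotypes")
    borders = _simulate_border_cores(layout, config)
    planted = set(config.resolved_signal_bins(layout))
    lr_ci, lr_pos = _longrange_seed_positions(layout, config)

    # SNPs seeded in planted long-range source bins carry planted signal too,
    # so they stay discoverable under significance-restricted seeding
    fine = config.fine_layout()
    lr_src = {src for src, _ in config.resolved_longrange_pairs(fine)}
    fine_offsets = np.array(fine.offsets, dtype=np.int64)

    def planted_mask(ci: np.ndarray, pos: np.ndarray, bins: np.ndarray) -> np.ndarray:
        mask = np.isin(bins, sorted(planted))
        if lr_src:
            fine_bins = fine_offsets[ci] + (pos - 1) // config.fine_bin_size
            mask |= np.isin(fine_bins, sorted(lr_src))
        return mask

    def positions(rng: np.random.Generator, n_base: int):
        ci_u, pos_u = _uniform_positions(rng, layout, n_base)
        ci_b, pos_b = _extra_border_positions(rng, layout, borders, n_base, config)
        ci = np.concatenate([ci_u, ci_b, lr_ci])
        pos = np.concatenate([pos_u, pos_b, lr_pos])
        order = np.lexsort((pos, ci))
        return ci[order], pos[order]

    chrom_names = np.array(layout.chrom_names)
    offsets = np.array(layout.offsets, dtype=np.int64)

    # ---- synthetic-style table
    rng_syn = np.random.default_rng([config.seed, _STREAM_SYN])
    ci, pos = positions(rng_syn, config.n_snps_synthetic)
    k = len(pos)
    n = config.n_founders
    base = rng_syn.dirichlet([config.base_concentration] * n, size=k)
    eps = rng_syn.standard_normal((k, n))
    d = config.frequency_noise_sd * (eps - eps.mean(axis=1, keepdims=True))
    bins = offsets[ci] + (pos - 1) // layout.bin_size
    in_plant = planted_mask(ci, pos, bins)
    if in_plant.any() and config.effect_size > 0:
        shift = np.zeros(n)
        half = n // 2
        shift[:half] = config.effect_size
        shift[half : 2 * half] = -config.effect_size
        shift -= shift.mean()
        d[in_plant] += shift
    h_o = base + d / 2.0
    h_y = base - d / 2.0
    clipped = ((h_o < 0) | (h_o > 1) | (h_y < 0) | (h_y > 1)).any(axis=1)
    if clipped.any():
        logger.info("clipping and renormalizing %d/%d haplotype rows", clipped.sum(), k)
        for h in (h_o, h_y):
            np.clip(h, 0.0, 1.0, out=h)
            h /= h.sum(axis=1, keepdims=True)
    syn = pd.DataFrame(
        {
            "chrom": chrom_names[ci],
            "pos": pos,
            "id": [f"syn_{i + 1}" for i in range(k)],
            "dataset": "synthetic",
        }
    )
    for j in range(n):
        syn[f"h_O_{j + 1}"] = h_o[:, j]
    for j in range(n):
        syn[f"h_Y_{j + 1}"] = h_y[:, j]

    # ---- DGRP-style table
    rng_dgrp = np.random.default_rng([config.seed, _STREAM_DGRP])
    ci, pos = positions(rng_dgrp, config.n_snps_dgrp)
    k = len(pos)
    pvals = rng_dgrp.uniform(0.0, 1.0, size=k)
    bins = offsets[ci] + (pos - 1) // layout.bin_size
    in_plant = planted_mask(ci, pos, bins)
    # suppress below the *fine-scale* Bonferroni cut so planted SNPs are
    # significant at both the 80-Kb and the 10-Kb significance levels
    cut = config.alpha / fine.n_bins
    pvals[in_plant] = pvals[in_plant] * cut
    dgrp = pd.DataFrame(
        {
            "chrom": chrom_names[ci],
            "pos": pos,
            "id": [f"dgrp_{i + 1}" for i in range(k)],
            "dataset": "dgrp",
            "pvalue": pvals,
        }
    )
    return syn, dgrp


# ---------------------------------------------------------------------------
# annotations


def simulate_annotations(
    layout: GenomeLayout, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the TAD border table and the gene annotation table.

    Borders are pairwise-disjoint cores (flanked regions disjoint as well).
    Genes are lognormal-length intervals placed uniformly (overlaps
    allowed), avoiding the planted long-range source bins so that SNPs
    seeded there stay non-coding — mirroring the gene-less bins seen in
    real fine-scale maps.  Most carriers of the planted GO term sit inside
    the planted module bins; phenotype flags follow a fixed multinomial.
    """
    borders = _simulate_border_cores(layout, config)
    rng = np.random.default_rng([config.seed, _STREAM_GENES])
    fine = config.fine_layout()
    avoid = [fine.bin_interval(src) for src, _ in config.resolved_longrange_pairs(fine)]

    mu, sd = config.gene_log_length
    module_bins = [
        layout.bin_interval(b) for mod in config.resolved_modules(layout) for b in mod
    ]

    rows = []
    made = 0
    while made < config.n_genes:
        want = config.n_genes - made
        lengths = np.exp(rng.normal(mu, sd, size=want)).astype(np.int64).clip(500, 200_000)
        ci, pos = _uniform_positions(rng, layout, want)
        for c, p, glen in zip(ci, pos, lengths):
            chrom, chrom_len = layout.chromosomes[c]
            start = int(p - 1)
            end = min(start + int(glen), chrom_len)
            if any(
                chrom == ac and start < ae and as_ < end for ac, as_, ae in avoid
            ):
                continue  # keep long-range source bins gene-free
            rows.append([chrom, start, end])
            made += 1
            if made == config.n_genes:
                break
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    genes["gene_id"] = [f"gene_{i + 1:05d}" for i in range(len(genes))]

    # phenotype flags
    flags = rng.choice(
        ["none", "long-lived", "short-lived", "increased-mortality", "lethal"],
        size=len(genes),
        p=[0.85, 0.04, 0.04, 0.04, 0.03],
    )
    genes["phenotype"] = flags

    # GO terms: background vocabulary plus one planted longevity term
    vocab = [f"process_{i + 1:02d}" for i in range(config.n_go_terms)]
    n_terms = rng.poisson(config.go_terms_per_gene, size=len(genes))
    in_module = np.zeros(len(genes), dtype=bool)
    for chrom, ms, me in module_bins:
        sel = (genes["chrom"] == chrom) & (genes["start"] < me) & (genes["end"] > ms)
        in_module |= sel.to_numpy()
    p_out = min(1.0, 2.0 / max(1, (~in_module).sum()))  # ~2 stray carriers
    planted_carrier = np.where(
        in_module, rng.random(len(genes)) < 0.9, rng.random(len(genes)) < p_out
    )
    go_cells = []
    for i in range(len(genes)):
        kk = min(int(n_terms[i]), len(vocab))
        terms = sorted(rng.choice(vocab, size=kk, replace=False)) if kk else []
        if planted_carrier[i]:
            terms.append(config.planted_go_term)
        go_cells.append(";".join(terms))
    genes["go_terms"] = go_cells
    genes = genes[["chrom", "start", "end", "gene_id", "phenotype", "go_terms"]]
    return borders, genes


# ---------------------------------------------------------------------------
# serialization


def write_simulation(config: SimulationConfig, outdir) -> dict[str, str]:
    """Generate every input and write it as TSV under ``outdir``.

    Returns a mapping of logical names to file paths.  Contact matrices are
    written as triplet TSVs with a layout sidecar per resolution.
    """
    from pathlib import Path

    from .annotations import write_borders_tsv, write_genes_tsv
    from .contacts import write_contacts_tsv
    from .layout import write_layout_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    layout = config.layout()
    fine = config.fine_layout()
    paths = {}

    write_layout_tsv(layout, out / "layout_80kb.tsv")
    write_layout_tsv(fine, out / "layout_10kb.tsv")
    paths["layout_80kb"] = str(out / "layout_80kb.tsv")
    paths["layout_10kb"] = str(out / "layout_10kb.tsv")

    contacts = simulate_contact_matrix(layout, config)
    write_contacts_tsv(contacts, out / "contacts_80kb.tsv")
    paths["contacts_80kb"] = str(out / "contacts_80kb.tsv")

    fine_contacts = simulate_fine_contacts(fine, config)
    write_contacts_tsv(fine_contacts, out / "contacts_10kb.tsv")
    paths["contacts_10kb"] = str(out / "contacts_10kb.tsv")

    syn, dgrp = simulate_gwas_tables(layout, config)
    syn.to_csv(out / "snps_synthetic.tsv", sep="\t", index=False, float_format="%.8g")
    dgrp.to_csv(out / "snps_dgrp.tsv", sep="\t", index=False, float_format="%.8g")
    paths["snps_synthetic"] = str(out / "snps_synthetic.tsv")
    paths["snps_dgrp"] = str(out / "snps_dgrp.tsv")

    borders, genes = simulate_annotations(layout, config)
    write_borders_tsv(borders, out / "borders.tsv")
    write_genes_tsv(genes, out / "genes.tsv")
    paths["borders"] = str(out / "borders.tsv")
    paths["genes"] = str(out / "genes.tsv")
    return paths
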
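# Methods

This note documents the models, conventions and numerical choices behind
`coloc_longevity`, and what the synthetic-data generator does and does not
emulate.

## Coordinates, bins and layouts

SNP positions are 1-based points (VCF style); all intervals — gene bodies,
TAD borders, bin footprints — are stored 0-based half-open (BED style).  A
`GenomeLayout` assigns each chromosome `ceil(length / bin_size)` bins with
1-based global IDs contiguous across chromosomes in declared order; a
position maps to local bin `floor((pos − 1)/bin_size) + 1`.  The default
chromosome set is a stylised fly genome (2L 22.96 Mb, 2R 21.12 Mb, 3L
24.56 Mb, 3R 27.92 Mb, 4 1.28 Mb, X 22.40 Mb) whose 80-Kb binning yields
exactly 1,503 bins with arm boundaries at 287/551/858/1207/1223/1503,
matching the genome-wide Hi-C bin table this analysis style is built on.
That bin table prints one node ("Chr2R: 20800000–20880000" for node 547)
that is one bin off from the convention fitting all its other printed
bin↔coordinate pairs; the package follows the majority convention.  The
10-Kb layout applies the same rule at the finer width; published 10-Kb bin
labels do not follow a single arithmetic rule, so the package's own indexing
is used consistently on both sides of every comparison.

Gene overlap treats printed gene start/end as a 1-based closed interval
("between gene start and gene end" read inclusively): a SNP at either
endpoint is coding.  Coding/non-coding is a partition; a SNP lists every
overlapping gene.

## The D statistic and significance policies

`D = 100·sqrt(Σ (h_O,j − h_Y,j)²/n)` over the n founder haplotypes present
at a SNP; `D ∈ [0, 100]`, invariant under founder permutation, and linear
in a uniform scaling of the frequency differences.  Duplicate positions
(from merging sub-population tables) are combined by concatenating each
group's frequency vectors, renormalizing the concatenation to sum 1, and
setting n to the combined founder count — the source procedure says only
"combined", and renormalization is the choice that preserves the
sum-to-one invariant.  Both cutoffs are strict (`D > 7.9`,
`p < α/m`), matching the "exceeding" wording of the thresholds.

## Contact thresholds

"Strong" interactions are the top 1% of the observed frequency
distribution, computed on *positive* entries only (Hi-C matrices are
zero-inflated; quantiles over all entries would be dominated by structural
zeros) and excluding the diagonal (a self-contact is not an interaction
between distinct loci).  The threshold is the order statistic τ = the
smallest observed value with at most `1 − q` of positive entries strictly
above it, so "strong" means `f > τ` and at most 1% of entries qualify even
with ties.  Intra-chromosomal thresholds pool arms (2L+2R → "2",
3L+3R → "3"), giving one threshold per numbered chromosome plus a single
inter-chromosomal threshold; contacts between two arms of one pooled
chromosome count as intra by default (`cross_arm="inter"` reclassifies
them).

## Networks

Original-network nodes are all significant bins, isolated ones included;
edges are strong contacts between nodes.  Extension is a single round:
every outside bin with a strong contact to an original node joins, tagged
`added`.  The extended edge set includes added–added strong pairs by
default — without them the reported single-component connectivity of
extended networks of this kind is implausible — while `star_extension=True`
restores the strict added-to-original reading.  Degree is unweighted (a
count of connections); edge weights (contact frequencies) are kept for
community detection.  Louvain modularity optimization runs on weights with
resolution 0.1 and an explicit seed; given the seed the partition is
deterministic, and community IDs are renumbered by smallest member bin so
reports are stable.  Note the resolution convention is networkx's: smaller
values favor fewer, larger communities.  Community structure in this
pipeline is usually carried by the components' density rather than the
resolution value.

## TAD-border enrichment

Border regions are core intervals ±100 bp, clamped at chromosome ends.  A
border is *mutated* if its flanked region contains ≥ 1 non-coding SNP of
the active dataset (the flanked region, not the bare core, because the
region is what the analysis defines).  Controls are matched per border:
same chromosome, same core width (a `point_borders` flag reproduces the
literal point-plus-flanks reading), flanked identically, placed uniformly
and rejected if overlapping any real flanked region; each of the 100
replicates uses an RNG substream of the given seed.  Control counts are
averaged and rounded half-up before entering the 2×2 table, since the
exact test needs integers.  Sidedness defaults to one-sided greater
(the hypothesis is over-representation); the published p-value for the
border table is reproduced with the two-sided variant, which is what that
number corresponds to.

Averaging 100 control replicates makes the second row of the table nearly
noiseless while Fisher's exact test budgets sampling variance for both
rows; the procedure is therefore conservative.  Measured over 200 null
datasets the rejection rate at α = 0.05 is well under the nominal level,
and with a 2× planted border SNP density the test rejects at p < 10⁻⁶
essentially always at the sizes used here.

Gene–border proximity windows are 30 Kb: the 10-Kb bin containing the
border's core midpoint plus one bin on each side; a gene is near a border
iff its interval intersects the window, and genes are classed
mutated-only / nonmutated-only / both / none over all nearby borders.

## Long-range targets

The strongest interactor of a 10-Kb bin is the intra-chromosomal partner
with maximal frequency, self excluded, ties broken toward smaller distance
then smaller bin ID.  "Long-range" means the strongest interactor is at
least 2 bins (20 Kb) away — the contrast is with the adjacent-bin dominance
of decaying contact maps — and the ranked report sorts qualifying pairs by
frequency descending, keeping the top k (default 30).  "Top" is not
precisely defined in the source description; frequency-descending among
distance-qualified pairs is this package's documented reading.  By default
any bin harboring non-coding SNPs seeds the search (most reported pairs in
practice involve non-significant SNPs); a significance-restricted mode
seeds only bins with significant non-coding SNPs, using D > 7.9 or the
10-Kb-scale Bonferroni cut.

## GO enrichment and reports

GO terms are flat labels (no DAG propagation).  Enrichment of query set n
against universe N with K term carriers and k in the overlap is the
one-sided hypergeometric tail `P(X ≥ k)`.  The universe defaults to all
genes residing in the active network's nodes — the background implied by
"genes residing within important nodes/clusters" and the conservative
choice — with a whole-table option.  Raw p-values are reported (mirroring
the raw-p presentation of such cluster tables); a Benjamini–Hochberg column
is available but off by default.  Cluster reports list nodes, genes,
phenotype tallies, per-gene SNP counts, and for each enriched term the
number of member nodes harboring an overlapping gene.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any real dataset; all distributions are artifact choices.

* **Contacts** (80 Kb, intra+inter, dense): expected intra frequency
  `C·(1 + d)^(−γ)` at bin distance d with `C = 1000`, decay `γ = 1`, and
  multiplicative log-normal noise (σ = 0.5); inter-chromosomal baseline 1.0
  with the same noise.  These values put the top-1% thresholds and the
  adjacent-bin dominance in the regime the analysis expects (per-chromosome
  thresholds a few hundred, inter threshold a few units).  Planted modules
  (three runs of five consecutive bins at 40% of successive chromosomes)
  have pairwise contacts boosted ×20, far above the 99th percentile.
  Self-contacts are generated but never enter thresholds.
* **Fine contacts** (10 Kb): intra-only within a 50-bin band of the
  diagonal (beyond it the decayed signal is negligible), same decay/noise;
  planted long-range pairs — two per chromosome, at 5 and 10 bins (50 and
  100 Kb) — are set to 20·C, so each planted source's strongest interactor
  is its planted target.
* **Synthetic-style SNPs**: positions uniform over the genome, plus extra
  SNPs inside flanked borders at `border_rate_multiplier` × the background
  rate (default 2, the planted enrichment), plus three deterministic SNPs
  in each planted long-range source bin.  Frequencies: a shared Dirichlet
  base (concentration 20 per founder) split as `h_O = base + δ/2`,
  `h_Y = base − δ/2` with δ a zero-sum Gaussian of scale σ = 0.03 per
  founder.  Because δ sums to zero, vectors sum to 1 exactly and the null
  D is `100σ·sqrt(χ²_{n−1}/n)` in closed form — the analytic oracle used in
  testing.  At the σ = 0.03 default, null SNPs essentially never cross
  D = 7.9; planted bins add an alternating ±0.12 founder shift giving
  E[D] ≈ 12.4, comfortably past the cut.  Frequencies pushed outside [0,1]
  (possible at extreme settings) are clipped and renormalized, with a log
  message.
* **DGRP-style SNPs**: uniform(0,1) p-values; planted SNPs multiplied below
  the 10-Kb-scale Bonferroni cut so they are significant at both
  resolutions.
* **Planted-signal placement**: the planted bin set is the module bins plus
  25 random extra bins; bins overlapping planted long-range source or
  target regions are excluded from the extras — sources carry their own
  planted signal, and targets must stay free of significant SNPs to remain
  the "novel" partner regions the target search is meant to discover.
* **Borders**: 2,847 disjoint cores (flanked regions disjoint as well),
  widths uniform 200–1000 bp, counts proportional to chromosome length.
  The GWAS generators re-derive the same borders from the shared RNG
  substream when planting enrichment.
* **Genes**: 3,000 intervals, log-normal lengths (median ≈ 5 Kb), uniform
  placement with overlaps allowed, avoiding long-range source bins (their
  SNPs stay non-coding, mirroring gene-less bins in real maps).  A 30-term
  background vocabulary plus one planted longevity term concentrated (≥80%)
  in the planted module bins; phenotype flags from a fixed multinomial
  (85% none).

Every generator draws from its own RNG substream (`[seed, stream]`), so
outputs are byte-identical for a fixed seed and adding a generator never
perturbs the others.

What the generator does *not* emulate: linkage disequilibrium, read-level
noise, real gene coordinates or real TAD calls, chromatin compartments, or
distance-dependent normalization artifacts.  Passing recovery tests on
these synthetics shows the pipeline's logic is sound and calibrated under
its own assumptions — not that real data meet those assumptions.

## Problem sizes and runtime choices

Default table sizes (100k synthetic-style, 200k DGRP-style SNPs) preserve
the 1:2 ratio of the motivating datasets at a size where the full pipeline
runs in well under a minute.  Recovery and calibration studies use: the
full 1,503-bin layout for planted-module community recovery (ARI over 20
seeds); a four-chromosome 12-Mb genome with 200 borders and 20k SNPs for
border-test calibration (200 null datasets) and power (20 datasets); and
the same small genome for long-range pair recovery (20 seeds).  These sizes
are the package's choices for desk-scale reproducibility; all scale up by
configuration.

## Known limitations

* Thresholding assumes the contact matrix is already normalized; no
  balancing is performed.
* The border test inherits the conservatism of the averaged-control design;
  it is a global test, with no per-border multiple-testing.
* GO enrichment ignores term hierarchy and gene length bias.
* Extension is one round by design; transitive closure would change the
  reported connectivity.
* External resources (FlyBase/FlyMine exports, ortholog tables, enhancer
  databases) are consumed as flat TSV inputs only; no lookups are
  performed.
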
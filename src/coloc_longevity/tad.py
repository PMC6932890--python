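"""TAD-border SNP enrichment against a matched random-border null.

TAD borders are supplied as core intervals; each is widened by 100 bp of
flanking sequence on both sides (clamped to the chromosome) to form the
*border region*.  Non-coding SNPs are counted inside border regions and
compared with the average count over 100 sets of matched random borders —
random positions on the same chromosome, with the same core widths and the
same flanks, rejected if they overlap any real border region.  Fisher's
exact test on the resulting 2x2 table assesses over-representation.

A border is *mutated* if its (flanked) region contains at least one
non-coding SNP of the active dataset.  Phenotype genes are classified by
whether the borders they sit near (within a 30-Kb window: the 10-Kb bin
containing the border plus one bin each side) are mutated, non-mutated, or
both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .layout import GenomeLayout

__all__ = [
    "BorderRegion",
    "EnrichmentTable",
    "make_border_regions",
    "count_snps_in_regions",
    "sample_control_borders",
    "fisher_enrichment",
    "tad_enrichment_test",
    "gene_border_proximity",
]


@dataclass(frozen=True)
class BorderRegion:
    """A TAD border: core interval plus flanked region (0-based half-open)."""

    border_id: int
    chrom: str
    core_start: int
    core_end: int
    start: int  # flanked
    end: int  # flanked
    snp_count: int = 0

    @property
    def mutated(self) -> bool:
        return self.snp_count > 0

    @property
    def width(self) -> int:
        return self.end - self.start


def make_border_regions(
    borders: pd.DataFrame, layout: GenomeLayout, flank: int = 100
) -> list[BorderRegion]:
    """Widen border cores by ``flank`` bp on both sides, clamped to the chromosome.

    ``borders`` is a BED-style table with columns chrom/start/end/border_id.
    Raises ``ValueError`` if a core lies outside its chromosome.
    """
    regions = []
    for row in borders.itertuples():
        length = layout.chrom_length(str(row.chrom))
        if row.start < 0 or row.end > length or row.start >= row.end:
            raise ValueError(
                f"border {row.border_id} [{row.start}, {row.end}) outside {row.chrom} (length {length})"
            )
        regions.append(
            BorderRegion(
                border_id=int(row.border_id),
                chrom=str(row.chrom),
                core_start=int(row.start),
                core_end=int(row.end),
                start=max(0, int(row.start) - flank),
                end=min(length, int(row.end) + flank),
            )
        )
    return regions


def count_snps_in_regions(
    snps: pd.DataFrame, regions: list[BorderRegion]
) -> tuple[list[BorderRegion], int]:
    """Count SNPs inside each (flanked) region.

    Returns the regions with ``snp_count`` filled in, plus the total count.
    A SNP is counted in every region containing its position, so for
    disjoint regions the total equals the number of SNPs falling in any
    region.  ``snps`` should already be restricted to the non-coding subset
    when reproducing the border analysis.
    """
    by_chrom: dict[str, np.ndarray] = (
        {}
        if snps.empty
        else {
            str(c): np.sort(g["pos"].to_numpy(dtype=np.int64)) - 1  # 0-based points
            for c, g in snps.groupby("chrom", sort=False)
        }
    )
    counted = []
    total = 0
    for reg in regions:
        pos = by_chrom.get(reg.chrom)
        if pos is None:
            k = 0
        else:
            k = int(
                np.searchsorted(pos, reg.end, side="left")
                - np.searchsorted(pos, reg.start, side="left")
            )
        counted.append(
            BorderRegion(
                border_id=reg.border_id,
                chrom=reg.chrom,
                core_start=reg.core_start,
                core_end=reg.core_end,
                start=reg.start,
                end=reg.end,
                snp_count=k,
            )
        )
        total += k
    return counted, total


def sample_control_borders(
    regions: list[BorderRegion],
    layout: GenomeLayout,
    reps: int = 100,
    seed: int = 0,
    flank: int = 100,
    point_borders: bool = False,
    max_retries: int = 10_000,
) -> list[list[BorderRegion]]:
    """Matched random border sets: same chromosome and core width per border.

    For each real border and each replicate, a random core of the same
    width (a single point if ``point_borders``) is placed uniformly on the
    same chromosome, flanked by ``flank`` bp, and rejected if the flanked
    region overlaps any real flanked border region.  Each replicate uses an
    independent RNG substream derived from ``seed``, so individual
    replicates are reproducible.

    Raises ``RuntimeError`` if a placement cannot be found within
    ``max_retries`` draws (chromosome saturated by real borders).
    """
    # real flanked intervals are disjoint by construction of real TAD borders;
    # sort them per chromosome for a binary-search overlap test
    real_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in regions}:
        ivs = sorted((r.start, r.end) for r in regions if r.chrom == chrom)
        real_by_chrom[chrom] = (
            np.array([s for s, _ in ivs], dtype=np.int64),
            np.array([e for _, e in ivs], dtype=np.int64),
        )

    by_chrom: dict[str, list[int]] = {}
    for k, reg in enumerate(regions):
        by_chrom.setdefault(reg.chrom, []).append(k)

    replicates: list[list[BorderRegion]] = []
    for rep in range(reps):
        rng = np.random.default_rng([seed, rep])
        placed: list[BorderRegion | None] = [None] * len(regions)
        for chrom, idxs in sorted(by_chrom.items()):
            length = layout.chrom_length(chrom)
            rs, re = real_by_chrom[chrom]
            widths = np.array(
                [
                    1 if point_borders
                    else regions[k].core_end - regions[k].core_start
                    for k in idxs
                ],
                dtype=np.int64,
            )
            hi = length - widths
            if (hi < 1).any():
                raise RuntimeError(f"chromosome {chrom} too short for control border")
            core_start = np.empty(len(idxs), dtype=np.int64)
            todo = np.arange(len(idxs))
            for _ in range(max_retries):
                core_start[todo] = rng.integers(0, hi[todo])
                start = np.maximum(core_start - flank, 0)
                end = np.minimum(core_start + widths + flank, length)
                # overlap with a real region iff the first real region ending
                # after `start` begins before `end`
                j = np.searchsorted(re, start, side="right")
                bad = (j < len(rs)) & (rs[np.minimum(j, len(rs) - 1)] < end)
                todo = np.flatnonzero(bad)
                if todo.size == 0:
                    break
            else:
                raise RuntimeError(
                    f"could not place all controls on {chrom} within {max_retries} rounds"
                )
            for k, cs, w, s, e in zip(
                idxs,
                core_start,
                widths,
                np.maximum(core_start - flank, 0),
                np.minimum(core_start + widths + flank, length),
            ):
                placed[k] = BorderRegion(
                    border_id=regions[k].border_id,
                    chrom=chrom,
                    core_start=int(cs),
                    core_end=int(cs + w),
                    start=int(s),
                    end=int(e),
                )
        replicates.append([p for p in placed if p is not None])
    return replicates


@dataclass(frozen=True)
class EnrichmentTable:
    """Result of the border-region SNP over-representation test."""

    obs_in: int
    obs_total: int
    ctrl_in: int  # averaged over control replicates, rounded half-up
    ctrl_total: int
    odds_ratio: float
    pvalue: float
    sided: str


def fisher_enrichment(
    obs_in: int,
    obs_total: int,
    ctrl_in: float,
    ctrl_total: int,
    sided: str = "greater",
) -> EnrichmentTable:
    """Fisher's exact test on [[obs_in, obs_out], [ctrl_in, ctrl_out]].

    ``ctrl_in`` may be fractional (an average over control replicates); it
    is rounded half-up to an integer, since the exact test needs an integer
    table.  ``sided`` is ``"greater"`` (one-sided over-representation,
    default) or ``"two-sided"``.
    """
    ctrl_in_int = int(np.floor(ctrl_in + 0.5))
    if min(obs_in, obs_total, ctrl_in_int, ctrl_total) < 0:
        raise ValueError("counts must be nonnegative")
    if obs_in > obs_total or ctrl_in_int > ctrl_total:
        raise ValueError("in-region counts exceed totals")
    if sided not in ("greater", "two-sided"):
        raise ValueError(f"sided must be 'greater' or 'two-sided', got {sided!r}")
    table = [
        [obs_in, obs_total - obs_in],
        [ctrl_in_int, ctrl_total - ctrl_in_int],
    ]
    odds, p = stats.fisher_exact(table, alternative=sided)
    return EnrichmentTable(
        obs_in=obs_in,
        obs_total=obs_total,
        ctrl_in=ctrl_in_int,
        ctrl_total=ctrl_total,
        odds_ratio=float(odds),
        pvalue=float(p),
        sided=sided,
    )


def tad_enrichment_test(
    noncoding_snps: pd.DataFrame,
    borders: pd.DataFrame,
    layout: GenomeLayout,
    reps: int = 100,
    seed: int = 0,
    flank: int = 100,
    sided: str = "greater",
    point_borders: bool = False,
) -> tuple[EnrichmentTable, list[BorderRegion]]:
    """End-to-end border enrichment: flank, count, 100 matched controls, Fisher.

    Returns the enrichment table and the real border regions with their SNP
    counts (from which mutated borders can be read off).
    """
    regions = make_border_regions(borders, layout, flank=flank)
    counted, obs_in = count_snps_in_regions(noncoding_snps, regions)
    controls = sample_control_borders(
        regions, layout, reps=reps, seed=seed, flank=flank, point_borders=point_borders
    )
    ctrl_counts = [count_snps_in_regions(noncoding_snps, ctrl)[1] for ctrl in controls]
    ctrl_mean = float(np.mean(ctrl_counts))
    n_total = len(noncoding_snps)
    result = fisher_enrichment(obs_in, n_total, ctrl_mean, n_total, sided=sided)
    return result, counted


def gene_border_proximity(
    genes: pd.DataFrame,
    regions: list[BorderRegion],
    layout10kb: GenomeLayout,
) -> pd.DataFrame:
    """Classify genes by the mutation status of nearby TAD borders.

    Each border is assigned to the 10-Kb bin containing its core midpoint;
    its proximity window is that bin plus one adjacent bin on each side
    (30 Kb in total, clamped at chromosome ends).  A gene is *near* a
    border iff its interval intersects the window.  The per-gene class is:

    * ``mutated-only`` — near >= 1 mutated border, no non-mutated ones
    * ``nonmutated-only`` — the reverse
    * ``both`` — near borders of both kinds
    * ``none`` — near no border

    Returns the gene table with a ``border_class`` column plus the lists of
    nearby mutated/non-mutated border IDs.
    """
    bs = layout10kb.bin_size
    windows: list[tuple[str, int, int, int, bool]] = []
    for reg in regions:
        mid = (reg.core_start + reg.core_end) // 2
        length = layout10kb.chrom_length(reg.chrom)
        mid = min(mid, length - 1)
        b0 = (mid // bs) * bs
        start = max(0, b0 - bs)
        end = min(length, b0 + 2 * bs)
        windows.append((reg.chrom, start, end, reg.border_id, reg.mutated))

    win_by_chrom: dict[str, list[tuple[int, int, int, bool]]] = {}
    for chrom, start, end, bid, mut in windows:
        win_by_chrom.setdefault(chrom, []).append((start, end, bid, mut))

    classes, mut_ids, nonmut_ids = [], [], []
    for row in genes.itertuples():
        near_mut, near_non = [], []
        for start, end, bid, mut in win_by_chrom.get(str(row.chrom), ()):
            if row.start < end and start < row.end:
                (near_mut if mut else near_non).append(bid)
        if near_mut and near_non:
            cls = "both"
        elif near_mut:
            cls = "mutated-only"
        elif near_non:
            cls = "nonmutated-only"
        else:
            cls = "none"
        classes.append(cls)
        mut_ids.append(";".join(map(str, sorted(near_mut))))
        nonmut_ids.append(";".join(map(str, sorted(near_non))))
    out = genes.copy()
    out["border_class"] = classes
    out["mutated_border_ids"] = mut_ids
    out["nonmutated_border_ids"] = nonmut_ids
    return out
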
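"""Long-range target assignment for non-coding SNPs at 10-Kb resolution.

For each 10-Kb bin harboring non-coding SNPs, the *strongest interactor* is
the intra-chromosomal partner bin with the highest contact frequency.  In a
distance-decaying contact map the strongest interactor is almost always an
adjacent bin; bins whose strongest interactor is farther away ("long-range",
default: at least 2 bins, i.e. non-adjacent) are candidate regulatory
loops, and the genes in the partner bin are candidate targets of the SNPs.
The top pairs by contact frequency are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .layout import GenomeLayout

__all__ = [
    "TargetPair",
    "strongest_interactor",
    "rank_long_range_pairs",
    "genes_in_bin",
    "write_target_pairs_tsv",
]


@dataclass(frozen=True)
class TargetPair:
    """A SNP-harboring bin paired with its strongest interacting bin."""

    snp_bin: int
    target_bin: int
    frequency: float
    distance_bins: int
    distance_bp: int
    genes_in_target: tuple[str, ...] = ()
    snp_ids: tuple[str, ...] = ()


def strongest_interactor(
    bin_id: int, contacts: ContactMatrix
) -> tuple[int, float] | None:
    """Intra-chromosomal partner with maximal contact frequency, or None.

    The bin itself is excluded.  Ties are broken toward the smaller bin
    distance, then the smaller bin ID.  Returns ``None`` when the bin has no
    positive intra-chromosomal contact ("no interactor").
    """
    layout = contacts.layout
    chrom = layout.bin_chrom(bin_id)
    first, last = layout.chrom_bin_range(chrom)
    m = contacts.matrix
    lo, hi = m.indptr[bin_id - 1], m.indptr[bin_id]
    cols = m.indices[lo:hi] + 1  # 1-based partner bins
    vals = m.data[lo:hi]
    keep = (cols >= first) & (cols <= last) & (cols != bin_id) & (vals > 0)
    cols, vals = cols[keep], vals[keep]
    if cols.size == 0:
        return None
    fmax = vals.max()
    cand = cols[vals == fmax]
    dist = np.abs(cand - bin_id)
    order = np.lexsort((cand, dist))
    best = int(cand[order[0]])
    return best, float(fmax)


def rank_long_range_pairs(
    snp_bins: dict[int, list[str]] | set[int],
    contacts: ContactMatrix,
    min_distance: int = 2,
    top_k: int = 30,
    genes: pd.DataFrame | None = None,
) -> list[TargetPair]:
    """Top long-range strongest-interactor pairs, ranked by frequency.

    ``snp_bins`` maps each 10-Kb bin harboring non-coding SNPs to the IDs
    of those SNPs (a bare set of bins is also accepted).  A pair is emitted
    when the bin's strongest interactor lies at least ``min_distance`` bins
    away (default 2, i.e. non-adjacent); pairs are sorted by frequency
    descending (ties: smaller snp_bin first) and the top ``top_k`` are
    returned — all of them if fewer qualify.
    """
    if not isinstance(snp_bins, dict):
        snp_bins = {b: [] for b in snp_bins}
    layout = contacts.layout
    pairs: list[TargetPair] = []
    for b in sorted(snp_bins):
        hit = strongest_interactor(b, contacts)
        if hit is None:
            continue
        target, f = hit
        d = abs(target - b)
        if d < min_distance:
            continue
        gene_ids: tuple[str, ...] = ()
        if genes is not None:
            gene_ids = tuple(sorted(genes_in_bin(target, genes, layout)))
        pairs.append(
            TargetPair(
                snp_bin=b,
                target_bin=target,
                frequency=f,
                distance_bins=d,
                distance_bp=d * layout.bin_size,
                genes_in_target=gene_ids,
                snp_ids=tuple(snp_bins[b]),
            )
        )
    pairs.sort(key=lambda p: (-p.frequency, p.snp_bin))
    return pairs[:top_k]


def genes_in_bin(bin_id: int, genes: pd.DataFrame, layout: GenomeLayout) -> set[str]:
    """IDs of genes whose interval intersects the bin's interval.

    May be empty ("gene-less" bins).  Intersection is on 0-based half-open
    intervals, so a gene abutting the bin end is not counted.
    """
    chrom, start, end = layout.bin_interval(bin_id)
    sel = genes[genes["chrom"] == chrom]
    hit = (sel["start"] < end) & (sel["end"] > start)
    return set(sel.loc[hit, "gene_id"])


def write_target_pairs_tsv(pairs: list[TargetPair], layout: GenomeLayout, path) -> None:
    rows = []
    for p in pairs:
        sc, ss, se = layout.bin_interval(p.snp_bin)
        tc, ts, te = layout.bin_interval(p.target_bin)
        rows.append(
            {
                "snp_bin": p.snp_bin,
                "snp_bin_coords": f"{sc}:{ss}-{se}",
                "target_bin": p.target_bin,
                "target_coords": f"{tc}:{ts}-{te}",
                "frequency": p.frequency,
                "distance_bp": p.distance_bp,
                "genes_in_target": ";".join(p.genes_in_target),
                "snp_ids": ";".join(p.snp_ids),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "snp_bin",
            "snp_bin_coords",
            "target_bin",
            "target_coords",
            "frequency",
            "distance_bp",
            "genes_in_target",
            "snp_ids",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
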
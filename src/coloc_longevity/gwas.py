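"""GWAS summary-statistic preprocessing.

Two dataset conventions are supported, mirroring the two longevity GWAS
designs the pipeline consumes:

* **synthetic-style** (evolve-and-resequence from a small founder panel):
  each SNP carries per-founder haplotype frequencies for an "old" group and
  a "young" control group, columns ``h_O_1..h_O_n`` and ``h_Y_1..h_Y_n``.
  Divergence is scored with the ``D`` statistic — 100 times the
  root-mean-square difference between old and young haplotype frequencies —
  and ``D > 7.9`` marks genome-wide significance.
* **dgrp-style** (inbred reference panel): each SNP carries an association
  ``pvalue``; significance is Bonferroni, ``p < alpha / m`` with ``m`` the
  number of Hi-C bins.

SNP tables are pandas DataFrames with columns ``chrom, pos, id, dataset``
plus the convention-specific score columns.  Positions are 1-based.
Combined duplicate positions may have different haplotype counts per row;
unused frequency columns hold NaN and the per-row ``n`` is the count of
non-NaN entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import GenomeLayout

logger = logging.getLogger(__name__)

__all__ = [
    "SignificancePolicy",
    "compute_D",
    "add_d_scores",
    "combine_duplicate_snps",
    "bonferroni_threshold",
    "select_significant",
    "classify_coding",
    "assign_bins",
    "freq_columns",
]


def freq_columns(df: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Old-group and young-group haplotype-frequency column names, in order."""
    o = sorted((c for c in df.columns if c.startswith("h_O_")), key=lambda c: int(c[4:]))
    y = sorted((c for c in df.columns if c.startswith("h_Y_")), key=lambda c: int(c[4:]))
    return o, y


def compute_D(h_O, h_Y) -> float:
    """Haplotype-frequency divergence ``D = 100 * sqrt(mean((h_O - h_Y)^2))``.

    ``h_O`` and ``h_Y`` are the per-founder haplotype frequencies of the old
    and young groups at one SNP; the mean is over the ``n`` founder
    haplotypes present.  D lies in [0, 100]; D = 0 iff the groups agree
    exactly.
    """
    h_O = np.asarray(h_O, dtype=float)
    h_Y = np.asarray(h_Y, dtype=float)
    if h_O.shape != h_Y.shape:
        raise ValueError(f"frequency vectors differ in length: {h_O.shape} vs {h_Y.shape}")
    if h_O.size == 0:
        raise ValueError("frequency vectors are empty")
    if (h_O < 0).any() or (h_O > 1).any() or (h_Y < 0).any() or (h_Y > 1).any():
        raise ValueError("haplotype frequencies must lie in [0, 1]")
    return float(100.0 * np.sqrt(np.mean((h_O - h_Y) ** 2)))


def add_d_scores(snps: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``D`` column computed row-wise (NaN-aware).

    Rows may carry different numbers of founder haplotypes (after duplicate
    combining); NaN frequency cells are ignored and ``n`` is the per-row
    count of non-NaN founders.
    """
    o_cols, y_cols = freq_columns(snps)
    if not o_cols or len(o_cols) != len(y_cols):
        raise ValueError("table lacks matched h_O_*/h_Y_* frequency columns")
    ho = snps[o_cols].to_numpy(dtype=float)
    hy = snps[y_cols].to_numpy(dtype=float)
    diff2 = (ho - hy) ** 2
    n = np.sum(~np.isnan(ho), axis=1)
    if (n == 0).any():
        raise ValueError("some rows have no haplotype frequencies")
    out = snps.copy()
    out["D"] = 100.0 * np.sqrt(np.nansum(diff2, axis=1) / n)
    return out


def combine_duplicate_snps(snps: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing (chrom, pos) into one record per position.

    The haplotype-frequency vectors of the duplicate rows are concatenated
    per group (old with old, young with young) and each group's combined
    vector is renormalized to sum to 1; the haplotype count ``n`` of the
    combined record is the total number of concatenated founders.  Frequency
    columns are widened as needed, padding with NaN.

    Non-frequency columns are taken from the first duplicate.
    """
    o_cols, y_cols = freq_columns(snps)
    dup_mask = snps.duplicated(subset=["chrom", "pos"], keep=False)
    if not dup_mask.any():
        return snps.copy()

    # merge only the duplicated positions; the (vast) unique majority passes
    # through untouched
    meta_cols = [c for c in snps.columns if not c.startswith(("h_O_", "h_Y_"))]
    merged_rows: list[dict] = []
    max_n = len(o_cols)
    for (chrom, pos), grp in snps.loc[dup_mask].groupby(["chrom", "pos"], sort=True):
        rec = {c: grp.iloc[0][c] for c in meta_cols}
        ho_parts, hy_parts = [], []
        for _, row in grp.iterrows():
            ho = row[o_cols].to_numpy(dtype=float)
            hy = row[y_cols].to_numpy(dtype=float)
            keep = ~np.isnan(ho)
            ho_parts.append(ho[keep])
            hy_parts.append(hy[keep])
        ho = np.concatenate(ho_parts)
        hy = np.concatenate(hy_parts)
        ho = ho / ho.sum() if ho.sum() > 0 else ho
        hy = hy / hy.sum() if hy.sum() > 0 else hy
        max_n = max(max_n, ho.size)
        rec["_ho"], rec["_hy"] = ho, hy
        merged_rows.append(rec)

    for rec in merged_rows:
        ho, hy = rec.pop("_ho"), rec.pop("_hy")
        for j in range(max_n):
            rec[f"h_O_{j + 1}"] = ho[j] if j < ho.size else np.nan
            rec[f"h_Y_{j + 1}"] = hy[j] if j < hy.size else np.nan
    merged = pd.DataFrame(merged_rows)
    out = pd.concat([snps.loc[~dup_mask], merged], ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Multiple-testing-corrected significance level ``alpha / m``."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


@dataclass(frozen=True)
class SignificancePolicy:
    """How a SNP table is filtered to genome-wide-significant SNPs.

    ``d_threshold`` mode keeps SNPs with ``D > d_cut`` (strict, matching the
    convention that significant SNPs *exceed* the cut); ``bonferroni`` mode
    keeps SNPs with ``pvalue < alpha / m``.
    """

    mode: str  # "d_threshold" | "bonferroni"
    d_cut: float = 7.9
    alpha: float = 0.05
    m: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("d_threshold", "bonferroni"):
            raise ValueError(f"unknown policy mode {self.mode!r}")
        if self.mode == "d_threshold" and self.d_cut <= 0:
            raise ValueError("d_cut must be positive")
        if self.mode == "bonferroni":
            bonferroni_threshold(self.alpha, self.m)  # validates

    @property
    def threshold(self) -> float:
        if self.mode == "d_threshold":
            return self.d_cut
        return bonferroni_threshold(self.alpha, self.m)


def select_significant(snps: pd.DataFrame, policy: SignificancePolicy) -> pd.DataFrame:
    """Filter to genome-wide-significant SNPs; input row order is preserved."""
    if policy.mode == "d_threshold":
        if "D" not in snps.columns:
            raise ValueError("policy is d_threshold but table has no D column")
        mask = snps["D"].to_numpy(dtype=float) > policy.d_cut
    else:
        if "pvalue" not in snps.columns:
            raise ValueError("policy is bonferroni but table has no pvalue column")
        mask = snps["pvalue"].to_numpy(dtype=float) < policy.threshold
    return snps.loc[mask].copy()


def classify_coding(snps: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Flag SNPs as coding and record overlapped gene IDs.

    A SNP is coding iff its position falls between the start and end of at
    least one gene, both endpoints inclusive (1-based point against the
    0-based half-open stored interval).  ``gene_ids`` lists all overlapping
    genes, semicolon-joined.  SNPs on chromosomes absent from the gene
    table are logged and flagged non-coding.
    """
    known_chroms = set(genes["chrom"].unique())
    coding = np.zeros(len(snps), dtype=bool)
    hit_lists: list[list[str]] = [[] for _ in range(len(snps))]
    unknown: set[str] = set()
    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos"].to_numpy(dtype=np.int64)
    row_idx = np.arange(len(snps))
    for chrom in pd.unique(chrom_arr):
        sel = chrom_arr == chrom
        if chrom not in known_chroms:
            unknown.add(str(chrom))
            continue
        pts = pos_arr[sel] - 1  # 0-based points
        order = np.argsort(pts, kind="stable")
        sorted_pts = pts[order]
        rows = row_idx[sel][order]
        # per gene, the SNPs inside it form a contiguous slice of sorted_pts
        for g in genes.loc[genes["chrom"] == chrom].itertuples():
            lo = np.searchsorted(sorted_pts, g.start, side="left")
            hi = np.searchsorted(sorted_pts, g.end, side="left")
            for r in rows[lo:hi]:
                hit_lists[r].append(g.gene_id)
    gene_ids = []
    for k, hits in enumerate(hit_lists):
        if hits:
            coding[k] = True
            gene_ids.append(";".join(sorted(hits)))
        else:
            gene_ids.append("")
    if unknown:
        logger.warning(
            "SNPs on chromosomes absent from gene table flagged non-coding: %s",
            sorted(unknown),
        )
    out = snps.copy()
    out["coding"] = coding
    out["gene_ids"] = gene_ids
    return out


def assign_bins(snps: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Map each SNP to its global Hi-C bin ID (column ``bin``).

    Raises ``ValueError`` listing offending rows if a position exceeds its
    chromosome length or a chromosome is absent from the layout.
    """
    bins = np.empty(len(snps), dtype=np.int64)
    offenders: list[str] = []
    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos"].to_numpy(dtype=np.int64)
    for chrom in pd.unique(chrom_arr):
        sel = chrom_arr == chrom
        try:
            first = layout.offsets[layout.chrom_index(chrom)]
            length = layout.chrom_length(chrom)
        except KeyError:
            offenders.extend(f"{chrom}:{p}" for p in pos_arr[sel][:5])
            continue
        pos = pos_arr[sel]
        bad = (pos < 1) | (pos > length)
        if bad.any():
            offenders.extend(f"{chrom}:{p}" for p in pos[bad][:5])
            continue
        bins[sel] = first + (pos - 1) // layout.bin_size
    if offenders:
        raise ValueError(f"SNP positions outside layout: {offenders}")
    out = snps.copy()
    out["bin"] = bins
    return out
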
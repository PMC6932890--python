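"""Hi-C contact matrices and the top-1% "strong interaction" thresholds.

A :class:`ContactMatrix` stores normalized interaction frequencies between
genome bins as a symmetric sparse matrix tied to a :class:`~coloc_longevity.layout.GenomeLayout`.
Zero entries mean "no recorded contact" and are excluded from all quantile
computations (Hi-C matrices are zero-inflated, so quantiles over all entries
would be meaningless).

Thresholds
----------
"Strong" interactions are the top tail of the observed frequency
distribution: intra-chromosomal contacts are thresholded per whole
chromosome (arms pooled, e.g. 2L+2R -> "2"), inter-chromosomal contacts get
a single genome-wide threshold.  The threshold for tail quantile ``q`` is
the smallest observed frequency ``v`` such that the fraction of positive
entries strictly greater than ``v`` is at most ``1 - q``; an interaction is
strong iff its frequency strictly exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .layout import GenomeLayout

__all__ = [
    "ContactMatrix",
    "ThresholdSet",
    "compute_thresholds",
    "tail_threshold",
    "read_contacts_tsv",
    "write_contacts_tsv",
]


class ContactMatrix:
    """Symmetric nonnegative contact frequencies over a genome layout.

    Parameters
    ----------
    layout:
        The bin layout; the matrix is ``layout.n_bins`` square, with
        row/column ``i`` corresponding to global bin ``i + 1``.
    matrix:
        Dense array or scipy sparse matrix of frequencies.  Must be
        symmetric and nonnegative.
    """

    def __init__(self, layout: GenomeLayout, matrix) -> None:
        m = sparse.csr_array(matrix)
        if m.shape != (layout.n_bins, layout.n_bins):
            raise ValueError(
                f"matrix shape {m.shape} does not match layout with {layout.n_bins} bins"
            )
        if (m.data < 0).any():
            raise ValueError("contact frequencies must be nonnegative")
        if abs(m - m.T).sum() > 1e-8 * max(1.0, abs(m).sum()):
            raise ValueError("contact matrix must be symmetric")
        self.layout = layout
        self.matrix = m

    @property
    def resolution(self) -> int:
        return self.layout.bin_size

    @property
    def n_bins(self) -> int:
        return self.layout.n_bins

    def value(self, bin_i: int, bin_j: int) -> float:
        return float(self.matrix[bin_i - 1, bin_j - 1])

    def row(self, bin_i: int) -> np.ndarray:
        """Dense frequency row for one global bin (1-based)."""
        return self.matrix[[bin_i - 1], :].toarray().ravel()

    def upper_triangle(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(bins_i, bins_j, f) for all positive entries with i < j (1-based)."""
        coo = sparse.triu(self.matrix, k=1).tocoo()
        keep = coo.data > 0
        return coo.row[keep] + 1, coo.col[keep] + 1, coo.data[keep]


@dataclass(frozen=True)
class ThresholdSet:
    """Top-tail interaction-frequency thresholds.

    ``intra`` maps pooled chromosome name ("2", "3", "4", "X", ...) to its
    threshold; ``inter`` is the single inter-chromosomal threshold.
    ``cross_arm`` records whether contacts between two arms of the same
    pooled chromosome were classed as intra (default) or inter.
    """

    q: float
    intra: dict[str, float]
    inter: float
    cross_arm: str = "intra"

    def threshold_for(self, layout: GenomeLayout, bin_i: int, bin_j: int) -> float:
        ci = layout.bin_chrom(bin_i)
        cj = layout.bin_chrom(bin_j)
        from .layout import pooled_chromosome

        pi, pj = pooled_chromosome(ci), pooled_chromosome(cj)
        if pi == pj and (self.cross_arm == "intra" or ci == cj):
            return self.intra[pi]
        return self.inter


def tail_threshold(values: np.ndarray, q: float) -> float:
    """Smallest observed value with at most ``1 - q`` of values strictly above.

    ``values`` must be the positive observed frequencies of one class
    (one pooled chromosome, or all inter-chromosomal pairs).
    """
    values = np.asarray(values, dtype=float)
    values = values[values > 0]
    if values.size == 0:
        raise ValueError("no positive entries to threshold")
    vals = np.sort(values)
    n = vals.size
    # fraction strictly greater than vals[k] = (n - right_rank(vals[k])) / n
    uniq, counts = np.unique(vals, return_counts=True)
    greater = n - np.cumsum(counts)  # entries strictly above each unique value
    ok = greater / n <= (1.0 - q)
    return float(uniq[np.argmax(ok)])  # first unique value satisfying the bound


def compute_thresholds(
    contacts: ContactMatrix, q: float = 0.99, cross_arm: str = "intra"
) -> ThresholdSet:
    """Per-chromosome intra and global inter thresholds at tail quantile ``q``.

    Arms are pooled (2L+2R -> "2"); the diagonal is excluded (a self-contact
    is not an interaction between two distinct loci).  ``cross_arm`` decides
    whether contacts between two arms of one pooled chromosome count as
    intra ("intra", default) or inter ("inter").

    Raises
    ------
    ValueError
        If some pooled chromosome (or the inter class) has no positive
        entries, so its threshold would be undefined.
    """
    if cross_arm not in ("intra", "inter"):
        raise ValueError(f"cross_arm must be 'intra' or 'inter', got {cross_arm!r}")
    layout = contacts.layout
    bi, bj, f = contacts.upper_triangle()
    pool = layout.pooled_index_array()  # per global bin
    chrom = layout.bin_chrom_array()
    pi, pj = pool[bi - 1], pool[bj - 1]
    same_pool = pi == pj
    if cross_arm == "inter":
        same_pool = same_pool & (chrom[bi - 1] == chrom[bj - 1])
    intra: dict[str, float] = {}
    for gi, name in enumerate(layout.pooled_names):
        vals = f[same_pool & (pi == gi)]
        if vals.size == 0:
            raise ValueError(f"no positive intra-chromosomal entries for chromosome {name}")
        intra[name] = tail_threshold(vals, q)
    inter_vals = f[~same_pool]
    if inter_vals.size == 0:
        if len(layout.pooled_names) == 1:
            inter = float("inf")  # single-chromosome layout: no inter class
        else:
            raise ValueError("no positive inter-chromosomal entries")
    else:
        inter = tail_threshold(inter_vals, q)
    return ThresholdSet(q=q, intra=intra, inter=inter, cross_arm=cross_arm)


def write_contacts_tsv(contacts: ContactMatrix, path) -> None:
    """Write positive entries with bin_i <= bin_j as a triplet TSV."""
    coo = sparse.triu(contacts.matrix, k=0).tocoo()
    keep = coo.data > 0
    df = pd.DataFrame(
        {
            "bin_i": coo.row[keep] + 1,
            "bin_j": coo.col[keep] + 1,
            "frequency": coo.data[keep],
        }
    ).sort_values(["bin_i", "bin_j"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_contacts_tsv(path, layout: GenomeLayout) -> ContactMatrix:
    df = pd.read_csv(path, sep="\t")
    i = df["bin_i"].to_numpy(dtype=int) - 1
    j = df["bin_j"].to_numpy(dtype=int) - 1
    f = df["frequency"].to_numpy(dtype=float)
    n = layout.n_bins
    upper = sparse.coo_array((f, (i, j)), shape=(n, n)).tocsr()
    full = upper + sparse.triu(upper, k=1).T
    return ContactMatrix(layout, full)
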
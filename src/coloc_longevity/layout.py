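"""Genome layouts: fixed-width bins indexed contiguously across chromosomes.

All networks and contact matrices in this package are defined over a
:class:`GenomeLayout` — an ordered set of chromosomes partitioned into
fixed-width bins (80 Kb for the genome-wide analysis, 10 Kb for the
fine-scale target search).  Global bin IDs are 1-based and contiguous in
chromosome order, so bin arithmetic is pure offset arithmetic.

Conventions
-----------
* SNP positions are 1-based points (VCF style).
* Intervals, including bin intervals, are 0-based half-open (BED style).
* The bin with global ID ``i`` on a chromosome whose first global index is
  ``o`` covers ``[(i - o) * bin_size, (i - o + 1) * bin_size)``, clamped to
  the chromosome length for the last bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "make_genome_layout",
    "DM3_LIKE_CHROMOSOMES",
    "pooled_chromosome",
    "read_layout_tsv",
    "write_layout_tsv",
]

#: Stylised D. melanogaster arm lengths (bp).  Chosen so that an 80-Kb
#: binning yields exactly 1,503 bins with arm boundaries at global bins
#: 287/551/858/1207/1223/1503, matching the published genome-wide Hi-C
#: bin layout for this genome.
DM3_LIKE_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("2L", 22_960_000),
    ("2R", 21_120_000),
    ("3L", 24_560_000),
    ("3R", 27_920_000),
    ("4", 1_280_000),
    ("X", 22_400_000),
)


def pooled_chromosome(name: str) -> str:
    """Collapse chromosome arms into whole chromosomes ("2L"/"2R" -> "2").

    Intra-chromosomal contact thresholds are computed per whole chromosome,
    pooling left and right arms.  Names that do not end in ``L`` or ``R``
    (or that are a bare ``L``/``R``) are returned unchanged.
    """
    if len(name) > 1 and name[-1] in ("L", "R"):
        return name[:-1]
    return name


@dataclass(frozen=True)
class GenomeLayout:
    """An ordered chromosome set partitioned into fixed-width bins."""

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int
    # first global bin ID per chromosome (1-based), parallel to chromosomes
    offsets: tuple[int, ...] = field(init=False)
    n_bins: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("chromosome list must be non-empty")
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        offsets = []
        nxt = 1
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            offsets.append(nxt)
            nxt += -(-length // self.bin_size)  # ceil division
        object.__setattr__(self, "offsets", tuple(offsets))
        object.__setattr__(self, "n_bins", nxt - 1)

    # -- lookups ---------------------------------------------------------

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def chrom_index(self, chrom: str) -> int:
        for i, (name, _) in enumerate(self.chromosomes):
            if name == chrom:
                return i
        raise KeyError(f"unknown chromosome {chrom!r}")

    def chrom_bin_count(self, chrom: str) -> int:
        i = self.chrom_index(chrom)
        length = self.chromosomes[i][1]
        return -(-length // self.bin_size)

    def chrom_bin_range(self, chrom: str) -> tuple[int, int]:
        """Inclusive (first, last) global bin IDs of a chromosome."""
        i = self.chrom_index(chrom)
        first = self.offsets[i]
        return first, first + self.chrom_bin_count(chrom) - 1

    def bin_of(self, chrom: str, pos: int) -> int:
        """Global bin ID of a 1-based position.

        Local bin ``k = floor((pos - 1) / bin_size) + 1``; the global ID is
        the chromosome's first global index plus ``k - 1``.
        """
        length = self.chrom_length(chrom)
        if not 1 <= pos <= length:
            raise ValueError(
                f"position {chrom}:{pos} outside chromosome length {length}"
            )
        k = (pos - 1) // self.bin_size + 1
        return self.offsets[self.chrom_index(chrom)] + k - 1

    def bin_chrom(self, global_bin: int) -> str:
        """Chromosome housing a global bin ID."""
        if not 1 <= global_bin <= self.n_bins:
            raise ValueError(f"global bin {global_bin} outside 1..{self.n_bins}")
        idx = int(np.searchsorted(self.offsets, global_bin, side="right")) - 1
        return self.chromosomes[idx][0]

    def bin_interval(self, global_bin: int) -> tuple[str, int, int]:
        """(chrom, start, end) 0-based half-open interval of a global bin."""
        chrom = self.bin_chrom(global_bin)
        i = self.chrom_index(chrom)
        local = global_bin - self.offsets[i]
        start = local * self.bin_size
        end = min(start + self.bin_size, self.chromosomes[i][1])
        return chrom, start, end

    def bin_chrom_array(self) -> np.ndarray:
        """Chromosome index (into ``chromosomes``) of every global bin."""
        out = np.empty(self.n_bins, dtype=np.int64)
        for i, name in enumerate(self.chrom_names):
            first, last = self.chrom_bin_range(name)
            out[first - 1 : last] = i
        return out

    def pooled_index_array(self) -> np.ndarray:
        """Pooled-chromosome group index of every global bin (arms merged)."""
        pools: list[str] = []
        for name in self.chrom_names:
            p = pooled_chromosome(name)
            if p not in pools:
                pools.append(p)
        pool_of_chrom = np.array(
            [pools.index(pooled_chromosome(n)) for n in self.chrom_names]
        )
        return pool_of_chrom[self.bin_chrom_array()]

    @property
    def pooled_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for name in self.chrom_names:
            p = pooled_chromosome(name)
            if p not in seen:
                seen.append(p)
        return tuple(seen)

    @property
    def genome_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


def make_genome_layout(
    chrom_spec: Sequence[tuple[str, int]] | Iterable[tuple[str, int]] = DM3_LIKE_CHROMOSOMES,
    bin_size: int = 80_000,
) -> GenomeLayout:
    """Build a :class:`GenomeLayout` from (name, length) pairs.

    Each chromosome contributes ``ceil(length / bin_size)`` bins; global bin
    IDs are 1-based and contiguous across chromosomes in the given order.
    """
    return GenomeLayout(chromosomes=tuple(chrom_spec), bin_size=int(bin_size))


def write_layout_tsv(layout: GenomeLayout, path) -> None:
    df = pd.DataFrame(
        {
            "chrom": layout.chrom_names,
            "length": [length for _, length in layout.chromosomes],
            "first_bin": layout.offsets,
            "last_bin": [layout.chrom_bin_range(c)[1] for c in layout.chrom_names],
        }
    )
    df.insert(1, "bin_size", layout.bin_size)
    df.to_csv(path, sep="\t", index=False)


def read_layout_tsv(path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t")
    bin_sizes = df["bin_size"].unique()
    if len(bin_sizes) != 1:
        raise ValueError("layout file mixes bin sizes")
    return make_genome_layout(
        [(str(r.chrom), int(r.length)) for r in df.itertuples()], int(bin_sizes[0])
    )
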
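"""Gene and TAD-border annotation tables.

Both annotation sets are plain BED-style TSV tables so that users can export
them from FlyBase/FlyMine (or any other source) themselves; the package
makes no network calls.

Genes
-----
Columns: ``chrom, start, end, gene_id, phenotype, go_terms``.  Intervals are
0-based half-open.  ``phenotype`` is one of ``long-lived``, ``short-lived``,
``increased-mortality``, ``lethal``, ``none``; ``go_terms`` is a
semicolon-joined (possibly empty) list of flat GO-term labels.

Borders
-------
Columns: ``chrom, start, end, border_id``.  These are the *core* intervals
of TAD borders; flanking is applied downstream (see
:mod:`coloc_longevity.tad`).
"""

from __future__ import annotations

import pandas as pd

PHENOTYPES = ("long-lived", "short-lived", "increased-mortality", "lethal", "none")

GENE_COLUMNS = ["chrom", "start", "end", "gene_id", "phenotype", "go_terms"]
BORDER_COLUMNS = ["chrom", "start", "end", "border_id"]

__all__ = [
    "PHENOTYPES",
    "GENE_COLUMNS",
    "BORDER_COLUMNS",
    "read_genes_tsv",
    "write_genes_tsv",
    "read_borders_tsv",
    "write_borders_tsv",
    "split_go_terms",
]


def split_go_terms(cell) -> frozenset[str]:
    if not isinstance(cell, str) or not cell:
        return frozenset()
    return frozenset(t for t in cell.split(";") if t)


def write_genes_tsv(genes: pd.DataFrame, path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    bad = set(df["phenotype"]) - set(PHENOTYPES)
    if bad:
        raise ValueError(f"unknown phenotype flags: {sorted(bad)}")
    return df


def write_borders_tsv(borders: pd.DataFrame, path) -> None:
    borders[BORDER_COLUMNS].to_csv(path, sep="\t", index=False)


def read_borders_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(BORDER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"border table missing columns: {sorted(missing)}")
    return df
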
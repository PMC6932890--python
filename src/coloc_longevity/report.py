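"""Gene-level reporting: node gene content, GO enrichment, cluster reports.

GO terms are treated as flat gene sets (no DAG propagation).  Enrichment of
a query gene set against a background universe is a one-sided
hypergeometric test: with ``N`` universe genes of which ``K`` carry the
term, and ``n`` query genes of which ``k`` carry it,
``p = P(X >= k), X ~ Hypergeometric(N, K, n)``.

The default universe is the set of genes residing in the active network's
nodes — the conservative background for "genes residing within important
nodes/clusters" — switchable to the whole gene table.  Raw p-values are
reported; a Benjamini-Hochberg column can be requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import split_go_terms
from .layout import GenomeLayout
from .network import ColocationNetwork, CommunityPartition

__all__ = [
    "EnrichmentResult",
    "genes_by_bin",
    "genes_in_nodes",
    "go_enrichment",
    "cluster_report",
    "cluster_report_frame",
]


def genes_by_bin(
    nodes: set[int], genes: pd.DataFrame, layout: GenomeLayout
) -> dict[int, set[str]]:
    """Map each member bin to the genes whose interval intersects it.

    Built in one pass over the gene table (each gene covers a contiguous
    bin range), so it is the workhorse behind all node/cluster gene
    lookups.  Intersection is on 0-based half-open intervals.
    """
    out: dict[int, set[str]] = {b: set() for b in nodes}
    if not nodes:
        return out
    chrom_names = set(layout.chrom_names)
    for g in genes.itertuples():
        if g.chrom not in chrom_names or g.end <= g.start:
            continue
        length = layout.chrom_length(g.chrom)
        first_bin = layout.bin_of(g.chrom, min(int(g.start), length - 1) + 1)
        last_bin = layout.bin_of(g.chrom, min(int(g.end), length))
        for b in range(first_bin, last_bin + 1):
            if b in out:
                out[b].add(g.gene_id)
    return out


def genes_in_nodes(
    nodes: set[int], genes: pd.DataFrame, layout: GenomeLayout
) -> set[str]:
    """IDs of genes whose interval intersects any member bin.

    A gene spanning several member bins is counted once.
    """
    per_bin = genes_by_bin(nodes, genes, layout)
    out: set[str] = set()
    for s in per_bin.values():
        out |= s
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    """One GO term's over-representation in a query gene set."""

    term: str
    k: int  # query genes carrying the term
    K: int  # universe genes carrying the term
    n: int  # query size
    N: int  # universe size
    pvalue: float
    overlap: tuple[str, ...]
    bh_qvalue: float | None = None


def go_enrichment(
    query: set[str],
    universe: set[str],
    annotations: pd.DataFrame,
    bh: bool = False,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric GO-term enrichment of ``query`` vs ``universe``.

    ``annotations`` is a gene table with ``gene_id`` and semicolon-joined
    ``go_terms`` columns; only universe genes contribute.  Results cover
    every term carried by at least one query gene and are sorted by
    ascending p-value (ties: term name).  With ``bh=True`` a
    Benjamini-Hochberg q-value column is filled in (off by default; raw
    p-values are the primary report).
    """
    if not universe:
        raise ValueError("universe is empty")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    ann = annotations[annotations["gene_id"].isin(universe)]
    term_genes: dict[str, set[str]] = {}
    for row in ann.itertuples():
        for term in split_go_terms(row.go_terms):
            term_genes.setdefault(term, set()).add(row.gene_id)
    N, n = len(universe), len(query)
    results = []
    for term, carriers in term_genes.items():
        overlap = carriers & query
        k, K = len(overlap), len(carriers)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                term=term, k=k, K=K, n=n, N=N,
                pvalue=min(p, 1.0), overlap=tuple(sorted(overlap)),
            )
        )
    results.sort(key=lambda r: (r.pvalue, r.term))
    if bh and results:
        m = len(results)
        ps = np.array([r.pvalue for r in results])
        q = ps * m / (np.arange(m) + 1)
        q = np.minimum.accumulate(q[::-1])[::-1].clip(max=1.0)
        results = [
            EnrichmentResult(
                term=r.term, k=r.k, K=r.K, n=r.n, N=r.N,
                pvalue=r.pvalue, overlap=r.overlap, bh_qvalue=float(qi),
            )
            for r, qi in zip(results, q)
        ]
    return results


@dataclass
class ClusterReport:
    """Per-community summary of one network partition."""

    cluster_id: int
    nodes: tuple[int, ...]
    genes: tuple[str, ...]
    phenotype_counts: dict[str, int]
    snp_counts: dict[str, int]  # gene -> SNPs residing in it
    enrichment: list[EnrichmentResult] = field(default_factory=list)
    # term -> number of member nodes harboring >= 1 gene of that term
    nodes_with_term: dict[str, int] = field(default_factory=dict)


def cluster_report(
    partition: CommunityPartition,
    net: ColocationNetwork,
    genes: pd.DataFrame,
    snps: pd.DataFrame | None = None,
    universe: set[str] | None = None,
    max_terms: int = 10,
) -> list[ClusterReport]:
    """Per-cluster gene/phenotype/enrichment summaries.

    The GO universe defaults to all genes residing in the network's nodes.
    ``snps`` (optional, with ``gene_ids`` column from coding classification)
    yields per-gene SNP counts.  Enrichment keeps the ``max_terms`` smallest
    p-values per cluster.
    """
    if set(partition.membership) != net.nodes:
        raise ValueError("partition does not cover exactly the network's nodes")
    layout = net.layout
    node_genes = genes_by_bin(net.nodes, genes, layout)
    if universe is None:
        universe = set().union(*node_genes.values()) if node_genes else set()
    pheno = dict(zip(genes["gene_id"], genes["phenotype"]))

    snp_count_per_gene: dict[str, int] = {}
    if snps is not None and "gene_ids" in snps.columns:
        for cell in snps["gene_ids"]:
            if isinstance(cell, str) and cell:
                for g in cell.split(";"):
                    snp_count_per_gene[g] = snp_count_per_gene.get(g, 0) + 1

    reports = []
    for cid, members in enumerate(partition.communities()):
        member_genes: set[str] = set()
        for b in members:
            member_genes |= node_genes[b]
        counts: dict[str, int] = {}
        for g in member_genes:
            counts[pheno.get(g, "none")] = counts.get(pheno.get(g, "none"), 0) + 1
        query = member_genes & universe
        enr = go_enrichment(query, universe, genes) if query else []
        enr = enr[:max_terms]
        nodes_with_term: dict[str, int] = {}
        for r in enr:
            overlap = set(r.overlap)
            nodes_with_term[r.term] = sum(
                1 for b in members if node_genes[b] & overlap
            )
        reports.append(
            ClusterReport(
                cluster_id=cid,
                nodes=tuple(sorted(members)),
                genes=tuple(sorted(member_genes)),
                phenotype_counts=counts,
                snp_counts={
                    g: snp_count_per_gene[g]
                    for g in sorted(member_genes)
                    if g in snp_count_per_gene
                },
                enrichment=enr,
                nodes_with_term=nodes_with_term,
            )
        )
    return reports


def cluster_report_frame(reports: list[ClusterReport]) -> pd.DataFrame:
    """Flatten cluster reports to one row per (cluster, enriched term)."""
    rows = []
    for rep in reports:
        base = {
            "cluster": rep.cluster_id,
            "n_nodes": len(rep.nodes),
            "n_genes": len(rep.genes),
            "long_lived": rep.phenotype_counts.get("long-lived", 0),
            "short_lived": rep.phenotype_counts.get("short-lived", 0),
        }
        if not rep.enrichment:
            rows.append({**base, "term": "", "pvalue": np.nan, "k": 0,
                         "nodes_with_term": 0, "genes_in_term": ""})
        for r in rep.enrichment:
            rows.append(
                {
                    **base,
                    "term": r.term,
                    "pvalue": r.pvalue,
                    "k": r.k,
                    "nodes_with_term": rep.nodes_with_term.get(r.term, 0),
                    "genes_in_term": ";".join(r.overlap),
                }
            )
    return pd.DataFrame(rows)
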
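"""End-to-end pipeline on synthetic (or user-supplied) inputs.

``run_all`` wires the stages together: generate inputs, score and filter
SNPs, map them to bins, build and extend the co-location networks, detect
communities, test TAD-border enrichment, rank long-range target pairs, and
emit cluster reports.  Every stage is deterministic given the configuration
seed; two runs with the same config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contacts import ThresholdSet, compute_thresholds
from .gwas import (
    SignificancePolicy,
    add_d_scores,
    assign_bins,
    classify_coding,
    combine_duplicate_snps,
    select_significant,
)
from .network import (
    ColocationNetwork,
    CommunityPartition,
    build_original_network,
    connected_components,
    detect_communities,
    extend_network,
    node_degree,
    shared_nodes,
    write_network_tsv,
)
from .report import cluster_report, cluster_report_frame
from .simulate import SimulationConfig, simulate_annotations, simulate_contact_matrix, \
    simulate_fine_contacts, simulate_gwas_tables
from .tad import BorderRegion, EnrichmentTable, tad_enrichment_test
from .targets import TargetPair, rank_long_range_pairs, write_target_pairs_tsv

__all__ = ["PipelineSettings", "PipelineResult", "run_all"]


@dataclass(frozen=True)
class PipelineSettings:
    """Analysis-stage thresholds (the generator has its own config)."""

    q: float = 0.99
    d_cut: float = 7.9
    alpha: float = 0.05
    resolution: float = 0.1
    reps: int = 100
    flank: int = 100
    top_k: int = 30
    min_distance: int = 2
    star_extension: bool = False
    sided: str = "greater"


@dataclass
class DatasetResult:
    """Per-GWAS-dataset network results."""

    name: str
    sig_bins: set[int]
    original: ColocationNetwork
    extended: ColocationNetwork
    partition: CommunityPartition
    degrees: dict[int, int]
    components: list[set[int]]


@dataclass
class PipelineResult:
    config: SimulationConfig
    settings: PipelineSettings
    thresholds: ThresholdSet
    datasets: dict[str, DatasetResult]
    shared_original: tuple[set[int], float]
    shared_extended: tuple[set[int], float]
    tad: EnrichmentTable
    border_regions: list[BorderRegion]
    target_pairs: dict[str, list[TargetPair]]
    snps: dict[str, pd.DataFrame] = field(default_factory=dict)


def _noncoding_bins(snps: pd.DataFrame, fine_layout) -> dict[str, list]:
    """Fine bins harboring non-coding SNPs -> their SNP IDs."""
    nc = snps[~snps["coding"]]
    nc = assign_bins(nc, fine_layout)
    return {
        int(b): list(ids) for b, ids in nc.groupby("bin")["id"].agg(list).items()
    }


def run_all(
    config: SimulationConfig | None = None,
    settings: PipelineSettings | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on generated inputs; optionally write reports.

    When ``outdir`` is given, writes networks, partitions, enrichment
    tables, target pairs, cluster reports and a run manifest as TSV/JSON.
    """
    config = config or SimulationConfig()
    settings = settings or PipelineSettings()

    layout = config.layout()
    fine_layout = config.fine_layout()
    contacts = simulate_contact_matrix(layout, config)
    fine_contacts = simulate_fine_contacts(fine_layout, config)
    borders, genes = simulate_annotations(layout, config)
    syn, dgrp = simulate_gwas_tables(layout, config)

    # --- score, filter, bin
    syn = combine_duplicate_snps(syn)
    syn = add_d_scores(syn)
    syn = classify_coding(syn, genes)
    syn = assign_bins(syn, layout)
    dgrp = classify_coding(dgrp, genes)
    dgrp = assign_bins(dgrp, layout)

    policies = {
        "synthetic": SignificancePolicy(mode="d_threshold", d_cut=settings.d_cut),
        "dgrp": SignificancePolicy(
            mode="bonferroni", alpha=settings.alpha, m=layout.n_bins
        ),
    }
    tables = {"synthetic": syn, "dgrp": dgrp}

    thresholds = compute_thresholds(contacts, q=settings.q)
    datasets: dict[str, DatasetResult] = {}
    partitions: dict[str, CommunityPartition] = {}
    for name, table in tables.items():
        sig = select_significant(table, policies[name])
        sig_bins = set(int(b) for b in sig["bin"].unique())
        original = build_original_network(sig_bins, contacts, thresholds, dataset=name)
        extended = extend_network(
            original, contacts, thresholds, star_extension=settings.star_extension
        )
        partition = detect_communities(
            extended, resolution=settings.resolution, seed=config.seed
        )
        datasets[name] = DatasetResult(
            name=name,
            sig_bins=sig_bins,
            original=original,
            extended=extended,
            partition=partition,
            degrees=node_degree(extended),
            components=connected_components(extended),
        )
        partitions[name] = partition

    shared_orig = shared_nodes(datasets["synthetic"].original, datasets["dgrp"].original)
    shared_ext = shared_nodes(datasets["synthetic"].extended, datasets["dgrp"].extended)

    # --- TAD border enrichment (p-value dataset, per the border analysis)
    tad_result, border_regions = tad_enrichment_test(
        dgrp[~dgrp["coding"]],
        borders,
        layout,
        reps=settings.reps,
        seed=config.seed,
        flank=settings.flank,
        sided=settings.sided,
    )

    # --- long-range targets at fine resolution
    target_pairs = {}
    for name, table in tables.items():
        seeds = _noncoding_bins(table, fine_layout)
        target_pairs[name] = rank_long_range_pairs(
            seeds,
            fine_contacts,
            min_distance=settings.min_distance,
            top_k=settings.top_k,
            genes=genes,
        )

    result = PipelineResult(
        config=config,
        settings=settings,
        thresholds=thresholds,
        datasets=datasets,
        shared_original=shared_orig,
        shared_extended=shared_ext,
        tad=tad_result,
        border_regions=border_regions,
        target_pairs=target_pairs,
        snps=tables,
    )
    if outdir is not None:
        _write_outputs(result, genes, Path(outdir))
    return result


def _config_hash(config: SimulationConfig, settings: PipelineSettings) -> str:
    blob = json.dumps([asdict(config), asdict(settings)], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_outputs(result: PipelineResult, genes: pd.DataFrame, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    layout = result.config.layout()

    for name, ds in result.datasets.items():
        write_network_tsv(ds.original, out / f"network_original_{name}.tsv")
        write_network_tsv(ds.extended, out / f"network_extended_{name}.tsv")
        pd.DataFrame(
            sorted(ds.partition.membership.items()), columns=["bin", "community"]
        ).to_csv(out / f"communities_{name}.tsv", sep="\t", index=False)
        reports = cluster_report(ds.partition, ds.extended, genes, snps=result.snps[name])
        cluster_report_frame(reports).to_csv(
            out / f"cluster_report_{name}.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        write_target_pairs_tsv(
            result.target_pairs[name],
            result.config.fine_layout(),
            out / f"target_pairs_{name}.tsv",
        )

    t = result.tad
    pd.DataFrame(
        [
            {
                "obs_in": t.obs_in,
                "obs_total": t.obs_total,
                "ctrl_in": t.ctrl_in,
                "ctrl_total": t.ctrl_total,
                "odds_ratio": t.odds_ratio,
                "pvalue": t.pvalue,
                "sided": t.sided,
                "borders_hit": sum(1 for r in result.border_regions if r.mutated),
                "n_borders": len(result.border_regions),
            }
        ]
    ).to_csv(out / "tad_enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    summary = {
        "version": __version__,
        "seed": result.config.seed,
        "config_hash": _config_hash(result.config, result.settings),
        "thresholds": {
            "intra": result.thresholds.intra,
            "inter": result.thresholds.inter,
            "q": result.thresholds.q,
        },
        "datasets": {
            name: {
                "sig_bins": len(ds.sig_bins),
                "original_nodes": ds.original.n_nodes,
                "original_edges": ds.original.n_edges,
                "extended_nodes": ds.extended.n_nodes,
                "extended_edges": ds.extended.n_edges,
                "components": len(ds.components),
                "communities": ds.partition.n_communities,
                "modularity": ds.partition.modularity,
                "max_degree": max(ds.degrees.values(), default=0),
            }
            for name, ds in result.datasets.items()
        },
        "shared_original_nodes": len(result.shared_original[0]),
        "shared_original_span_mb": result.shared_original[1],
        "shared_extended_nodes": len(result.shared_extended[0]),
        "shared_extended_span_mb": result.shared_extended[1],
        "tad_pvalue": result.tad.pvalue,
        "genome_bins": layout.n_bins,
    }
    (out / "manifest.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
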
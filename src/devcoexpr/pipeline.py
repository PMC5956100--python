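"""End-to-end orchestration: counts -> DE -> SDR -> network -> modules -> calls.

``run_pipeline`` executes every stage in order, writes all intermediates
under an output directory, and returns a manifest recording the config
snapshot, input digests, per-stage counts, the selected cutoff and its
R^2, and the seed — enough to reproduce the run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .enrichment import enrich_modules
from .expression import (
    compute_sdr,
    consecutive_stage_de,
    normalize_log2_cpm,
    pca_scores,
    stage_mean_sdr,
)
from .io import get_logger, write_config, write_count_matrix, write_network, \
    write_sample_metadata
from .mcl import MCLParams, filter_modules, mcl_cluster
from .network import (
    average_degree,
    build_network,
    connected_components,
    pairwise_pcc,
    pcc_pvalues,
    scan_cutoffs,
)
from .simulate import SimConfig, simulate_dataset, write_ground_truth
from .stages import SpecificityRule, annotate_gene_list, classify_stage_specific
from .types import CountMatrix, GeneSetCollection, RunConfig, SampleMetadata

log = get_logger("devcoexpr.pipeline")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    counts: CountMatrix | None = None,
    meta: SampleMetadata | None = None,
    sim_config: SimConfig | None = None,
    gene_sets: GeneSetCollection | None = None,
    gene_list: list[str] | None = None,
    input_digests: dict[str, str] | None = None,
) -> dict:
    """Run every stage; returns the manifest (also written as JSON).

    Provide either ``counts`` + ``meta`` (a real dataset) or ``sim_config``
    (a simulation request).  ``gene_sets`` enables module enrichment;
    ``gene_list`` (e.g. an SSTF catalogue) restricts the exported
    stage-specificity calls alongside the full call table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": dict(input_digests or {}),
        "counts": {},
    }

    if sim_config is not None:
        log.info("simulating dataset (seed %d)", sim_config.seed)
        counts, meta, truth = simulate_dataset(sim_config)
        write_count_matrix(counts, outdir / "counts.tsv")
        write_sample_metadata(meta, outdir / "samples.tsv")
        write_ground_truth(truth, outdir / "ground_truth.tsv")
    elif counts is None or meta is None:
        raise ValueError("provide counts+meta or a sim_config")

    missing = [s for s in meta.sample_ids if s not in counts.sample_ids]
    if missing:
        raise ValueError(f"metadata sample {missing[0]!r} not in count matrix")
    manifest["counts"]["n_genes"] = counts.shape[0]
    manifest["counts"]["n_samples"] = len(meta.sample_ids)
    manifest["counts"]["n_stages"] = len(meta.stage_order)

    norm = normalize_log2_cpm(counts, config.pseudocount)
    norm = norm[meta.sample_ids]
    norm.to_csv(outdir / "log2cpm.tsv", sep="\t", index_label="gene")

    n_pcs = min(5, min(norm.shape))
    scores, varfrac = pca_scores(norm, n_pcs)
    scores.assign(stage=[meta.stage_of[s] for s in scores.index]).to_csv(
        outdir / "pca_scores.tsv", sep="\t", index_label="sample"
    )
    manifest["pca_variance_fractions"] = [float(v) for v in varfrac]

    de = consecutive_stage_de(norm, meta, config.de_fc_min, config.de_q_max)
    for (a, b), table in de.tables.items():
        table.to_csv(outdir / f"de_{a}_vs_{b}.tsv", sep="\t", index_label="gene")
    (outdir / "de_genes.txt").write_text("".join(g + "\n" for g in de.de_genes))
    manifest["counts"]["n_de_genes"] = len(de.de_genes)
    log.info("%d DE genes across consecutive stage pairs", len(de.de_genes))

    sdr = compute_sdr(norm)
    sdr.to_csv(outdir / "sdr.tsv", sep="\t", index_label="gene")
    profile = stage_mean_sdr(sdr, meta)
    profile.to_csv(outdir / "sdr_stage_means.tsv", sep="\t", index_label="gene")

    rule = SpecificityRule(
        config.single_stage_min,
        config.single_stage_margin,
        config.dual_stage_min,
        config.dual_mean_min,
        config.dual_margin,
    )
    calls = classify_stage_specific(profile.loc[de.de_genes], rule, meta.stage_order)
    call_table = profile.loc[de.de_genes].copy()
    call_table.insert(0, "stage_label", calls)
    call_table.to_csv(outdir / "stage_calls.tsv", sep="\t", index_label="gene")
    if gene_list is not None:
        annotate_gene_list(calls, gene_list).to_frame().to_csv(
            outdir / "stage_calls_filtered.tsv", sep="\t", index_label="gene"
        )
    manifest["counts"]["n_stage_called"] = int((calls != "").sum())

    if len(de.de_genes) < 2:
        log.warning("fewer than 2 DE genes; network stages skipped")
        manifest["network"] = {"n_nodes": 0, "n_edges": 0}
        _finish(manifest, config, outdir)
        return manifest

    table = pcc_pvalues(pairwise_pcc(norm, de.de_genes))
    scan = scan_cutoffs(table, config.scan_grid, config.scale_free_r2)
    scan.rows.to_csv(outdir / "threshold_scan.tsv", sep="\t", index=False)
    manifest["scan"] = {
        "selected_cutoff": scan.selected_cutoff,
        "qualified": scan.qualified,
        "r2": _scan_r2(scan),
    }

    network = build_network(table, scan.selected_cutoff)
    write_network(network, outdir / "network_edges.tsv", "edgelist")
    write_network(network, outdir / "network.graphml", "graphml")
    manifest["network"] = {
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
    }
    if network.number_of_nodes():
        _, giant = connected_components(network)
        manifest["network"]["giant_component_fraction"] = giant
        manifest["network"]["average_degree"] = average_degree(network)
    else:
        log.warning("empty network at cutoff %g", scan.selected_cutoff)
        _finish(manifest, config, outdir)
        return manifest

    params = MCLParams(
        expansion=config.mcl_expansion,
        inflation=config.mcl_inflation,
        prune=config.mcl_prune,
        max_iterations=config.mcl_max_iterations,
        tolerance=config.mcl_tolerance,
        self_loop=config.mcl_self_loop,
    )
    assignment = filter_modules(mcl_cluster(network, params), config.module_min_size)
    pd.DataFrame(
        {
            "gene": sorted(assignment.cluster_of),
            "cluster": [assignment.cluster_of[g] for g in sorted(assignment.cluster_of)],
            "retained": [
                assignment.cluster_of[g] in assignment.retained
                for g in sorted(assignment.cluster_of)
            ],
        }
    ).to_csv(outdir / "modules.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(
            ({"cluster": c, "size": len(assignment.clusters[c])} for c in assignment.retained),
            key=lambda r: r["cluster"],
        )
    ).to_csv(outdir / "modules_retained.tsv", sep="\t", index=False)
    manifest["modules"] = {
        "n_clusters": len(assignment.clusters),
        "n_retained": len(assignment.retained),
        "converged": assignment.converged,
    }

    if gene_sets is not None and assignment.retained:
        result = enrich_modules(assignment, gene_sets, de.de_genes)
        result.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        manifest["counts"]["n_enrichment_tests"] = len(result)

    _finish(manifest, config, outdir)
    return manifest


def _scan_r2(scan) -> float | None:
    row = scan.rows[scan.rows.cutoff == scan.selected_cutoff]
    if len(row) and pd.notna(row.iloc[0].r2):
        return float(row.iloc[0].r2)
    return None


def _finish(manifest: dict, config: RunConfig, outdir: Path) -> None:
    write_config(config, outdir / "config.yaml")
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
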
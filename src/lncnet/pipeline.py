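"""Config-driven orchestration of the full pipeline.

Stages run in the study's order — differential expression, positional
classification, pathway enrichment (+ pathway-act network), co-expression
networks (general and pathway-seeded sub-network), qPCR quantification —
each writing its tables under the output directory.  A manifest records the
seed, parameters, SHA-256 checksums and per-stage row counts; re-running
with the same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import classify, de, enrich, io, network, qpcr
from .datatypes import ConfigError, ExpressionMatrix, InputError, LNCRNA, MRNA
from .simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
    simulate_pathways,
    simulate_qpcr,
)

logger = logging.getLogger(__name__)


def demo_simulation(seed: int = 42) -> SimulationConfig:
    """The default synthetic study: 11 vs 5 samples, planted DE genes at
    |log2FC| = 4, three hub lncRNAs plus satellite pairs at PCC 0.95, the
    six-category annotation mix, the standard pathway fixture and four qPCR
    validation targets."""
    edges = []
    for h, hub in enumerate(("LNC0000", "LNC0001", "LNC0010")):
        for j in range(5):
            edges.append((hub, f"MRNA{h * 5 + j:04d}", 0.95))
    for j in range(5):
        edges.append((f"LNC{11 + j:04d}", f"MRNA{20 + j:04d}", 0.95))
    return SimulationConfig(
        seed=seed,
        planted_edges=tuple(edges),
        qpcr_targets=(
            ("LNC0000", 4.0),
            ("LNC0010", 0.25),
            ("MRNA0000", 4.0),
            ("MRNA0100", 1.0),
        ),
    )


@dataclass
class PipelineConfig:
    """Inputs (file paths or a simulation block) plus stage parameters."""

    outdir: str = "lncnet_out"
    seed: int = 42
    simulation: SimulationConfig | None = None
    matrix_path: str | None = None
    sheet_path: str | None = None
    biotype_path: str | None = None
    gtf_path: str | None = None
    gmt_path: str | None = None
    ct_path: str | None = None
    thresholds: de.DEThresholds = field(default_factory=de.DEThresholds)
    general_min_abs_pcc: float = 0.90
    general_max_p: float = 1.0
    sub_min_abs_pcc: float = 0.80
    sub_max_p: float = 0.001
    cohort: str = "tumor"
    neg_log10_cut: float = 1.3
    top_k: int = 20
    min_shared: int = 5
    promoter_window: int = 1000
    qpcr_reference: str = "GAPDH"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_paths = self.matrix_path is not None
        if self.simulation is None and not has_paths:
            # no inputs at all -> demo simulation
            self.simulation = demo_simulation(self.seed)
        if self.simulation is not None and has_paths:
            raise ConfigError("give either input paths or a simulation block, not both")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim = raw.pop("simulation", None)
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if thr is not None:
            cfg.thresholds = de.DEThresholds(**thr)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Collect all fatal inconsistencies across the inputs (empty = OK)."""
    issues: list[str] = []
    if config.simulation is not None:
        try:
            config.simulation.validate()
        except ConfigError as exc:
            issues.append(f"simulation: {exc}")
        return issues
    try:
        matrix = io.read_matrix(
            config.matrix_path, config.sheet_path, config.biotype_path
        )
    except Exception as exc:
        issues.append(f"matrix: {exc}")
        return issues
    if config.gtf_path:
        try:
            io.read_gtf(config.gtf_path)
        except Exception as exc:
            issues.append(f"gtf: {exc}")
    if config.gmt_path:
        try:
            sets = io.read_gmt(config.gmt_path)
            universe = set(matrix.gene_ids)
            all_members = set().union(*(s.members for s in sets))
            frac = len(all_members & universe) / max(1, len(all_members))
            if frac == 0:
                issues.append("gmt: no gene-set member overlaps the matrix")
            elif frac < 0.5:
                logger.warning("gmt: only %.0f%% of set members in matrix", 100 * frac)
        except Exception as exc:
            issues.append(f"gmt: {exc}")
    if config.ct_path:
        try:
            ct = io.read_ct_table(config.ct_path)
            if config.qpcr_reference not in set(ct["gene_id"]):
                issues.append(f"ct: reference gene {config.qpcr_reference!r} missing")
        except Exception as exc:
            issues.append(f"ct: {exc}")
    return issues


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if not isinstance(v, dict) or k == "thresholds"
        },
        "stages": {},
        "files": {},
    }
    written: list[Path] = []

    def emit(df, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    issues = validate_inputs(config)
    if issues:
        raise InputError("input validation failed: " + "; ".join(issues))

    # ---- stage: inputs ---------------------------------------------------
    try:
        if config.simulation is not None:
            sim = config.simulation
            matrix, truth = simulate_expression(sim)
            genes, labels = simulate_annotation(sim)
            truth.category_labels = labels
            gene_sets = simulate_pathways(sim, truth)
            ct = simulate_qpcr(sim) if sim.qpcr_targets else None
            truth.qpcr_fold_changes = {g: fc for g, fc in sim.qpcr_targets}
            io.write_matrix(
                matrix, outdir / "matrix.tsv", outdir / "samples.tsv",
                outdir / "biotypes.tsv",
            )
            io.write_gtf(genes, outdir / "annotation.gtf")
            io.write_gmt(gene_sets, outdir / "pathways.gmt")
            if ct is not None:
                io.write_ct_table(ct, outdir / "ct_table.tsv")
            io.write_truth(truth, outdir / "truth.json")
            written += [
                outdir / n
                for n in (
                    "matrix.tsv", "samples.tsv", "biotypes.tsv",
                    "annotation.gtf", "pathways.gmt", "truth.json",
                )
            ]
            if ct is not None:
                written.append(outdir / "ct_table.tsv")
        else:
            matrix = io.read_matrix(
                config.matrix_path, config.sheet_path, config.biotype_path
            )
            genes = io.read_gtf(config.gtf_path) if config.gtf_path else []
            gene_sets = io.read_gmt(config.gmt_path) if config.gmt_path else []
            ct = io.read_ct_table(config.ct_path) if config.ct_path else None
        manifest["stages"]["inputs"] = {"n_genes": len(matrix.gene_ids),
                                        "n_samples": len(matrix.sample_ids)}
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    # ---- stage: differential expression ---------------------------------
    try:
        records = de.run_de(matrix, config.thresholds)
        emit(records, "de_table.tsv")
        summary = de.summarize_counts(records)
        emit(summary, "de_summary.tsv")
        tables = de.export_plot_tables(records, matrix, config.thresholds.pseudocount)
        emit(tables["volcano"], "volcano.tsv")
        emit(tables["scatter"], "scatter.tsv")
        n_sig = int(records["significant"].sum())
        if n_sig >= 2:
            gene_order, sample_order = de.cluster_order(
                matrix, records, config.thresholds.pseudocount
            )
            (outdir / "cluster_order.json").write_text(
                json.dumps({"genes": gene_order, "samples": sample_order}, indent=1)
            )
            written.append(outdir / "cluster_order.json")
        manifest["stages"]["de"] = {"n_significant": n_sig}
    except Exception as exc:
        raise RuntimeError(f"stage 'de' failed: {exc}") from exc

    sig = records[records["significant"]]
    de_lnc = set(sig.loc[sig["biotype"] == LNCRNA, "gene_id"])
    de_mrna = set(sig.loc[sig["biotype"] == MRNA, "gene_id"])
    direction = dict(zip(sig["gene_id"], sig["direction"]))

    # ---- stage: classification ------------------------------------------
    try:
        if genes:
            lncs = [g for g in genes if g.biotype == "lncRNA"]
            coding = [g for g in genes if g.biotype == "coding"]
            de_lnc_models = [g for g in lncs if g.gene_id in de_lnc]
            labels_out = classify.classify_all(
                de_lnc_models or lncs, coding, config.promoter_window
            )
            emit(classify.tabulate_categories(labels_out, direction), "categories.tsv")
            emit(
                classify.chromosome_distribution(genes, direction),
                "chromosome_distribution.tsv",
            )
            manifest["stages"]["classify"] = {"n_lncrna": len(labels_out)}
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    # ---- stage: enrichment ----------------------------------------------
    try:
        if gene_sets:
            universe = set(matrix.genes_of(MRNA))
            results = enrich.fisher_enrichment(
                de_mrna & universe, gene_sets, universe, de_records=records
            )
            emit(results, "enrichment.tsv")
            significant_sets = enrich.significance_filter(
                results, config.neg_log10_cut
            )
            emit(significant_sets, "enrichment_significant.tsv")
            act_edges, act_graph = enrich.pathway_act_network(
                results, gene_sets, de_mrna & universe,
                top_k=config.top_k, min_shared=config.min_shared,
            )
            emit(act_edges, "pathway_act_edges.tsv")
            import networkx as nx

            nx.write_graphml(act_graph, outdir / "pathway_act.graphml")
            written.append(outdir / "pathway_act.graphml")
            manifest["stages"]["enrich"] = {
                "n_sets": len(results),
                "n_significant": len(significant_sets),
                "n_act_edges": len(act_edges),
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'enrich' failed: {exc}") from exc

    # ---- stage: networks -------------------------------------------------
    try:
        if de_lnc and de_mrna:
            net = network.build_network(
                matrix, de_lnc, de_mrna,
                min_abs_pcc=config.general_min_abs_pcc,
                max_p=config.general_max_p, cohort=config.cohort,
            )
            network.export_graph(
                net, outdir / "network_edges.tsv", outdir / "network.graphml"
            )
            written += [outdir / "network_edges.tsv", outdir / "network.graphml"]
            emit(network.node_degrees(net, status=direction), "network_degrees.tsv")
            manifest["stages"]["network"] = {
                "n_nodes": net.n_nodes, "n_edges": net.n_edges,
            }
            # sub-network seeded on the top enriched pathway's DE members
            if gene_sets:
                ranked = enrich.significance_filter(results, config.neg_log10_cut)
                if len(ranked):
                    top_set = next(
                        s for s in gene_sets if s.set_id == ranked["set_id"].iloc[0]
                    )
                    seeds = sorted(top_set.members & de_mrna)
                    if seeds:
                        sub, report = network.extract_subnetwork(
                            matrix, de_lnc, seeds,
                            min_abs_pcc=config.sub_min_abs_pcc,
                            max_p=config.sub_max_p, cohort=config.cohort,
                        )
                        network.export_graph(
                            sub, outdir / "subnetwork_edges.tsv",
                            outdir / "subnetwork.graphml",
                        )
                        written += [
                            outdir / "subnetwork_edges.tsv",
                            outdir / "subnetwork.graphml",
                        ]
                        emit(report, "subnetwork_seeds.tsv")
                        emit(
                            network.node_degrees(sub, status=direction),
                            "subnetwork_degrees.tsv",
                        )
                        manifest["stages"]["subnetwork"] = {
                            "seed_set": top_set.set_id,
                            "n_lncrna": len(sub.nodes_of(LNCRNA)),
                            "n_mrna": len(sub.nodes_of(MRNA)),
                            "n_edges": sub.n_edges,
                        }
    except Exception as exc:
        raise RuntimeError(f"stage 'network' failed: {exc}") from exc

    # ---- stage: qPCR -----------------------------------------------------
    try:
        if ct is not None:
            targets = sorted(
                set(ct["gene_id"]) - {config.qpcr_reference}
            )
            rel, summary = qpcr.quantify_all(ct, targets, config.qpcr_reference)
            emit(rel, "qpcr_relative_expression.tsv")
            emit(summary, "qpcr_summary.tsv")
            manifest["stages"]["qpcr"] = {"n_targets": len(targets)}
    except Exception as exc:
        raise RuntimeError(f"stage 'qpcr' failed: {exc}") from exc

    manifest["files"] = {p.name: _sha256(p) for p in sorted(set(written))}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
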
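#!/usr/bin/env python
"""Co-expression networks at both threshold regimes.

Builds the general lncRNA-mRNA network (|PCC| >= 0.90 over the tumor
cohort), ranks hubs by degree, then extracts the pathway-seeded
sub-network (|PCC| >= 0.80, p < 0.001) around the top enriched pathway's
DE coding genes, and reports recovery of the planted edges.
"""

from pathlib import Path

from lncnet import de, enrich, io, network

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "networks"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    inputs = ROOT / "inputs"
    matrix = io.read_matrix(
        inputs / "matrix.tsv", inputs / "samples.tsv", inputs / "biotypes.tsv"
    )
    truth = io.read_truth(inputs / "truth.json")
    sets = io.read_gmt(inputs / "pathways.gmt")
    records = de.run_de(matrix)
    sig = records[records["significant"]]
    de_lnc = set(sig.loc[sig["biotype"] == "lncRNA", "gene_id"])
    de_mrna = set(sig.loc[sig["biotype"] == "mRNA", "gene_id"])
    direction = dict(zip(sig["gene_id"], sig["direction"]))

    net = network.build_network(matrix, de_lnc, de_mrna, min_abs_pcc=0.90)
    network.export_graph(net, OUT / "network_edges.tsv", OUT / "network.graphml")
    degrees = network.node_degrees(net, status=direction)
    degrees.to_csv(OUT / "network_degrees.tsv", sep="\t", index=False)

    planted = {(l, m) for l, m, _ in truth.correlated_pairs}
    got = {(e.lncrna_id, e.mrna_id) for e in net.edges_frame().itertuples(index=False)}
    print(f"general network: {net.n_nodes} nodes, {net.n_edges} edges")
    print(f"planted edges recovered: {len(got & planted)}/{len(planted)}; "
          f"false edges: {len(got - planted)}")
    print("top hubs:")
    print(degrees.head(5).to_string(index=False))

    universe = set(matrix.genes_of("mRNA"))
    results = enrich.fisher_enrichment(de_mrna & universe, sets, universe)
    top_set = next(s for s in sets if s.set_id == results["set_id"].iloc[0])
    seeds = sorted(top_set.members & de_mrna)
    sub, report = network.extract_subnetwork(matrix, de_lnc, seeds)
    network.export_graph(sub, OUT / "subnetwork_edges.tsv", OUT / "subnetwork.graphml")
    report.to_csv(OUT / "subnetwork_seeds.tsv", sep="\t", index=False)
    print(
        f"\nsub-network seeded on {top_set.set_id} ({len(seeds)} seeds): "
        f"{len(sub.nodes_of('lncRNA'))} lncRNAs interacting with "
        f"{len(sub.nodes_of('mRNA'))} mRNAs, {sub.n_edges} connections"
    )


if __name__ == "__main__":
    main()
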
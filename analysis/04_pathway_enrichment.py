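#!/usr/bin/env python
"""Fisher-exact pathway enrichment and the pathway-act network.

Tests every gene set against the DE coding genes, keeps sets with
-log10(p) > 1.3, scores activation by sign consistency, and joins top
pathways sharing more than five DE genes into the act network.
"""

from pathlib import Path

import networkx as nx

from lncnet import de, enrich, io

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "enrichment"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    inputs = ROOT / "inputs"
    matrix = io.read_matrix(
        inputs / "matrix.tsv", inputs / "samples.tsv", inputs / "biotypes.tsv"
    )
    sets = io.read_gmt(inputs / "pathways.gmt")
    records = de.run_de(matrix)
    sig = records[records["significant"]]
    universe = set(matrix.genes_of("mRNA"))
    de_mrna = set(sig.loc[sig["biotype"] == "mRNA", "gene_id"]) & universe

    results = enrich.fisher_enrichment(de_mrna, sets, universe, de_records=records)
    results.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    kept = enrich.significance_filter(results)
    kept.to_csv(OUT / "enrichment_significant.tsv", sep="\t", index=False)
    edges, graph = enrich.pathway_act_network(results, sets, de_mrna)
    edges.to_csv(OUT / "pathway_act_edges.tsv", sep="\t", index=False)
    nx.write_graphml(graph, OUT / "pathway_act.graphml")

    print(results[["set_id", "n_overlap", "p_value", "neg_log10_p"]]
          .head(10).to_string(index=False))
    print(f"\nsignificant at -log10(p) > 1.3: {len(kept)}/{len(results)}")
    print(f"pathway-act edges (shared DE genes > 5): {len(edges)}")


if __name__ == "__main__":
    main()
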
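#!/usr/bin/env python
"""Generate the synthetic study cohort all downstream analyses consume.

11 tumor vs 5 normal samples over 300 mRNAs and 200 lncRNAs; 184 planted
DE genes at |log2FC| = 4; three hub lncRNAs and five satellite pairs
planted at PCC 0.95; gene models covering all six positional categories;
ten pathway sets with controlled DE overlap; a triplicate Ct table for
four validation genes.  Everything is reproducible from SEED.
"""

from pathlib import Path

from lncnet import io
from lncnet.pipeline import demo_simulation
from lncnet.simulate import (
    simulate_annotation,
    simulate_expression,
    simulate_pathways,
    simulate_qpcr,
)

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = demo_simulation(SEED)
    matrix, truth = simulate_expression(cfg)
    genes, labels = simulate_annotation(cfg)
    truth.category_labels = labels
    sets = simulate_pathways(cfg, truth)
    ct = simulate_qpcr(cfg)
    truth.qpcr_fold_changes = dict(cfg.qpcr_targets)

    io.write_matrix(matrix, OUT / "matrix.tsv", OUT / "samples.tsv", OUT / "biotypes.tsv")
    io.write_gtf(genes, OUT / "annotation.gtf")
    io.write_gmt(sets, OUT / "pathways.gmt")
    io.write_ct_table(ct, OUT / "ct_table.tsv")
    io.write_truth(truth, OUT / "truth.json")

    print(f"cohort: {matrix.values.shape[0]} genes x {matrix.values.shape[1]} samples")
    print(f"planted DE genes: {len(truth.de_genes)}")
    print(f"planted correlation edges: {len(truth.correlated_pairs)}")
    print(f"pathway sets: {len(sets)}; qPCR targets: {len(cfg.qpcr_targets)}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
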
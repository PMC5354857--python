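#!/usr/bin/env python
"""Positional classification of the differentially expressed lncRNAs.

Assigns each DE lncRNA one of the six categories (exonic/intronic x
sense/antisense, bidirectional, intergenic), tabulates category
proportions split by regulation direction, and writes the per-chromosome
distribution table.
"""

from pathlib import Path

import pandas as pd

from lncnet import classify, de, io

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "classification"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    inputs = ROOT / "inputs"
    matrix = io.read_matrix(
        inputs / "matrix.tsv", inputs / "samples.tsv", inputs / "biotypes.tsv"
    )
    genes = io.read_gtf(inputs / "annotation.gtf")
    truth = io.read_truth(inputs / "truth.json")

    records = de.run_de(matrix)
    sig = records[records["significant"]]
    de_lnc = set(sig.loc[sig["biotype"] == "lncRNA", "gene_id"])
    direction = dict(zip(sig["gene_id"], sig["direction"]))

    lncs = [g for g in genes if g.biotype == "lncRNA" and g.gene_id in de_lnc]
    coding = [g for g in genes if g.biotype == "coding"]
    labels = classify.classify_all(lncs, coding)

    table = classify.tabulate_categories(labels, direction)
    table.to_csv(OUT / "categories.tsv", sep="\t", index=False)
    chrom = classify.chromosome_distribution(genes, direction)
    chrom.to_csv(OUT / "chromosome_distribution.tsv", sep="\t", index=False)

    agree = sum(labels[g] == truth.category_labels[g] for g in labels)
    print(table.to_string(index=False))
    print(f"\nlabels agreeing with construction: {agree}/{len(labels)}")
    print(f"chromosomes carrying DE lncRNAs: {len(chrom)}")


if __name__ == "__main__":
    main()
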
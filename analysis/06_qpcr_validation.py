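#!/usr/bin/env python
"""2^-ddCt quantification of the simulated qPCR validation panel.

Averages triplicate wells, normalizes to the reference gene, calibrates on
the normal group, and compares groups by Welch's t-test; reports estimated
vs planted fold changes.
"""

from pathlib import Path

from lncnet import io, qpcr

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "qpcr"
REFERENCE = "GAPDH"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    inputs = ROOT / "inputs"
    ct = io.read_ct_table(inputs / "ct_table.tsv")
    truth = io.read_truth(inputs / "truth.json")

    targets = sorted(set(ct["gene_id"]) - {REFERENCE})
    rel, summary = qpcr.quantify_all(ct, targets, REFERENCE)
    rel.to_csv(OUT / "relative_expression.tsv", sep="\t", index=False)
    summary.to_csv(OUT / "group_summary.tsv", sep="\t", index=False)

    summary = summary.set_index("gene_id")
    print(f"{'gene':<10} {'planted':>8} {'estimated':>10} {'p':>10} sig")
    for g in targets:
        row = summary.loc[g]
        print(
            f"{g:<10} {truth.qpcr_fold_changes.get(g, float('nan')):>8.2f} "
            f"{row['mean_tumor']:>10.3f} {row['p_value']:>10.2e} "
            f"{'*' if row['significant'] else ''}"
        )


if __name__ == "__main__":
    main()
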
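"""Six-way positional classification of lncRNAs against coding genes.

Each lncRNA receives exactly one label, decided by precedence:

1. ``exonic_sense``      — >= 1 bp exon overlap with a same-strand coding exon
2. ``intronic_sense``    — span contained in a same-strand coding gene span
                           with no exonic overlap
3. ``exonic_antisense``  — rule 1 on the opposite strand
4. ``intronic_antisense``— rule 2 on the opposite strand
5. ``bidirectional``     — no overlap with any coding span, and the lncRNA
                           TSS within ``promoter_window`` bp of an
                           opposite-strand coding TSS (divergent promoter)
6. ``intergenic``        — otherwise

Precedence makes the label independent of coding-gene iteration order, and
flipping every strand leaves labels unchanged (rules pair up symmetrically).
"""

from __future__ import annotations

import logging
from collections import defaultdict

import pandas as pd

from .datatypes import CATEGORIES, GeneModel, InputError

logger = logging.getLogger(__name__)


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _exonic_overlap(lnc: GeneModel, gene: GeneModel) -> bool:
    return any(
        _intervals_overlap(le, ge) for le in lnc.exons for ge in gene.exons
    )


def _contained(lnc: GeneModel, gene: GeneModel) -> bool:
    return gene.span[0] <= lnc.span[0] and lnc.span[1] <= gene.span[1]


def index_by_chrom(genes: list[GeneModel]) -> dict[str, list[GeneModel]]:
    idx: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        idx[g.chrom].append(g)
    return dict(idx)


def classify_lncrna(
    lnc: GeneModel,
    coding_index: dict[str, list[GeneModel]],
    promoter_window: int = 1000,
) -> str:
    """Assign one of the six positional categories to ``lnc``."""
    if lnc.biotype != "lncRNA":
        raise InputError(f"{lnc.gene_id}: classify_lncrna expects a lncRNA model")
    coding = coding_index.get(lnc.chrom)
    if coding is None:
        logger.info(
            "%s: chromosome %s absent from coding index -> intergenic",
            lnc.gene_id, lnc.chrom,
        )
        return "intergenic"

    same = [g for g in coding if g.strand == lnc.strand]
    anti = [g for g in coding if g.strand != lnc.strand]

    if any(_exonic_overlap(lnc, g) for g in same):
        return "exonic_sense"
    if any(
        _contained(lnc, g) and not _exonic_overlap(lnc, g) for g in same
    ):
        return "intronic_sense"
    if any(_exonic_overlap(lnc, g) for g in anti):
        return "exonic_antisense"
    if any(
        _contained(lnc, g) and not _exonic_overlap(lnc, g) for g in anti
    ):
        return "intronic_antisense"

    overlaps_any_span = any(
        _intervals_overlap(lnc.span, g.span) for g in coding
    )
    if not overlaps_any_span and any(
        abs(lnc.tss - g.tss) <= promoter_window for g in anti
    ):
        return "bidirectional"
    return "intergenic"


def classify_all(
    lncs: list[GeneModel],
    coding: list[GeneModel],
    promoter_window: int = 1000,
) -> dict[str, str]:
    idx = index_by_chrom(coding)
    return {
        l.gene_id: classify_lncrna(l, idx, promoter_window) for l in lncs
    }


def tabulate_categories(
    labels: dict[str, str],
    direction: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Category counts and proportions, optionally split by DE direction.

    Proportions sum to 1 over all labelled lncRNAs; with a direction map,
    per-direction proportions are fractions of the same overall total (so a
    category's up + down proportions add to its overall proportion).
    """
    if not labels:
        raise InputError("tabulate_categories: no labels given")
    total = len(labels)
    rows = []
    for cat in CATEGORIES:
        in_cat = [g for g, c in labels.items() if c == cat]
        row = {
            "category": cat,
            "count": len(in_cat),
            "proportion": len(in_cat) / total,
        }
        if direction is not None:
            for d in ("up", "down"):
                n = sum(1 for g in in_cat if direction.get(g) == d)
                row[f"count_{d}"] = n
                row[f"proportion_{d}"] = n / total
        rows.append(row)
    return pd.DataFrame(rows)


def chromosome_distribution(
    genes: list[GeneModel],
    direction: dict[str, str],
) -> pd.DataFrame:
    """Circos-ready per-chromosome counts of up/down/total DE lncRNAs.

    ``direction`` maps DE lncRNA ids to 'up'/'down'; genes absent from the
    map are ignored.
    """
    counts: dict[str, dict[str, int]] = defaultdict(lambda: {"up": 0, "down": 0})
    by_id = {g.gene_id: g for g in genes}
    for gid, d in direction.items():
        g = by_id.get(gid)
        if g is None or d not in ("up", "down"):
            continue
        counts[g.chrom][d] += 1
    rows = [
        {
            "chrom": chrom,
            "n_up": c["up"],
            "n_down": c["down"],
            "n_total": c["up"] + c["down"],
        }
        for chrom, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "n_up", "n_down", "n_total"])
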
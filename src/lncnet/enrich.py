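"""Fisher-exact gene-set enrichment, activation scoring, pathway-act network.

Enrichment uses the one-sided (greater) Fisher exact test on the 2x2 table
(overlap, DE-only, set-only, neither) against a background universe of all
detected genes; significance keeps sets with -log10(p) strictly above 1.3
(p < 10^-1.3 ~ 0.05), unadjusted.  Pathway activation is a sign-consistency
z-score z = (n_consistent - n_inconsistent) / sqrt(n) over DE members that
carry an expected regulation direction — an explicit stand-in for
commercial causal-analytics scores, labelled as such in the output.  The
pathway-act network joins two of the top-k most significant sets whenever
they share strictly more than ``min_shared`` DE genes.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSet, InputError
from .de import bh_fdr

logger = logging.getLogger(__name__)

ACTIVATION_NOTE = "sign-consistency z-score (stand-in for proprietary causal analytics)"


def fisher_pvalue(n_overlap: int, n_de: int, n_set: int, n_universe: int) -> float:
    """One-sided enrichment p: probability of >= n_overlap white draws in a
    hypergeometric(n_universe, n_set, n_de) experiment."""
    if n_universe <= 0:
        raise InputError("fisher_pvalue: empty universe")
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_set, n_de))


def activation_zscore(
    gene_set: GeneSet, de_records: pd.DataFrame
) -> tuple[float, str]:
    """Sign-consistency activation call for one gene set.

    Over the set's significant DE members with an ``expected_direction``
    annotation: z = (n_consistent - n_inconsistent) / sqrt(n).  Status is
    ``activated`` at z >= 2, ``suppressed`` at z <= -2, else
    ``unpredicted``; with no annotated DE members z is NaN/unpredicted.
    """
    if gene_set.expected_direction is None:
        return float("nan"), "unpredicted"
    sig = de_records[de_records["significant"]]
    observed = dict(zip(sig["gene_id"], sig["direction"]))
    n_c = n_i = 0
    for g, expected in gene_set.expected_direction.items():
        got = observed.get(g)
        if got in ("up", "down"):
            if got == expected:
                n_c += 1
            else:
                n_i += 1
    n = n_c + n_i
    if n == 0:
        return float("nan"), "unpredicted"
    z = (n_c - n_i) / np.sqrt(n)
    status = "activated" if z >= 2 else "suppressed" if z <= -2 else "unpredicted"
    return float(z), status


def fisher_enrichment(
    de_genes: set[str] | list[str],
    sets: list[GeneSet],
    universe: set[str] | list[str],
    de_records: pd.DataFrame | None = None,
    two_sided: bool = False,
    adjust_p: bool = False,
) -> pd.DataFrame:
    """Per-set enrichment table, sorted by p (ties by set id).

    Set members are intersected with the universe before testing; sets with
    an empty intersection are skipped with a warning.  ``de_records``
    enables the activation z-score columns.  ``adjust_p`` adds a BH column
    (off by default: the filtering rule is on raw p).
    """
    universe = set(universe)
    if not universe:
        raise InputError("fisher_enrichment: empty universe")
    de = set(de_genes) & universe
    if set(de_genes) - universe:
        raise InputError("fisher_enrichment: de_genes must be a subset of universe")
    rows = []
    for s in sets:
        members = s.members & universe
        if not members:
            logger.warning("fisher_enrichment: set %s has no genes in universe", s.set_id)
            continue
        k = len(members & de)
        if two_sided:
            table = [
                [k, len(de) - k],
                [len(members) - k, len(universe) - len(de) - len(members) + k],
            ]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            p = fisher_pvalue(k, len(de), len(members), len(universe))
        row = {
            "set_id": s.set_id,
            "n_universe": len(universe),
            "n_set": len(members),
            "n_de": len(de),
            "n_overlap": k,
            "p_value": p,
            "neg_log10_p": float(-np.log10(p)) if p > 0 else np.inf,
        }
        if de_records is not None:
            z, status = activation_zscore(s, de_records)
            row["z_score"] = z
            row["status"] = status
            row["z_score_method"] = ACTIVATION_NOTE
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if adjust_p:
        df["fdr"] = bh_fdr(df["p_value"].values)
    return df.sort_values(["p_value", "set_id"], ignore_index=True)


def significance_filter(
    results: pd.DataFrame, neg_log10_cut: float = 1.3
) -> pd.DataFrame:
    """Keep sets with -log10(p) strictly above the cut (default 1.3)."""
    return results[results["neg_log10_p"] > neg_log10_cut].reset_index(drop=True)


def pathway_act_network(
    results: pd.DataFrame,
    sets: list[GeneSet],
    de_genes: set[str] | list[str],
    top_k: int = 20,
    min_shared: int = 5,
) -> tuple[pd.DataFrame, nx.Graph]:
    """Shared-DE-gene graph over the top-k most significant sets.

    An edge joins two sets iff they share strictly more than ``min_shared``
    DE genes.  Node attributes carry the activation status when present.
    Returns the edge table and the graph (isolated top-k sets stay as
    nodes so status coloring covers every plotted pathway).
    """
    de = set(de_genes)
    ranked = results.sort_values(["p_value", "set_id"]).head(top_k)
    by_id = {s.set_id: s for s in sets}
    chosen = [sid for sid in ranked["set_id"] if sid in by_id]
    g = nx.Graph()
    for _, row in ranked.iterrows():
        attrs = {"p_value": float(row["p_value"])}
        if "status" in row and isinstance(row["status"], str):
            attrs["status"] = row["status"]
        g.add_node(row["set_id"], **attrs)
    rows = []
    for i, a in enumerate(chosen):
        for b in chosen[i + 1:]:
            shared = len(by_id[a].members & by_id[b].members & de)
            if shared > min_shared:
                x, y = sorted((a, b))
                rows.append({"set_id_a": x, "set_id_b": y, "n_shared_de": shared})
                g.add_edge(x, y, n_shared_de=shared)
    edges = pd.DataFrame(rows, columns=["set_id_a", "set_id_b", "n_shared_de"])
    return edges.sort_values(["set_id_a", "set_id_b"], ignore_index=True), g
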
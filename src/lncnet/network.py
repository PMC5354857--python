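"""Pearson lncRNA-mRNA co-expression networks, degrees and sub-networks.

Two threshold regimes are used: the general network at |PCC| >= 0.90 (no p
cut-off) and pathway-seeded sub-networks at |PCC| >= 0.80 with p < 0.001.
Correlation magnitude is thresholded and the sign kept as an edge
attribute, since both positively and negatively correlated pairs are
linked.  Correlations are computed across the tumor cohort by default, on
log2(value + pseudocount); p-values come from the t transform
t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom and are left
unadjusted (an optional BH mode exists).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    LNCRNA,
    MRNA,
    TUMOR,
    CoexpressionNetwork,
    ExpressionMatrix,
    InputError,
)
from .de import bh_fdr

logger = logging.getLogger(__name__)


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("pearson_correlation: vectors must share one shape")
    if x.size < 3:
        raise InputError("pearson_correlation: need n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise InputError("pearson_correlation: constant vector")
    return float((xc @ yc) / denom)


def correlation_pvalue(pcc: float, n: int) -> float:
    """Two-sided p for a Pearson r via the t transform on n-2 df."""
    if n < 3:
        raise InputError("correlation_pvalue: need n >= 3")
    if not -1.0 <= pcc <= 1.0:
        raise InputError("correlation_pvalue: |pcc| must be <= 1")
    if abs(pcc) == 1.0:
        return 0.0
    t = pcc * np.sqrt(n - 2) / np.sqrt(1.0 - pcc * pcc)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _cohort_samples(matrix: ExpressionMatrix, cohort: str) -> list[str]:
    if cohort == "all":
        return list(matrix.sample_ids)
    return matrix.samples_in(cohort)


def build_network(
    matrix: ExpressionMatrix,
    de_lnc: set[str] | list[str],
    de_mrna: set[str] | list[str],
    min_abs_pcc: float = 0.90,
    max_p: float = 1.0,
    cohort: str = TUMOR,
    log2: bool = True,
    pseudocount: float = 0.25,
    adjust_p: bool = False,
) -> CoexpressionNetwork:
    """All-pairs bipartite network over DE lncRNAs x DE mRNAs.

    An edge is kept iff |r| >= min_abs_pcc and p < max_p; nodes are exactly
    the endpoints of retained edges.  Constant-expression genes are dropped
    before correlation with a logged count.  ``adjust_p`` switches the p
    cut-off to BH-adjusted values.
    """
    lnc = sorted(set(de_lnc))
    mrna = sorted(set(de_mrna))
    if not lnc or not mrna:
        raise InputError("build_network: empty lncRNA or mRNA gene set")
    missing = (set(lnc) | set(mrna)) - set(matrix.gene_ids)
    if missing:
        raise InputError(f"build_network: genes absent from matrix: {sorted(missing)[:5]}")
    samples = _cohort_samples(matrix, cohort)
    n = len(samples)
    if n < 3:
        raise InputError(f"build_network: cohort {cohort!r} has < 3 samples")

    data = matrix.values.loc[lnc + mrna, samples].to_numpy(float)
    if log2:
        data = np.log2(data + pseudocount)
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    if constant.any():
        dropped = [g for g, c in zip(lnc + mrna, constant) if c]
        logger.warning(
            "build_network: dropping %d constant genes: %s%s",
            len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
        )
    keep = ~constant
    ids = np.array(lnc + mrna)[keep]
    z = centered[keep] / np.where(norms[keep] == 0, 1, norms[keep])[:, None]
    is_lnc = np.array([g in set(lnc) for g in ids])
    zl, zm = z[is_lnc], z[~is_lnc]
    lnc_ids, mrna_ids = ids[is_lnc], ids[~is_lnc]

    r = np.clip(zl @ zm.T, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = np.where(np.abs(r) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    if adjust_p:
        p = bh_fdr(p.ravel()).reshape(p.shape)

    graph = nx.Graph()
    li, mi = np.where((np.abs(r) >= min_abs_pcc) & (p < max_p))
    for i, j in zip(li, mi):
        l, m = str(lnc_ids[i]), str(mrna_ids[j])
        graph.add_node(l, biotype=LNCRNA)
        graph.add_node(m, biotype=MRNA)
        graph.add_edge(
            l, m,
            pcc=float(r[i, j]),
            p_value=float(p[i, j]),
            sign="positive" if r[i, j] > 0 else "negative",
        )
    return CoexpressionNetwork(graph=graph, min_abs_pcc=min_abs_pcc, max_p=max_p)


def node_degrees(
    net: CoexpressionNetwork,
    status: dict[str, str] | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Per-node degree table ranked by degree descending, ties broken by id."""
    rows = [
        {
            "gene_id": node,
            "biotype": data["biotype"],
            "degree": net.graph.degree(node),
            "status": (status or {}).get(node, ""),
        }
        for node, data in net.graph.nodes(data=True)
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "biotype", "degree", "status"])
    df = df.sort_values(
        ["degree", "gene_id"], ascending=[False, True], ignore_index=True
    )
    return df.head(top_k) if top_k is not None else df


def extract_subnetwork(
    matrix: ExpressionMatrix,
    de_lnc: set[str] | list[str],
    seed_mrnas: set[str] | list[str],
    min_abs_pcc: float = 0.80,
    max_p: float = 0.001,
    **kwargs,
) -> tuple[CoexpressionNetwork, pd.DataFrame]:
    """Sub-network seeded on key coding genes (e.g. one pathway's members).

    Builds the network at the sub-network thresholds restricted to edges
    incident to the seeds, and reports per-seed retention (seeds with no
    supra-threshold partner are excluded from the node set but listed in
    the report).
    """
    seeds = sorted(set(seed_mrnas))
    if not seeds:
        raise InputError("extract_subnetwork: empty seed set")
    net = build_network(
        matrix, de_lnc, seeds, min_abs_pcc=min_abs_pcc, max_p=max_p, **kwargs
    )
    report = pd.DataFrame(
        {
            "seed_mrna": seeds,
            "n_partners": [
                net.graph.degree(s) if s in net.graph else 0 for s in seeds
            ],
        }
    )
    return net, report


def export_graph(net: CoexpressionNetwork, edge_tsv, graphml_path) -> None:
    """Write the TSV edge list and a GraphML with biotype/degree attributes."""
    net.edges_frame().to_csv(edge_tsv, sep="\t", index=False)
    g = net.graph.copy()
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
    try:
        nx.write_graphml(g, graphml_path)
    except OSError as exc:  # pragma: no cover - I/O context
        raise OSError(f"failed writing GraphML to {graphml_path}: {exc}") from exc


def read_graphml(path, min_abs_pcc: float, max_p: float) -> CoexpressionNetwork:
    g = nx.read_graphml(path)
    return CoexpressionNetwork(
        graph=nx.Graph(g), min_abs_pcc=min_abs_pcc, max_p=max_p
    )
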
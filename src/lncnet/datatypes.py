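"""Core in-memory containers shared across the pipeline stages.

Expression values live in a genes x samples :class:`pandas.DataFrame`
(FPKM-like, non-negative).  Gene structures are stranded, exon-resolved
models in 0-based half-open coordinates (GTF's 1-based inclusive intervals
are converted on read).  Networks wrap a :class:`networkx.Graph`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

MRNA = "mRNA"
LNCRNA = "lncRNA"
BIOTYPES = (MRNA, LNCRNA)

TUMOR = "tumor"
NORMAL = "normal"
GROUPS = (TUMOR, NORMAL)

#: the closed six-way positional vocabulary for lncRNAs
CATEGORIES = (
    "exonic_sense",
    "intronic_sense",
    "exonic_antisense",
    "intronic_antisense",
    "bidirectional",
    "intergenic",
)


class InputError(ValueError):
    """Malformed or inconsistent pipeline input."""


class ConfigError(ValueError):
    """Invalid configuration value; the message names the offending field."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with group labels and per-gene biotypes.

    Parameters
    ----------
    values
        Non-negative expression values, index = gene ids, columns = sample ids.
    biotype
        Per-gene label, ``"mRNA"`` or ``"lncRNA"``, indexed like ``values``.
    groups
        Per-sample label, ``"tumor"`` or ``"normal"``, indexed by sample id.
    """

    values: pd.DataFrame
    biotype: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise InputError("duplicate gene ids in expression matrix")
        if v.columns.duplicated().any():
            raise InputError("duplicate sample ids in expression matrix")
        if (v.values < 0).any():
            raise InputError("negative expression values")
        self.biotype = self.biotype.reindex(v.index)
        if self.biotype.isna().any():
            raise InputError("missing biotype for some genes")
        bad = set(self.biotype.unique()) - set(BIOTYPES)
        if bad:
            raise InputError(f"unknown biotypes: {sorted(bad)}")
        self.groups = self.groups.reindex(v.columns)
        if self.groups.isna().any():
            raise InputError("missing group label for some samples")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise InputError(f"unknown sample groups: {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def genes_of(self, biotype: str) -> list[str]:
        return list(self.biotype.index[self.biotype == biotype])

    def log2(self, pseudocount: float = 0.25) -> pd.DataFrame:
        """log2(value + pseudocount); the scale tests and correlations use."""
        return np.log2(self.values + pseudocount)


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene structure (union of exons over isoforms).

    ``span`` and ``exons`` are 0-based half-open intervals; exons are sorted,
    disjoint, and contained in the span.
    """

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    exons: tuple[tuple[int, int], ...]
    biotype: str  # "coding" | "lncRNA"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"{self.gene_id}: strand must be '+' or '-'")
        s, e = self.span
        if not s < e:
            raise InputError(f"{self.gene_id}: empty span")
        prev = s - 1
        for (a, b) in self.exons:
            if not (s <= a < b <= e):
                raise InputError(f"{self.gene_id}: exon outside span")
            if a < prev:
                raise InputError(f"{self.gene_id}: exons unsorted or overlapping")
            prev = b

    @property
    def tss(self) -> int:
        """Transcription start: span start on '+', span end on '-'."""
        return self.span[0] if self.strand == "+" else self.span[1]


@dataclass
class CoexpressionNetwork:
    """Bipartite lncRNA-mRNA correlation graph.

    Node attribute ``biotype``; edge attributes ``pcc``, ``p_value``, ``sign``.
    ``min_abs_pcc`` / ``max_p`` record the thresholds every edge satisfies.
    """

    graph: nx.Graph
    min_abs_pcc: float
    max_p: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of(self, biotype: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("biotype") == biotype
        )

    def edges_frame(self) -> pd.DataFrame:
        rows = []
        for u, v, d in self.graph.edges(data=True):
            l, m = (u, v) if self.graph.nodes[u]["biotype"] == LNCRNA else (v, u)
            rows.append((l, m, d["pcc"], d["p_value"], d["sign"]))
        df = pd.DataFrame(
            rows, columns=["lncrna_id", "mrna_id", "pcc", "p_value", "sign"]
        )
        return df.sort_values(["lncrna_id", "mrna_id"], ignore_index=True)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line), optionally with expected per-member
    regulation directions used by the activation score."""

    set_id: str
    description: str
    members: frozenset[str]
    expected_direction: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError(f"gene set {self.set_id}: empty member set")


@dataclass
class PlantedTruth:
    """Ground truth recorded by the simulator for recovery tests."""

    de_genes: dict[str, tuple[str, float]] = field(default_factory=dict)
    correlated_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    category_labels: dict[str, str] = field(default_factory=dict)
    pathway_memberships: dict[str, set[str]] = field(default_factory=dict)
    qpcr_fold_changes: dict[str, float] = field(default_factory=dict)
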
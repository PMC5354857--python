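"""Synthetic cohort generator with planted ground truth.

Emulates the study design the pipeline was built for: a small tumor/normal
cohort (11 vs 5 samples) profiled for mRNAs and lncRNAs, with

* planted differentially expressed genes at a chosen log2 fold change,
* planted lncRNA-mRNA correlation modules at a chosen Pearson correlation,
* gene models realizing all six positional lncRNA categories,
* pathway gene sets with controlled differential-expression overlap,
* a replicate-level qPCR Ct table for chosen validation genes.

Expression is log-normal: log2 values are Normal(mu_g, noise_sd) around a
per-gene baseline mu_g ~ Uniform[2, 8], because the pipeline consumes
FPKM-like post-quantification abundances, not read counts.  Correlated
pairs are built from a shared latent factor per lncRNA module, constructed
orthonormally *in sample* over the tumor cohort so that with zero noise the
realized tumor-cohort Pearson correlation equals the target exactly; with
noise the factor loading is attenuation-compensated so the expected
correlation still sits at the target.  All randomness flows from
``SimulationConfig.seed``; each generator uses its own derived stream so
the four generators are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CATEGORIES,
    LNCRNA,
    MRNA,
    NORMAL,
    TUMOR,
    ConfigError,
    ExpressionMatrix,
    GeneModel,
    GeneSet,
    PlantedTruth,
)

#: positional category mix observed in the differential lncRNA population
#: (exonic sense / intronic sense / exonic antisense / intronic antisense /
#: bidirectional / intergenic)
DEFAULT_CATEGORY_PROPORTIONS: dict[str, float] = {
    "exonic_sense": 0.129,
    "intronic_sense": 0.082,
    "exonic_antisense": 0.203,
    "intronic_antisense": 0.151,
    "bidirectional": 0.013,
    "intergenic": 0.422,
}

DEFAULT_CHROMOSOMES = ("chr1", "chr2", "chr3", "chr4", "chr5", "chrX", "chrY")

# per-pair defaults for the pathway fixture: (set_id, n_de_members, n_background)
DEFAULT_PATHWAY_SPECS = (
    ("PW01", 20, 15),
    ("PW02", 15, 15),
    ("PW03", 12, 15),
    ("PW04", 10, 15),
    ("PW05", 8, 15),
    ("PW06", 6, 15),
    ("PW07", 4, 15),
    ("PW08", 3, 15),
    ("PW09", 2, 15),
    ("PW10", 0, 15),
)
DEFAULT_PATHWAY_SHARED = (
    ("PW01", "PW02", 8),
    ("PW01", "PW03", 6),
    ("PW02", "PW03", 6),
    ("PW04", "PW05", 2),
)

_BLOCK = 100_000  # bp allocated per simulated gene locus


@dataclass
class SimulationConfig:
    """Study-design knobs for all four generators.

    Defaults reproduce the cohort the pipeline targets: 11 tumor vs 5 normal
    samples, a few hundred genes with a ~1:8 up:down split among planted DE
    genes, |log2FC| = 4 effects over log2-scale residual noise of 0.3, and a
    between-sample biological spread of 2.0 log2 units for co-regulated
    modules.
    """

    seed: int
    n_tumor: int = 11
    n_normal: int = 5
    n_mrna: int = 300
    n_lncrna: int = 200
    n_de_up_mrna: int = 20
    n_de_down_mrna: int = 80
    n_de_up_lncrna: int = 10
    n_de_down_lncrna: int = 74
    planted_log2fc: float = 4.0
    noise_sd: float = 0.3
    signal_sd: float = 2.0
    planted_edges: tuple[tuple[str, str, float], ...] = ()
    category_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS)
    )
    chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES
    promoter_window: int = 1000
    pathway_specs: tuple[tuple[str, int, int], ...] = DEFAULT_PATHWAY_SPECS
    pathway_shared_de: tuple[tuple[str, str, int], ...] = DEFAULT_PATHWAY_SHARED
    qpcr_targets: tuple[tuple[str, float], ...] = ()
    qpcr_reference: str = "GAPDH"
    qpcr_noise_sd: float = 0.1
    qpcr_replicates: int = 3

    def __post_init__(self) -> None:
        self.validate()

    # -- id helpers ---------------------------------------------------------
    def mrna_ids(self) -> list[str]:
        return [f"MRNA{i:04d}" for i in range(self.n_mrna)]

    def lncrna_ids(self) -> list[str]:
        return [f"LNC{i:04d}" for i in range(self.n_lncrna)]

    def sample_ids(self) -> tuple[list[str], list[str]]:
        tumor = [f"T{i + 1:02d}" for i in range(self.n_tumor)]
        normal = [f"N{i + 1:02d}" for i in range(self.n_normal)]
        return tumor, normal

    def validate(self) -> None:
        for name in (
            "n_tumor", "n_normal", "n_mrna", "n_lncrna",
            "n_de_up_mrna", "n_de_down_mrna", "n_de_up_lncrna",
            "n_de_down_lncrna", "qpcr_replicates",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_de_up_mrna + self.n_de_down_mrna > self.n_mrna:
            raise ConfigError("n_de_up_mrna + n_de_down_mrna exceeds n_mrna")
        if self.n_de_up_lncrna + self.n_de_down_lncrna > self.n_lncrna:
            raise ConfigError("n_de_up_lncrna + n_de_down_lncrna exceeds n_lncrna")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.signal_sd <= 0:
            raise ConfigError("signal_sd must be > 0")
        if self.qpcr_noise_sd < 0:
            raise ConfigError("qpcr_noise_sd must be >= 0")
        mrna, lnc = set(self.mrna_ids()), set(self.lncrna_ids())
        for l, m, r in self.planted_edges:
            if l not in lnc:
                raise ConfigError(f"planted_edges: unknown lncRNA id {l}")
            if m not in mrna:
                raise ConfigError(f"planted_edges: unknown mRNA id {m}")
            if not -1.0 <= r <= 1.0:
                raise ConfigError(f"planted_edges: target_pcc {r} outside [-1, 1]")
        _edge_modules(self.planted_edges)  # raises on non-star components
        unknown = set(self.category_proportions) - set(CATEGORIES)
        if unknown:
            raise ConfigError(f"category_proportions: unknown categories {sorted(unknown)}")
        if self.category_proportions:
            total = sum(self.category_proportions.values())
            if not np.isclose(total, 1.0):
                raise ConfigError("category_proportions must sum to 1")
        if self.promoter_window < 0:
            raise ConfigError("promoter_window must be >= 0")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _edge_modules(
    edges: tuple[tuple[str, str, float], ...]
) -> list[tuple[str, list[tuple[str, float]]]]:
    """Group planted edges into star modules sharing one latent factor.

    Each connected component of the planted-edge graph must be a star; its
    hub (either a lncRNA with several mRNA partners or an mRNA with several
    lncRNA partners) carries the factor, the satellites load onto it at
    their target correlations.  Returns (hub, [(satellite, pcc), ...])
    sorted by hub id.
    """
    adj: dict[str, dict[str, float]] = {}
    for l, m, r in edges:
        adj.setdefault(l, {})[m] = r
        adj.setdefault(m, {})[l] = r
    seen: set[str] = set()
    modules = []
    for start in sorted(adj):
        if start in seen:
            continue
        comp = []
        stack = [start]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            comp.append(node)
            stack.extend(adj[node])
        hubs = [n for n in comp if len(adj[n]) == len(comp) - 1]
        if len(comp) == 2:
            hub = comp[0] if comp[0].startswith("LNC") else comp[1]
        elif hubs:
            hub = sorted(hubs, key=lambda n: (-len(adj[n]), n))[0]
        else:
            raise ConfigError(
                f"planted_edges: component containing {start!r} is not a star; "
                "chained correlation modules are not constructible"
            )
        modules.append((hub, sorted(adj[hub].items())))
    return sorted(modules)


def _center_unit(x: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to unit sample SD (ddof=1)."""
    x = x - x.mean()
    sd = x.std(ddof=1)
    return x / sd


# ------------------------------------------------------------- expression

def planted_de_assignment(config: SimulationConfig) -> dict[str, tuple[str, float]]:
    """Deterministic DE assignment: leading ids of each biotype are up, the
    following block down."""
    fc = config.planted_log2fc
    de: dict[str, tuple[str, float]] = {}
    m = config.mrna_ids()
    for g in m[: config.n_de_up_mrna]:
        de[g] = ("up", fc)
    for g in m[config.n_de_up_mrna : config.n_de_up_mrna + config.n_de_down_mrna]:
        de[g] = ("down", -fc)
    l = config.lncrna_ids()
    for g in l[: config.n_de_up_lncrna]:
        de[g] = ("up", fc)
    for g in l[config.n_de_up_lncrna : config.n_de_up_lncrna + config.n_de_down_lncrna]:
        de[g] = ("down", -fc)
    return de


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Generate the FPKM-like expression matrix and its planted truth.

    Tumor-group log2 means differ from normal by the planted log2FC exactly
    (before noise); planted correlation modules realize their target Pearson
    correlation over the tumor cohort exactly when ``noise_sd == 0``.
    """
    rng = _rng(config, 1)
    tumor_ids, normal_ids = config.sample_ids()
    gene_ids = config.mrna_ids() + config.lncrna_ids()
    n_genes = len(gene_ids)
    n_t, n_n = config.n_tumor, config.n_normal
    idx = {g: i for i, g in enumerate(gene_ids)}

    mu = rng.uniform(2.0, 8.0, size=n_genes)
    log2m = np.tile(mu[:, None], (1, n_t + n_n))  # tumor columns first

    de = planted_de_assignment(config)
    for g, (_, lfc) in de.items():
        log2m[idx[g], :n_t] += lfc

    # correlation modules: one latent factor per star module (hub lncRNA or
    # hub mRNA), realized orthonormally in-sample over the tumor cohort
    atten = 1.0 + (config.noise_sd / config.signal_sd) ** 2
    for hub, satellites in _edge_modules(config.planted_edges):
        z = _center_unit(rng.standard_normal(n_t))
        log2m[idx[hub], :n_t] += config.signal_sd * z
        w = rng.standard_normal(n_n)
        log2m[idx[hub], n_t:] += config.signal_sd * (w - w.mean())
        for sat, r in satellites:
            eps = rng.standard_normal(n_t)
            eps = eps - eps.mean()
            eps = eps - (eps @ z) / (z @ z) * z
            eps = _center_unit(eps)
            r0 = float(np.clip(r * atten, -1.0, 1.0))
            sig = r0 * z + np.sqrt(max(0.0, 1.0 - r0 * r0)) * eps
            log2m[idx[sat], :n_t] += config.signal_sd * sig
            w = rng.standard_normal(n_n)
            log2m[idx[sat], n_t:] += config.signal_sd * (w - w.mean())

    if config.noise_sd > 0:
        log2m = log2m + rng.standard_normal(log2m.shape) * config.noise_sd

    values = pd.DataFrame(
        np.exp2(log2m), index=pd.Index(gene_ids, name="gene_id"),
        columns=tumor_ids + normal_ids,
    )
    biotype = pd.Series(
        [MRNA] * config.n_mrna + [LNCRNA] * config.n_lncrna, index=values.index
    )
    groups = pd.Series(
        [TUMOR] * n_t + [NORMAL] * n_n, index=values.columns
    )
    matrix = ExpressionMatrix(values=values, biotype=biotype, groups=groups)
    truth = PlantedTruth(
        de_genes=de, correlated_pairs=list(config.planted_edges)
    )
    return matrix, truth


# -------------------------------------------------------------- annotation

def _category_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n lncRNAs over the six categories."""
    cats = [c for c in CATEGORIES if proportions.get(c, 0) > 0]
    raw = {c: proportions[c] * n for c in cats}
    counts = {c: int(np.floor(raw[c])) for c in cats}
    short = n - sum(counts.values())
    by_remainder = sorted(cats, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def _lnc_geometry(category: str, origin: int) -> tuple[tuple[int, int], str]:
    """Span and strand of a lncRNA realizing ``category`` against the block's
    coding gene at [origin+10000, origin+20000) on '+' with exons at
    [10000,11000), [14000,15000), [19000,20000) (block-relative)."""
    o = origin
    if category == "exonic_sense":
        return (o + 10_500, o + 12_000), "+"
    if category == "intronic_sense":
        return (o + 11_500, o + 13_500), "+"
    if category == "exonic_antisense":
        return (o + 10_500, o + 12_000), "-"
    if category == "intronic_antisense":
        return (o + 11_500, o + 13_500), "-"
    if category == "bidirectional":
        # divergent: lncRNA on '-' ending (TSS) 500 bp upstream of the coding TSS
        return (o + 7_000, o + 9_500), "-"
    if category == "intergenic":
        return (o + 60_000, o + 62_000), "+"
    raise ConfigError(f"unknown category {category!r}")


def simulate_annotation(
    config: SimulationConfig, categories: list[str] | None = None
) -> tuple[list[GeneModel], dict[str, str]]:
    """Build coding and lncRNA gene models so that every lncRNA's positional
    category is unambiguous under the classification rules.

    Each lncRNA occupies its own 100-kb locus together with (for overlapping
    or divergent categories) a partner coding gene; loci are spaced so no
    other coding gene can interfere.  Returns the gene models and the map
    lncRNA id -> true category.

    Parameters
    ----------
    categories
        Optional explicit per-lncRNA category list (length ``n_lncrna``);
        by default categories are apportioned from
        ``config.category_proportions`` by largest remainder.
    """
    lnc_ids = config.lncrna_ids()
    mrna_ids = config.mrna_ids()
    if categories is None:
        counts = _category_counts(config.category_proportions, config.n_lncrna)
        categories = []
        for c in CATEGORIES:
            categories.extend([c] * counts.get(c, 0))
        # seeded shuffle so categories are not confounded with the id-ordered
        # DE assignment (planted DE genes take the leading ids)
        categories = [
            categories[i] for i in _rng(config, 2).permutation(len(categories))
        ]
    if len(categories) != config.n_lncrna:
        raise ConfigError(
            f"categories: expected {config.n_lncrna} labels, got {len(categories)}"
        )
    bad = set(categories) - set(CATEGORIES)
    if bad:
        raise ConfigError(f"categories: unknown labels {sorted(bad)}")
    if config.n_mrna < config.n_lncrna:
        raise ConfigError(
            "n_mrna must be >= n_lncrna so each lncRNA locus has a partner coding gene"
        )

    genes: list[GeneModel] = []
    labels: dict[str, str] = {}
    chroms = config.chromosomes
    next_block = {c: 0 for c in chroms}

    def alloc(chrom: str) -> int:
        o = next_block[chrom] * _BLOCK
        next_block[chrom] += 1
        return o

    def coding_model(gid: str, chrom: str, o: int) -> GeneModel:
        return GeneModel(
            gene_id=gid, chrom=chrom, strand="+",
            span=(o + 10_000, o + 20_000),
            exons=(
                (o + 10_000, o + 11_000),
                (o + 14_000, o + 15_000),
                (o + 19_000, o + 20_000),
            ),
            biotype="coding",
        )

    for i, (lid, cat) in enumerate(zip(lnc_ids, categories)):
        chrom = chroms[i % len(chroms)]
        o = alloc(chrom)
        genes.append(coding_model(mrna_ids[i], chrom, o))
        span, strand = _lnc_geometry(cat, o)
        genes.append(
            GeneModel(
                gene_id=lid, chrom=chrom, strand=strand,
                span=span, exons=(span,), biotype="lncRNA",
            )
        )
        labels[lid] = cat

    for gid in mrna_ids[config.n_lncrna:]:
        chrom = chroms[len(genes) % len(chroms)]
        genes.append(coding_model(gid, chrom, alloc(chrom)))

    return genes, labels


# ---------------------------------------------------------------- pathways

def simulate_pathways(
    config: SimulationConfig,
    truth: PlantedTruth,
    direction_agreement: float = 1.0,
) -> list[GeneSet]:
    """Build GMT-serializable pathway sets with controlled DE overlap.

    Pairwise shared-DE counts are realized with dedicated disjoint gene
    blocks, so each configured pair shares exactly the requested number of
    DE genes and unrelated pairs share none.  ``direction_agreement`` sets
    the fraction of each set's DE members whose annotated expected direction
    matches the planted direction (1.0 -> the activation score should call
    the pathway consistent with the planted regulation).
    """
    if not truth.de_genes:
        raise ConfigError("simulate_pathways requires planted DE genes in truth")
    mrna = set(config.mrna_ids())
    de_pool = [g for g in sorted(truth.de_genes) if g in mrna]
    bg_pool = [g for g in config.mrna_ids() if g not in truth.de_genes]
    members: dict[str, list[str]] = {s[0]: [] for s in config.pathway_specs}
    cursor = 0

    def take_de(n: int, what: str) -> list[str]:
        nonlocal cursor
        if cursor + n > len(de_pool):
            raise ConfigError(
                f"{what}: requested overlap exceeds available DE genes "
                f"({len(de_pool)} in pool)"
            )
        block = de_pool[cursor : cursor + n]
        cursor += n
        return block

    for a, b, n in config.pathway_shared_de:
        if a not in members or b not in members:
            raise ConfigError(f"pathway_shared_de: unknown set in ({a}, {b})")
        block = take_de(n, f"shared block ({a}, {b})")
        members[a].extend(block)
        members[b].extend(block)

    sets: list[GeneSet] = []
    bg_cursor = 0
    for set_id, n_de, n_bg in config.pathway_specs:
        have = len(members[set_id])
        if have > n_de:
            raise ConfigError(
                f"pathway {set_id}: shared blocks ({have}) exceed n_de ({n_de})"
            )
        members[set_id].extend(take_de(n_de - have, f"pathway {set_id}"))
        bg = [bg_pool[(bg_cursor + j) % len(bg_pool)] for j in range(n_bg)]
        bg_cursor += n_bg
        de_members = list(members[set_id])
        n_agree = int(np.floor(direction_agreement * len(de_members)))
        expected: dict[str, str] = {}
        for j, g in enumerate(de_members):
            planted = truth.de_genes[g][0]
            expected[g] = planted if j < n_agree else (
                "down" if planted == "up" else "up"
            )
        full = sorted(set(de_members) | set(bg))
        sets.append(
            GeneSet(
                set_id=set_id,
                description=f"synthetic pathway ({n_de} DE members)",
                members=frozenset(full),
                expected_direction=expected or None,
            )
        )
        truth.pathway_memberships[set_id] = set(full)
    return sets


# -------------------------------------------------------------------- qPCR

def simulate_qpcr(config: SimulationConfig) -> pd.DataFrame:
    """Per-well Ct table for the configured validation targets.

    The reference gene sits at Ct ~18 in every sample; each target sits at
    Ct ~24 in normals and ``24 - log2(true_fc)`` in tumors, so the ddCt
    machinery recovers ``true_fc`` exactly at zero noise.  Well-to-well
    scatter is Normal(0, qpcr_noise_sd) cycles; three wells per sample-gene
    by default.
    """
    if not config.qpcr_targets:
        raise ConfigError("qpcr_targets: at least one target gene required")
    rng = _rng(config, 4)
    tumor_ids, normal_ids = config.sample_ids()
    samples = [(s, TUMOR) for s in tumor_ids] + [(s, NORMAL) for s in normal_ids]
    rows = []
    genes = [(config.qpcr_reference, 1.0)] + [
        (g, float(fc)) for g, fc in config.qpcr_targets
    ]
    for gene_id, true_fc in genes:
        if true_fc <= 0:
            raise ConfigError(f"qpcr_targets: fold change for {gene_id} must be > 0")
        base = 18.0 if gene_id == config.qpcr_reference else 24.0
        for sample_id, group in samples:
            mean_ct = base
            if gene_id != config.qpcr_reference and group == TUMOR:
                mean_ct = base - np.log2(true_fc)
            for rep in range(1, config.qpcr_replicates + 1):
                ct = mean_ct + rng.standard_normal() * config.qpcr_noise_sd
                rows.append((sample_id, group, gene_id, rep, ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene_id", "replicate", "ct"])
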
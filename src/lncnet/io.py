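"""Readers and writers for the pipeline's on-disk formats.

All formats are plain text: expression matrix TSV (first column ``gene_id``),
sample sheet TSV (``sample_id``, ``group``), biotype TSV, 9-column GTF
(1-based inclusive, attributes ``gene_id``/``gene_biotype``), GMT, Ct table
TSV and a JSON serialization of the planted truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pyranges as pr

from .datatypes import ExpressionMatrix, GeneModel, GeneSet, InputError, PlantedTruth


# ---------------------------------------------------------------- expression

def write_matrix(matrix: ExpressionMatrix, matrix_path, sheet_path, biotype_path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(matrix_path, sep="\t")
    sheet = pd.DataFrame(
        {"sample_id": matrix.sample_ids, "group": matrix.groups.values}
    )
    sheet.to_csv(sheet_path, sep="\t", index=False)
    bio = pd.DataFrame({"gene_id": matrix.gene_ids, "biotype": matrix.biotype.values})
    bio.to_csv(biotype_path, sep="\t", index=False)


def read_matrix(matrix_path, sheet_path, biotype_path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
    sheet = pd.read_csv(sheet_path, sep="\t")
    bio = pd.read_csv(biotype_path, sep="\t")
    groups = pd.Series(sheet["group"].values, index=sheet["sample_id"].astype(str))
    biotype = pd.Series(bio["biotype"].values, index=bio["gene_id"].astype(str))
    return ExpressionMatrix(values=values, biotype=biotype, groups=groups)


# ----------------------------------------------------------------------- GTF

def normalize_chrom(name: str) -> str:
    """Accept 'chr1'/'1' dialects; return the 'chr'-prefixed form."""
    name = str(name)
    return name if name.startswith("chr") else f"chr{name}"


def write_gtf(genes: list[GeneModel], path) -> None:
    """Serialize gene models as GTF (1-based inclusive gene + exon rows)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.span, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            s, e = g.span
            fh.write(
                f"{g.chrom}\tlncnet\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for (a, b) in g.exons:
                fh.write(
                    f"{g.chrom}\tlncnet\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_gtf(path) -> list[GeneModel]:
    """Read gene models from GTF via pyranges (0-based half-open internally)."""
    df = pr.read_gtf(str(path)).df
    if df.empty:
        return []
    required = {"gene_id", "gene_biotype"}
    if not required <= set(df.columns):
        raise InputError(f"GTF {path}: missing attributes {required - set(df.columns)}")
    genes: list[GeneModel] = []
    for gid, sub in df.groupby("gene_id", sort=True):
        grow = sub[sub["Feature"] == "gene"]
        erows = sub[sub["Feature"] == "exon"]
        if grow.empty:
            # tolerate exon-only files: infer span from exons
            chrom = sub["Chromosome"].iloc[0]
            strand = sub["Strand"].iloc[0]
            biotype = sub["gene_biotype"].iloc[0]
            span = (int(erows["Start"].min()), int(erows["End"].max()))
        else:
            chrom = grow["Chromosome"].iloc[0]
            strand = grow["Strand"].iloc[0]
            biotype = grow["gene_biotype"].iloc[0]
            span = (int(grow["Start"].iloc[0]), int(grow["End"].iloc[0]))
        exons = tuple(
            sorted((int(a), int(b)) for a, b in zip(erows["Start"], erows["End"]))
        )
        genes.append(
            GeneModel(
                gene_id=str(gid),
                chrom=normalize_chrom(chrom),
                strand=str(strand),
                span=span,
                exons=exons,
                biotype=str(biotype),
            )
        )
    return genes


# ----------------------------------------------------------------------- GMT

def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.set_id}\t{s.description}\t{members}\n")


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"GMT {path}: line with fewer than 3 fields")
            sets.append(
                GeneSet(
                    set_id=parts[0],
                    description=parts[1],
                    members=frozenset(p for p in parts[2:] if p),
                )
            )
    return sets


def read_direction_annotations(path) -> dict[str, dict[str, str]]:
    """Optional per-set expected member directions: TSV set_id, gene_id, direction."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["set_id"]), {})[str(row["gene_id"])] = str(
            row["direction"]
        )
    return out


# ------------------------------------------------------------------ Ct table

CT_COLUMNS = ["sample_id", "group", "gene_id", "replicate", "ct"]


def write_ct_table(records: pd.DataFrame, path) -> None:
    records[CT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"Ct table {path}: missing columns {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise InputError(f"Ct table {path}: non-positive Ct values")
    return df


# --------------------------------------------------------------------- truth

def write_truth(truth: PlantedTruth, path) -> None:
    payload = {
        "de_genes": {g: list(v) for g, v in truth.de_genes.items()},
        "correlated_pairs": [list(t) for t in truth.correlated_pairs],
        "category_labels": truth.category_labels,
        "pathway_memberships": {k: sorted(v) for k, v in truth.pathway_memberships.items()},
        "qpcr_fold_changes": truth.qpcr_fold_changes,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    return PlantedTruth(
        de_genes={g: (v[0], float(v[1])) for g, v in payload["de_genes"].items()},
        correlated_pairs=[(a, b, float(r)) for a, b, r in payload["correlated_pairs"]],
        category_labels=payload["category_labels"],
        pathway_memberships={k: set(v) for k, v in payload["pathway_memberships"].items()},
        qpcr_fold_changes={k: float(v) for k, v in payload["qpcr_fold_changes"].items()},
    )
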
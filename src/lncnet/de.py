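"""Differential expression: fold change, Welch testing, BH-FDR, filtering.

Significance follows the strict three-way rule used throughout the pipeline:
linear fold change > 2 or < 0.5, p < 0.05, FDR < 0.1 (all strict).  Fold
change is the ratio of group means with a pseudocount inside both mean and
denominator so zero-expression genes stay computable; the test is a
two-sided Welch t on log2(value + pseudocount).  FDR is Benjamini-Hochberg,
computed per biotype by default since lncRNAs and mRNAs are reported as
separate populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, InputError, NORMAL, TUMOR

logger = logging.getLogger(__name__)

#: -log10 stand-in for an FDR of exactly zero in plot tables
NEG_LOG10_CAP = 320.0


@dataclass(frozen=True)
class DEThresholds:
    """Significance cut-offs: FC > fc_up or < fc_down, p < p_max, FDR < fdr_max."""

    fc_up: float = 2.0
    fc_down: float = 0.5
    p_max: float = 0.05
    fdr_max: float = 0.1
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        if not self.fc_up > 1:
            raise InputError("fc_up must be > 1")
        if not 0 < self.fc_down < 1:
            raise InputError("fc_down must be in (0, 1)")
        if not 0 < self.p_max <= 1:
            raise InputError("p_max must be in (0, 1]")
        if not 0 < self.fdr_max <= 1:
            raise InputError("fdr_max must be in (0, 1]")
        if self.pseudocount < 0:
            raise InputError("pseudocount must be >= 0")


def _group_arrays(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    t = matrix.samples_in(TUMOR)
    n = matrix.samples_in(NORMAL)
    if not t or not n:
        raise InputError("both tumor and normal samples are required")
    return matrix.values[t].to_numpy(float), matrix.values[n].to_numpy(float)


def compute_fold_change(
    matrix: ExpressionMatrix, thresholds: DEThresholds = DEThresholds()
) -> pd.DataFrame:
    """Per-gene linear fold change (tumor/normal) and its log2.

    fc = (mean_tumor + pseudocount) / (mean_normal + pseudocount); defined
    for every gene, including genes at zero expression in either group.
    """
    tv, nv = _group_arrays(matrix)
    mean_t = tv.mean(axis=1)
    mean_n = nv.mean(axis=1)
    pc = thresholds.pseudocount
    with np.errstate(divide="ignore"):  # pseudocount 0 with a zero group mean
        fc = (mean_t + pc) / (mean_n + pc)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "biotype": matrix.biotype.values,
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "fc": fc,
            "log2fc": np.log2(fc, where=fc > 0, out=np.full_like(fc, -np.inf)),
        }
    )


def welch_t_test(
    matrix: ExpressionMatrix, pseudocount: float = 0.25
) -> pd.Series:
    """Two-sided Welch t-test per gene on log2(value + pseudocount).

    Degenerate genes: zero variance in both groups gives p = 1 when the
    means agree, and the smallest positive float when they differ.
    """
    tv, nv = _group_arrays(matrix)
    n1, n2 = tv.shape[1], nv.shape[1]
    if n1 < 2 or n2 < 2:
        raise InputError("Welch test requires >= 2 samples per group")
    x = np.log2(tv + pseudocount)
    y = np.log2(nv + pseudocount)
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    p = np.ones(len(m1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    ok = se2 > 0
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    degenerate = (~ok) & (m1 != m2)
    p[degenerate] = np.nextafter(0.0, 1.0)
    return pd.Series(p, index=matrix.gene_ids, name="p_value")


def bh_fdr(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InputError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_de(
    matrix: ExpressionMatrix,
    thresholds: DEThresholds = DEThresholds(),
    fdr_per_biotype: bool = True,
) -> pd.DataFrame:
    """Full DE table: fold change, Welch p, BH-FDR and significance calls."""
    records = compute_fold_change(matrix, thresholds)
    records["p_value"] = welch_t_test(matrix, thresholds.pseudocount).values
    records["fdr"] = np.nan
    if fdr_per_biotype:
        for bt in records["biotype"].unique():
            mask = records["biotype"] == bt
            records.loc[mask, "fdr"] = bh_fdr(records.loc[mask, "p_value"].values)
    else:
        records["fdr"] = bh_fdr(records["p_value"].values)
    return filter_significant(records, thresholds)


def filter_significant(
    records: pd.DataFrame, thresholds: DEThresholds = DEThresholds()
) -> pd.DataFrame:
    """Apply the strict three-way rule; adds ``significant`` and ``direction``."""
    records = records.copy()
    fc = records["fc"]
    passes_fc = (fc > thresholds.fc_up) | (fc < thresholds.fc_down)
    sig = (
        passes_fc
        & (records["p_value"] < thresholds.p_max)
        & (records["fdr"] < thresholds.fdr_max)
    )
    direction = np.where(
        ~sig, "none", np.where(fc > thresholds.fc_up, "up", "down")
    )
    records["significant"] = sig.values
    records["direction"] = direction
    return records


def summarize_counts(records: pd.DataFrame, extra_fc_cut: float = 10.0) -> pd.DataFrame:
    """Per-biotype DE bookkeeping: up/down/total counts, plus the counts of
    significant genes beyond the extreme fold-change cut (FC > cut up,
    FC < 1/cut down)."""
    rows = []
    for bt in sorted(records["biotype"].unique()):
        sub = records[(records["biotype"] == bt) & records["significant"]]
        n_up = int((sub["direction"] == "up").sum())
        n_down = int((sub["direction"] == "down").sum())
        up_x = int(((sub["direction"] == "up") & (sub["fc"] > extra_fc_cut)).sum())
        down_x = int(
            ((sub["direction"] == "down") & (sub["fc"] < 1.0 / extra_fc_cut)).sum()
        )
        rows.append(
            {
                "biotype": bt,
                "n_up": n_up,
                "n_down": n_down,
                "n_total": n_up + n_down,
                "n_up_extreme": up_x,
                "n_down_extreme": down_x,
                "n_extreme_total": up_x + down_x,
            }
        )
    return pd.DataFrame(rows)


def export_plot_tables(
    records: pd.DataFrame,
    matrix: ExpressionMatrix | None = None,
    pseudocount: float = 0.25,
) -> dict[str, pd.DataFrame]:
    """Plot-ready tables: a volcano table (log2FC vs -log10 FDR, classed
    up/down/ns) and, when the matrix is given, a per-group log2-mean scatter
    table."""
    with np.errstate(divide="ignore"):
        y = -np.log10(records["fdr"].to_numpy(float))
    y = np.where(np.isinf(y), NEG_LOG10_CAP, y)
    volcano = pd.DataFrame(
        {
            "gene_id": records["gene_id"],
            "log2fc": records["log2fc"],
            "neg_log10_fdr": y,
            "class": np.where(records["significant"], records["direction"], "ns"),
        }
    )
    out = {"volcano": volcano}
    if matrix is not None:
        tv, nv = _group_arrays(matrix)
        out["scatter"] = pd.DataFrame(
            {
                "gene_id": matrix.gene_ids,
                "log2_mean_tumor": np.log2(tv.mean(axis=1) + pseudocount),
                "log2_mean_normal": np.log2(nv.mean(axis=1) + pseudocount),
            }
        )
    return out


# ----------------------------------------------------- hierarchical ordering

def _correlation_distance(data: np.ndarray, ids: list[str]) -> pd.DataFrame:
    """1 - Pearson distance matrix; constant rows get the maximal distance 2
    to every other item (with a logged warning)."""
    centered = data - data.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant rows assigned maximal distance in clustering",
            int(constant.sum()),
        )
    sd_safe = np.where(constant, 1.0, sd)
    z = centered / sd_safe[:, None]
    corr = z @ z.T / data.shape[1]
    dist = 1.0 - corr
    dist[constant, :] = 2.0
    dist[:, constant] = 2.0
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=ids, columns=ids)


def average_linkage(dist: pd.DataFrame) -> tuple[list[str], list[float]]:
    """UPGMA agglomeration with a deterministic tie-break.

    Merge distance between clusters is the mean of all cross-pair
    distances; ties are broken by the lexicographically smallest combined
    member-id tuple.  Returns the leaf order and the merge heights.
    """
    ids = list(dist.index)
    # members[k]: leaf order within cluster k; key = min member id (stable)
    members: dict[str, list[str]] = {i: [i] for i in ids}
    sizes: dict[str, int] = {i: 1 for i in ids}
    def pair_key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    d: dict[tuple[str, str], float] = {}
    arr = dist.to_numpy(float)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            d[pair_key(a, ids[j])] = float(arr[i, j])

    heights: list[float] = []
    while len(members) > 1:
        best = None
        for (a, b), h in d.items():
            key = (h, tuple(sorted(members[a] + members[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        (h, _), a, b = best
        heights.append(h)
        ca, cb = members.pop(a), members.pop(b)
        first, second = (ca, cb) if min(ca) <= min(cb) else (cb, ca)
        na, nb = sizes.pop(a), sizes.pop(b)
        new = min(a, b)
        other = max(a, b)
        # UPGMA (Lance-Williams) update against every remaining cluster
        for c in list(members):
            hc = (
                na * d.pop(pair_key(a, c)) + nb * d.pop(pair_key(b, c))
            ) / (na + nb)
            d[pair_key(new, c)] = hc
        d.pop(pair_key(a, b), None)
        members[new] = first + second
        sizes[new] = na + nb
        assert other not in members
    (order,) = members.values()
    return order, heights


def cluster_order(
    matrix: ExpressionMatrix,
    records: pd.DataFrame,
    pseudocount: float = 0.25,
) -> tuple[list[str], list[str]]:
    """Heatmap leaf orders: genes and samples ordered by average-linkage
    clustering on correlation distance over the significant genes."""
    sig = records.loc[records["significant"], "gene_id"].tolist()
    if len(sig) < 2:
        raise InputError("clustering requires >= 2 significant genes")
    log2v = np.log2(matrix.values.loc[sig].to_numpy(float) + pseudocount)
    gene_order, _ = average_linkage(_correlation_distance(log2v, sig))
    sample_ids = list(matrix.sample_ids)
    sample_order, _ = average_linkage(
        _correlation_distance(log2v.T, sample_ids)
    )
    return gene_order, sample_order
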
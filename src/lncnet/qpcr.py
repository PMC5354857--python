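"""Relative quantification of qPCR validation data by the 2^-ddCt method.

Replicate wells are averaged arithmetically per (sample, gene); the
calibrator subtracts the mean normal-group dCt (equivalent to calibrating
on the geometric mean of the normal samples, so the normal group's
geometric-mean relative expression is 1 by construction).  A per-sample
calibrator mode is available.  Group comparison is a two-sided t-test,
Welch by default given the unequal 11 vs 5 group sizes, with a
pooled-variance Student variant by flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GROUPS, InputError, NORMAL, TUMOR

logger = logging.getLogger(__name__)


def _mean_ct(records: pd.DataFrame, gene: str) -> pd.Series:
    sub = records[records["gene_id"] == gene]
    return sub.groupby("sample_id")["ct"].mean()


def relative_expression(
    records: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str = "normal_mean",
) -> pd.DataFrame:
    """Per-sample 2^-ddCt of ``target`` normalized to ``reference``.

    dCt_s = mean Ct_target(s) - mean Ct_reference(s);
    ddCt_s = dCt_s - calibrator, where the default calibrator is the mean
    dCt over normal samples.  ``calibrator`` may instead name a sample id
    to calibrate against.  Samples lacking the reference gene are excluded
    with a warning.
    """
    groups = records.drop_duplicates("sample_id").set_index("sample_id")["group"]
    bad = set(groups.unique()) - set(GROUPS)
    if bad:
        raise InputError(f"unknown groups in Ct table: {sorted(bad)}")
    tgt = _mean_ct(records, target)
    ref = _mean_ct(records, reference)
    if tgt.empty:
        raise InputError(f"target gene {target!r} absent from Ct table")
    missing_ref = sorted(set(tgt.index) - set(ref.index))
    if missing_ref:
        logger.warning(
            "samples without reference gene excluded: %s", missing_ref
        )
    samples = [s for s in tgt.index if s in set(ref.index)]
    dct = tgt.loc[samples] - ref.loc[samples]
    if calibrator == "normal_mean":
        normals = [s for s in samples if groups[s] == NORMAL]
        if not normals:
            raise InputError("no normal samples to form the calibrator")
        base = dct.loc[normals].mean()
    else:
        if calibrator not in dct.index:
            raise InputError(f"calibrator sample {calibrator!r} not measured")
        base = dct.loc[calibrator]
    ddct = dct - base
    return pd.DataFrame(
        {
            "sample_id": samples,
            "group": groups.loc[samples].values,
            "delta_ct": dct.values,
            "delta_delta_ct": ddct.values,
            "rel_expr": np.exp2(-ddct.values),
        }
    )


def group_compare(
    rel: pd.DataFrame, welch: bool = True, alpha: float = 0.05
) -> pd.DataFrame:
    """Mean +/- SD of relative expression per group with a t-test p.

    One summary row: tumor mean/SD, normal mean/SD, two-sided p
    (Welch by default, pooled-variance Student with ``welch=False``) and a
    significance flag at p < alpha.
    """
    t = rel.loc[rel["group"] == TUMOR, "rel_expr"].to_numpy(float)
    n = rel.loc[rel["group"] == NORMAL, "rel_expr"].to_numpy(float)
    if len(t) < 2 or len(n) < 2:
        raise InputError("group_compare needs >= 2 samples per group")
    if np.allclose(t, t[0]) and np.allclose(n, n[0]) and np.isclose(t[0], n[0]):
        p = 1.0
    else:
        p = float(stats.ttest_ind(t, n, equal_var=not welch).pvalue)
    return pd.DataFrame(
        [
            {
                "mean_tumor": t.mean(),
                "sd_tumor": t.std(ddof=1),
                "mean_normal": n.mean(),
                "sd_normal": n.std(ddof=1),
                "p_value": p,
                "significant": p < alpha,
            }
        ]
    )


def quantify_all(
    records: pd.DataFrame,
    targets: list[str],
    reference: str,
    welch: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative expression and group summary for every target gene."""
    per_sample = []
    summaries = []
    for gene in targets:
        rel = relative_expression(records, gene, reference)
        rel.insert(0, "gene_id", gene)
        per_sample.append(rel)
        summary = group_compare(rel, welch=welch)
        summary.insert(0, "gene_id", gene)
        summaries.append(summary)
    return (
        pd.concat(per_sample, ignore_index=True),
        pd.concat(summaries, ignore_index=True),
    )
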
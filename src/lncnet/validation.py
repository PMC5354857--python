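"""Planted-truth recovery studies on synthetic cohorts.

These are the package's calibration experiments: they generate synthetic
cohorts at the study's design (11 tumor vs 5 normal samples), run the
pipeline stages, and score recovery of the planted signal.  Problem sizes
are desk-scale (hundreds of genes); the statistics involved are scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .de import DEThresholds, run_de
from .network import build_network
from .simulate import SimulationConfig, simulate_expression


@dataclass
class RecoveryResult:
    sensitivity: float
    fdp: float
    n_planted: int
    n_seeds: int


def _offset(base_seed: int, k: int) -> int:
    return (int(base_seed) * 1000 + k) % (2**31)


def de_recovery(
    n_seeds: int = 50,
    base_seed: int = 0,
    planted_log2fc: float = 4.0,
    noise_sd: float = 0.3,
    thresholds: DEThresholds = DEThresholds(),
) -> RecoveryResult:
    """Sensitivity and false-discovery proportion of the DE stage.

    200 genes per cohort, 20 planted DE genes (|log2FC| = planted_log2fc),
    averaged over ``n_seeds`` seeded cohorts.
    """
    sens, fdps = [], []
    n_planted = 20
    for k in range(n_seeds):
        cfg = SimulationConfig(
            seed=_offset(base_seed, k),
            n_mrna=100, n_lncrna=100,
            n_de_up_mrna=5, n_de_down_mrna=5,
            n_de_up_lncrna=5, n_de_down_lncrna=5,
            planted_log2fc=planted_log2fc, noise_sd=noise_sd,
            pathway_specs=(), pathway_shared_de=(),
        )
        matrix, truth = simulate_expression(cfg)
        rec = run_de(matrix, thresholds)
        called = set(rec.loc[rec["significant"], "gene_id"])
        planted = set(truth.de_genes)
        sens.append(len(called & planted) / len(planted))
        fdps.append(len(called - planted) / max(1, len(called)))
    return RecoveryResult(
        sensitivity=float(np.mean(sens)), fdp=float(np.mean(fdps)),
        n_planted=n_planted, n_seeds=n_seeds,
    )


def edge_recovery(
    n_seeds: int = 10,
    base_seed: int = 0,
    target_pcc: float = 0.95,
    min_abs_pcc: float = 0.90,
) -> tuple[RecoveryResult, float]:
    """Recovery of planted correlation edges at the general-network cut.

    20 planted lncRNA-mRNA pairs at ``target_pcc`` among 30 x 20 candidate
    pairs per cohort.  Returns the recovery result plus the mean count of
    false edges per cohort.
    """
    planted_edges = tuple(
        (f"LNC{i:04d}", f"MRNA{i:04d}", target_pcc) for i in range(20)
    )
    lnc = [f"LNC{i:04d}" for i in range(30)]
    mrna = [f"MRNA{i:04d}" for i in range(20)]
    truth_set = {(l, m) for l, m, _ in planted_edges}
    sens, false_counts = [], []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            seed=_offset(base_seed, 500 + k),
            n_mrna=20, n_lncrna=30,
            n_de_up_mrna=0, n_de_down_mrna=0,
            n_de_up_lncrna=0, n_de_down_lncrna=0,
            planted_edges=planted_edges,
            pathway_specs=(), pathway_shared_de=(),
        )
        matrix, _ = simulate_expression(cfg)
        net = build_network(matrix, lnc, mrna, min_abs_pcc=min_abs_pcc)
        got = {
            (r.lncrna_id, r.mrna_id)
            for r in net.edges_frame().itertuples(index=False)
        }
        sens.append(len(got & truth_set) / len(truth_set))
        false_counts.append(len(got - truth_set))
    rec = RecoveryResult(
        sensitivity=float(np.mean(sens)),
        fdp=float(np.mean(false_counts)) / max(1.0, np.mean(false_counts) + 20),
        n_planted=len(truth_set), n_seeds=n_seeds,
    )
    return rec, float(np.mean(false_counts))


def null_edge_rate(
    n_seeds: int = 20, base_seed: int = 0, max_p: float = 0.001
) -> tuple[float, int]:
    """False-positive edge rate under a pure null at the p < max_p rule.

    No planted structure; the PCC threshold is disabled so the rate
    isolates the p-value calibration.  Returns (rate, number of pairs
    tested), for comparison against the nominal level within binomial
    error.
    """
    lnc = [f"LNC{i:04d}" for i in range(30)]
    mrna = [f"MRNA{i:04d}" for i in range(30)]
    edges = 0
    pairs = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(
            seed=_offset(base_seed, 900 + k),
            n_mrna=30, n_lncrna=30,
            n_de_up_mrna=0, n_de_down_mrna=0,
            n_de_up_lncrna=0, n_de_down_lncrna=0,
            pathway_specs=(), pathway_shared_de=(),
        )
        matrix, _ = simulate_expression(cfg)
        net = build_network(matrix, lnc, mrna, min_abs_pcc=0.0, max_p=max_p)
        edges += net.n_edges
        pairs += len(lnc) * len(mrna)
    return edges / pairs, pairs


def null_de_rate(
    n_seeds: int = 100, base_seed: int = 0,
    thresholds: DEThresholds = DEThresholds(),
) -> float:
    """Mean fraction of genes called significant under a pure null
    (1000 genes, no planted effects)."""
    fracs = []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            seed=_offset(base_seed, 700 + k),
            n_mrna=500, n_lncrna=500,
            n_de_up_mrna=0, n_de_down_mrna=0,
            n_de_up_lncrna=0, n_de_down_lncrna=0,
            pathway_specs=(), pathway_shared_de=(),
        )
        matrix, _ = simulate_expression(cfg)
        rec = run_de(matrix, thresholds)
        fracs.append(rec["significant"].mean())
    return float(np.mean(fracs))
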
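"""Neuron -> cluster -> brain aggregation and two-group comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .. import stats as _stats
from .roi import NeuronMeasurement

TOTAL_LABEL = "total"


@dataclass(frozen=True)
class ClusterSummary:
    """Neuron count and summed FI for one cluster of one brain."""

    cluster: str
    neuron_count: int
    cluster_fi: float


@dataclass(frozen=True)
class BrainSummary:
    """Per-cluster summaries plus whole-brain totals for one brain."""

    brain_id: str
    condition: str
    clusters: tuple[ClusterSummary, ...]
    total_fi: float
    total_neurons: int

    def cluster_fi(self, cluster: str) -> float:
        for c in self.clusters:
            if c.cluster == cluster:
                return c.cluster_fi
        return 0.0

    def cluster_count(self, cluster: str) -> int:
        for c in self.clusters:
            if c.cluster == cluster:
                return c.neuron_count
        return 0


def summarize_brain(measurements, brain_id: str, condition: str) -> BrainSummary:
    """Sum neuron FIs into cluster FIs and the whole-brain total.

    Cluster FI is the plain sum of member neuron FIs; the brain total is
    the sum over clusters — both invariant to measurement order.
    """
    by_cluster: dict[str, list[NeuronMeasurement]] = {}
    for m in measurements:
        by_cluster.setdefault(m.cluster, []).append(m)
    clusters = tuple(
        ClusterSummary(
            cluster=name,
            neuron_count=len(ms),
            cluster_fi=float(sum(m.neuron_fi for m in ms)),
        )
        for name, ms in sorted(by_cluster.items())
    )
    return BrainSummary(
        brain_id=brain_id,
        condition=condition,
        clusters=clusters,
        total_fi=float(sum(c.cluster_fi for c in clusters)),
        total_neurons=sum(c.neuron_count for c in clusters),
    )


def compare_groups(control, treated, alpha: float = 0.05) -> pd.DataFrame:
    """Compare FI and neuron counts between brain groups, per cluster and in toto.

    For every cluster present in either group, and for the whole-brain
    total (row ``"total"``), reports group means, SEM, percent change
    computed on group means ``(mean_ctrl - mean_trt) / mean_ctrl * 100``,
    the pooled two-tailed t statistic and p-value, and the same
    comparison for neuron counts.
    """
    if len(control) < 2 or len(treated) < 2:
        raise ValueError("need >= 2 brains per group")
    names = sorted(
        {c.cluster for b in list(control) + list(treated) for c in b.clusters}
    )
    rows = []
    for name in names + [TOTAL_LABEL]:
        if name == TOTAL_LABEL:
            fi_c = np.array([b.total_fi for b in control])
            fi_t = np.array([b.total_fi for b in treated])
            n_c = np.array([b.total_neurons for b in control], dtype=float)
            n_t = np.array([b.total_neurons for b in treated], dtype=float)
        else:
            fi_c = np.array([b.cluster_fi(name) for b in control])
            fi_t = np.array([b.cluster_fi(name) for b in treated])
            n_c = np.array([b.cluster_count(name) for b in control], dtype=float)
            n_t = np.array([b.cluster_count(name) for b in treated], dtype=float)
        fi_test = _stats.unpaired_t_test(fi_c, fi_t, alpha=alpha)
        ct_test = _stats.unpaired_t_test(n_c, n_t, alpha=alpha)
        mean_c = float(fi_c.mean())
        rows.append(
            {
                "cluster": name,
                "n_brains_control": fi_c.size,
                "n_brains_treated": fi_t.size,
                "mean_fi_control": mean_c,
                "sem_fi_control": _stats.sem(fi_c),
                "mean_fi_treated": float(fi_t.mean()),
                "sem_fi_treated": _stats.sem(fi_t),
                "percent_change": (
                    (mean_c - float(fi_t.mean())) / mean_c * 100.0
                    if mean_c else float("nan")
                ),
                "t_statistic": fi_test.statistic,
                "p_value": fi_test.p_value,
                "significant": fi_test.significant,
                "mean_count_control": float(n_c.mean()),
                "mean_count_treated": float(n_t.mean()),
                "count_p_value": ct_test.p_value,
            }
        )
    return pd.DataFrame(rows)
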
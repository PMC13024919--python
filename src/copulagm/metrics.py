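"""Edge-recovery metrics between a learned and a ground-truth graph."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

from .graph import UndirectedGraph


@dataclass
class RecoveryReport:
    """Exact edge-set comparison summary.

    For undirected graphs the structural Hamming distance equals
    ``FP + FN`` (each differing adjacency entry counted once per unordered
    pair).  Degenerate precision/recall (zero denominator) are reported as
    0.0 with the corresponding flag set, keeping benchmark aggregation
    total.
    """

    tp: int
    fp: int
    fn: int
    shd: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True

    def as_dict(self) -> Dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "shd": self.shd,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


def compare(G_true: UndirectedGraph, G_learned: UndirectedGraph) -> RecoveryReport:
    """Compare learned vs true edge sets (set arithmetic on canonical pairs)."""
    if G_true.d != G_learned.d:
        raise ValueError(
            f"vertex counts differ: {G_true.d} vs {G_learned.d}"
        )
    E, Ehat = G_true.edges, G_learned.edges
    tp = len(Ehat & E)
    fp = len(Ehat - E)
    fn = len(E - Ehat)
    shd = fp + fn
    p_def = (tp + fp) > 0
    r_def = (tp + fn) > 0
    precision = tp / (tp + fp) if p_def else 0.0
    recall = tp / (tp + fn) if r_def else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0 else 0.0
    )
    return RecoveryReport(
        tp=tp, fp=fp, fn=fn, shd=shd, precision=precision, recall=recall,
        f1=f1, precision_defined=p_def, recall_defined=r_def,
    )


def shd_from_adjacency(W_true, W_learned) -> int:
    """SHD via the adjacency-matrix formula ``(1/2) sum |W - What|``."""
    import numpy as np
    W_true = np.asarray(W_true)
    W_learned = np.asarray(W_learned)
    return int(round(np.abs(W_true - W_learned).sum() / 2))
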
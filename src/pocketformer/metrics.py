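"""Evaluation metrics for screening, fishing, and docking.

AUROC uses the rank-sum (Mann-Whitney) formulation with ties counted as
half.  BEDROC follows the Truchon-Bayly exponential early-recognition
formula with configurable alpha (default 80.5, the community convention
for enrichment-style benchmarks).  The enrichment factor uses the
hit-rate-ratio convention EF_f = (hits in top ceil(fN) / ceil(fN)) /
(actives / N).  Pose success rates follow the top-k / RMSD < threshold
protocol.  Ranking ties break deterministically by item id.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD in a fixed frame (no superposition)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum(axis=-1).mean()))


def _check_labels(labels: np.ndarray):
    if labels.min() == labels.max():
        raise ValueError("need both actives and decoys")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """P(random active outranks random decoy); ties count one half."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    _check_labels(labels)
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _descending_order(scores: np.ndarray) -> np.ndarray:
    # stable sort on (-score, original index): deterministic tie-break
    return np.lexsort((np.arange(len(scores)), -scores))


def bedroc(scores: Sequence[float], labels: Sequence[int],
           alpha: float = 80.5) -> float:
    """Boltzmann-enhanced discrimination of ROC, normalized to [0, 1]."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    _check_labels(labels)
    N = len(scores)
    n = int(labels.sum())
    order = _descending_order(scores)
    ranks = np.nonzero(labels[order] == 1)[0] + 1  # 1-based ranks of actives
    ra = n / N
    s = np.exp(-alpha * ranks / N).sum()
    rand_sum = (n / N) * (1 - math.exp(-alpha)) / (math.exp(alpha / N) - 1)
    rie = s / rand_sum
    factor = ra * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra))
    const = 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))
    return float(rie * factor + const)


def enrichment_factor(scores: Sequence[float], labels: Sequence[int],
                      fraction: float) -> float:
    """Hit-rate in the top ``fraction`` divided by the overall hit-rate."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    N = len(scores)
    n = int(labels.sum())
    if n == 0:
        raise ValueError("no actives")
    m = math.ceil(fraction * N)
    top = _descending_order(scores)[:m]
    hits = int(labels[top].sum())
    return float((hits / m) / (n / N))


def make_score_table(item_ids: Sequence[str], scores: Sequence[float],
                     labels: Optional[Sequence[int]] = None,
                     rmsds: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Build a ranked score table (descending; ties broken by item id)."""
    df = pd.DataFrame({"item_id": list(item_ids),
                       "score": np.asarray(scores, dtype=np.float64)})
    if labels is not None:
        df["label"] = np.asarray(labels).astype(int)
    if rmsds is not None:
        df["rmsd"] = np.asarray(rmsds, dtype=np.float64)
    df = df.sort_values(["score", "item_id"],
                        ascending=[False, True], kind="stable")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    cols = ["item_id", "score", "rank"] + [c for c in ("label", "rmsd")
                                           if c in df.columns]
    return df[cols]


def topk_success(decoy_sets: Sequence[pd.DataFrame], k: int,
                 threshold: float = 2.0) -> float:
    """Percentage of sets whose top-k by score contains a pose with
    RMSD < threshold."""
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = 0
    for table in decoy_sets:
        if "rmsd" not in table.columns:
            raise ValueError("score table lacks RMSD annotations")
        if len(table) < k:
            raise ValueError("score table has fewer than k poses")
        top = table.nsmallest(k, "rank")
        if (top["rmsd"] < threshold).any():
            hits += 1
    return 100.0 * hits / len(decoy_sets)


def topk_retrieval(score_tables: Sequence[pd.DataFrame], k: int) -> float:
    """Percentage of tables whose true item (label == 1) is in the top k."""
    hits = 0
    for table in score_tables:
        top = table.nsmallest(k, "rank")
        if (top["label"] == 1).any():
            hits += 1
    return 100.0 * hits / len(score_tables)
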
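"""Pre-training objectives: contrastive alignment, pocket-grounded
matching with hard-negative mining, and the geometric docking losses.

All expectations over the pair distribution are realized as mini-batch
means.  The four loss components sum with unit weights into the total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from . import nn
from .model import ProjectionHead
from .nn import Tensor


@dataclass
class DockingLossConfig:
    """Huber threshold (Angstrom) for the intra-molecular distance loss."""

    delta: float = 1.0

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass
class LossReport:
    """The four loss components and their unit-weight sum."""

    l_pmc: float = 0.0
    l_pmm: float = 0.0
    l_intra: float = 0.0
    l_inter: float = 0.0

    @property
    def total(self) -> float:
        return self.l_pmc + self.l_pmm + self.l_intra + self.l_inter

    def to_dict(self) -> dict:
        return {"l_pmc": self.l_pmc, "l_pmm": self.l_pmm,
                "l_intra": self.l_intra, "l_inter": self.l_inter,
                "total": self.total}


def check_finite(report: LossReport) -> LossReport:
    for name, val in report.to_dict().items():
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite loss component {name} = {val}")
    return report


# ---------------------------------------------------------------------------
# contrastive
# ---------------------------------------------------------------------------

def similarity(v_cls_p: Tensor, v_cls_m: Tensor, head: ProjectionHead) -> Tensor:
    """Cosine similarity of the projected CLS embeddings, in [-1, 1]."""
    zp = head.project_pocket(nn.reshape(v_cls_p, (1, -1)))
    zm = head.project_molecule(nn.reshape(v_cls_m, (1, -1)))
    return nn.reshape(nn.sum_(zp * zm, axis=-1), ())


def _diag_cross_entropy(logits: Tensor) -> Tensor:
    """Mean cross-entropy of row-wise softmax against the diagonal."""
    m = Tensor(np.max(logits.data, axis=-1, keepdims=True))
    z = logits - m
    lse = nn.log(nn.sum_(nn.exp(z), axis=-1))
    diag = nn.gather_rows(z, np.arange(z.shape[0]))
    return nn.mean_(lse - diag)


def contrastive_loss(cls_p: Tensor, cls_m: Tensor, head: ProjectionHead
                     ) -> Tuple[Tensor, Tensor]:
    """Symmetric InfoNCE over an in-batch similarity matrix.

    Row i of both inputs is the matched pair.  Returns (loss, similarity
    matrix) — the matrix is reused for hard-negative mining.
    """
    if cls_p.shape[0] == 0:
        raise ValueError("empty batch")
    sims = head.project_pocket(cls_p) @ nn.transpose(
        head.project_molecule(cls_m), (1, 0))
    logits = sims / head.tau
    l_p2m = _diag_cross_entropy(logits)
    l_m2p = _diag_cross_entropy(nn.transpose(logits, (1, 0)))
    return 0.5 * (l_p2m + l_m2p), sims


def mine_hard_negatives(sim_matrix: np.ndarray, rng: np.random.Generator,
                        strategy: str = "sample") -> List[Tuple[int, int]]:
    """Pick one hard negative per pocket and per molecule.

    For each pocket i a non-matching molecule j != i is drawn with
    probability proportional to the softmax of its off-diagonal
    similarity (strategy "sample"), or the single highest off-diagonal
    (strategy "argmax").  Symmetrically one pocket per molecule.  Returns
    (pocket_index, molecule_index) tuples; empty for N < 2.
    """
    S = np.asarray(sim_matrix, dtype=np.float64)
    N = S.shape[0]
    if N < 2:
        return []
    if strategy not in ("sample", "argmax"):
        raise ValueError(f"unknown strategy {strategy!r}")
    out: List[Tuple[int, int]] = []

    def pick(row: np.ndarray, exclude: int) -> int:
        idx = np.array([k for k in range(N) if k != exclude])
        vals = row[idx]
        if strategy == "argmax":
            return int(idx[np.argmax(vals)])
        p = np.exp(vals - vals.max())
        p /= p.sum()
        return int(rng.choice(idx, p=p))

    for i in range(N):                      # hard negative molecule per pocket
        out.append((i, pick(S[i], i)))
    for j in range(N):                      # hard negative pocket per molecule
        out.append((pick(S[:, j], j), j))
    return out


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def matching_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of matched/unmatched logits."""
    labels = np.asarray(labels)
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary")
    m = Tensor(np.max(logits.data, axis=-1, keepdims=True))
    z = logits - m
    lse = nn.log(nn.sum_(nn.exp(z), axis=-1))
    picked = nn.gather_rows(z, labels.astype(np.int64))
    return nn.mean_(lse - picked)


# ---------------------------------------------------------------------------
# docking
# ---------------------------------------------------------------------------

def huber(a: Tensor, delta: float) -> Tensor:
    """Elementwise Huber penalty: quadratic within ±delta, linear outside.

    Continuous and once-differentiable at |a| = delta (both branches give
    delta^2/2 there).
    """
    absa = nn.abs_(a)
    quad_mask = (absa.data <= delta).astype(a.dtype)
    quad = 0.5 * a * a
    lin = delta * (absa - 0.5 * delta)
    return quad * Tensor(quad_mask) + lin * Tensor(1.0 - quad_mask)


def _pair_distances(coords: Tensor, eps: float = 1e-12) -> Tensor:
    n = coords.shape[0]
    diff = nn.reshape(coords, (n, 1, 3)) - nn.reshape(coords, (1, n, 3))
    return nn.sqrt(nn.sum_(diff * diff, axis=-1) + eps)


def intra_loss(pred_coords: Tensor, true_coords: np.ndarray,
               cfg: DockingLossConfig) -> Tensor:
    """Huber loss on all unordered intra-molecular distance errors."""
    pred_coords = pred_coords if isinstance(pred_coords, Tensor) else Tensor(pred_coords)
    true_coords = np.asarray(true_coords, dtype=np.float64)
    n = pred_coords.shape[0]
    if n < 2:
        warnings.warn("intra_loss needs >= 2 atoms; defined as 0")
        return Tensor(np.zeros((), dtype=pred_coords.dtype))
    d_pred = _pair_distances(pred_coords)
    d_true = np.sqrt(((true_coords[:, None, :] - true_coords[None, :, :]) ** 2
                      ).sum(-1))
    iu = np.triu_indices(n, k=1)
    sel = np.zeros((n, n), dtype=pred_coords.dtype)
    sel[iu] = 1.0
    per_pair = huber(d_pred - Tensor(d_true.astype(pred_coords.dtype)),
                     cfg.delta) * Tensor(sel)
    return nn.sum_(per_pair) / float(len(iu[0]))


def inter_loss(pred_coords: Tensor, true_coords: np.ndarray) -> Tensor:
    """MSE on coordinates: mean over atoms of squared deviation norms (A^2)."""
    pred_coords = pred_coords if isinstance(pred_coords, Tensor) else Tensor(pred_coords)
    true_coords = np.asarray(true_coords, dtype=np.float64)
    if tuple(pred_coords.shape) != true_coords.shape:
        raise ValueError("shape mismatch between predicted and true coordinates")
    diff = pred_coords - Tensor(true_coords.astype(pred_coords.dtype))
    return nn.mean_(nn.sum_(diff * diff, axis=-1))


def total_loss(l_pmc=0.0, l_pmm=0.0, l_intra=0.0, l_inter=0.0) -> LossReport:
    """Unit-weight composition of the four components."""
    def val(x):
        return float(x.data) if isinstance(x, Tensor) else float(x)
    return check_finite(LossReport(val(l_pmc), val(l_pmm),
                                   val(l_intra), val(l_inter)))
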
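"""Dual-track graph transformer backbone.

Two coupled feature tracks run through the network:

* an *atom track* ``a_i`` (one vector per atom, initialized from the
  atom-type embedding), and
* a *pair track* ``q_ij`` (one scalar channel per attention head,
  initialized from a Gaussian RBF expansion of squared inter-atomic
  distances plus a bond-type embedding).

Each block performs pair-biased multi-head self-attention (the pair
channel enters the per-head logits additively), residual + layer norm, a
feed-forward block, and then writes the block's scaled pre-softmax
query-key logits back into the pair track (atom-to-pair communication).
Because the pair track sees only distances and bond types, every internal
representation is invariant to global rotations and translations.

Two output heads consume the pair track:

* an SE(3)-equivariant coordinate head that proposes per-atom position
  updates from the *change* in the pair track, weighting the equivariant
  difference vectors ``x_i - x_j``; and
* an invariant distance head mapping symmetrized pair features to a
  non-negative predicted distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from . import nn
from .graphs import GraphBatch, VOCAB_SIZE
from .nn import Tensor


@dataclass
class BackboneConfig:
    layers: int = 2
    heads: int = 4
    atom_dim: int = 64
    rbf_kernels: int = 16
    rbf_gammas: Optional[np.ndarray] = None  # Angstrom^-2; log-spaced bank by default
    ffn_dim: int = 128
    recycles: int = 0
    max_atoms: int = 256
    dtype: str = "float32"

    def __post_init__(self):
        if self.atom_dim % self.heads:
            raise ValueError("atom_dim must be divisible by heads")
        if self.recycles < 0:
            raise ValueError("recycles must be >= 0")
        if self.rbf_gammas is None:
            self.rbf_gammas = np.logspace(np.log10(0.01), np.log10(10.0),
                                          self.rbf_kernels)
        self.rbf_gammas = np.asarray(self.rbf_gammas, dtype=np.float64)
        if len(self.rbf_gammas) != self.rbf_kernels:
            raise ValueError("rbf_gammas length must equal rbf_kernels")
        if np.any(self.rbf_gammas <= 0):
            raise ValueError("all RBF gammas must be positive")

    @property
    def pair_channels(self) -> int:
        # one pair channel per attention head: the bias enters each
        # per-head softmax directly and each head writes one logit back
        return self.heads

    @property
    def head_dim(self) -> int:
        return self.atom_dim // self.heads

    def np_dtype(self):
        return np.dtype(self.dtype)

    def to_dict(self) -> dict:
        return {
            "layers": self.layers, "heads": self.heads,
            "atom_dim": self.atom_dim, "rbf_kernels": self.rbf_kernels,
            "rbf_gammas": self.rbf_gammas.tolist(), "ffn_dim": self.ffn_dim,
            "recycles": self.recycles, "max_atoms": self.max_atoms,
            "dtype": self.dtype,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        d = dict(d)
        d["rbf_gammas"] = np.asarray(d["rbf_gammas"])
        return cls(**d)


def rbf_encode(sq_dists: np.ndarray, gammas: np.ndarray) -> np.ndarray:
    """Gaussian RBF expansion exp(-gamma_g * d^2) of squared distances."""
    sq_dists = np.asarray(sq_dists)
    if np.any(sq_dists < 0):
        raise ValueError("negative squared distance")
    gammas = np.asarray(gammas, dtype=np.float64)
    return np.exp(-sq_dists[..., None] * gammas)


@dataclass
class EncoderOutput:
    """Everything downstream heads need from one encoder pass."""

    atom_reps: Tensor          # (B, N, d)
    pair_initial: Tensor       # (B, N, N, H) = q^0
    pair_final: Tensor         # (B, N, N, H) = q^L
    batch: GraphBatch
    cls_embedding: Optional[Tensor] = None   # (B, d) at the virtual token
    attn_logits: Optional[List[np.ndarray]] = None

    @property
    def coords_in(self) -> np.ndarray:
        return self.batch.coords


class AttentionBlock(nn.Module):
    """Pair-biased multi-head attention + FFN, post-norm, with the
    atom-to-pair update emitted alongside the atom update."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        d, f = cfg.atom_dim, cfg.ffn_dim
        dt = cfg.np_dtype()
        self.cfg = cfg
        self.wq = nn.glorot(rng, (d, d), dt)
        self.wk = nn.glorot(rng, (d, d), dt)
        self.wv = nn.glorot(rng, (d, d), dt)
        self.wo = nn.glorot(rng, (d, d), dt)
        self.bq = nn.zeros_param((d,), dt)
        self.bk = nn.zeros_param((d,), dt)
        self.bv = nn.zeros_param((d,), dt)
        self.bo = nn.zeros_param((d,), dt)
        self.ln1_g = nn.ones_param((d,), dt)
        self.ln1_b = nn.zeros_param((d,), dt)
        self.w1 = nn.glorot(rng, (d, f), dt)
        self.b1 = nn.zeros_param((f,), dt)
        self.w2 = nn.glorot(rng, (f, d), dt)
        self.b2 = nn.zeros_param((d,), dt)
        self.ln2_g = nn.ones_param((d,), dt)
        self.ln2_b = nn.zeros_param((d,), dt)

    def __call__(self, x: Tensor, pair: Tensor, mask: np.ndarray):
        """One block.  ``mask`` is (B, N) validity.  Returns
        (atom reps, next pair tensor, pre-softmax biased logits as numpy)."""
        cfg = self.cfg
        B, N, d = x.shape
        H, dh = cfg.heads, cfg.head_dim
        scale = 1.0 / np.sqrt(dh)

        def split_heads(t):  # (B,N,d) -> (B,H,N,dh)
            return nn.transpose(nn.reshape(t, (B, N, H, dh)), (0, 2, 1, 3))

        q = split_heads(x @ self.wq + self.bq)
        k = split_heads(x @ self.wk + self.bk)
        v = split_heads(x @ self.wv + self.bv)

        qk = (q @ nn.transpose(k, (0, 1, 3, 2))) * scale      # (B,H,N,N)
        bias = nn.transpose(pair, (0, 3, 1, 2))               # (B,H,N,N)
        logits = qk + bias
        if np.any(np.isnan(logits.data)):
            raise FloatingPointError("NaN in attention logits")
        neg = np.where(mask[:, None, None, :], 0.0, -1e9).astype(x.dtype)
        att = nn.softmax(logits + Tensor(neg), axis=-1)
        ctx = att @ v                                          # (B,H,N,dh)
        ctx = nn.reshape(nn.transpose(ctx, (0, 2, 1, 3)), (B, N, d))
        x = nn.layer_norm(x + (ctx @ self.wo + self.bo), self.ln1_g, self.ln1_b)
        ff = nn.relu(x @ self.w1 + self.b1) @ self.w2 + self.b2
        x = nn.layer_norm(x + ff, self.ln2_g, self.ln2_b)

        # atom-to-pair communication: add this block's scaled pre-softmax,
        # pre-mask query-key logits (without the incoming bias)
        pair_next = pair + nn.transpose(qk, (0, 2, 3, 1))
        return x, pair_next, logits.data


def pair_update(pair: Tensor, q: Tensor, k: Tensor, head_dim: int) -> Tensor:
    """Standalone atom-to-pair update: q^{l+1} = q^l + (Q K^T)/sqrt(d_H).

    ``q``/``k`` are (B, H, N, dh) per-head projections of the same layer.
    """
    qk = (q @ nn.transpose(k, (0, 1, 3, 2))) * (1.0 / np.sqrt(head_dim))
    return pair + nn.transpose(qk, (0, 2, 3, 1))


class Encoder(nn.Module):
    """A stack of attention blocks with RBF + bond pair initialization."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        dt = cfg.np_dtype()
        self.cfg = cfg
        self.embed = Tensor(rng.normal(0, 0.02, (VOCAB_SIZE, cfg.atom_dim)
                                       ).astype(dt), requires_grad=True)
        self.pair_w = nn.glorot(rng, (cfg.rbf_kernels, cfg.heads), dt)
        self.pair_b = nn.zeros_param((cfg.heads,), dt)
        # rows for bond codes 1..4; no-bond contributes a zero vector
        self.bond_embed = Tensor(rng.normal(0, 0.02, (4, cfg.heads)).astype(dt),
                                 requires_grad=True)
        self.blocks = [AttentionBlock(cfg, rng) for _ in range(cfg.layers)]

    # ------------------------------------------------------------------
    def init_pair(self, gb: GraphBatch) -> Tensor:
        """q^0 from RBF-encoded distances plus bond-type embeddings.

        Fully connected: every ordered pair, including pairs involving
        virtual atoms at their centroid coordinates.
        """
        cfg = self.cfg
        diff = gb.coords[:, :, None, :] - gb.coords[:, None, :, :]
        sq = (diff * diff).sum(-1)
        feats = rbf_encode(sq, cfg.rbf_gammas).astype(cfg.np_dtype())
        onehot = np.zeros(gb.bond_codes.shape + (4,), dtype=cfg.np_dtype())
        for c in range(1, 5):
            onehot[..., c - 1] = gb.bond_codes == c
        return Tensor(feats) @ self.pair_w + self.pair_b \
            + Tensor(onehot) @ self.bond_embed

    def __call__(self, gb: GraphBatch, collect_logits: bool = False
                 ) -> EncoderOutput:
        cfg = self.cfg
        if gb.max_n > cfg.max_atoms:
            raise ValueError(f"batch width {gb.max_n} exceeds max_atoms={cfg.max_atoms}")
        x = nn.embedding(self.embed, gb.atom_types)
        pair0 = self.init_pair(gb)
        pair = pair0
        logits_trace = [] if collect_logits else None
        for block in self.blocks:
            x, pair, logits = block(x, pair, gb.mask)
            if collect_logits:
                logits_trace.append(logits)
        cls = None
        if np.all(gb.token_index >= 0):
            cls = nn.gather_rows(x, gb.token_index)
        return EncoderOutput(atom_reps=x, pair_initial=pair0, pair_final=pair,
                             batch=gb, cls_embedding=cls,
                             attn_logits=logits_trace)


class CoordinateHead(nn.Module):
    """SE(3)-equivariant coordinate update head.

    A scalar coupling ``c_ij = ReLU((q^L_ij - q^0_ij) U) W`` weights the
    equivariant difference vectors:  ``x_i <- x_i + (1/n) sum_j (x_i - x_j)
    c_ij`` with j over all real atoms in context and n the per-sample real
    atom count.  No bias terms, so an unchanged pair track proposes no
    movement.
    """

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator,
                 hidden: int = 64):
        dt = cfg.np_dtype()
        self.u = Tensor(rng.normal(0, 0.1, (cfg.heads, hidden)).astype(dt),
                        requires_grad=True)
        self.w = Tensor(rng.normal(0, 0.01, (hidden, 1)).astype(dt),
                        requires_grad=True)

    def couplings(self, enc: EncoderOutput) -> Tensor:
        dq = enc.pair_final - enc.pair_initial
        c = nn.relu(dq @ self.u) @ self.w           # (B,N,N,1)
        return nn.reshape(c, c.shape[:3])

    def __call__(self, enc: EncoderOutput,
                 movable_mask: np.ndarray) -> Tensor:
        """Predicted coordinates (B, N, 3); only movable atoms change."""
        gb = enc.batch
        ctx = gb.real_mask                          # context j: real atoms only
        n_ctx = ctx.sum(axis=1)
        if np.any(n_ctx == 0):
            raise ValueError("empty context for coordinate head")
        c = self.couplings(enc) * Tensor(ctx[:, None, :].astype(
            enc.pair_final.dtype))
        diff = (gb.coords[:, :, None, :] - gb.coords[:, None, :, :]).astype(
            enc.pair_final.dtype)
        disp = nn.sum_(c.reshape(c.shape + (1,)) * Tensor(diff), axis=2)
        disp = disp * Tensor((movable_mask[..., None] /
                              n_ctx[:, None, None]).astype(enc.pair_final.dtype))
        return Tensor(gb.coords.astype(enc.pair_final.dtype)) + disp


class DistanceHead(nn.Module):
    """Invariant pair MLP projecting symmetrized pair features into a
    non-negative predicted distance matrix (diagonal forced to zero)."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator,
                 hidden: int = 64):
        dt = cfg.np_dtype()
        self.w1 = nn.glorot(rng, (cfg.heads, hidden), dt)
        self.b1 = nn.zeros_param((hidden,), dt)
        self.w2 = nn.glorot(rng, (hidden, 1), dt)
        self.b2 = nn.zeros_param((1,), dt)

    def __call__(self, enc: EncoderOutput) -> Tensor:
        q = enc.pair_final
        sym = (q + nn.transpose(q, (0, 2, 1, 3))) * 0.5
        h = nn.relu(sym @ self.w1 + self.b1) @ self.w2 + self.b2
        d = nn.softplus(nn.reshape(h, h.shape[:3]))
        N = d.shape[-1]
        off_diag = (1.0 - np.eye(N, dtype=d.dtype))[None, :, :]
        valid = enc.batch.mask
        pm = (valid[:, :, None] & valid[:, None, :]).astype(d.dtype)
        return d * Tensor(off_diag * pm)
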
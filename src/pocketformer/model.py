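"""The full multi-task interaction model.

Two encoder stacks share one architecture: a *pocket encoder* and a
*molecular encoder*.  Separate-encoder passes (one entity at a time, with
a CLS token) feed the contrastive projection heads; joint passes
concatenate pocket and molecule atoms into one fully connected graph and
run through the molecular encoder, feeding the matching classifier (via
the ENCODE token), the coordinate head, and the distance head.

The docking score of a pose is the negative mean displacement the
coordinate head proposes for the ligand at that pose: a model trained on
the docking objective proposes large movements for poses far from the
binding mode and almost none for near-native poses, so "little proposed
movement" ranks poses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from . import nn
from .backbone import (BackboneConfig, CoordinateHead, DistanceHead, Encoder,
                       EncoderOutput)
from .graphs import (AtomGraph, batch as make_batch, insert_virtual_atom,
                     make_joint)
from .nn import Tensor

MODEL_VERSION = "1"


class ProjectionHead(nn.Module):
    """Linear maps g_P, g_M into a shared k-dim space plus a learnable
    temperature (parameterized as exp(log tau) to stay positive)."""

    def __init__(self, atom_dim: int, proj_dim: int, rng: np.random.Generator,
                 dtype, tau_init: float = 0.07):
        self.wp = nn.glorot(rng, (atom_dim, proj_dim), dtype)
        self.bp = nn.zeros_param((proj_dim,), dtype)
        self.wm = nn.glorot(rng, (atom_dim, proj_dim), dtype)
        self.bm = nn.zeros_param((proj_dim,), dtype)
        self.log_tau = Tensor(np.array(np.log(tau_init), dtype=dtype),
                              requires_grad=True)

    @property
    def tau(self) -> Tensor:
        return nn.exp(self.log_tau)

    def project_pocket(self, v: Tensor) -> Tensor:
        return _l2_normalize(v @ self.wp + self.bp)

    def project_molecule(self, v: Tensor) -> Tensor:
        return _l2_normalize(v @ self.wm + self.bm)


def _l2_normalize(v: Tensor) -> Tensor:
    sq = nn.sum_(v * v, axis=-1, keepdims=True)
    norms = np.sqrt(sq.data)
    if np.any(norms < 1e-12):
        raise ValueError("zero-norm projection")
    return v / nn.sqrt(sq)


class InteractionModel(nn.Module):
    """Pocket encoder + molecular encoder + task heads."""

    def __init__(self, cfg: BackboneConfig, proj_dim: int = 128, seed: int = 0):
        dt = cfg.np_dtype()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.proj_dim = proj_dim
        self.seed = seed
        self.pocket_encoder = Encoder(cfg, rng)
        self.mol_encoder = Encoder(cfg, rng)
        self.proj = ProjectionHead(cfg.atom_dim, proj_dim, rng, dt)
        self.match_w = nn.glorot(rng, (cfg.atom_dim, 2), dt)
        self.match_b = nn.zeros_param((2,), dt)
        self.coord_head = CoordinateHead(cfg, rng)
        self.dist_head = DistanceHead(cfg, rng)

    # ------------------------------------------------------------------
    # separate-encoder passes
    # ------------------------------------------------------------------
    def encode_pockets(self, pockets: Sequence[AtomGraph], **kw) -> EncoderOutput:
        graphs = [p if p.has_virtual("CLS") else insert_virtual_atom(p, "CLS")
                  for p in pockets]
        return self.pocket_encoder(make_batch(graphs, self.cfg.max_atoms), **kw)

    def encode_molecules(self, mols: Sequence[AtomGraph], **kw) -> EncoderOutput:
        graphs = [m if m.has_virtual("CLS") else insert_virtual_atom(m, "CLS")
                  for m in mols]
        return self.mol_encoder(make_batch(graphs, self.cfg.max_atoms), **kw)

    # ------------------------------------------------------------------
    # joint passes (through the molecular encoder)
    # ------------------------------------------------------------------
    def encode_joint(self, pairs: Sequence[Tuple[AtomGraph, AtomGraph]],
                     encode_token: bool = False,
                     molecule_coords: Optional[Sequence[np.ndarray]] = None,
                     **kw) -> EncoderOutput:
        graphs, segs = [], []
        for idx, (p, m) in enumerate(pairs):
            mc = None if molecule_coords is None else molecule_coords[idx]
            g, s = make_joint(p, m, encode_token=encode_token,
                              molecule_coords=mc)
            graphs.append(g)
            segs.append(s)
        gb = make_batch(graphs, self.cfg.max_atoms, segments=segs)
        return self.mol_encoder(gb, **kw)

    # ------------------------------------------------------------------
    # heads
    # ------------------------------------------------------------------
    def similarity_matrix(self, cls_p: Tensor, cls_m: Tensor) -> Tensor:
        """(N_pockets, N_molecules) cosine similarities in [-1, 1]."""
        zp = self.proj.project_pocket(cls_p)
        zm = self.proj.project_molecule(cls_m)
        return zp @ nn.transpose(zm, (1, 0))

    def match_logits(self, enc: EncoderOutput) -> Tensor:
        """Binary matched/unmatched logits from the ENCODE embedding."""
        if enc.cls_embedding is None:
            raise ValueError("joint pass lacks the ENCODE token")
        return enc.cls_embedding @ self.match_w + self.match_b

    def predict_coords(self, enc: EncoderOutput) -> Tensor:
        """Apply the coordinate head to real molecule atoms of a joint pass."""
        gb = enc.batch
        movable = gb.real_mask & (gb.segments == 1)
        return self.coord_head(enc, movable)

    def proposed_displacement(self, enc: EncoderOutput) -> np.ndarray:
        """Mean ligand displacement magnitude (A) the head proposes, per sample."""
        gb = enc.batch
        movable = gb.real_mask & (gb.segments == 1)
        with nn.no_grad():
            coords = self.coord_head(enc, movable).data
        disp = np.linalg.norm(coords - gb.coords, axis=-1)
        return (disp * movable).sum(axis=1) / movable.sum(axis=1)

    def docking_score(self, pocket: AtomGraph, molecule: AtomGraph,
                      molecule_coords: Optional[np.ndarray] = None) -> float:
        """Score a pose: negative mean proposed displacement (higher = better)."""
        with nn.no_grad():
            enc = self.encode_joint([(pocket, molecule)],
                                    molecule_coords=None if molecule_coords is None
                                    else [molecule_coords])
            return float(-self.proposed_displacement(enc)[0])

    # ------------------------------------------------------------------
    def no_decay_predicate(self):
        def pred(name: str) -> bool:
            leaf = name.rsplit(".", 1)[-1]
            is_bias = leaf.endswith("_b") or (len(leaf) == 2 and leaf[0] == "b")
            return leaf.startswith("ln") or leaf == "log_tau" or is_bias
        return pred
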
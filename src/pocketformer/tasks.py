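"""Task modes: virtual screening, target fishing, docking, pose ranking.

Screening runs the two *separate* encoders and ranks a molecule library
by projected-CLS similarity to the pocket.  Target fishing runs a joint
pocket-grounded pass per candidate pocket and ranks by the matched-class
probability.  Docking applies the equivariant coordinate head
iteratively (recycling); the docking score of a pose is the negative
mean displacement the head proposes at that pose, so near-native poses
score highest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import nn
from .graphs import AtomGraph, ComplexPair, GraphError
from .metrics import make_score_table, rmsd
from .model import InteractionModel


@dataclass
class PoseResult:
    """Outcome of one docking run."""

    predicted_coords: np.ndarray
    docking_score: float
    rmsd_to_truth: Optional[float] = None
    recycle_trace: List[np.ndarray] = field(default_factory=list)


def screen_library(pocket: AtomGraph, molecules: Sequence[AtomGraph],
                   model: InteractionModel, chunk: int = 64) -> pd.DataFrame:
    """Similarity-rank a molecule library against one pocket.

    The pocket is encoded once; molecules are encoded in chunks through
    the molecular encoder only (no joint pass).
    """
    molecules = list(molecules)
    if not molecules:
        raise GraphError("empty molecule library")
    with nn.no_grad():
        enc_p = model.encode_pockets([pocket])
        zp = model.proj.project_pocket(enc_p.cls_embedding).data  # (1, k)
        scores = []
        for start in range(0, len(molecules), chunk):
            enc_m = model.encode_molecules(molecules[start:start + chunk])
            zm = model.proj.project_molecule(enc_m.cls_embedding).data
            scores.extend((zm @ zp[0]).tolist())
    ids = [m.source_id or f"mol{i}" for i, m in enumerate(molecules)]
    return make_score_table(ids, scores)


def fish_targets(molecule: AtomGraph, pockets: Sequence[AtomGraph],
                 model: InteractionModel,
                 labels: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """Rank candidate pockets for one molecule by matching probability.

    The molecule (with an ENCODE token) is placed at each candidate
    pocket's centroid for the joint pass.
    """
    pockets = list(pockets)
    if not pockets:
        raise GraphError("empty pocket list")
    lig = molecule.strip_virtual()
    scores = []
    with nn.no_grad():
        for pocket in pockets:
            site = pocket.strip_virtual().coords.mean(axis=0)
            coords = lig.coords - lig.coords.mean(axis=0) + site
            enc = model.encode_joint([(pocket, lig)], encode_token=True,
                                     molecule_coords=[coords])
            logits = model.match_logits(enc).data[0]
            z = logits - logits.max()
            p = np.exp(z)
            scores.append(float(p[1] / p.sum()))
    ids = [p.source_id or f"pocket{i}" for i, p in enumerate(pockets)]
    return make_score_table(ids, scores, labels=labels)


def dock(pair: ComplexPair, model: InteractionModel,
         recycles: Optional[int] = None,
         initial_coords: Optional[np.ndarray] = None) -> PoseResult:
    """Move the ligand with the coordinate head, re-encoding each round.

    ``recycles`` = R means R+1 coordinate-head applications; the score is
    computed in a final scoring pass at the resulting pose (no movement
    applied there).
    """
    if recycles is None:
        recycles = max(model.cfg.recycles, 0)
    lig = pair.molecule.strip_virtual()
    coords = (lig.coords if initial_coords is None
              else np.asarray(initial_coords, dtype=np.float64)).copy()
    if coords.shape != (lig.n_atoms, 3):
        raise GraphError("initial coords shape mismatch")
    trace = [coords.copy()]
    with nn.no_grad():
        for _ in range(recycles + 1):
            enc = model.encode_joint([(pair.pocket, lig)],
                                     molecule_coords=[coords])
            pred = model.predict_coords(enc).data[0]
            seg = enc.batch.segments[0]
            real = enc.batch.real_mask[0]
            coords = pred[real & (seg == 1)].astype(np.float64)
            trace.append(coords.copy())
    score = model.docking_score(pair.pocket, lig, coords)
    out_rmsd = None
    if pair.true_ligand_coords is not None:
        out_rmsd = rmsd(coords, pair.true_ligand_coords)
    return PoseResult(predicted_coords=coords, docking_score=score,
                      rmsd_to_truth=out_rmsd, recycle_trace=trace)


def rank_poses(pair: ComplexPair, candidate_poses: Sequence[np.ndarray],
               model: InteractionModel,
               pose_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Score candidate poses without moving atoms and rank them.

    Each pose must share the molecule's topology (one row per real atom).
    When the pair carries a true pose, per-pose RMSDs are annotated so
    the table feeds the top-k success-rate protocol directly.
    """
    lig = pair.molecule.strip_virtual()
    scores, rmsds = [], []
    for pose in candidate_poses:
        pose = np.asarray(pose, dtype=np.float64)
        if pose.shape != (lig.n_atoms, 3):
            raise GraphError(f"pose shape {pose.shape} does not match "
                             f"molecule ({lig.n_atoms}, 3)")
        scores.append(model.docking_score(pair.pocket, lig, pose))
        if pair.true_ligand_coords is not None:
            rmsds.append(rmsd(pose, pair.true_ligand_coords))
    ids = (list(pose_ids) if pose_ids is not None
           else [f"pose{i}" for i in range(len(scores))])
    return make_score_table(ids, scores,
                            rmsds=rmsds if rmsds else None)
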
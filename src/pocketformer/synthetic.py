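"""Seeded lock-and-key complex generator.

Pocket atoms sit on a partial spherical shell around the origin; the
ligand is a self-avoiding 1.5-Angstrom-step chain inside the cavity.
Each ligand atom's element is the *complement* (a fixed permutation over
the type vocabulary) of its nearest pocket atom's element, so matched
pairs carry a geometric + chemical complementarity signal that a
hand-coded nearest-neighbour classifier — and therefore a trained model —
can detect.  Mismatched pairs swap ligands between pockets; decoy poses
are rigid perturbations of the true pose dialed to a target RMSD.

Everything is a pure function of (spec, seed, call sequence): single
threaded, bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .fileio import write_complexes
from .graphs import AtomGraph, ComplexPair, ELEMENTS, GraphError
from .metrics import rmsd


@dataclass
class SyntheticSpec:
    """Parameterization of the lock-and-key generator.

    Defaults give 48 shell atoms at 7 A around a 4 A cavity holding a
    12-atom chain ligand over a 6-element vocabulary with 0.1 A jitter —
    small enough that joint pocket+ligand attention stays fast.
    """

    n_pocket_atoms: int = 48
    n_ligand_atoms: int = 12
    cavity_radius: float = 4.0
    shell_radius: float = 7.0
    type_vocab_size: int = 6
    complementarity_map: Optional[Tuple[int, ...]] = None
    coord_noise_sigma: float = 0.1
    seed: int = 0

    bond_length: float = 1.5
    min_separation: float = 1.2
    residue_size: int = 4

    def __post_init__(self):
        if not (self.shell_radius > self.cavity_radius > 0):
            raise ValueError("need shell_radius > cavity_radius > 0")
        if self.n_pocket_atoms < 3 or self.n_ligand_atoms < 3:
            raise ValueError("atom counts must be >= 3")
        if self.coord_noise_sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.type_vocab_size > len(ELEMENTS):
            raise ValueError(f"vocab larger than element set ({len(ELEMENTS)})")
        if self.complementarity_map is None:
            v = self.type_vocab_size
            self.complementarity_map = tuple((i + 1) % v for i in range(v))
        cm = tuple(self.complementarity_map)
        if sorted(cm) != list(range(self.type_vocab_size)):
            raise ValueError("complementarity_map must be a permutation")
        self.complementarity_map = cm

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self).items()}


def _sample_shell(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Points on a partial shell (cos(polar) > -0.5: an opening remains)."""
    pts = []
    while len(pts) < spec.n_pocket_atoms:
        u = rng.uniform(-0.5, 1.0)
        phi = rng.uniform(0, 2 * np.pi)
        s = np.sqrt(1 - u * u)
        pts.append([s * np.cos(phi), s * np.sin(phi), u])
    return spec.shell_radius * np.asarray(pts)


def _grow_chain(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding chain of fixed-length steps inside the cavity."""
    limit = spec.cavity_radius - 3.0 * spec.coord_noise_sigma - 0.2
    for _ in range(40):  # chain restarts
        start = rng.normal(0, 0.3, 3)
        chain = [start]
        ok = True
        for _ in range(spec.n_ligand_atoms - 1):
            placed = False
            for _ in range(60):  # candidate directions
                d = rng.normal(0, 1, 3)
                d /= np.linalg.norm(d)
                cand = chain[-1] + spec.bond_length * d
                if np.linalg.norm(cand) >= limit:
                    continue
                if len(chain) > 1:
                    dists = np.linalg.norm(np.asarray(chain[:-1]) - cand, axis=1)
                    if dists.min() < spec.min_separation:
                        continue
                chain.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(chain)
    raise GraphError("cannot fit ligand chain in cavity; increase cavity_radius")


def generate_complex(spec: SyntheticSpec,
                     rng: Optional[np.random.Generator] = None,
                     pair_id: str = "") -> ComplexPair:
    """One matched pocket-ligand complex (label 1, true pose recorded)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    shell = _sample_shell(spec, rng)
    pocket_types = rng.integers(0, spec.type_vocab_size, spec.n_pocket_atoms)
    chain = _grow_chain(spec, rng)
    nearest = np.argmin(cdist(chain, shell), axis=1)
    cm = np.asarray(spec.complementarity_map)
    ligand_types = cm[pocket_types[nearest]]
    if spec.coord_noise_sigma > 0:
        shell = shell + rng.normal(0, spec.coord_noise_sigma, shell.shape)
        chain = chain + rng.normal(0, spec.coord_noise_sigma, chain.shape)
    if cdist(chain, shell).min() < 1.0:
        raise GraphError("pocket-ligand clash; widen shell/cavity gap")
    rid = [f"RES{i // spec.residue_size}" for i in range(spec.n_pocket_atoms)]
    pid = pair_id or f"synth-{spec.seed}"
    pocket = AtomGraph(entity_role="pocket", atom_types=pocket_types,
                       coords=shell, residue_ids=tuple(rid),
                       source_id=f"{pid}:pocket")
    bonds = tuple((i, i + 1, 1) for i in range(spec.n_ligand_atoms - 1))
    mol = AtomGraph(entity_role="molecule", atom_types=ligand_types,
                    coords=chain, bonds=bonds, source_id=f"{pid}:ligand")
    return ComplexPair(pocket=pocket, molecule=mol, match_label=1,
                       true_ligand_coords=chain.copy(), pair_id=pid)


def make_negative_pair(a: ComplexPair, b: ComplexPair,
                       rng: Optional[np.random.Generator] = None) -> ComplexPair:
    """a's pocket with b's ligand recentered into a's binding site (label 0)."""
    if a.pair_id == b.pair_id and a.pair_id:
        raise GraphError("negative pair needs two distinct complexes")
    if np.array_equal(a.molecule.coords, b.molecule.coords) and \
            np.array_equal(a.molecule.atom_types, b.molecule.atom_types):
        raise GraphError("negative pair needs two distinct complexes")
    site = a.true_ligand_coords.mean(axis=0) if a.true_ligand_coords is not None \
        else np.zeros(3)
    lig = b.molecule.strip_virtual()
    coords = lig.coords - lig.coords.mean(axis=0) + site
    mol = AtomGraph(entity_role="molecule", atom_types=lig.atom_types,
                    coords=coords, bonds=lig.bonds,
                    source_id=lig.source_id)
    return ComplexPair(pocket=a.pocket, molecule=mol, match_label=0,
                       true_ligand_coords=None,
                       pair_id=f"{a.pair_id}x{b.pair_id}")


def perturb_pose(coords: np.ndarray, rng: np.random.Generator,
                 max_angle: float, trans_sigma: float) -> np.ndarray:
    """Random rigid motion about the centroid (rotation + translation)."""
    coords = np.asarray(coords, dtype=np.float64)
    angle = rng.uniform(0, max_angle)
    axis = rng.normal(0, 1, 3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.normal(0, trans_sigma, 3)
    c = coords.mean(axis=0)
    return (coords - c) @ R.T + c + t


def make_decoy_pose(pair: ComplexPair, rmsd_target: float,
                    rng: np.random.Generator, jitter: float = 0.0
                    ) -> np.ndarray:
    """A rigid decoy of the true pose at (within 10% of) a target RMSD.

    A random rotation + translation is scaled by bisection on an
    interpolation parameter until the plain RMSD to the true pose hits
    the target; exact for target 0.
    """
    if pair.true_ligand_coords is None:
        raise GraphError("decoys need a true pose")
    if rmsd_target < 0:
        raise ValueError("rmsd_target must be >= 0")
    truth = pair.true_ligand_coords
    if rmsd_target == 0:
        return truth.copy()
    c = truth.mean(axis=0)
    pose = truth.copy()
    achieved = 0.0

    for _ in range(20):
        angle = rng.uniform(0.3, np.pi)
        axis = rng.normal(0, 1, 3)
        axis /= np.linalg.norm(axis)
        tdir = rng.normal(0, 1, 3)
        tdir /= np.linalg.norm(tdir)
        tmag = rng.uniform(0.5, 1.5) * rmsd_target

        def pose_at(s: float) -> np.ndarray:
            R = Rotation.from_rotvec(s * angle * axis).as_matrix()
            out = (truth - c) @ R.T + c + s * tmag * tdir
            if jitter > 0:
                out = out + jit
            return out

        jit = rng.normal(0, jitter, truth.shape) if jitter > 0 else 0.0
        full = pose_at(1.0)
        reach = rmsd(full, truth)
        if reach < rmsd_target:
            if reach > achieved:  # best-effort fallback
                pose, achieved = full, reach
            continue  # this transform cannot reach the target; redraw
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if rmsd(pose_at(mid), truth) < rmsd_target:
                lo = mid
            else:
                hi = mid
        pose = pose_at(0.5 * (lo + hi))
        achieved = rmsd(pose, truth)
        if abs(achieved - rmsd_target) <= 0.1 * rmsd_target:
            return pose
    warnings.warn(f"decoy target {rmsd_target} A not reached; "
                  f"returning pose at {achieved:.2f} A")
    return pose


def make_docking_set(pairs: Sequence[ComplexPair],
                     rng: np.random.Generator,
                     start_rmsds: Sequence[float] = (0.0, 2.0)
                     ) -> List[ComplexPair]:
    """Docking fine-tuning examples with fixed decoy start poses.

    For each matched complex and each start RMSD a new pair is emitted
    whose molecule sits at a rigid decoy pose while the true pose stays
    the target — the model learns to propose zero movement at the native
    pose and progressively larger corrections further from it.
    """
    out: List[ComplexPair] = []
    for pair in pairs:
        if pair.true_ligand_coords is None:
            raise GraphError("docking set needs true poses")
        for r in start_rmsds:
            start = make_decoy_pose(pair, r, rng)
            mol = AtomGraph(entity_role="molecule",
                            atom_types=pair.molecule.atom_types,
                            coords=start, bonds=pair.molecule.bonds,
                            source_id=pair.molecule.source_id)
            out.append(ComplexPair(pocket=pair.pocket, molecule=mol,
                                   match_label=1,
                                   true_ligand_coords=pair.true_ligand_coords,
                                   pair_id=f"{pair.pair_id}@{r:g}A"))
    return out


def complementarity_fraction(pocket: AtomGraph, molecule: AtomGraph,
                             comp_map: Tuple[int, ...],
                             molecule_coords: Optional[np.ndarray] = None
                             ) -> float:
    """Hand-coded oracle: fraction of ligand atoms whose element equals the
    complement of their nearest pocket atom's element.  Bounds from above
    the signal a learned model can exploit."""
    cm = np.asarray(comp_map)
    pk = pocket.strip_virtual()
    lig = molecule.strip_virtual()
    coords = lig.coords if molecule_coords is None else molecule_coords
    nearest = np.argmin(cdist(coords, pk.coords), axis=1)
    return float(np.mean(cm[pk.atom_types[nearest]] == lig.atom_types))


def generate_dataset(spec: SyntheticSpec, n_complexes: int,
                     actives_per_pocket: int, decoys_per_pocket: int,
                     rng: Optional[np.random.Generator] = None,
                     out_dir: Optional[Path] = None) -> dict:
    """Matched complexes plus per-pocket screening libraries.

    Actives are fresh complementary ligands grown in the same pocket;
    decoys are ligands generated against *other* pockets, recentered.
    Returns a manifest (spec, seed, counts, digests); when ``out_dir`` is
    given the JSON-lines files are written there.
    """
    if min(n_complexes, actives_per_pocket, decoys_per_pocket) < 1:
        raise ValueError("counts must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    complexes = [generate_complex(spec, rng, pair_id=f"cpx{i:03d}")
                 for i in range(n_complexes)]

    libraries: List[List[ComplexPair]] = []
    for i, base in enumerate(complexes):
        lib = []
        for j in range(actives_per_pocket):
            # a fresh complementary ligand grown inside the same pocket
            shell = base.pocket.coords
            chain = _grow_chain(spec, rng)
            nearest = np.argmin(cdist(chain, shell), axis=1)
            cm = np.asarray(spec.complementarity_map)
            types = cm[base.pocket.atom_types[nearest]]
            if spec.coord_noise_sigma > 0:
                chain = chain + rng.normal(0, spec.coord_noise_sigma, chain.shape)
            bonds = tuple((k, k + 1, 1) for k in range(spec.n_ligand_atoms - 1))
            mol = AtomGraph(entity_role="molecule", atom_types=types,
                            coords=chain, bonds=bonds,
                            source_id=f"cpx{i:03d}:act{j}")
            lib.append(ComplexPair(pocket=base.pocket, molecule=mol,
                                   match_label=1, true_ligand_coords=chain,
                                   pair_id=f"cpx{i:03d}:act{j}"))
        others = [k for k in range(n_complexes) if k != i]
        for j in range(decoys_per_pocket):
            k = int(rng.choice(others))
            neg = make_negative_pair(base, complexes[k])
            lib.append(ComplexPair(pocket=base.pocket, molecule=neg.molecule,
                                   match_label=0,
                                   pair_id=f"cpx{i:03d}:dec{j}"))
        libraries.append(lib)

    manifest = {
        "spec": spec.to_dict(),
        "seed": spec.seed,
        "n_complexes": n_complexes,
        "actives_per_pocket": actives_per_pocket,
        "decoys_per_pocket": decoys_per_pocket,
        "files": {},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cpath = out_dir / "complexes.jsonl"
        manifest["files"]["complexes.jsonl"] = write_complexes(complexes, cpath)
        lpath = out_dir / "screening.jsonl"
        flat = [p for lib in libraries for p in lib]
        manifest["files"]["screening.jsonl"] = write_complexes(flat, lpath)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["complexes"] = complexes
    manifest["libraries"] = libraries
    return manifest
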
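"""Typed 3D atom graphs for binding pockets and small molecules.

A pocket or molecule is an :class:`AtomGraph`: element-typed atoms with
Cartesian coordinates in Angstrom, optional chemical bonds (molecules
only), and optional *virtual* atoms — CLS / ENCODE summary tokens placed
at the centroid of the real atoms.  A matched (or mismatched) pocket +
molecule with an optional ground-truth ligand pose is a
:class:`ComplexPair`.  :func:`batch` pads a list of graphs into dense
arrays for the encoder.

Conventions: coordinates in Angstrom; 0-based indices everywhere except
inside file formats; hydrogens are dropped on input; atom vocabulary is
element-only plus four reserved virtual-token codes, one per
(token kind x entity role).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

ELEMENTS: Tuple[str, ...] = ("C", "N", "O", "S", "P", "F")
ELEMENT_CODES = {e: i for i, e in enumerate(ELEMENTS)}

TOKEN_KINDS = ("CLS", "ENCODE")
ENTITY_ROLES = ("pocket", "molecule")

# one reserved code per (token kind, entity role)
VIRTUAL_CODES = {
    ("CLS", "pocket"): len(ELEMENTS) + 0,
    ("CLS", "molecule"): len(ELEMENTS) + 1,
    ("ENCODE", "pocket"): len(ELEMENTS) + 2,
    ("ENCODE", "molecule"): len(ELEMENTS) + 3,
}
VOCAB_SIZE = len(ELEMENTS) + len(VIRTUAL_CODES)

BOND_TYPES = ("single", "double", "triple", "aromatic")
BOND_CODES = {b: i + 1 for i, b in enumerate(BOND_TYPES)}  # 0 = no bond
BOND_NAMES = {v: k for k, v in BOND_CODES.items()}


class GraphError(ValueError):
    pass


@dataclass(frozen=True)
class AtomGraph:
    """A 3D atom graph for one pocket or one molecule.

    ``atom_types`` are vocabulary codes (elements first, reserved virtual
    codes after).  ``bonds`` is a tuple of ``(i, j, bond_code)`` with
    ``i < j``; pockets carry no bonds.  ``residue_ids`` (pockets only)
    gives per-atom residue labels used by the pocket-filter rules.
    """

    entity_role: str
    atom_types: np.ndarray
    coords: np.ndarray
    bonds: Tuple[Tuple[int, int, int], ...] = ()
    virtual_flags: Optional[np.ndarray] = None
    source_id: str = ""
    residue_ids: Optional[Tuple[str, ...]] = None

    def __post_init__(self):
        object.__setattr__(self, "atom_types", np.asarray(self.atom_types, dtype=np.int64))
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=np.float64))
        n = len(self.atom_types)
        if self.virtual_flags is None:
            object.__setattr__(self, "virtual_flags", np.zeros(n, dtype=bool))
        else:
            object.__setattr__(self, "virtual_flags", np.asarray(self.virtual_flags, dtype=bool))
        if self.entity_role not in ENTITY_ROLES:
            raise GraphError(f"unknown entity_role {self.entity_role!r}")
        if self.coords.shape != (n, 3):
            raise GraphError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise GraphError("non-finite coordinates")
        if n == 0 or self.n_real < 1:
            raise GraphError("graph needs at least one real atom")
        virt = self.virtual_flags
        for i, j, b in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise GraphError(f"invalid bond endpoints ({i}, {j})")
            if b not in BOND_NAMES:
                raise GraphError(f"unknown bond code {b}")
            if virt[i] or virt[j]:
                raise GraphError("virtual atoms carry no chemical bonds")
        vcodes = self.atom_types[virt]
        if len(vcodes) != len(set(vcodes.tolist())):
            raise GraphError("at most one virtual atom per token kind")
        if self.residue_ids is not None and len(self.residue_ids) != n:
            raise GraphError("residue_ids length mismatch")

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_types)

    @property
    def n_real(self) -> int:
        return int((~self.virtual_flags).sum())

    @property
    def real_mask(self) -> np.ndarray:
        return ~self.virtual_flags

    @property
    def real_coords(self) -> np.ndarray:
        return self.coords[self.real_mask]

    def element_symbols(self) -> Tuple[str, ...]:
        out = []
        for t, v in zip(self.atom_types, self.virtual_flags):
            out.append("*" if v else ELEMENTS[t])
        return tuple(out)

    def has_virtual(self, token_kind: str) -> bool:
        code = VIRTUAL_CODES[(token_kind, self.entity_role)]
        return bool(np.any(self.atom_types[self.virtual_flags] == code))

    def strip_virtual(self) -> "AtomGraph":
        m = self.real_mask
        if m.all():
            return self
        return replace(self, atom_types=self.atom_types[m], coords=self.coords[m],
                       virtual_flags=None,
                       residue_ids=None if self.residue_ids is None
                       else tuple(r for r, keep in zip(self.residue_ids, m) if keep))


@dataclass(frozen=True)
class ComplexPair:
    """Pocket + molecule with a binary match label and optional true pose."""

    pocket: AtomGraph
    molecule: AtomGraph
    match_label: int
    true_ligand_coords: Optional[np.ndarray] = None
    pair_id: str = ""

    def __post_init__(self):
        if self.match_label not in (0, 1):
            raise GraphError("match_label must be 0 or 1")
        if self.true_ligand_coords is not None:
            tc = np.asarray(self.true_ligand_coords, dtype=np.float64)
            if tc.shape != (self.molecule.n_real, 3):
                raise GraphError("true_ligand_coords must have one row per real molecule atom")
            object.__setattr__(self, "true_ligand_coords", tc)


def insert_virtual_atom(graph: AtomGraph, token_kind: str) -> AtomGraph:
    """Append a CLS or ENCODE virtual atom at the centroid of real atoms."""
    if token_kind not in TOKEN_KINDS:
        raise GraphError(f"unknown token kind {token_kind!r}")
    if graph.has_virtual(token_kind):
        raise GraphError(f"graph already has a {token_kind} token")
    centroid = graph.real_coords.mean(axis=0)
    code = VIRTUAL_CODES[(token_kind, graph.entity_role)]
    return replace(
        graph,
        atom_types=np.append(graph.atom_types, code),
        coords=np.vstack([graph.coords, centroid[None, :]]),
        virtual_flags=np.append(graph.virtual_flags, True),
        residue_ids=None if graph.residue_ids is None else graph.residue_ids + ("",),
    )


def count_pocket_residues(pocket: AtomGraph, ligand_coords: np.ndarray,
                          radius: float) -> int:
    """Number of pocket residues having >= 1 atom within ``radius`` of the ligand."""
    if pocket.residue_ids is None:
        raise GraphError("pocket lacks residue metadata")
    from scipy.spatial.distance import cdist

    ligand_coords = np.asarray(ligand_coords, dtype=np.float64)
    mask = pocket.real_mask
    d = cdist(pocket.coords[mask], ligand_coords).min(axis=1)
    rids = [r for r, keep in zip(pocket.residue_ids, mask) if keep]
    close = set()
    for rid, dist in zip(rids, d):
        if dist <= radius:
            close.add(rid)
    return len(close)


def validate_complex(pair: ComplexPair, min_residues: int = 5,
                     radius: float = 5.0) -> Tuple[bool, str]:
    """Accept a complex iff >= ``min_residues`` pocket residues lie within
    ``radius`` Angstrom of the ligand (the bound pose when available)."""
    lig = pair.true_ligand_coords
    if lig is None:
        lig = pair.molecule.real_coords
    n = count_pocket_residues(pair.pocket, lig, radius)
    if n >= min_residues:
        return True, f"{n} residues within {radius} A"
    return False, f"insufficient pocket residues ({n} < {min_residues} within {radius} A)"


@dataclass
class GraphBatch:
    """Dense padded batch of atom graphs.

    ``atom_types``: (B, N) int codes, 0-padded; ``coords``: (B, N, 3);
    ``mask``: (B, N) True on occupied positions; ``real_mask`` excludes
    virtual tokens as well as padding; ``bond_codes``: (B, N, N) int8
    symmetric matrix (0 = no bond); ``counts``: atoms per graph;
    ``segments``: (B, N) 0 for pocket atoms, 1 for molecule atoms in joint
    graphs (all-0 or all-1 otherwise); ``token_index``: per-graph index of
    the trailing virtual token, or -1.
    """

    atom_types: np.ndarray
    coords: np.ndarray
    mask: np.ndarray
    real_mask: np.ndarray
    bond_codes: np.ndarray
    counts: np.ndarray
    segments: np.ndarray
    token_index: np.ndarray

    @property
    def size(self) -> int:
        return self.atom_types.shape[0]

    @property
    def max_n(self) -> int:
        return self.atom_types.shape[1]


def batch(graphs: Sequence[AtomGraph], max_atoms: Optional[int] = None,
          segments: Optional[Sequence[np.ndarray]] = None) -> GraphBatch:
    """Pad a list of graphs into one :class:`GraphBatch`."""
    graphs = list(graphs)
    if not graphs:
        raise GraphError("empty graph list")
    counts = np.array([g.n_atoms for g in graphs], dtype=np.int64)
    if max_atoms is not None:
        for g, c in zip(graphs, counts):
            if c > max_atoms:
                raise GraphError(
                    f"graph {g.source_id or '<unnamed>'} has {c} atoms > max_atoms={max_atoms}")
    N = int(counts.max())
    B = len(graphs)
    types = np.zeros((B, N), dtype=np.int64)
    coords = np.zeros((B, N, 3), dtype=np.float64)
    mask = np.zeros((B, N), dtype=bool)
    real = np.zeros((B, N), dtype=bool)
    bonds = np.zeros((B, N, N), dtype=np.int8)
    seg = np.zeros((B, N), dtype=np.int8)
    tok = np.full(B, -1, dtype=np.int64)
    for b, g in enumerate(graphs):
        n = g.n_atoms
        types[b, :n] = g.atom_types
        coords[b, :n] = g.coords
        mask[b, :n] = True
        real[b, :n] = g.real_mask
        for i, j, code in g.bonds:
            bonds[b, i, j] = code
            bonds[b, j, i] = code
        if segments is not None:
            seg[b, :n] = segments[b]
        elif g.entity_role == "molecule":
            seg[b, :n] = 1
        if g.virtual_flags[-1]:
            tok[b] = n - 1
    return GraphBatch(types, coords, mask, real, bonds, counts, seg, tok)


def make_joint(pocket: AtomGraph, molecule: AtomGraph,
               encode_token: bool = False,
               molecule_coords: Optional[np.ndarray] = None
               ) -> Tuple[AtomGraph, np.ndarray]:
    """Concatenate a pocket and a molecule into one fully connected graph.

    Virtual atoms are stripped from both entities first; when
    ``encode_token`` is set an ENCODE token is appended at the molecule
    centroid.  Returns the joint graph (entity_role='molecule', since the
    joint pass runs through the molecular encoder) and a per-atom segment
    array (0 pocket / 1 molecule).
    """
    p = pocket.strip_virtual()
    m = molecule.strip_virtual()
    mc = m.coords if molecule_coords is None else np.asarray(molecule_coords, dtype=np.float64)
    if mc.shape != (m.n_atoms, 3):
        raise GraphError("molecule_coords shape mismatch")
    types = np.concatenate([p.atom_types, m.atom_types])
    coords = np.vstack([p.coords, mc])
    virt = np.zeros(len(types), dtype=bool)
    bonds = tuple((i + p.n_atoms, j + p.n_atoms, c) for i, j, c in m.bonds)
    seg = np.concatenate([np.zeros(p.n_atoms, dtype=np.int8),
                          np.ones(m.n_atoms, dtype=np.int8)])
    if encode_token:
        centroid = mc.mean(axis=0)
        types = np.append(types, VIRTUAL_CODES[("ENCODE", "molecule")])
        coords = np.vstack([coords, centroid[None, :]])
        virt = np.append(virt, True)
        seg = np.append(seg, np.int8(1))
    joint = AtomGraph(entity_role="molecule", atom_types=types, coords=coords,
                      bonds=bonds, virtual_flags=virt,
                      source_id=f"{pocket.source_id}|{molecule.source_id}")
    return joint, seg
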
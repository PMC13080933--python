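"""Structure file I/O: SDF molecules, PDB pockets, JSON-lines fixtures.

SDF (V2000) parsing and writing go through RDKit; PDB parsing goes
through gemmi.  The JSON-lines ComplexPair format is the package's own
canonical fixture format: one pair per line with explicit element
strings, coordinate arrays, bond triples, match label, and optional true
ligand coordinates — emitted by the synthetic generator and consumed by
training.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import List, Sequence

import numpy as np

from .graphs import (AtomGraph, BOND_CODES, BOND_NAMES, ComplexPair,
                     ELEMENT_CODES, ELEMENTS, GraphError)


class ParseError(ValueError):
    pass


class EmptyPocketError(ValueError):
    pass


# ---------------------------------------------------------------------------
# SDF
# ---------------------------------------------------------------------------

_RDKIT_BOND = None


def _rdkit():
    global _RDKIT_BOND
    from rdkit import Chem, RDLogger
    RDLogger.DisableLog("rdApp.*")
    if _RDKIT_BOND is None:
        _RDKIT_BOND = {
            Chem.BondType.SINGLE: BOND_CODES["single"],
            Chem.BondType.DOUBLE: BOND_CODES["double"],
            Chem.BondType.TRIPLE: BOND_CODES["triple"],
            Chem.BondType.AROMATIC: BOND_CODES["aromatic"],
        }
    return Chem


def read_molecule(path) -> List[AtomGraph]:
    """Read an SDF (V2000) file into one AtomGraph per molecule block.

    Hydrogens are dropped.  Unknown heavy elements raise; an all-z=0
    geometry explicitly flagged as 2D in the molfile header warns but
    still loads.
    """
    Chem = _rdkit()
    path = Path(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    out: List[AtomGraph] = []
    for block_idx, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"{path}: malformed SDF molecule block #{block_idx + 1}")
        if mol.GetNumConformers() == 0:
            raise ParseError(f"{path}: block #{block_idx + 1} has no coordinates")
        conf = mol.GetConformer()
        coords_all = conf.GetPositions()
        info = mol.GetProp("_MolFileInfo") if mol.HasProp("_MolFileInfo") else ""
        if "2D" in info and np.allclose(coords_all[:, 2], 0.0):
            warnings.warn(f"{path}: block #{block_idx + 1} is flagged 2D (all z = 0)")
        keep = []
        types = []
        coords = []
        for atom in mol.GetAtoms():
            sym = atom.GetSymbol()
            if sym == "H":
                keep.append(-1)
                continue
            if sym not in ELEMENT_CODES:
                raise ParseError(
                    f"{path}: unknown element {sym!r} in block #{block_idx + 1}")
            keep.append(len(types))
            types.append(ELEMENT_CODES[sym])
            coords.append(coords_all[atom.GetIdx()])
        bonds = []
        for bond in mol.GetBonds():
            i = keep[bond.GetBeginAtomIdx()]
            j = keep[bond.GetEndAtomIdx()]
            if i < 0 or j < 0:
                continue  # bond to a dropped hydrogen
            bt = bond.GetBondType()
            if bt not in _RDKIT_BOND:
                raise ParseError(
                    f"{path}: unsupported bond type {bt} in block #{block_idx + 1}")
            lo, hi = (i, j) if i < j else (j, i)
            bonds.append((lo, hi, _RDKIT_BOND[bt]))
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        out.append(AtomGraph(entity_role="molecule",
                             atom_types=np.array(types, dtype=np.int64),
                             coords=np.array(coords, dtype=np.float64),
                             bonds=tuple(sorted(bonds)),
                             source_id=name or f"{path.stem}#{block_idx}"))
    if not out:
        raise ParseError(f"{path}: no molecule blocks found")
    return out


def write_pose(molecule: AtomGraph, coords: np.ndarray, path,
               append: bool = False) -> None:
    """Write a molecule with replaced coordinates as SDF V2000.

    Virtual atoms are omitted; ``coords`` must have one row per real atom.
    """
    Chem = _rdkit()
    from rdkit.Geometry import Point3D

    real = molecule.strip_virtual()
    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape != (real.n_atoms, 3):
        raise GraphError(
            f"coords shape {coords.shape} != ({real.n_atoms}, 3)")
    inv_bond = {v: k for k, v in _RDKIT_BOND.items()}
    rw = Chem.RWMol()
    for t in real.atom_types:
        a = Chem.Atom(ELEMENTS[t])
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j, code in real.bonds:
        rw.AddBond(int(i), int(j), inv_bond[code])
        if code == BOND_CODES["aromatic"]:
            rw.GetBondBetweenAtoms(int(i), int(j)).SetIsAromatic(True)
            rw.GetAtomWithIdx(int(i)).SetIsAromatic(True)
            rw.GetAtomWithIdx(int(j)).SetIsAromatic(True)
    conf = Chem.Conformer(real.n_atoms)
    for i, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    mol.SetProp("_Name", real.source_id)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        writer = Chem.SDWriter(fh)
        writer.SetKekulize(False)
        writer.write(mol)
        writer.close()


# ---------------------------------------------------------------------------
# PDB pockets
# ---------------------------------------------------------------------------

def read_pocket(path, ligand_coords: np.ndarray, radius: float) -> AtomGraph:
    """Extract a binding pocket from a PDB file.

    Returns every atom of every residue having at least one heavy atom
    within ``radius`` Angstrom of any ligand coordinate.  HETATM records,
    waters and hydrogens are excluded; alternate locations keep the
    highest-occupancy conformer.  Inclusion is residue-level: a residue is
    either fully in or fully out.
    """
    import gemmi

    if radius <= 0:
        raise ValueError("radius must be positive")
    ligand_coords = np.asarray(ligand_coords, dtype=np.float64)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ParseError(f"{path}: no models")
    model = st[0]
    types: List[int] = []
    coords: List[np.ndarray] = []
    rids: List[str] = []
    for chain in model:
        for res in chain:
            if res.is_water() or res.het_flag == "H":
                continue
            # resolve altlocs: highest occupancy per atom name, file order ties
            by_name = {}
            for atom in res:
                if atom.element.name == "H" or atom.element.name == "D":
                    continue
                prev = by_name.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    by_name[atom.name] = atom
            atoms = list(by_name.values())
            if not atoms:
                continue
            pos = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
            dmin = np.sqrt(((pos[:, None, :] - ligand_coords[None, :, :]) ** 2
                            ).sum(-1)).min()
            if dmin > radius:
                continue
            rid = f"{chain.name}.{res.seqid.num}{res.seqid.icode.strip()}.{res.name}"
            for a, p in zip(atoms, pos):
                sym = a.element.name
                if sym not in ELEMENT_CODES:
                    raise ParseError(f"{path}: unknown element {sym!r} in {rid}")
                types.append(ELEMENT_CODES[sym])
                coords.append(p)
                rids.append(rid)
    if not types:
        raise EmptyPocketError(
            f"{path}: no residue within {radius} A of the ligand")
    return AtomGraph(entity_role="pocket",
                     atom_types=np.array(types, dtype=np.int64),
                     coords=np.array(coords, dtype=np.float64),
                     bonds=(), residue_ids=tuple(rids),
                     source_id=Path(path).stem)


# ---------------------------------------------------------------------------
# JSON-lines ComplexPair fixtures
# ---------------------------------------------------------------------------

def _graph_to_dict(g: AtomGraph) -> dict:
    g = g.strip_virtual()
    d = {
        "entity_role": g.entity_role,
        "atom_types": list(g.element_symbols()),
        "coords": np.round(g.coords, 6).tolist(),
        "bonds": [[int(i), int(j), BOND_NAMES[c]] for i, j, c in g.bonds],
        "source_id": g.source_id,
    }
    if g.residue_ids is not None:
        d["residue_ids"] = list(g.residue_ids)
    return d


def _graph_from_dict(d: dict) -> AtomGraph:
    types = np.array([ELEMENT_CODES[s] for s in d["atom_types"]], dtype=np.int64)
    bonds = tuple((int(i), int(j), BOND_CODES[name]) for i, j, name in d["bonds"])
    return AtomGraph(entity_role=d["entity_role"], atom_types=types,
                     coords=np.array(d["coords"], dtype=np.float64),
                     bonds=bonds, source_id=d.get("source_id", ""),
                     residue_ids=tuple(d["residue_ids"]) if "residue_ids" in d else None)


def pair_to_json(pair: ComplexPair) -> str:
    d = {
        "pair_id": pair.pair_id,
        "match_label": int(pair.match_label),
        "pocket": _graph_to_dict(pair.pocket),
        "molecule": _graph_to_dict(pair.molecule),
        "true_ligand_coords": (None if pair.true_ligand_coords is None
                               else np.round(pair.true_ligand_coords, 6).tolist()),
    }
    return json.dumps(d, sort_keys=True, separators=(",", ":"))


def pair_from_json(line: str) -> ComplexPair:
    d = json.loads(line)
    return ComplexPair(pocket=_graph_from_dict(d["pocket"]),
                       molecule=_graph_from_dict(d["molecule"]),
                       match_label=int(d["match_label"]),
                       true_ligand_coords=(None if d["true_ligand_coords"] is None
                                           else np.array(d["true_ligand_coords"])),
                       pair_id=d.get("pair_id", ""))


def write_complexes(pairs: Sequence[ComplexPair], path) -> str:
    """Write pairs as JSON-lines; returns the file's sha256 digest."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(pair_to_json(p) + "\n")
    return sha256_file(path)


def read_complexes(path) -> List[ComplexPair]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(pair_from_json(line))
    return out


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
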
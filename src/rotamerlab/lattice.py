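"""Crystal-lattice environment: symmetry mates and packing contacts.

A residue participates in a crystal contact when any of its heavy atoms
lies within a distance cutoff (default 4.0 A, boundary inclusive) of a
heavy atom of any symmetry- or translation-related neighbor copy in the
lattice.  Space-group operators and cell transforms come from gemmi;
distance queries use a k-d tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .torsions import ResidueId

__all__ = ["LatticeModel", "expand_neighbors", "detect_contacts"]

log = logging.getLogger(__name__)

#: residue names treated as polymer when filtering hetero components
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL".split()
)


@dataclass
class LatticeModel:
    """Asymmetric-unit heavy atoms plus cell and space-group symmetry.

    Coordinates are Cartesian (A).  Hydrogens are excluded on
    construction; waters/ligands/ions are excluded by default.
    """

    coords: np.ndarray           # (n_atoms, 3)
    chain: np.ndarray            # (n_atoms,) str
    resnum: np.ndarray           # (n_atoms,) int
    resname: np.ndarray          # (n_atoms,) str
    element: np.ndarray          # (n_atoms,) str
    cell: gemmi.UnitCell = field(default_factory=lambda: gemmi.UnitCell(1, 1, 1, 90, 90, 90))
    space_group: str = "P 1"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        for name in ("chain", "resnum", "resname", "element"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name}: expected shape ({n},), got {arr.shape}")
            setattr(self, name, arr)
        if gemmi.find_spacegroup_by_name(self.space_group) is None:
            raise ValueError(f"unknown space group {self.space_group!r}")

    @classmethod
    def from_structure(cls, structure: gemmi.Structure,
                       include_hetero: bool = False) -> "LatticeModel":
        """Extract heavy atoms of the first model.

        ``include_hetero=False`` keeps standard amino acids only (waters,
        ions and ligands are left out of contact and SASA calculations).
        """
        coords, chains, resnums, resnames, elements = [], [], [], [], []
        model = structure[0]
        for chain in model:
            for residue in chain:
                if not include_hetero and residue.name not in STANDARD_AMINO_ACIDS:
                    continue
                for atom in residue:
                    if atom.element.is_hydrogen:
                        continue
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    chains.append(chain.name)
                    resnums.append(residue.seqid.num)
                    resnames.append(residue.name)
                    elements.append(atom.element.name)
        sg = structure.spacegroup_hm or "P 1"
        return cls(np.array(coords, dtype=float), np.array(chains),
                   np.array(resnums), np.array(resnames), np.array(elements),
                   cell=structure.cell, space_group=sg)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residue_ids(self) -> list[ResidueId]:
        """Unique residues in file order."""
        seen: dict[ResidueId, None] = {}
        for c, n, r in zip(self.chain, self.resnum, self.resname):
            seen.setdefault(ResidueId(str(c), int(n), str(r)), None)
        return list(seen)


def _fractional(lattice: LatticeModel) -> np.ndarray:
    frac_mat = np.array(lattice.cell.frac.mat.tolist(), dtype=float)
    return lattice.coords @ frac_mat.T


def _orthogonal(lattice: LatticeModel, frac: np.ndarray) -> np.ndarray:
    orth_mat = np.array(lattice.cell.orth.mat.tolist(), dtype=float)
    return frac @ orth_mat.T


def expand_neighbors(lattice: LatticeModel, shell: int = 1
                     ) -> list[tuple[str, np.ndarray]]:
    """Cartesian coordinates of every neighbor copy of the asymmetric unit.

    Applies each space-group operator combined with integer cell
    translations in ``[-shell, shell]^3``; the identity copy (identity
    operator, zero translation) is excluded.  Returns ``(label, coords)``
    pairs, coords of shape (n_atoms, 3).
    """
    sg = gemmi.find_spacegroup_by_name(lattice.space_group)
    if sg is None:
        raise ValueError(f"unknown space group {lattice.space_group!r}")
    frac = _fractional(lattice)
    neighbors: list[tuple[str, np.ndarray]] = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        base = frac @ rot.T + tran
        is_identity = op.triplet() == "x,y,z"
        for tx in range(-shell, shell + 1):
            for ty in range(-shell, shell + 1):
                for tz in range(-shell, shell + 1):
                    if is_identity and tx == ty == tz == 0:
                        continue
                    shifted = base + np.array([tx, ty, tz], dtype=float)
                    label = f"{op.triplet()}+({tx},{ty},{tz})"
                    neighbors.append((label, _orthogonal(lattice, shifted)))
    return neighbors


def detect_contacts(lattice: LatticeModel, cutoff: float = 4.0,
                    shell: int = 1) -> dict[ResidueId, bool]:
    """Flag residues with any heavy atom within ``cutoff`` A (inclusive)
    of a heavy atom of a neighbor copy."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    residues = lattice.residue_ids()
    neighbors = expand_neighbors(lattice, shell=shell)
    if not neighbors:
        log.warning("no neighbor copies generated; all residues non-contacting")
        return {rid: False for rid in residues}
    neighbor_coords = np.vstack([c for _, c in neighbors])
    tree = cKDTree(neighbor_coords)
    dmin, _ = tree.query(lattice.coords, k=1)
    # boundary inclusive; tiny epsilon absorbs fractional/Cartesian roundoff
    atom_contact = dmin <= cutoff + 1e-9
    flags = {rid: False for rid in residues}
    for i in np.nonzero(atom_contact)[0]:
        rid = ResidueId(str(lattice.chain[i]), int(lattice.resnum[i]),
                        str(lattice.resname[i]))
        flags[rid] = True
    return flags
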
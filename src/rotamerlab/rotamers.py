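"""Rotamer library: discrete side-chain conformational states.

A rotamer is a low-energy side-chain conformation characterized by modal
values of the chi torsion angles.  The packaged library transcribes the
common-atom modal values of the Penultimate Rotamer Library, in the
published table order, so that integer state IDs are stable and match the
conventional rotamer-table numbering.  ALA and GLY carry no chi angles and
are excluded by construction.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "RotamerDefinition",
    "RotamerLibrary",
    "load_rotamer_library",
    "CHI_ATOMS",
    "SYMMETRIC_TERMINAL_CHI",
    "N_CHI",
]

#: chi dihedral atom quadruples per residue type, in chi order.
CHI_ATOMS: Mapping[str, tuple[tuple[str, str, str, str], ...]] = {
    "ARG": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")),
    "LYS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")),
    "MET": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")),
    "GLU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")),
    "GLN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")),
    "ASP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "ASN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "HIS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")),
    "PHE": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "TYR": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "TRP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "LEU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "ILE": (("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")),
    "PRO": (("N", "CA", "CB", "CG"),),
    "SER": (("N", "CA", "CB", "OG"),),
    "THR": (("N", "CA", "CB", "OG1"),),
    "VAL": (("N", "CA", "CB", "CG1"),),
    "CYS": (("N", "CA", "CB", "SG"),),
}

#: number of chi angles per rotameric residue type
N_CHI: Mapping[str, int] = {res: len(quads) for res, quads in CHI_ATOMS.items()}

#: 1-based chi index of the terminal dihedral with 2-fold chemical symmetry
#: (indistinguishable atom labelings); folded into (-90, 90] before use.
SYMMETRIC_TERMINAL_CHI: Mapping[str, int] = {
    "PHE": 2, "TYR": 2, "ASP": 2, "GLU": 3,
}


@dataclass(frozen=True)
class RotamerDefinition:
    """One named rotamer state of a residue type.

    Parameters
    ----------
    residue_type : str
        Three-letter amino-acid code.
    state_id : int
        1-based index in library order.
    state_name : str
        Conventional short label, e.g. ``"mt"`` or ``"ttp85"``.
    modal_chis : tuple of float
        Modal chi angles in degrees, each in (-180, 180].
    """

    residue_type: str
    state_id: int
    state_name: str
    modal_chis: tuple[float, ...]

    @property
    def n_chi(self) -> int:
        return len(self.modal_chis)

    def __post_init__(self) -> None:
        expected = N_CHI.get(self.residue_type)
        if expected is not None and expected != len(self.modal_chis):
            raise ValueError(
                f"{self.residue_type} {self.state_name}: {len(self.modal_chis)} "
                f"modal chi angles, expected {expected}"
            )
        for a in self.modal_chis:
            if not (-180.0 < a <= 180.0):
                raise ValueError(
                    f"{self.residue_type} {self.state_name}: angle {a} "
                    "outside (-180, 180]"
                )


@dataclass
class RotamerLibrary:
    """Ordered rotamer definitions per residue type.

    ``entries[res_type]`` is the list of :class:`RotamerDefinition` in
    library order; ``state_id`` of the k-th entry is ``k + 1``.
    """

    entries: dict[str, list[RotamerDefinition]] = field(default_factory=dict)

    def __contains__(self, residue_type: str) -> bool:
        return residue_type in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def states(self, residue_type: str) -> list[RotamerDefinition]:
        try:
            return self.entries[residue_type]
        except KeyError:
            raise KeyError(
                f"residue type {residue_type!r} has no rotamer definitions"
            ) from None

    def n_states(self, residue_type: str) -> int:
        return len(self.states(residue_type))

    def n_chi(self, residue_type: str) -> int:
        return self.states(residue_type)[0].n_chi

    def state(self, residue_type: str, state_id: int) -> RotamerDefinition:
        states = self.states(residue_type)
        if not 1 <= state_id <= len(states):
            raise KeyError(f"{residue_type} has no state {state_id}")
        return states[state_id - 1]

    def modal_matrix(self, residue_type: str) -> np.ndarray:
        """(N, n_chi) array of modal angles in library order."""
        return np.array([s.modal_chis for s in self.states(residue_type)],
                        dtype=float)

    def validate(self) -> None:
        for res, states in self.entries.items():
            if res in ("ALA", "GLY"):
                raise ValueError(f"{res} must not carry rotamer definitions")
            ids = [s.state_id for s in states]
            if ids != list(range(1, len(states) + 1)):
                raise ValueError(f"{res}: state IDs not contiguous 1..N: {ids}")
            n_chi = {s.n_chi for s in states}
            if len(n_chi) != 1:
                raise ValueError(f"{res}: inconsistent chi counts {n_chi}")


def _packaged_path(name: str) -> Path:
    return Path(importlib.resources.files("rotamerlab") / "data" / name)


def load_rotamer_library(path: str | Path | None = None) -> RotamerLibrary:
    """Read a rotamer library table.

    The dialect is tab-separated with a header row and columns
    ``residue_type  state_id  state_name  n_chi  chi1..chi4`` (trailing chi
    columns absent or empty for residues with fewer angles).  ``#`` lines
    are comments.  With ``path=None`` the packaged library is loaded.
    """
    if path is None:
        path = _packaged_path("penultimate_rotamers.tsv")
    path = Path(path)
    lib = RotamerLibrary()
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:4] != ["residue_type", "state_id", "state_name", "n_chi"]:
                    raise ValueError(
                        f"{path}:{lineno}: unexpected header {header[:4]}"
                    )
                continue
            try:
                res = fields[0].strip().upper()
                state_id = int(fields[1])
                state_name = fields[2].strip()
                n_chi = int(fields[3])
                chis = tuple(float(x) for x in fields[4:4 + n_chi])
                if len(chis) != n_chi:
                    raise ValueError("missing chi columns")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            entry = RotamerDefinition(res, state_id, state_name, chis)
            lib.entries.setdefault(res, []).append(entry)
    if header is None:
        raise ValueError(f"{path}: empty library file")
    lib.validate()
    missing = set(CHI_ATOMS) - set(lib.entries)
    if missing:
        raise ValueError(f"{path}: residue types missing: {sorted(missing)}")
    return lib


def load_max_sasa_table(path: str | Path | None = None) -> dict[str, float]:
    """Read the per-residue-type theoretical maximum SASA table (A^2)."""
    if path is None:
        path = _packaged_path("max_sasa_tripeptide.tsv")
    table: dict[str, float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("residue_type"):
                continue
            res, value = line.split("\t")
            table[res.upper()] = float(value)
    if not table:
        raise ValueError(f"{path}: empty reference table")
    return table
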
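"""Structure and chi-table readers/writers plus run configuration.

The supported trajectory interchange format is a plain tab-separated
chi-angle table (one row per residue per frame), so the statistics core
never depends on binary trajectory formats.  Structures are read with
gemmi (PDB and mmCIF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import gemmi
import numpy as np
import pandas as pd
import yaml

from .lattice import STANDARD_AMINO_ACIDS, LatticeModel
from .rotamers import CHI_ATOMS, N_CHI
from .torsions import ChiTrajectory, ResidueId, compute_chi_angles

__all__ = [
    "RunConfig",
    "StructureData",
    "read_structure",
    "read_chi_table",
    "write_chi_table",
    "lattice_to_pdb",
]

log = logging.getLogger(__name__)

CHI_TABLE_COLUMNS = ["condition", "chain_copy", "chain", "resnum", "resname",
                     "frame", "chi1", "chi2", "chi3", "chi4"]

#: S-S bond length threshold (A) for flagging disulfide cysteines
DISULFIDE_SG_CUTOFF = 2.3


@dataclass
class RunConfig:
    """Tunable parameters of the comparison pipeline.

    Defaults follow the analysis conventions this package implements:
    4 A heavy-atom contact cutoff, 1.4 A SASA probe, relative
    accessibility > 0.2 for exposure, +-30 deg rotamer identity
    tolerance, T = 300 K, and region boundaries at OC = 0.5 and
    |T*dS| = 0.5 kcal/mol.
    """

    contact_cutoff: float = 4.0
    symmetry_shell: int = 1
    probe_radius: float = 1.4
    sasa_point_number: int = 1000
    exposure_threshold: float = 0.2
    agreement_tolerance: float = 30.0
    temperature: float = 300.0
    oc_boundary: float = 0.5
    tds_boundary: float = 0.5
    window: str = "last-half"   # "last-half" | "all" | "start:stop"
    stride: int = 1
    pool_copies: bool = True
    altloc_policy: str = "A"
    kl_pseudocount: float | None = None  # None -> 1/n_frames
    disulfide_cutoff: float = DISULFIDE_SG_CUTOFF
    exclude_disulfide_cys: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "probe_radius", "agreement_tolerance",
                     "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def frame_window(self, n_frames: int) -> tuple[int, int]:
        """Resolve the window spec against a concrete frame count."""
        if self.window == "all":
            return 0, n_frames
        if self.window == "last-half":
            return n_frames // 2, n_frames
        try:
            start, stop = self.window.split(":")
            return int(start or 0), int(stop or n_frames)
        except ValueError:
            raise ValueError(f"bad window spec {self.window!r}") from None


@dataclass
class StructureData:
    """Parsed X-ray structure: heavy-atom lattice model, per-residue
    experimental chi vectors, and excluded residues with reasons."""

    lattice: LatticeModel
    xray_chis: dict[ResidueId, np.ndarray]
    alternate_chis: dict[ResidueId, list[np.ndarray]]
    exclusions: dict[ResidueId, str] = field(default_factory=dict)

    @property
    def rotameric_residues(self) -> list[ResidueId]:
        return list(self.xray_chis)


def _residue_conformer_coords(residue: gemmi.Residue,
                              altloc_policy: str) -> dict[str, np.ndarray]:
    """Atom-name -> xyz using blank-altloc atoms plus the chosen conformer."""
    coords: dict[str, np.ndarray] = {}
    for atom in residue:
        alt = atom.altloc if atom.altloc not in ("\x00", "") else ""
        if alt in ("", altloc_policy) and atom.name not in coords:
            coords[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
    return coords


def _altloc_labels(residue: gemmi.Residue) -> list[str]:
    return sorted({a.altloc for a in residue
                   if a.altloc not in ("\x00", "")})


def read_structure(path: str | Path, altloc_policy: str = "A",
                   exclude_disulfide_cys: bool = True,
                   disulfide_cutoff: float = DISULFIDE_SG_CUTOFF,
                   ) -> StructureData:
    """Read a PDB/mmCIF file and derive the X-ray chi vectors.

    Alternate locations are resolved by ``altloc_policy`` (conformer A by
    default); complete alternate conformers are retained separately.
    Residues are excluded, with a machine-readable reason, when they are
    non-rotameric (ALA/GLY), disulfide-bonded CYS, or missing side-chain
    atoms.
    """
    path = Path(path)
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    lattice = LatticeModel.from_structure(structure)

    # disulfide detection: SG-SG pairs within cutoff
    sg_atoms: list[tuple[ResidueId, np.ndarray]] = []
    for chain in structure[0]:
        for residue in chain:
            if residue.name == "CYS":
                for atom in residue:
                    if atom.name == "SG":
                        rid = ResidueId(chain.name, residue.seqid.num, "CYS")
                        sg_atoms.append((rid, np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z])))
    disulfide: set[ResidueId] = set()
    for i in range(len(sg_atoms)):
        for j in range(i + 1, len(sg_atoms)):
            if np.linalg.norm(sg_atoms[i][1] - sg_atoms[j][1]) <= disulfide_cutoff:
                disulfide.update((sg_atoms[i][0], sg_atoms[j][0]))

    xray_chis: dict[ResidueId, np.ndarray] = {}
    alternates: dict[ResidueId, list[np.ndarray]] = {}
    exclusions: dict[ResidueId, str] = {}
    for chain in structure[0]:
        for residue in chain:
            name = residue.name
            if name not in STANDARD_AMINO_ACIDS:
                continue
            rid = ResidueId(chain.name, residue.seqid.num, name)
            if name not in CHI_ATOMS:
                exclusions[rid] = "non-rotameric"
                continue
            if exclude_disulfide_cys and rid in disulfide:
                exclusions[rid] = "disulfide-cys"
                continue
            coords = _residue_conformer_coords(residue, altloc_policy)
            try:
                xray_chis[rid] = compute_chi_angles(coords, name)
            except KeyError as exc:
                log.warning("%s skipped: %s", rid, exc.args[0])
                exclusions[rid] = "missing-atoms"
                continue
            for alt in _altloc_labels(residue):
                if alt == altloc_policy:
                    continue
                alt_coords = _residue_conformer_coords(residue, alt)
                try:
                    alternates.setdefault(rid, []).append(
                        compute_chi_angles(alt_coords, name))
                except KeyError:
                    pass
    return StructureData(lattice, xray_chis, alternates, exclusions)


# ---------------------------------------------------------------------------
# chi-angle tables

def write_chi_table(trajectories: list[ChiTrajectory],
                    path: str | Path) -> None:
    """Write trajectories in the tab-separated chi-table dialect."""
    rows = []
    for traj in trajectories:
        rid = traj.residue_id
        n_chi = traj.frames.shape[1]
        for f in range(traj.n_frames):
            row = {
                "condition": traj.condition,
                "chain_copy": traj.chain_copy,
                "chain": rid.chain,
                "resnum": rid.resnum,
                "resname": rid.resname,
                "frame": f,
            }
            for k in range(4):
                row[f"chi{k + 1}"] = (f"{traj.frames[f, k]:.3f}"
                                      if k < n_chi else "")
            rows.append(row)
    pd.DataFrame(rows, columns=CHI_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_chi_table(path: str | Path) -> list[ChiTrajectory]:
    """Read a chi-angle table into per-(residue, condition, copy)
    trajectories, preserving frame order."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chain": str,
                                                "chain_copy": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty chi table") from None
    missing = set(CHI_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: chi table has no rows")
    key_cols = ["condition", "chain_copy", "chain", "resnum", "frame"]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate row for "
            f"{tuple(first[c] for c in key_cols)}"
        )
    out: list[ChiTrajectory] = []
    group_cols = ["condition", "chain_copy", "chain", "resnum", "resname"]
    for (cond, copy, chain, resnum, resname), grp in df.groupby(
            group_cols, sort=False):
        resname = str(resname).upper()
        n_chi = N_CHI.get(resname)
        if n_chi is None:
            raise ValueError(f"{path}: non-rotameric residue type {resname}")
        grp = grp.sort_values("frame")
        chi_cols = [f"chi{k + 1}" for k in range(n_chi)]
        values = grp[chi_cols].to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError(
                f"{path}: missing chi values for {chain}:{resname}{resnum} "
                f"(expected {n_chi} angles)"
            )
        rid = ResidueId(str(chain), int(resnum), resname)
        out.append(ChiTrajectory(rid, str(cond), str(copy), values))
    return out


def lattice_to_pdb(lattice: LatticeModel, path: str | Path) -> None:
    """Write a lattice model as a PDB file with a populated CRYST1 record."""
    st = gemmi.Structure()
    st.cell = lattice.cell
    st.spacegroup_hm = lattice.space_group
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    order: list[tuple[str, int]] = []
    for i in range(lattice.n_atoms):
        ckey = str(lattice.chain[i])
        rkey = (ckey, int(lattice.resnum[i]))
        if ckey not in chains:
            chains[ckey] = gemmi.Chain(ckey)
        if rkey not in residues:
            res = gemmi.Residue()
            res.name = str(lattice.resname[i])
            res.seqid = gemmi.SeqId(int(lattice.resnum[i]), " ")
            residues[rkey] = res
            order.append(rkey)
        atom = gemmi.Atom()
        atom.name = str(lattice.element[i])
        atom.element = gemmi.Element(str(lattice.element[i]))
        atom.pos = gemmi.Position(*lattice.coords[i])
        atom.occ = 1.0
        residues[rkey].add_atom(atom)
    for ckey, rnum in order:
        chains[ckey].add_residue(residues[(ckey, rnum)])
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
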
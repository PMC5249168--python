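"""Relative solvent accessibility and residue environment classes.

Per-residue SASA (Shrake-Rupley, probe 1.4 A) is normalized by the
theoretical maximum of the residue type in an extended tripeptide
context; a residue is "exposed" when the fraction strictly exceeds the
exposure threshold (default 0.2).  SASA is computed per chain in
isolation, so lattice neighbors never shadow the surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import biotite.structure as struc
import numpy as np

from .lattice import LatticeModel
from .rotamers import load_max_sasa_table
from .torsions import ResidueId

__all__ = [
    "EnvironmentAnnotation",
    "residue_sasa",
    "relative_accessibility",
    "classify_environment",
]


@dataclass(frozen=True)
class EnvironmentAnnotation:
    """Crystal-contact and solvent-exposure status of one residue."""

    residue_id: ResidueId
    contacting: bool
    relative_accessibility: float
    exposed: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.relative_accessibility):
            raise ValueError(f"{self.residue_id}: non-finite accessibility")


def _to_atom_array(lattice: LatticeModel, mask: np.ndarray) -> struc.AtomArray:
    n = int(mask.sum())
    arr = struc.AtomArray(n)
    arr.coord = lattice.coords[mask]
    arr.chain_id = lattice.chain[mask].astype(str)
    arr.res_id = lattice.resnum[mask]
    arr.res_name = lattice.resname[mask].astype(str)
    arr.element = lattice.element[mask].astype(str)
    arr.atom_name = lattice.element[mask].astype(str)
    return arr


def residue_sasa(lattice: LatticeModel, chain: str,
                 probe_radius: float = 1.4,
                 point_number: int = 1000) -> dict[ResidueId, float]:
    """Per-residue SASA (A^2) of one chain considered in isolation.

    ``point_number`` is the Shrake-Rupley sphere sampling per atom; 1000
    points on a typical extended atom sphere approximates a density of
    ~10-15 points per A^2.
    """
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    mask = lattice.chain == chain
    if not mask.any():
        raise ValueError(f"chain {chain!r} not present")
    arr = _to_atom_array(lattice, mask)
    atom_sasa = struc.sasa(arr, probe_radius=probe_radius,
                           point_number=point_number, vdw_radii="Single")
    out: dict[ResidueId, float] = {}
    for i in range(arr.array_length()):
        rid = ResidueId(str(arr.chain_id[i]), int(arr.res_id[i]),
                        str(arr.res_name[i]))
        out[rid] = out.get(rid, 0.0) + float(atom_sasa[i])
    return out


def relative_accessibility(lattice: LatticeModel, chain: str,
                           probe_radius: float = 1.4,
                           point_number: int = 1000,
                           reference: Mapping[str, float] | None = None,
                           ) -> dict[ResidueId, float]:
    """SASA of each residue divided by its residue-type theoretical
    maximum (extended tripeptide reference)."""
    if reference is None:
        reference = load_max_sasa_table()
    sasa = residue_sasa(lattice, chain, probe_radius, point_number)
    out: dict[ResidueId, float] = {}
    for rid, area in sasa.items():
        try:
            ref = reference[rid.resname]
        except KeyError:
            raise KeyError(
                f"residue type {rid.resname!r} missing from max-SASA reference"
            ) from None
        out[rid] = area / ref
    return out


def classify_environment(contacts: Mapping[ResidueId, bool],
                         accessibilities: Mapping[ResidueId, float],
                         exposure_threshold: float = 0.2,
                         ) -> dict[ResidueId, EnvironmentAnnotation]:
    """Combine contact flags and accessibility fractions.

    Exposure uses a strict ``>`` comparison: a fraction exactly at the
    threshold is buried.  Both inputs must cover the same residues.
    """
    if set(contacts) != set(accessibilities):
        only_c = sorted(str(r) for r in set(contacts) - set(accessibilities))
        only_a = sorted(str(r) for r in set(accessibilities) - set(contacts))
        raise ValueError(
            "residue sets differ between contacts and accessibilities: "
            f"contacts-only={only_c}, accessibility-only={only_a}"
        )
    out: dict[ResidueId, EnvironmentAnnotation] = {}
    for rid in contacts:
        acc = float(accessibilities[rid])
        out[rid] = EnvironmentAnnotation(
            residue_id=rid,
            contacting=bool(contacts[rid]),
            relative_accessibility=acc,
            exposed=acc > exposure_threshold,
        )
    return out
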
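"""Chi dihedrals and their mapping onto discrete rotamer states.

Angles are degrees throughout, reported in the interval (-180, 180] with
the IUPAC sign convention.  Terminal dihedrals with 2-fold chemical
symmetry (PHE/TYR chi2, ASP chi2, GLU chi3) are folded into (-90, 90]
before any comparison, since the two atom labelings are chemically
indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .rotamers import (
    CHI_ATOMS,
    SYMMETRIC_TERMINAL_CHI,
    RotamerDefinition,
    RotamerLibrary,
)

__all__ = [
    "ResidueId",
    "ChiTrajectory",
    "RotamerStateSeries",
    "wrap_angle",
    "circular_distance",
    "chi_periods",
    "dihedral",
    "fold_symmetric_chis",
    "compute_chi_angles",
    "assign_rotamer",
    "assign_states",
    "assign_series",
    "matches_within_tolerance",
]


class ResidueId(NamedTuple):
    """(chain label, author residue number, three-letter residue type)."""

    chain: str
    resnum: int
    resname: str

    def __str__(self) -> str:  # e.g. "A:GLN6"
        return f"{self.chain}:{self.resname.capitalize()}{self.resnum}"


@dataclass
class ChiTrajectory:
    """Per-frame chi vectors of one residue under one condition.

    ``frames`` is an (n_frames, n_chi) float array in degrees, time-ordered.
    """

    residue_id: ResidueId
    condition: str
    chain_copy: str
    frames: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.size == 0:
            n_chi = len(CHI_ATOMS.get(self.residue_id.resname, ()))
            frames = frames.reshape(0, n_chi)
        self.frames = np.atleast_2d(frames)
        if self.condition not in ("solution", "crystal"):
            raise ValueError(f"unknown condition {self.condition!r}")
        expected = len(CHI_ATOMS.get(self.residue_id.resname, ()))
        if expected and self.frames.shape[0] and self.frames.shape[1] != expected:
            raise ValueError(
                f"{self.residue_id}: chi vectors of length {self.frames.shape[1]}, "
                f"expected {expected}"
            )
        out = (self.frames <= -180.0) | (self.frames > 180.0)
        if out.any():
            raise ValueError(f"{self.residue_id}: angles outside (-180, 180]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class RotamerStateSeries:
    """Per-frame rotamer state IDs for one residue/condition/copy."""

    residue_id: ResidueId
    condition: str
    chain_copy: str
    states: np.ndarray  # int state_id per frame

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]


def wrap_angle(a):
    """Wrap degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -np.mod(-a + 180.0, 360.0) + 180.0
    return wrapped if wrapped.shape else float(wrapped)


def circular_distance(a, b, period: float = 360.0):
    """Shortest angular separation |a - b| on a circle of the given
    period, in [0, period/2].  Period 180 is the metric for 2-fold
    degenerate terminal dihedrals."""
    half = period / 2.0
    d = np.abs(np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
                      + half, period) - half)
    return d if d.shape else float(d)


def chi_periods(residue_type: str, n_chi: int) -> np.ndarray:
    """Angular period (360 or 180 deg) of each chi of a residue type."""
    periods = np.full(n_chi, 360.0)
    idx = SYMMETRIC_TERMINAL_CHI.get(residue_type)
    if idx is not None and idx <= n_chi:
        periods[idx - 1] = 180.0
    return periods


def dihedral(p0, p1, p2, p3) -> float | np.ndarray:
    """Signed dihedral angle (degrees) of four points, IUPAC convention.

    Accepts single points of shape (3,) or batches of shape (..., 3).
    Positive when, looking down the p1->p2 bond, the far bond is rotated
    clockwise from the near bond.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return wrap_angle(ang)


def fold_symmetric_chis(chis: Sequence[float] | np.ndarray,
                        residue_type: str) -> np.ndarray:
    """Fold the 2-fold-degenerate terminal chi into (-90, 90].

    Chi vectors may be a single vector (n_chi,) or a batch (n, n_chi).
    Residue types without a symmetric terminal dihedral pass through
    unchanged (apart from wrapping).
    """
    single = np.asarray(chis).ndim == 1
    chis = np.atleast_2d(wrap_angle(np.asarray(chis, dtype=float)))
    idx = SYMMETRIC_TERMINAL_CHI.get(residue_type)
    if idx is not None and chis.shape[1] >= idx:
        col = chis[:, idx - 1]
        folded = np.mod(col + 90.0, 180.0) - 90.0  # in [-90, 90)
        folded = np.where(folded == -90.0, 90.0, folded)
        chis = chis.copy()
        chis[:, idx - 1] = folded
    return chis[0] if single else chis


def compute_chi_angles(atom_coords: dict[str, np.ndarray],
                       residue_type: str,
                       fold_symmetric: bool = True) -> np.ndarray:
    """Chi vector (degrees) of one residue from an atom-name -> xyz map.

    Raises ``KeyError`` naming the first missing atom; callers extracting
    from whole structures should catch it and skip the residue with a
    warning rather than aborting.
    """
    try:
        quads = CHI_ATOMS[residue_type]
    except KeyError:
        raise KeyError(f"{residue_type} is not a rotameric residue type") from None
    chis = []
    for quad in quads:
        try:
            pts = [atom_coords[name] for name in quad]
        except KeyError as exc:
            raise KeyError(
                f"{residue_type}: missing side-chain atom {exc.args[0]}"
            ) from None
        chis.append(dihedral(*pts))
    chis = np.array(chis, dtype=float)
    if fold_symmetric:
        chis = np.atleast_1d(fold_symmetric_chis(chis, residue_type))
    return chis


def _max_circular_deviation(chis: np.ndarray, modal: np.ndarray,
                            periods: np.ndarray) -> np.ndarray:
    """Per-state maximum per-angle circular deviation.

    chis: (n, n_chi); modal: (N, n_chi); periods: (n_chi,) -> (n, N).
    """
    d = circular_distance(chis[:, None, :], modal[None, :, :],
                          period=periods[None, None, :])
    return d.max(axis=-1)


def assign_states(chis: np.ndarray, residue_type: str,
                  library: RotamerLibrary) -> np.ndarray:
    """Vectorized nearest-rotamer assignment for a batch of chi vectors.

    Nearest = minimal maximum per-angle circular deviation; ties broken by
    the lowest state ID (argmin picks the first minimum).  The 2-fold
    degenerate terminal dihedrals are compared with a 180 deg period, so
    chemically indistinguishable labelings map to the same state.
    """
    if residue_type not in library:
        raise KeyError(f"residue type {residue_type!r} absent from library")
    chis = np.atleast_2d(np.asarray(chis, dtype=float))
    n_chi = library.n_chi(residue_type)
    if chis.shape[1] != n_chi:
        raise ValueError(
            f"{residue_type}: chi vector length {chis.shape[1]}, expected {n_chi}"
        )
    modal = library.modal_matrix(residue_type)
    periods = chi_periods(residue_type, n_chi)
    dev = _max_circular_deviation(chis, modal, periods)
    return dev.argmin(axis=1) + 1


def assign_rotamer(chis: Sequence[float] | np.ndarray, residue_type: str,
                   library: RotamerLibrary) -> int:
    """Nearest rotamer state ID for a single chi vector."""
    return int(assign_states(np.atleast_2d(chis), residue_type, library)[0])


def assign_series(traj: ChiTrajectory, library: RotamerLibrary) -> RotamerStateSeries:
    """Assign every frame of a chi trajectory to its nearest rotamer state."""
    res = traj.residue_id.resname
    if traj.n_frames == 0:
        states = np.empty(0, dtype=int)
    else:
        states = assign_states(traj.frames, res, library)
    return RotamerStateSeries(traj.residue_id, traj.condition,
                              traj.chain_copy, states)


def matches_within_tolerance(chis: Sequence[float] | np.ndarray,
                             state: RotamerDefinition,
                             tol: float = 30.0) -> bool:
    """True iff every chi angle is within ``tol`` degrees of the state's
    modal angle by circular distance (all angles must match)."""
    chis = np.atleast_1d(np.asarray(chis, dtype=float))
    modal = np.atleast_1d(np.asarray(state.modal_chis, dtype=float))
    if chis.shape != modal.shape:
        raise ValueError(
            f"chi vector length {chis.shape} != state length {modal.shape}"
        )
    periods = chi_periods(state.residue_type, len(modal))
    return bool(np.all(circular_distance(chis, modal, periods) <= tol))
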
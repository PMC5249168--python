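"""Synthetic chi-angle trajectories and toy mini-crystals with ground truth.

The trajectory generator emulates the stationary per-residue rotamer
sampling of an equilibrated MD trajectory: each frame draws a rotamer
state from a categorical mixture over the residue's library states and
adds wrapped-Gaussian within-well noise (truncated at 3 SD before
wrapping so wells stay separable) to the modal chi angles.  An optional
sticky-Markov mode produces autocorrelated frames with the same
stationary distribution, for exercising segment-split uncertainty under
slow mixing.  Closed-form overlap and entropy truths accompany each
generated condition pair, so pipeline estimates can be checked for
parameter recovery.

The mini-crystal generator places a linear pseudo-atom chain in a P1 or
P21 cell such that which residues touch a lattice neighbor is known by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

from .lattice import LatticeModel
from .rotamers import RotamerLibrary
from .stats import (BOLTZMANN_KCAL, DEFAULT_TEMPERATURE, conf_entropy,
                    overlap_coefficient)
from .torsions import ChiTrajectory, ResidueId, wrap_angle

__all__ = [
    "EnsembleSpec",
    "MiniCrystalSpec",
    "generate_torsion_trajectory",
    "generate_condition_pair",
    "generate_mini_crystal",
    "overlap_truth",
    "delta_entropy_truth",
]


@dataclass
class EnsembleSpec:
    """Recipe for one residue's synthetic chi trajectory."""

    residue_type: str
    mixture_weights: tuple[float, ...]
    #: default keeps 3*SD below half the minimal inter-well separation in
    #: the library (40 deg, ASP/ASN chi2), so wells never overlap
    noise_sd: float = 6.0
    n_frames: int = 1000
    seed: int = 0
    condition: str = "solution"
    chain: str = "A"
    resnum: int = 1
    chain_copy: str = "A1"
    #: probability of re-drawing the previous frame's state; ``None`` =
    #: independent frames.  The stationary law is mixture_weights either way.
    stickiness: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture_weights must be a probability vector")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.stickiness is not None and not 0.0 <= self.stickiness < 1.0:
            raise ValueError("stickiness must be in [0, 1)")

    @property
    def residue_id(self) -> ResidueId:
        return ResidueId(self.chain, self.resnum, self.residue_type)


@dataclass
class MiniCrystalSpec:
    """Recipe for a toy lattice with known contact truth.

    A chain of ``n_residues`` pseudo-residues (``atoms_per_residue``
    carbon atoms each) lies along x with ``spacing`` A between residues;
    the cell is sized so the closest heavy-atom distance between adjacent
    lattice copies equals ``gap``.
    """

    n_residues: int = 8
    atoms_per_residue: int = 1
    spacing: float = 3.0
    gap: float = 3.5
    space_group: str = "P 1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.space_group not in ("P 1", "P 1 21 1"):
            raise ValueError("space group must be 'P 1' or 'P 1 21 1'")
        if self.space_group == "P 1 21 1" and self.atoms_per_residue != 1:
            raise ValueError("P 1 21 1 layout supports one atom per residue")


def _draw_states(spec: EnsembleSpec, rng: np.random.Generator,
                 n_states: int) -> np.ndarray:
    w = np.asarray(spec.mixture_weights, dtype=float)
    if len(w) != n_states:
        raise ValueError(
            f"{spec.residue_type}: {len(w)} mixture weights for "
            f"{n_states} library states"
        )
    if spec.stickiness is None:
        return rng.choice(n_states, size=spec.n_frames, p=w)
    states = np.empty(spec.n_frames, dtype=int)
    states[0] = rng.choice(n_states, p=w)
    stay = rng.random(spec.n_frames) < spec.stickiness
    jumps = rng.choice(n_states, size=spec.n_frames, p=w)
    for t in range(1, spec.n_frames):
        states[t] = states[t - 1] if stay[t] else jumps[t]
    return states


def generate_torsion_trajectory(spec: EnsembleSpec,
                                library: RotamerLibrary) -> ChiTrajectory:
    """Draw a stationary chi-angle trajectory for one residue.

    Per frame: state ~ mixture_weights, then each chi angle = the state's
    modal angle plus Gaussian noise truncated at 3 SD, wrapped to
    (-180, 180].  Deterministic for a fixed seed.
    """
    modal = library.modal_matrix(spec.residue_type)
    rng = np.random.default_rng(spec.seed)
    states = _draw_states(spec, rng, len(modal))
    noise = rng.normal(0.0, spec.noise_sd or 1.0,
                       size=(spec.n_frames, modal.shape[1]))
    if spec.noise_sd > 0:
        np.clip(noise, -3.0 * spec.noise_sd, 3.0 * spec.noise_sd, out=noise)
    else:
        noise[:] = 0.0
    chis = wrap_angle(modal[states] + noise)
    return ChiTrajectory(spec.residue_id, spec.condition, spec.chain_copy,
                         chis)


def overlap_truth(weights_solution, weights_crystal) -> float:
    """Closed-form overlap coefficient of two mixture-weight vectors."""
    return overlap_coefficient(np.asarray(weights_solution, dtype=float),
                               np.asarray(weights_crystal, dtype=float))


def delta_entropy_truth(weights_solution, weights_crystal,
                        temperature: float = DEFAULT_TEMPERATURE,
                        k_b: float = BOLTZMANN_KCAL) -> float:
    """Closed-form T*(S_crystal - S_solution) of two weight vectors."""
    return (conf_entropy(np.asarray(weights_crystal, dtype=float),
                         temperature, k_b)
            - conf_entropy(np.asarray(weights_solution, dtype=float),
                           temperature, k_b))


def generate_condition_pair(spec_solution: EnsembleSpec,
                            spec_crystal: EnsembleSpec,
                            library: RotamerLibrary,
                            ) -> tuple[ChiTrajectory, ChiTrajectory, float, float]:
    """Trajectories for both conditions plus analytic (OC, T*Delta S)
    truths computed from the mixture weights."""
    if spec_solution.residue_type != spec_crystal.residue_type:
        raise ValueError("condition pair must share a residue type")
    traj_s = generate_torsion_trajectory(spec_solution, library)
    traj_c = generate_torsion_trajectory(spec_crystal, library)
    oc = overlap_truth(spec_solution.mixture_weights,
                       spec_crystal.mixture_weights)
    tds = delta_entropy_truth(spec_solution.mixture_weights,
                              spec_crystal.mixture_weights)
    return traj_s, traj_c, oc, tds


def generate_mini_crystal(spec: MiniCrystalSpec, cutoff: float = 4.0
                          ) -> tuple[LatticeModel, dict[ResidueId, bool]]:
    """Toy lattice plus per-residue contact truth at ``cutoff``.

    P 1: copies are pure cell translations along x; residue i touches a
    neighbor iff ``i*spacing + gap <= cutoff`` (left image) or the mirror
    condition ``(n-1-i)*spacing + gap <= cutoff`` (right image).

    P 1 21 1: the chain runs parallel to the screw axis and its mate runs
    antiparallel at perpendicular distance ``gap`` with a half-cell y
    stagger; residue i touches the mate iff
    ``hypot(gap, spacing*min(i+1, n-i)) <= cutoff``.
    """
    n, apr, s, gap = (spec.n_residues, spec.atoms_per_residue,
                      spec.spacing, spec.gap)
    ys = 0.4 * np.arange(apr)  # small intra-residue offsets, same per residue
    coords, chains, resnums, resnames, elements = [], [], [], [], []
    truth: dict[ResidueId, bool] = {}

    if spec.space_group == "P 1":
        a = (n - 1) * s + gap
        cell = gemmi.UnitCell(a, 30.0 + ys.max(), 30.0, 90, 90, 90)
        for i in range(n):
            for k in range(apr):
                coords.append([i * s, ys[k], 0.0])
            rid = ResidueId("X", i + 1, "ALA")
            left = i * s + gap        # to nearest atom of the -a image
            right = (n - 1 - i) * s + gap
            truth[rid] = min(left, right) <= cutoff
    else:  # P 1 21 1, screw axis along y: (x,y,z) -> (-x, y+1/2, -z)
        # chain runs parallel to the screw axis at x = gap/2, so the mate
        # chain runs antiparallel at x = -gap/2 with a half-cell y offset;
        # the perpendicular separation is exactly `gap` and the residual
        # y stagger is s * min(i+1, n-i) for residue i (0-based).
        x0 = gap / 2.0
        a = gap + 30.0
        b = 2.0 * n * s
        cell = gemmi.UnitCell(a, b, 30.0, 90, 90, 90)
        for i in range(n):
            coords.append([x0, i * s, 0.0])
            rid = ResidueId("X", i + 1, "ALA")
            d = math.hypot(gap, s * min(i + 1, n - i))
            truth[rid] = d <= cutoff
    for i in range(n):
        for _ in range(apr):
            chains.append("X")
            resnums.append(i + 1)
            resnames.append("ALA")
            elements.append("C")
    lattice = LatticeModel(np.array(coords), np.array(chains),
                           np.array(resnums), np.array(resnames),
                           np.array(elements), cell=cell,
                           space_group=spec.space_group)
    if spec.space_group == "P 1" and (n - 1) * s >= cell.a:
        raise ValueError("chain does not fit in the cell (gap too small)")
    return lattice, truth
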
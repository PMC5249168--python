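"""Ensemble comparison statistics over rotamer-state distributions.

Each residue's sampled chi trajectory is reduced to a categorical
distribution over its N library rotamer states, one distribution per
condition (solution / crystal).  The module then quantifies:

* correspondence with the X-ray conformation — a likelihood score
  relative to the uniform null model 1/N, averaged over residues, and a
  top-two dominant-rotamer agreement criterion;
* similarity of the two simulated ensembles — the histogram overlap
  coefficient OC = sum_i min(p_i, q_i), cross-checked by the
  Kullback-Leibler divergence;
* change in side-chain dynamics — the configurational entropy
  S = -k_B sum_i p_i ln p_i reported as T*S (kcal/mol, T = 300 K by
  default), with Delta S defined crystal minus solution;
* a quadrant classification of (OC, T*Delta S) into regions I-IV;
* uncertainty from two equal, non-overlapping trajectory segments.

Only the inter-well (configurational) entropy term is computed; the
within-well thermal term is assumed identical across conditions for a
given residue and cancels from the difference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .rotamers import RotamerLibrary
from .torsions import ResidueId, RotamerStateSeries

__all__ = [
    "BOLTZMANN_KCAL",
    "DEFAULT_TEMPERATURE",
    "RotamerDistribution",
    "XrayAssignment",
    "ResidueComparison",
    "SetSummary",
    "build_distribution",
    "likelihood_score",
    "likelihood_quotient",
    "overlap_coefficient",
    "kl_divergence",
    "conf_entropy",
    "delta_entropy",
    "dominant_states",
    "rotamer_agreement",
    "classify_region",
    "segment_uncertainty",
    "compare_residue",
    "summarize_sets",
    "residue_composition",
]

log = logging.getLogger(__name__)

#: Boltzmann constant in kcal/(mol*K)
BOLTZMANN_KCAL = 0.0019872
#: reporting temperature (K) for T*S values
DEFAULT_TEMPERATURE = 300.0


@dataclass
class RotamerDistribution:
    """Normalized rotamer-state probabilities for one residue/condition."""

    residue_id: ResidueId
    condition: str
    probabilities: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("probabilities must be a non-empty 1-D vector")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"{self.residue_id}/{self.condition}: invalid distribution "
                f"(sum={p.sum():.12f})"
            )
        self.probabilities = p

    @property
    def n_states(self) -> int:
        return self.probabilities.size


@dataclass(frozen=True)
class XrayAssignment:
    """Rotamer state of the experimental side chain (conformer A), with
    any alternate-conformer states kept for reporting."""

    residue_id: ResidueId
    state_id: int
    alternates: tuple[int, ...] = ()


@dataclass
class ResidueComparison:
    """All per-residue comparison statistics."""

    residue_id: ResidueId
    oc: float
    kl: float
    t_s_conf_solution: float
    t_s_conf_crystal: float
    t_delta_s_conf: float
    region: str
    agreement_solution: bool | None = None
    agreement_crystal: bool | None = None
    oc_bounds: tuple[float, float] | None = None
    tds_bounds: tuple[float, float] | None = None


@dataclass
class SetSummary:
    """Set-level aggregation over solvent-exposed rotameric residues."""

    chain: str
    residue_set: str  # all | contacting | non-contacting
    n_residues: int
    likelihood_solution: float
    likelihood_crystal: float
    likelihood_quotient: float
    mean_oc: float
    sd_oc: float
    mean_tds: float
    sd_tds: float
    pct_agreement_solution: float
    pct_agreement_crystal: float


# ---------------------------------------------------------------------------
# distributions

def build_distribution(series: Sequence[RotamerStateSeries] | RotamerStateSeries,
                       n_states: int,
                       window: tuple[int, int] | None = None,
                       ) -> RotamerDistribution:
    """Pool one or more state series into a normalized distribution.

    ``window=(start, stop)`` selects frames ``start:stop`` of each series
    before pooling (used e.g. to keep the last half of a trajectory);
    ``None`` keeps everything.  States never visited keep probability 0.
    """
    if isinstance(series, RotamerStateSeries):
        series = [series]
    if not series:
        raise ValueError("no state series given")
    rid, cond = series[0].residue_id, series[0].condition
    for s in series:
        if s.residue_id != rid or s.condition != cond:
            raise ValueError(
                f"cannot pool {s.residue_id}/{s.condition} with {rid}/{cond}"
            )
    pooled = []
    for s in series:
        sel = s.states if window is None else s.states[window[0]:window[1]]
        pooled.append(sel)
    states = np.concatenate(pooled) if pooled else np.empty(0, dtype=int)
    if states.size == 0:
        raise ValueError(f"{rid}/{cond}: selected frame window is empty")
    if states.min() < 1 or states.max() > n_states:
        raise ValueError(f"{rid}/{cond}: state IDs outside 1..{n_states}")
    counts = np.bincount(states, minlength=n_states + 1)[1:]
    return RotamerDistribution(rid, cond, counts / counts.sum(),
                               n_frames=int(states.size))


# ---------------------------------------------------------------------------
# X-ray correspondence

def likelihood_score(dists: Mapping[ResidueId, RotamerDistribution],
                     xray: Mapping[ResidueId, XrayAssignment],
                     residue_set: Iterable[ResidueId] | None = None,
                     ) -> float:
    """Mean over residues of P(x_xray) / (1/N): how much more likely the
    sampled ensemble is to produce the X-ray rotamer than the uniform
    null model.  Residues lacking an X-ray state are excluded with a
    logged warning."""
    rids = list(residue_set) if residue_set is not None else list(dists)
    ratios = []
    skipped = 0
    for rid in rids:
        dist = dists[rid]
        asn = xray.get(rid)
        if asn is None:
            skipped += 1
            continue
        n = dist.n_states
        ratios.append(dist.probabilities[asn.state_id - 1] * n)
    if skipped:
        log.warning("likelihood_score: %d residue(s) without X-ray state "
                    "excluded", skipped)
    if not ratios:
        raise ValueError("no residues with both distribution and X-ray state")
    return float(np.mean(ratios))


def likelihood_quotient(l_crystal: float, l_solution: float) -> float:
    """L_crystal / L_solution; > 1 means the crystal ensemble matches the
    X-ray conformations better than the solution ensemble."""
    if l_solution <= 0:
        raise ValueError(
            "degenerate solution likelihood (X-ray state never sampled)"
        )
    return l_crystal / l_solution


def dominant_states(p: np.ndarray) -> set[int]:
    """State IDs of the two most populated bins, ties at the second rank
    included.  Only visited states (p > 0) qualify."""
    p = np.asarray(p, dtype=float)
    nz = np.nonzero(p > 0)[0]
    if nz.size <= 2:
        return {int(i) + 1 for i in nz}
    order = nz[np.argsort(p[nz], kind="stable")[::-1]]
    threshold = p[order[1]]
    return {int(i) + 1 for i in nz if p[i] >= threshold}


def rotamer_agreement(dist: RotamerDistribution,
                      xray: XrayAssignment) -> bool:
    """True iff the X-ray rotamer is one of the two most dominant states
    sampled in the ensemble."""
    return xray.state_id in dominant_states(dist.probabilities)


# ---------------------------------------------------------------------------
# distribution similarity

def overlap_coefficient(p_solution: np.ndarray, p_crystal: np.ndarray) -> float:
    """OC = sum_i min(p_i, q_i) in [0, 1]; 1 = identical histograms."""
    p = np.asarray(p_solution, dtype=float)
    q = np.asarray(p_crystal, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    return float(np.minimum(p, q).sum())


def kl_divergence(p_solution: np.ndarray, p_crystal: np.ndarray,
                  pseudocount: float = 0.0) -> float:
    """KL(p_solution || p_crystal) in nats after optional pseudocount
    smoothing (added to every bin of both distributions, then
    renormalized).  Returns ``inf`` when an unsmoothed crystal bin is
    empty where the solution bin is not."""
    p = np.asarray(p_solution, dtype=float)
    q = np.asarray(p_crystal, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount > 0:
        p = (p + pseudocount) / (p + pseudocount).sum()
        q = (q + pseudocount) / (q + pseudocount).sum()
    mask = p > 0
    if np.any(q[mask] == 0):
        log.warning("kl_divergence: empty crystal bin with solution mass; "
                    "returning inf")
        return math.inf
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


# ---------------------------------------------------------------------------
# configurational entropy

def conf_entropy(p: np.ndarray,
                 temperature: float = DEFAULT_TEMPERATURE,
                 k_b: float = BOLTZMANN_KCAL) -> float:
    """Configurational entropy -k_B sum p ln p, returned as T*S in
    kcal/mol (0 ln 0 := 0)."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    s = -k_b * float(np.sum(nz * np.log(nz)))
    return temperature * s + 0.0  # avoid IEEE negative zero


def delta_entropy(dist_solution: RotamerDistribution,
                  dist_crystal: RotamerDistribution,
                  temperature: float = DEFAULT_TEMPERATURE,
                  k_b: float = BOLTZMANN_KCAL) -> float:
    """T*(S_crystal - S_solution) in kcal/mol; negative = dynamics are
    reduced in the crystal."""
    return (conf_entropy(dist_crystal.probabilities, temperature, k_b)
            - conf_entropy(dist_solution.probabilities, temperature, k_b))


# ---------------------------------------------------------------------------
# region classification

def classify_region(oc: float, t_delta_s: float,
                    oc_boundary: float = 0.5,
                    tds_boundary: float = 0.5) -> str:
    """Quadrant label for the (OC, T*Delta S) plane.

    I  — conformation and dynamics unchanged (OC >= boundary, |TdS| <= boundary)
    II — conformation changed, dynamics unchanged
    III — conformation and dynamics changed
    IV — dynamics changed, conformation unchanged
    Boundaries are inclusive toward region I.
    """
    if not 0.0 <= oc <= 1.0:
        raise ValueError(f"OC {oc} outside [0, 1]")
    conf_ok = oc >= oc_boundary
    dyn_ok = abs(t_delta_s) <= tds_boundary
    if conf_ok and dyn_ok:
        return "I"
    if not conf_ok and dyn_ok:
        return "II"
    if not conf_ok and not dyn_ok:
        return "III"
    return "IV"


# ---------------------------------------------------------------------------
# uncertainty from trajectory halves

def _half_windows(n_frames: int) -> tuple[tuple[int, int], tuple[int, int]]:
    if n_frames < 2:
        raise ValueError("need at least 2 frames to split into segments")
    mid = (n_frames + 1) // 2  # odd frame count: first half gets the extra
    return (0, mid), (mid, n_frames)


def segment_uncertainty(
    solution_series: Mapping[ResidueId, Sequence[RotamerStateSeries]],
    crystal_series: Mapping[ResidueId, Sequence[RotamerStateSeries]],
    n_states: Mapping[ResidueId, int],
    statistic: str | Callable[[RotamerDistribution, RotamerDistribution], float] = "oc",
) -> tuple[dict[ResidueId, tuple[float, float]], float]:
    """Per-residue (low, high) bounds of a solution-vs-crystal statistic
    from two equal-length, non-overlapping trajectory segments, plus the
    Pearson correlation of per-residue values between the segments.

    ``statistic`` is ``"oc"``, ``"tds"`` or a callable on the two
    distributions (solution, crystal).
    """
    if statistic == "oc":
        func = lambda ds, dc: overlap_coefficient(ds.probabilities,
                                                  dc.probabilities)
    elif statistic == "tds":
        func = delta_entropy
    elif callable(statistic):
        func = statistic
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    if set(solution_series) != set(crystal_series):
        raise ValueError("solution and crystal residue sets differ")
    halves: tuple[list[float], list[float]] = ([], [])
    bounds: dict[ResidueId, tuple[float, float]] = {}
    for rid in solution_series:
        values = []
        for half in (0, 1):
            dists = []
            for group in (solution_series[rid], crystal_series[rid]):
                n_frames = min(s.n_frames for s in group)
                win = _half_windows(n_frames)[half]
                dists.append(build_distribution(list(group), n_states[rid],
                                                window=win))
            values.append(func(dists[0], dists[1]))
        halves[0].append(values[0])
        halves[1].append(values[1])
        bounds[rid] = (min(values), max(values))
    if len(bounds) >= 2 and np.std(halves[0]) > 0 and np.std(halves[1]) > 0:
        r = float(sps.pearsonr(halves[0], halves[1])[0])
    else:
        r = math.nan
    return bounds, r


# ---------------------------------------------------------------------------
# per-residue and set-level aggregation

def compare_residue(dist_solution: RotamerDistribution,
                    dist_crystal: RotamerDistribution,
                    xray: XrayAssignment | None = None,
                    kl_pseudocount: float | None = None,
                    temperature: float = DEFAULT_TEMPERATURE,
                    oc_boundary: float = 0.5,
                    tds_boundary: float = 0.5) -> ResidueComparison:
    """All pairwise statistics for one residue.

    ``kl_pseudocount=None`` defaults to 1/n_frames of the pooled solution
    distribution (a single pseudo-observation spread over the bins).
    """
    if dist_solution.n_states != dist_crystal.n_states:
        raise ValueError("state-space mismatch between conditions")
    if kl_pseudocount is None:
        kl_pseudocount = 1.0 / max(dist_solution.n_frames, 1)
    p, q = dist_solution.probabilities, dist_crystal.probabilities
    oc = overlap_coefficient(p, q)
    tds_sol = conf_entropy(p, temperature)
    tds_cry = conf_entropy(q, temperature)
    tds = tds_cry - tds_sol
    return ResidueComparison(
        residue_id=dist_solution.residue_id,
        oc=oc,
        kl=kl_divergence(p, q, pseudocount=kl_pseudocount),
        t_s_conf_solution=tds_sol,
        t_s_conf_crystal=tds_cry,
        t_delta_s_conf=tds,
        region=classify_region(oc, tds, oc_boundary, tds_boundary),
        agreement_solution=(rotamer_agreement(dist_solution, xray)
                            if xray is not None else None),
        agreement_crystal=(rotamer_agreement(dist_crystal, xray)
                           if xray is not None else None),
    )


def _population_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=0))


def summarize_sets(comparisons: Mapping[ResidueId, ResidueComparison],
                   dists_solution: Mapping[ResidueId, RotamerDistribution],
                   dists_crystal: Mapping[ResidueId, RotamerDistribution],
                   xray: Mapping[ResidueId, XrayAssignment],
                   contacting: Mapping[ResidueId, bool],
                   chain: str) -> list[SetSummary]:
    """Aggregate per-residue statistics for one chain over the residue
    sets "all", "contacting" and "non-contacting".

    Callers restrict the comparison mapping to solvent-exposed rotameric
    residues beforehand; this function only splits by contact status.
    Standard deviations are population (divide by n) SDs.  Empty sets are
    omitted with a warning.
    """
    rids = [rid for rid in comparisons if rid.chain == chain]
    sets = {
        "all": rids,
        "contacting": [r for r in rids if contacting[r]],
        "non-contacting": [r for r in rids if not contacting[r]],
    }
    out: list[SetSummary] = []
    for name, members in sets.items():
        if not members:
            log.warning("chain %s: residue set %r is empty; omitted", chain, name)
            continue
        oc = np.array([comparisons[r].oc for r in members])
        tds = np.array([comparisons[r].t_delta_s_conf for r in members])
        l_sol = likelihood_score(dists_solution, xray, members)
        l_cry = likelihood_score(dists_crystal, xray, members)
        agr_sol = [comparisons[r].agreement_solution for r in members]
        agr_cry = [comparisons[r].agreement_crystal for r in members]
        out.append(SetSummary(
            chain=chain,
            residue_set=name,
            n_residues=len(members),
            likelihood_solution=l_sol,
            likelihood_crystal=l_cry,
            likelihood_quotient=likelihood_quotient(l_cry, l_sol),
            mean_oc=float(oc.mean()),
            sd_oc=_population_sd(oc),
            mean_tds=float(tds.mean()),
            sd_tds=_population_sd(tds),
            pct_agreement_solution=100.0 * np.mean([bool(a) for a in agr_sol]),
            pct_agreement_crystal=100.0 * np.mean([bool(a) for a in agr_cry]),
        ))
    return out


def residue_composition(residues: Mapping[str, Sequence[ResidueId]],
                        library: RotamerLibrary) -> dict[str, dict[str, float]]:
    """Normalized residue-type frequencies per residue set, ordered by
    library state count descending (longer / more flexible types first)."""
    order = sorted(library.entries,
                   key=lambda r: (-library.n_states(r), r))
    out: dict[str, dict[str, float]] = {}
    for set_name, rids in residues.items():
        if not rids:
            out[set_name] = {}
            continue
        names = [r.resname for r in rids]
        total = len(names)
        out[set_name] = {res: names.count(res) / total
                         for res in order if res in names}
    return out
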
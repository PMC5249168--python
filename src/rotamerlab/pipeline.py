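"""End-to-end orchestration: structure + chi trajectories -> reports.

Stages: assign every trajectory frame to a rotamer state, pool identical
lattice copies, build per-condition distributions over the configured
frame window, annotate residues with crystal-contact and exposure status
from the structure, compute all per-residue comparison statistics with
segment-split uncertainty bounds, and aggregate set-level summaries for
solvent-exposed residues.  Output is deterministic for fixed inputs and
configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accessibility import (EnvironmentAnnotation, classify_environment,
                            relative_accessibility)
from .io import RunConfig, StructureData
from .lattice import detect_contacts
from .rotamers import RotamerLibrary, load_rotamer_library
from .stats import (ResidueComparison, RotamerDistribution, SetSummary,
                    XrayAssignment, build_distribution, compare_residue,
                    segment_uncertainty, summarize_sets)
from .torsions import (ChiTrajectory, ResidueId, RotamerStateSeries,
                       assign_rotamer, assign_series)

__all__ = ["PipelineResult", "run_pipeline", "write_reports"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the comparison pipeline produces."""

    comparisons: dict[ResidueId, ResidueComparison]
    distributions_solution: dict[ResidueId, RotamerDistribution]
    distributions_crystal: dict[ResidueId, RotamerDistribution]
    xray: dict[ResidueId, XrayAssignment]
    annotations: dict[ResidueId, EnvironmentAnnotation]
    summaries: list[SetSummary]
    oc_segment_r: float
    tds_segment_r: float
    manifest: dict = field(default_factory=dict)


def _window_series(series: RotamerStateSeries, config: RunConfig
                   ) -> RotamerStateSeries:
    states = series.states[::config.stride]
    start, stop = config.frame_window(len(states))
    return RotamerStateSeries(series.residue_id, series.condition,
                              series.chain_copy, states[start:stop])


def _group_series(trajectories: list[ChiTrajectory], library: RotamerLibrary,
                  config: RunConfig
                  ) -> dict[str, dict[ResidueId, list[RotamerStateSeries]]]:
    """condition -> residue -> windowed state series (one per pooled copy)."""
    grouped: dict[str, dict[ResidueId, list[RotamerStateSeries]]] = {
        "solution": {}, "crystal": {}}
    for traj in trajectories:
        series = _window_series(assign_series(traj, library), config)
        key = traj.residue_id
        if not config.pool_copies:
            key = ResidueId(f"{traj.residue_id.chain}/{traj.chain_copy}",
                            traj.residue_id.resnum, traj.residue_id.resname)
        grouped[traj.condition].setdefault(key, []).append(series)
    return grouped


def annotate_structure(structure: StructureData, config: RunConfig
                       ) -> dict[ResidueId, EnvironmentAnnotation]:
    """Contact + exposure annotation for every residue of the structure."""
    contacts = detect_contacts(structure.lattice, cutoff=config.contact_cutoff,
                               shell=config.symmetry_shell)
    access: dict[ResidueId, float] = {}
    for chain in dict.fromkeys(str(c) for c in structure.lattice.chain):
        access.update(relative_accessibility(
            structure.lattice, chain,
            probe_radius=config.probe_radius,
            point_number=config.sasa_point_number))
    return classify_environment(contacts, access,
                                exposure_threshold=config.exposure_threshold)


def run_pipeline(config: RunConfig,
                 trajectories: list[ChiTrajectory],
                 structure: StructureData | None = None,
                 library: RotamerLibrary | None = None) -> PipelineResult:
    """Run the full ensemble comparison.

    Without a structure the environment annotation, X-ray likelihood and
    agreement stages are skipped and only solution-vs-crystal statistics
    are computed.
    """
    if library is None:
        library = load_rotamer_library()
    grouped = _group_series(trajectories, library, config)
    common = sorted(set(grouped["solution"]) & set(grouped["crystal"]))
    if not common:
        raise ValueError("no residue present in both conditions")
    only = (set(grouped["solution"]) ^ set(grouped["crystal"]))
    if only:
        log.warning("%d residue(s) present in one condition only; skipped",
                    len(only))

    xray: dict[ResidueId, XrayAssignment] = {}
    annotations: dict[ResidueId, EnvironmentAnnotation] = {}
    if structure is not None:
        annotations = annotate_structure(structure, config)
        for rid, chis in structure.xray_chis.items():
            alternates = tuple(
                assign_rotamer(a, rid.resname, library)
                for a in structure.alternate_chis.get(rid, []))
            xray[rid] = XrayAssignment(
                rid, assign_rotamer(chis, rid.resname, library), alternates)

    dists_s: dict[ResidueId, RotamerDistribution] = {}
    dists_c: dict[ResidueId, RotamerDistribution] = {}
    comparisons: dict[ResidueId, ResidueComparison] = {}
    n_states = {rid: library.n_states(rid.resname) for rid in common}
    for rid in common:
        dists_s[rid] = build_distribution(grouped["solution"][rid],
                                          n_states[rid])
        dists_c[rid] = build_distribution(grouped["crystal"][rid],
                                          n_states[rid])
        comparisons[rid] = compare_residue(
            dists_s[rid], dists_c[rid], xray.get(rid),
            kl_pseudocount=config.kl_pseudocount,
            temperature=config.temperature,
            oc_boundary=config.oc_boundary,
            tds_boundary=config.tds_boundary)

    sol = {rid: grouped["solution"][rid] for rid in common}
    cry = {rid: grouped["crystal"][rid] for rid in common}
    oc_bounds, oc_r = segment_uncertainty(sol, cry, n_states, "oc")
    tds_bounds, tds_r = segment_uncertainty(sol, cry, n_states, "tds")
    for rid in common:
        comparisons[rid].oc_bounds = oc_bounds[rid]
        comparisons[rid].tds_bounds = tds_bounds[rid]

    summaries: list[SetSummary] = []
    if structure is not None:
        exposed = {rid: cmp for rid, cmp in comparisons.items()
                   if rid in annotations and annotations[rid].exposed
                   and rid in xray}
        contacting = {rid: annotations[rid].contacting for rid in exposed}
        for chain in sorted({rid.chain for rid in exposed}):
            summaries.extend(summarize_sets(exposed, dists_s, dists_c, xray,
                                            contacting, chain))

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_trajectories": len(trajectories),
        "n_residues_compared": len(common),
        "excluded_residues": (
            {str(rid): reason
             for rid, reason in structure.exclusions.items()}
            if structure is not None else {}),
        "oc_segment_r": oc_r,
        "tds_segment_r": tds_r,
    }
    return PipelineResult(comparisons, dists_s, dists_c, xray, annotations,
                          summaries, oc_r, tds_r, manifest)


# ---------------------------------------------------------------------------
# report writing

def _comparison_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for rid, cmp in sorted(result.comparisons.items()):
        ann = result.annotations.get(rid)
        rows.append({
            "chain": rid.chain, "resnum": rid.resnum, "resname": rid.resname,
            "contacting": ann.contacting if ann else "",
            "exposed": ann.exposed if ann else "",
            "rel_access": (round(ann.relative_accessibility, 4)
                           if ann else ""),
            "OC": round(cmp.oc, 6),
            "OC_low": round(cmp.oc_bounds[0], 6) if cmp.oc_bounds else "",
            "OC_high": round(cmp.oc_bounds[1], 6) if cmp.oc_bounds else "",
            "KL": round(cmp.kl, 6),
            "TdS": round(cmp.t_delta_s_conf, 6),
            "TdS_low": round(cmp.tds_bounds[0], 6) if cmp.tds_bounds else "",
            "TdS_high": round(cmp.tds_bounds[1], 6) if cmp.tds_bounds else "",
            "region": cmp.region,
            "agree_solution": ("" if cmp.agreement_solution is None
                               else cmp.agreement_solution),
            "agree_crystal": ("" if cmp.agreement_crystal is None
                              else cmp.agreement_crystal),
            "xray_state": (result.xray[rid].state_id
                           if rid in result.xray else ""),
        })
    return pd.DataFrame(rows)


def _summary_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for s in result.summaries:
        rows.append({
            "chain": s.chain, "set": s.residue_set, "n_res": s.n_residues,
            "L_solution": round(s.likelihood_solution, 4),
            "L_crystal": round(s.likelihood_crystal, 4),
            "L_quotient": round(s.likelihood_quotient, 4),
            "mean_OC": round(s.mean_oc, 4), "sd_OC": round(s.sd_oc, 4),
            "mean_TdS": round(s.mean_tds, 4), "sd_TdS": round(s.sd_tds, 4),
            "pct_agree_solution": round(s.pct_agreement_solution, 2),
            "pct_agree_crystal": round(s.pct_agreement_crystal, 2),
        })
    return pd.DataFrame(rows)


def write_reports(result: PipelineResult, outdir: str | Path) -> None:
    """Write per-residue table, set summaries, per-residue histograms and
    the run manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _comparison_frame(result).to_csv(outdir / "per_residue.tsv", sep="\t",
                                     index=False)
    _summary_frame(result).to_csv(outdir / "set_summary.tsv", sep="\t",
                                  index=False)
    hist_dir = outdir / "histograms"
    hist_dir.mkdir(exist_ok=True)
    for rid in sorted(result.comparisons):
        ps = result.distributions_solution[rid].probabilities
        pc = result.distributions_crystal[rid].probabilities
        xray_state = result.xray[rid].state_id if rid in result.xray else None
        df = pd.DataFrame({
            "state_id": np.arange(1, len(ps) + 1),
            "p_solution": np.round(ps, 6),
            "p_crystal": np.round(pc, 6),
            "xray_flag": [int(i + 1 == xray_state) for i in range(len(ps))],
        })
        name = f"{rid.chain}_{rid.resname}_{rid.resnum}.tsv".replace("/", "-")
        df.to_csv(hist_dir / name, sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
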
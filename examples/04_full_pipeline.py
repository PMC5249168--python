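"""End-to-end run: synthetic cohort -> per-residue table + set summaries.

Simulates a small cohort of residues under solution and crystal
conditions (contacting residues get perturbed crystal mixtures), writes
the chi tables, runs the full comparison pipeline, and prints the
per-residue statistics it produces.  Reports land in ./scratch/demo_run.
"""

import dataclasses
from pathlib import Path

import numpy as np

from rotamerlab import (EnsembleSpec, RunConfig, generate_torsion_trajectory,
                        load_rotamer_library, run_pipeline, write_reports)

library = load_rotamer_library()
rng = np.random.default_rng(0)

residue_types = ["GLN", "GLU", "LYS", "SER", "LEU", "ASN"]
trajectories = []
for i, res in enumerate(residue_types):
    n = library.n_states(res)
    w_sol = rng.dirichlet(np.ones(3))
    wells = rng.choice(n, size=3, replace=False)
    weights_sol = np.zeros(n)
    weights_sol[wells] = w_sol
    # even-indexed residues are "frozen" in the crystal condition
    weights_cry = np.zeros(n)
    if i % 2 == 0:
        weights_cry[wells[0]] = 1.0
    else:
        weights_cry[wells] = w_sol
    for cond, w in (("solution", weights_sol), ("crystal", weights_cry)):
        for copy in ("A1", "A2"):
            spec = EnsembleSpec(res, tuple(w), noise_sd=6.0, n_frames=2000,
                                seed=int(rng.integers(2**31)), chain="A",
                                resnum=i + 1, condition=cond, chain_copy=copy)
            trajectories.append(generate_torsion_trajectory(spec, library))

result = run_pipeline(RunConfig(window="last-half"), trajectories)

print(f"{'residue':>10} {'OC':>6} {'KL':>6} {'TdS':>7} {'region':>6}")
for rid, cmp in sorted(result.comparisons.items()):
    print(f"{str(rid):>10} {cmp.oc:>6.2f} {cmp.kl:>6.2f} "
          f"{cmp.t_delta_s_conf:>+7.2f} {cmp.region:>6}")
print(f"\nOC segment correlation R = {result.oc_segment_r:.3f} "
      "(two trajectory halves)")

outdir = Path("scratch/demo_run")
write_reports(result, outdir)
print(f"reports written to {outdir}/ (per_residue.tsv, set_summary.tsv, "
      "histograms/, manifest.json)")
print("\nResidues frozen into a single rotamer in the crystal show low OC"
      "\nand strongly negative T*dS_conf (regions II/III); residues with"
      "\nunchanged mixtures sit in region I with OC near 1.")
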
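"""Compare a residue's rotamer ensemble between solution and crystal.

Simulates the same glutamine side chain under two conditions — freely
exchanging between three wells in solution, pinned mostly to one well in
the crystal — then computes the overlap coefficient (OC), the
Kullback-Leibler divergence, and the configurational-entropy change
T*dS_conf, and classifies the residue into the conformation/dynamics
quadrant scheme.
"""

from rotamerlab import (EnsembleSpec, RunConfig, generate_condition_pair,
                        load_rotamer_library, run_pipeline)

library = load_rotamer_library()

solution = EnsembleSpec("GLN", (0.4, 0.35, 0.25, 0, 0, 0, 0, 0, 0),
                        noise_sd=6.0, n_frames=4000, seed=1, chain="A",
                        resnum=6)
crystal = EnsembleSpec("GLN", (1.0, 0, 0, 0, 0, 0, 0, 0, 0),
                       noise_sd=6.0, n_frames=4000, seed=2, chain="A",
                       resnum=6, condition="crystal")

traj_s, traj_c, oc_true, tds_true = generate_condition_pair(
    solution, crystal, library)

result = run_pipeline(RunConfig(window="all"), [traj_s, traj_c])
cmp = result.comparisons[traj_s.residue_id]

print(f"residue {traj_s.residue_id}")
print(f"  OC        = {cmp.oc:.3f}   (closed-form truth {oc_true:.3f})")
print(f"  KL        = {cmp.kl:.3f} nats")
print(f"  T*dS_conf = {cmp.t_delta_s_conf:+.3f} kcal/mol "
      f"(truth {tds_true:+.3f})")
print(f"  region    = {cmp.region}")
print(f"  OC bounds from trajectory halves: "
      f"[{cmp.oc_bounds[0]:.3f}, {cmp.oc_bounds[1]:.3f}]")
print("\nOC < 0.5 with |T*dS| > 0.5 kcal/mol means the crystal changes both"
      "\nthe preferred conformation and the side-chain dynamics (region III):"
      "\nthe residue is frozen into one rotamer by crystal packing.")
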
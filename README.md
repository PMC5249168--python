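# rotamerlab

Crystal packing can pin protein side chains into conformations that do not
represent their behavior in solution, complicating the functional
interpretation of X-ray structures. `rotamerlab` quantifies this effect: it
discretizes side-chain χ-angle trajectories (e.g. from crystal and solution
MD simulations of the same protein) into rotamer states and compares the
resulting per-residue rotamer probability distributions between the two
environments, alongside crystal-contact and solvent-exposure annotation
derived from the deposited structure. It is aimed at structural
bioinformaticians and simulators who want to know, residue by residue,
whether the crystal changed a side chain's conformation, its dynamics, or
both.

## What it computes

Every frame's χ vector is mapped to the nearest state of the Penultimate
Rotamer Library (nearest = smallest maximum per-angle circular deviation;
2-fold degenerate terminal dihedrals such as PHE/TYR χ₂, ASP χ₂ and GLU χ₃
are compared with a 180° period). For each residue with state probabilities
*p^S* (solution) and *p^C* (crystal) over its *N* library states:

- **Overlap coefficient** — OC = Σᵢ min(pᵢ^S, pᵢ^C) ∈ [0, 1]; 1 means
  identical histograms, and 1 − OC equals half the L1 distance. A
  Kullback–Leibler divergence (pseudocount-smoothed) is computed as a
  cross-check.
- **Configurational entropy** — S_conf = −k_B Σᵢ pᵢ ln pᵢ, reported as
  T·S in kcal/mol (T = 300 K, k_B = 0.0019872 kcal/(mol·K)); ΔS_conf =
  S_crystal − S_solution, so negative TΔS_conf means dynamics are reduced
  in the crystal. Only this inter-well term is computed; the within-well
  thermal term is assumed to cancel between conditions.
- **X-ray likelihood score** — L^y = ⟨P_i^y(x_i^xray) / (1/N_i)⟩ over
  residues: how much more often the simulated ensemble visits the X-ray
  rotamer than a uniform null model, with the quotient
  L_crystal/L_solution > 1 indicating the crystal ensemble matches the
  experimental conformations better. A top-two dominant-rotamer agreement
  criterion (per-angle ±30° identity) is reported as well.
- **Region classification** — each residue lands in a quadrant of the
  (OC, TΔS_conf) plane: I (no effect), II (conformation changed), III
  (conformation and dynamics changed), IV (dynamics changed only), with
  boundaries at OC = 0.5 and |TΔS_conf| = 0.5 kcal/mol.
- **Environment annotation** — a residue is crystal-contacting when any
  heavy atom lies within 4 Å of a heavy atom of a symmetry/translation
  neighbor copy, and solvent-exposed when its Shrake–Rupley SASA (1.4 Å
  probe) exceeds 20 % of the residue type's tripeptide maximum.
- **Uncertainty** — every OC and TΔS_conf carries bounds from recomputing
  the statistic on two equal, non-overlapping trajectory halves.

A synthetic-data module generates χ trajectories from known rotamer
mixtures (with wrapped, truncated Gaussian within-well noise) and toy
mini-crystals with contact truth known by construction, so the whole
pipeline is testable without any downloads.

## Worked example

`examples/02_compare_conditions.py` simulates one glutamine that exchanges
between three rotamer wells in solution but is pinned to a single well in
the crystal:

```
residue A:Gln6
  OC        = 0.406   (closed-form truth 0.400)
  KL        = 3.846 nats
  T*dS_conf = -0.644 kcal/mol (truth -0.644)
  region    = III
  OC bounds from trajectory halves: [0.402, 0.409]
```

The overlap coefficient below 0.5 says the dominant conformation changed;
TΔS_conf ≈ −0.64 kcal/mol says the crystal removed most of the side
chain's configurational entropy — together region III, the signature of a
residue frozen by crystal packing. The other scripts in `examples/` cover
rotamer assignment, contact/exposure annotation on a toy lattice, and the
full report-writing pipeline; each prints the numbers it computes and what
they mean.

There is also a thin CLI (`rotamerlab extract-chi | annotate | compare |
simulate | report`) over the same functions; χ angles are interchanged as
a plain tab-separated table so no binary trajectory format is required.

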
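# Methods

## Model

A side chain's conformation is reduced to a discrete rotamer state: the
entry of the Penultimate Rotamer Library whose modal χ angles are nearest
to the observed χ vector. "Nearest" is the smallest **maximum** per-angle
circular deviation across the residue's χ angles, with ties broken by the
lowest state ID. The max metric (rather than an L2 or summed deviation)
was chosen because it matches the all-angles-must-match logic of the ±30°
agreement criterion and makes assignment decisions interpretable one angle
at a time. Terminal dihedrals with 2-fold chemical symmetry (PHE/TYR χ₂,
ASP χ₂, GLU χ₃) are compared with an angular period of 180° instead of
360°, because the two atom labelings of those groups are chemically
indistinguishable; for reporting, such angles are folded into (−90°, 90°].
All angles are degrees in (−180°, 180°], IUPAC sign convention; dihedrals
are computed with a vectorized closed-form expression (validated against
gemmi's implementation in the tests).

Given per-frame states, each residue/condition gets a categorical
distribution over its N library states (zero-count states keep probability
0). Identical lattice copies (e.g. the A1/A2 pair of a crystal-simulation
unit cell) are pooled by concatenating their frames, since they sample the
same packing environment. The default analysis window is the last half of
the frames (equilibrated portion); window and stride are configurable.

Comparison statistics on the two distributions p^S, p^C:

- OC = Σ min(pᵢ^S, pᵢ^C). Identity used in tests: 1 − OC = ½‖p^S − p^C‖₁.
- KL(p^S‖p^C) in nats, after adding a pseudocount to every bin of both
  distributions and renormalizing. Default pseudocount 1/n_frames (one
  pseudo-observation spread over the histogram); 0 is allowed and yields
  +inf when an unsmoothed crystal bin is empty where solution has mass.
- Configurational entropy S = −k_B Σ pᵢ ln pᵢ with 0·ln 0 = 0, reported
  as T·S (k_B = 0.0019872 kcal/(mol·K), T = 300 K default). ΔS_conf =
  S_crystal − S_solution. The within-well (thermal) entropy term is
  deliberately not computed: the model assumes it is state- and
  condition-independent for a given residue, so it cancels from the
  difference. Inter-residue coupling is likewise ignored (independent-site
  approximation), which can overestimate absolute entropies but not the
  per-residue comparison this package reports.
- Likelihood score L^y: mean over residues of P_i^y(x_i^xray)·N_i. The
  1/N_i null normalization stops small residues (few states, easy to match
  by chance) from dominating the average. The X-ray state x_i^xray is the
  nearest-library assignment of the conformer-A χ vector; alternate
  conformers are kept for reporting only.
- Dominant-rotamer agreement: the X-ray state must be one of the two most
  populated states. Only visited states (p > 0) qualify as dominant, and
  ties at the second rank include all tied states to avoid
  order-dependence. Agreement can alternatively be judged by the strict
  per-angle ±30° identity of `matches_within_tolerance`.
- Region classification on (OC, TΔS_conf): boundaries OC = 0.5 and
  |TΔS_conf| = 0.5 kcal/mol, both inclusive toward region I ("no
  effect"), i.e. OC exactly 0.5 counts as conformation unchanged.

Uncertainty: every statistic is recomputed on the two equal, non-
overlapping halves of the analysis window (an odd frame goes to the first
half); the pair of values gives (low, high) bounds per residue and a
cross-half Pearson R over residues as a sampling-adequacy summary. Note
that the pooled-window value is not mathematically guaranteed to lie
inside the half-window bounds (OC is concave under distribution mixing),
but for stationary sampling it does so up to noise, which the tests assert
with a small margin.

## Crystal environment

Contacts: the asymmetric unit's heavy atoms (hydrogens excluded; waters,
ions and ligands excluded by default) are expanded with all space-group
operators combined with integer cell translations in ±1 cell (the shell is
configurable), and a residue is flagged contacting when any heavy atom
lies within the cutoff (default 4.0 Å, boundary inclusive, with a 1e-9 Å
epsilon absorbing fractional/Cartesian round-trip error) of any neighbor
copy atom. Distance queries use a k-d tree; tests compare against a
brute-force all-pairs oracle and against mini-crystals whose contact truth
is known by construction.

Solvent exposure: per-residue SASA is computed chain-by-chain in isolation
(Shrake–Rupley, probe 1.4 Å, element-based radii, 1000 sphere points per
atom — about the classical 10–15 points/Å² sampling density on a typical
extended atom) and divided by the residue type's theoretical maximum in an
extended tripeptide (packaged reference table, Tien et al. 2013
"theoretical" values). A residue is exposed when the fraction strictly
exceeds 0.2. Because point-sampling density and reference tables differ
slightly between SASA implementations, counts of exposed residues should
be compared across tools with a ±2-residue margin.

Disulfide-bonded cysteines (SG–SG ≤ 2.3 Å, configurable) and the
non-rotameric ALA/GLY are excluded from rotamer analysis; every exclusion
is recorded in the run manifest with a machine-readable reason.

## Synthetic data

The generator emulates the one property of an equilibrated MD trajectory
that the statistics consume: stationary per-residue sampling of rotamer
wells. Each frame draws a state from a configurable mixture over the
library states and adds Gaussian within-well noise, truncated at 3 SD and
wrapped to (−180°, 180°]. The default noise SD is 6°: the closest pair of
wells in the library is 40° apart (ASP/ASN χ₂, p-10 vs p30), so 3·SD must
stay below 20° for wells to remain non-overlapping — at the default width
discretization is exact and estimation error is purely binomial. An
optional sticky-Markov mode (stay with probability s, otherwise redraw
from the mixture, stationary law unchanged) produces autocorrelated frames
for exercising the segment-split uncertainty under slow mixing.

What the generator does **not** emulate: within-well anharmonicity,
correlated motions between χ angles or between residues, slow drift or
non-stationarity, and backbone-dependent well positions. Passing
parameter-recovery tests therefore demonstrates the correctness of the
discretization and statistics pipeline, not the fidelity of any MD force
field or the convergence behavior of real trajectories.

Mini-crystals place a linear pseudo-atom chain in a P 1 or P 1 2₁ 1 cell
sized so the closest inter-copy heavy-atom distance is a chosen gap;
which residues contact a neighbor is then a closed-form function of the
layout, giving an independent truth for the contact detector.

## Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| contact cutoff | 4.0 Å | heavy-atom distance to a neighbor copy, inclusive |
| symmetry shell | ±1 cell | translation range for neighbor expansion |
| probe radius | 1.4 Å | SASA probe sphere |
| SASA points/atom | 1000 | Shrake–Rupley sampling |
| exposure threshold | 0.2 | strict > on relative accessibility |
| agreement tolerance | ±30° | per-angle rotamer identity |
| temperature | 300 K | T·S reporting scale |
| region boundaries | OC 0.5, TΔS 0.5 kcal/mol | inclusive toward region I |
| analysis window | last half | equilibrated portion of the frames |
| KL pseudocount | 1/n_frames | smoothing before divergence |
| generator noise SD | 6° | within-well width, 3 SD < half minimal well separation |

Degenerate inputs: empty frame windows, empty residue sets, a zero
solution likelihood (X-ray state never sampled) and mismatched residue
universes are errors, not silent results; missing side-chain atoms skip
the residue with a logged warning.

## Problem sizes

The test suite and the acceptance script run on synthetic inputs sized for
a laptop-class single core: parameter recovery uses 50 residues × 10,000
frames (where binomial sampling error is ≈0.005 per bin, comfortably
inside the 0.02 acceptance band), likelihood calibration 2,000 residues ×
1,000 frames, and lattice checks a few hundred atoms. These sizes were
chosen as the smallest at which the expected statistical behavior is
unambiguous.

## Known limitations

- The nearest-state rule is a documented choice; the historical CCP4
  `rotamer` tool's internal metric is unspecified, so assignments near
  well boundaries may differ from legacy analyses.
- Non-rotameric terminal angles (e.g. LYS χ₄ near eclipsed values) are
  assigned to the nearest defined state rather than clamped or flagged.
- The packaged library is backbone-independent; φ/ψ-dependent rotamer
  definitions are out of scope.
- SASA-derived counts depend on sphere-point density and the reference
  maxima; cross-tool agreement is expected only within a couple of
  residues.
- Binary trajectory formats are not read directly; χ angles enter as a
  plain table (extraction from multi-model PDB is provided).
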
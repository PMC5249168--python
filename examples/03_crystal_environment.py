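"""Crystal contacts and solvent exposure on a toy lattice.

Builds a mini-crystal whose chain ends approach their lattice neighbors
at a known distance, expands the symmetry/translation neighbors, flags
contacting residues with the 4 A heavy-atom rule, and computes relative
solvent accessibility for the isolated chain.
"""

from rotamerlab import (MiniCrystalSpec, classify_environment,
                        detect_contacts, expand_neighbors,
                        generate_mini_crystal, relative_accessibility)

spec = MiniCrystalSpec(n_residues=8, gap=3.5, space_group="P 1")
lattice, truth = generate_mini_crystal(spec, cutoff=4.0)

neighbors = expand_neighbors(lattice, shell=1)
print(f"P 1 cell, shell 1: {len(neighbors)} neighbor copies "
      f"({lattice.n_atoms} atoms each)")

contacts = detect_contacts(lattice, cutoff=4.0)
access = relative_accessibility(lattice, "X")
annotations = classify_environment(contacts, access, exposure_threshold=0.2)

print(f"{'residue':>10} {'contacting':>10} {'truth':>6} "
      f"{'rel_access':>10} {'exposed':>8}")
for rid, ann in annotations.items():
    print(f"{str(rid):>10} {str(ann.contacting):>10} "
          f"{str(truth[rid]):>6} {ann.relative_accessibility:>10.2f} "
          f"{str(ann.exposed):>8}")
print("\nOnly the two chain-end residues sit within 4 A of a neighbor copy"
      "\n(the inter-copy gap is 3.5 A), and detection agrees with the"
      "\nconstruction truth exactly. All pseudo-residues of this open chain"
      "\nare solvent-exposed.")
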
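"""Superpose a paralog pair and measure a planted helix displacement.

The second structure differs from the first by three point
substitutions and a rigid 1.4 Å shift of one helix. After sequence
alignment, Kabsch superposition on all matched Cα atoms gives the
overall RMSD; measuring the shifted residue's Cα in a frame fitted to
the *unshifted* helices recovers the planted 1.4 Å exactly.
"""

import numpy as np

from poregraph import (
    kabsch_superpose,
    paired_rmsd,
    residue_displacement,
    structure_residue_map,
)
from poregraph.synthetic import FixtureSpec, PlantedBond, make_paralog_pair

spec = FixtureSpec(seed=5, n_helices=5, residues_per_helix=20,
                   planted_hbonds=[PlantedBond(2, 25, 2.8)])
s_a, s_b, truth = make_paralog_pair(
    spec,
    mutations=[(40, "ALA"), (55, "PHE"), (70, "VAL")],
    displacement=(85, 1.4),
)

rmap = structure_residue_map(s_a, s_b)
print(f"sequence identity: {rmap.identity_pct:.1f} %  ({len(rmap)} matched residues)")
print(f"Cα RMSD (optimal fit): {paired_rmsd(s_a, s_b, rmap):.3f} Å")

# frame from the helices that did NOT move — for this pair it is the identity
helix = truth.displacement["helix"]
rph = truth.displacement["helix_residues"]
keep = [(ka, kb) for ka, kb in rmap.pairs
        if not (helix * rph < ka[1] <= (helix + 1) * rph)]
P = np.array([s_a.find(ka).get_atom("CA").coords for ka, _ in keep])
Q = np.array([s_b.find(kb).get_atom("CA").coords for _, kb in keep])
frame = kabsch_superpose(P, Q)

key = tuple(truth.displacement["residue_key"])
d = residue_displacement(s_a, s_b, rmap, key, "CA", frame)
print(f"Cα displacement of residue {key[1]} in the unshifted frame: {d:.2f} Å")
# Prints 1.40 — the planted shift. The whole-structure RMSD above is
# smaller because the optimal fit spreads the one-helix shift over all
# residues, exactly as happens when comparing real paralog structures.
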
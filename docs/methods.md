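# Methods

This note documents the models, parameter choices and numerical
conventions behind `poregraph`, and what the synthetic test fixtures do
and do not establish about behaviour on real structures.

## Structure model and entity classification

Coordinate files (mmCIF or PDB, parsed with gemmi) are reduced to an
explicit Structure → Residue → Atom hierarchy keyed by *author*
numbering — the numbering used in the literature (e.g. Asp116) — with
no renumbering anywhere. Zero-occupancy atoms are dropped; within an
altloc group only the highest-occupancy conformer is kept, ties going
to the alphabetically first altloc. This matches common practice for
distance-based analysis, where a single consistent conformer is needed
and occupancy is the only principled selector.

Every residue receives exactly one entity label: protein (standard
amino acids plus MSE and the retinylidene-lysine LYR), water, monatomic
ion (known ion codes, plus any unknown single-atom het group),
phospholipid (PEE — dioleoylphosphatidylethanolamine — and related
codes), sterol (CLR, CHS, …), retinal, or other-het (with a logged
warning). The tables are plain dicts and caller-extensible, because
lipid modelling conventions vary between depositions.

Censuses run over the whole model or per protomer. Protomer membership
of het groups is not recorded in deposited files, so it is assigned by
minimum heteroatom distance to each protomer's protein atoms — the
natural geometric reading of "the waters of this protomer". For
trimers, a phospholipid is *central* when its centroid projects inside
the triangle of the three protomer centroids in the membrane plane;
this reproduces a "central lipid plug vs annular lipids" split without
manual curation.

## Residue correspondence

Two-structure comparison needs exactly one pairwise correspondence, so
multiple-alignment machinery is deliberately avoided: Needleman–Wunsch
global alignment (Biopython's PairwiseAligner) with BLOSUM62, gap open
−11, gap extend −1. Identity is identical pairs over aligned (two-
residue) columns; similarity counts pairs with a positive BLOSUM62
score. For a ~74 %-identical pair the alignment is essentially forced
and any reasonable scoring gives the same residue map; the map is then
restricted to residues actually modeled in both structures. For
equal-length ungapped paralogs the map provably reduces to same-number
pairing, which the tests assert. A caveat discovered while testing: on
low-complexity sequences (e.g. the glycine background of synthetic
fixtures) gap placement within a homopolymer run is degenerate, so
correspondence for engineered fixtures should be the explicit identity
map, not an alignment.

## Superposition and displacement

Kabsch superposition: SVD of the covariance of centered coordinate
sets with the usual determinant correction, so the rotation is always
proper. Inputs need ≥3 non-collinear points. RMSD is reported for two
selections — Cα-only and all heavy atoms shared by name within each
residue pair — because published single-number RMSDs rarely state the
selection; both are in the report.

Per-residue displacement between paralogs requires a common frame. The
only frame both structures define without manual choices is the
superposition on *all* mapped Cα atoms, so that is the default. Note
the consequence, visible in the fixtures: a rigid 1.4 Å shift of one
helix out of four is partially absorbed by the whole-structure fit and
reads as ~1.0 Å in that frame; in a frame fitted to the unshifted
remainder it reads 1.40 Å exactly. Displacements are therefore
frame-annotated, and the API accepts any caller-supplied frame.

## H-bond network graphs

The criterion is distance-only: donor and acceptor heteroatoms within
4.0 Å, no angle terms and no hydrogens (the models carry none). The
3.5 Å threshold marks *strong* bonds; the wider default exists to admit
the weak interactions of Met SD. The donor/acceptor table covers
side-chain polar atoms only (hydroxyls as both donor and acceptor; His
ND1/NE2 both, since protonation is unknown; Cys SG both; Met SD
acceptor only; Lys NZ doubles as the retinal Schiff-base nitrogen when
the lysine carries the chromophore). Backbone N/O are excluded: these
are side-chain network graphs, and including the backbone would bury
the selectivity-relevant signal under the helical i→i+4 ladder.

Detection uses a k-d tree; an all-pairs brute-force twin exists purely
as a test oracle and the two are asserted identical on hundreds of
random structures. Graphs are residue-level: one node per side chain /
water / Schiff base, parallel atom contacts collapsed to a single edge
keeping the minimum distance (strong if any contributing contact is).

Difference graphs: an edge of A is conserved iff both endpoints map
through the residue correspondence and the image pair is an edge of B.
Waters never map across structures — there is no canonical water
numbering — so every water-mediated edge is structure-specific by
construction, and conserved edges involve only amino-acid/Schiff-base
nodes. Whether published edge totals for a given pair include
water–water edges is not always stated; both policies are implemented
(`include_water_water` default, a flag flips it) and the comparison
against a published total should try both and record which reproduces.

Projection for 2D drawing assumes the membrane normal is on z (the
convention of membrane-oriented depositions; inputs are taken as
pre-oriented). x is the first principal component of the node (x, y)
anchors (Cα for residues, O for waters), sign fixed so the node of
largest |x| is positive; z is the Cα z *exactly*, so vertical order in
the drawing is the true height order along the pathway.

## Cavities and tunnels

The structure is cast on a cubic lattice (default 0.5 Å) with Bondi
(1964) element radii; a voxel is protein when its center lies inside
any atom's vdW sphere. The grid origin snaps to the spacing lattice so
results do not depend on absolute coordinates and symmetric inputs stay
symmetric. Bulk solvent is defined HOLLOW-style by a surface probe
(default 1.4 Å, a water radius): free space is eroded by the probe
using the *exact* clearance field (distance to the nearest vdW surface,
computed per distinct radius with k-d trees — not the voxelized
distance transform, whose half-voxel bias is enough to seal a 1 Å
pinhole against a 0.9 Å probe), components touching the box boundary
are flood-filled, and the result is dilated back by the probe within
free space. The dilation adds half a voxel diagonal of slack because
the probe *center* is quantized to voxel centers; without the slack, a
thin sheet of free voxels hovering just above the surface is orphaned
into phantom cavities. Remaining free components are cavities
(6-connected); components under 1 Å³ are inter-atom surface crevices no
solvent could occupy and are dropped from the cavity list. Cavity
voxels can be written as dummy pseudo-atom PDB files for display.

Tunnels: max–min (widest-bottleneck) Dijkstra over the clearance field
from a seed voxel to any bulk voxel, restricted to voxels where the
probe fits (default 0.9 Å, the conventional ion-pathway probe). Ties
break by path length, then lexicographic voxel order — fully
deterministic. This replaces Voronoi-based tunnel methods; for the
scientific question asked here (does a tunnel exist at a given probe,
and what is its bottleneck) the grid formulation is equivalent and much
simpler, and the monotonicity property (found at probe p ⇒ found at
every p′ < p, with the same bottleneck) is tested. For channel
comparisons the seed is computed, not hand-placed: the midpoint between
the Schiff-base nitrogen and the centroid of the extracellular aromatic
cluster side chains (residues configurable; defaults 233 and
102/210/221/222 for the channelrhodopsin pair).

## Synthetic fixtures

The generator builds idealized α-helical bundles (rise 1.5 Å/residue,
100° twist, 2.3 Å Cα radius, axes 10 Å apart on a ring) of glycines,
then plants specific side chains: each planted H-bond places the two
heteroatoms at the stated distance to within 0.01 Å, either between two
residues or between a residue and a newly placed water aimed into the
bundle lumen. Decoy entities (waters, Na⁺, PEE- and CLR-like groups)
sit on a wide ring far from every polar atom. After placement the
generator *verifies* its own truth record with the brute-force
detector at a 4.2 Å margin and refuses fixtures with accidental or
missing bonds — planted truth is checked, not assumed. Paralog pairs
rebuild the same backbone with point substitutions (non-polar targets
only, so the bond inventory stays controlled), optionally a different
planted bond set, and a rigid shift of one helix along x. All
randomness flows through one numpy generator seeded from the spec;
identical seeds give byte-identical files.

Analytic cavity fixtures are Fibonacci-sphere shells (interior volume
(4/3)πr³) with optional exact-clearance pinhole rims, and slabs pierced
by a cylindrical channel whose wall is an exact-radius ring stack.

What the fixtures do **not** emulate: real side-chain geometry and
rotamers, backbone H-bonding, crystallographic/EM coordinate noise,
alternate conformations, partial occupancy, or realistic lipid
geometry. Passing tests therefore establish the *algorithms* (detection
≡ oracle, partition identities, volume convergence, exact recovery of
planted quantities), not model quality on experimental data; the
deposited-pair checks in the acceptance suite exist for that and run
whenever the two PDB entries can be fetched.

## Problem sizes and determinism

The reference computation (`scripts/acceptance.py`) uses a seven-helix
bundle of 175 residues — the scale of a 7TM domain — with a ten-bond
planted network, 15 waters and one ion in the protomer-analogue, and
~50³-voxel cavity grids; it completes in seconds and is fully
determined by `--seed`. Reports serialize with sorted keys and no
timestamps, so re-running any comparison on the same inputs is
byte-identical.

## Known limitations

* Distance-only H-bonds accept some non-bonding close contacts that an
  angle-aware criterion would reject; this is the price of working
  without hydrogens and matches the published criterion.
* The difference graph keys on residue correspondence only; a conserved
  edge says the same residue pair is bonded, not that the geometry is
  identical (edge distances are reported for that).
* Entity classification of exotic lipids falls back to `other_het`;
  extend the tables per deposition.
* Tunnel paths are voxel chains: bottleneck radii carry ~half-voxel
  uncertainty, and path *identity* (unlike existence and bottleneck) is
  not a stable output.
* Membrane orientation is assumed (z = normal); no membrane-positioning
  calculation is performed.
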
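"""H-bond detection, graphs, difference graphs, projection, distances."""

import random

import networkx as nx
import numpy as np
import pytest

from poregraph import (
    Atom,
    Residue,
    Structure,
    build_graph,
    detect_hbonds,
    difference_graph,
    hbond_graph,
    min_sidechain_distance,
    project_graph,
    structure_residue_map,
    summarize_graph,
)
from poregraph.hbond import STRONG_CUTOFF, detect_hbonds_bruteforce
from poregraph.synthetic import FixtureSpec, PlantedBond, make_fixture

POLAR_POOL = [
    ("SER", "OG", "O"), ("ASP", "OD1", "O"), ("LYS", "NZ", "N"),
    ("TYR", "OH", "O"), ("HIS", "ND1", "N"), ("MET", "SD", "S"),
    ("HOH", "O", "O"), ("GLN", "NE2", "N"), ("GLU", "OE2", "O"),
    ("THR", "OG1", "O"),
]


def random_polar_structure(seed: int, n_res: int = 25, box: float = 16.0) -> Structure:
    """Random scatter of polar groups — dense enough for many contacts."""
    rng = np.random.default_rng(seed)
    residues = []
    for i in range(n_res):
        comp, aname, elem = POLAR_POOL[int(rng.integers(len(POLAR_POOL)))]
        base = rng.uniform(0, box, 3)
        atoms = [Atom(2 * i + 1, aname, elem, base)]
        chain = "W" if comp == "HOH" else "A"
        if comp != "HOH":
            atoms.append(Atom(2 * i + 2, "CA", "C", base + rng.normal(size=3) * 0.5))
        residues.append(Residue(chain, i + 1, "", comp, atoms))
    s = Structure(id=f"rand-{seed}", residues=residues)
    s.assembly = {ch: 0 for ch in s.chains()}
    return s


def edge_set(bonds):
    return {
        (frozenset((b.donor.residue_key, b.acceptor.residue_key)), round(b.distance, 9))
        for b in bonds
    }


def test_glycine_only_chain_has_no_hbonds():
    s, _ = make_fixture(FixtureSpec(seed=2, planted_hbonds=[]))
    assert detect_hbonds(s) == []
    assert build_graph([], s).number_of_edges() == 0


def test_planted_bond_detected_with_distance_and_class(basic_fixture):
    s, truth = basic_fixture
    bonds = detect_hbonds(s)
    assert len(bonds) == truth.n_bonds
    dists = sorted(round(b.distance, 2) for b in bonds)
    assert dists == sorted(round(t["distance"], 2) for t in truth.planted_bonds)
    assert all(b.strength_class == "strong" for b in bonds if b.distance <= 3.5)


def _two_residue_structure(comp_a, atom_a, elem_a, comp_b, atom_b, elem_b, dist):
    ra = Residue("A", 1, "", comp_a, [
        Atom(1, "CA", "C", np.array([-1.5, 0.0, 0.0])),
        Atom(2, atom_a, elem_a, np.array([0.0, 0.0, 0.0])),
    ])
    rb = Residue("A", 2, "", comp_b, [
        Atom(3, "CA", "C", np.array([dist + 1.5, 0.0, 0.0])),
        Atom(4, atom_b, elem_b, np.array([dist, 0.0, 0.0])),
    ])
    s = Structure(id="pair", residues=[ra, rb], assembly={"A": 0})
    return s


def test_met_thioether_bond_needs_wide_cutoff():
    s = _two_residue_structure("MET", "SD", "S", "TYR", "OH", "O", 3.8)
    assert len(detect_hbonds(s, cutoff=4.0)) == 1
    assert detect_hbonds(s, cutoff=4.0)[0].strength_class == "weak"
    assert detect_hbonds(s, cutoff=3.5) == []


def test_acceptor_acceptor_pairs_rejected():
    s = _two_residue_structure("ASP", "OD1", "O", "GLU", "OE2", "O", 3.0)
    assert detect_hbonds(s) == []


@pytest.mark.parametrize("seed", range(8))
def test_grid_detection_equals_all_pairs_oracle(seed):
    s = random_polar_structure(seed)
    assert edge_set(detect_hbonds(s)) == edge_set(detect_hbonds_bruteforce(s))


@pytest.mark.parametrize("seed", [0, 3, 5])
def test_cutoff_monotonicity(seed):
    s = random_polar_structure(seed)
    e35 = edge_set(detect_hbonds(s, 3.5))
    e40 = edge_set(detect_hbonds(s, 4.0))
    assert {p for p, _ in e35} <= {p for p, _ in e40}
    g = build_graph(detect_hbonds(s, 4.0), s)
    assert summarize_graph(g)["strong_edges"] == build_graph(
        detect_hbonds(s, STRONG_CUTOFF), s
    ).number_of_edges()


def test_graph_independent_of_atom_order():
    s = random_polar_structure(42)
    shuffled = Structure(
        id="shuffled",
        residues=random.Random(7).sample(s.residues, len(s.residues)),
    )
    shuffled.assembly = dict(s.assembly)
    for r in shuffled.residues:
        random.Random(9).shuffle(r.atoms)
    assert edge_set(detect_hbonds(s)) == edge_set(detect_hbonds(shuffled))


def test_parallel_atom_pairs_collapse_to_one_edge():
    ra = Residue("A", 1, "", "SER", [
        Atom(1, "CA", "C", np.array([-1.5, 0.0, 0.0])),
        Atom(2, "OG", "O", np.array([0.0, 0.0, 0.0])),
    ])
    rb = Residue("A", 2, "", "ASP", [
        Atom(3, "CA", "C", np.array([4.0, 1.0, 0.0])),
        Atom(4, "OD1", "O", np.array([2.8, 0.0, 0.0])),
        Atom(5, "OD2", "O", np.array([3.0, 0.8, 0.0])),
    ])
    # add a LYS donor so both carboxylate oxygens can also bond elsewhere
    rc = Residue("A", 3, "", "LYS", [
        Atom(6, "CA", "C", np.array([0.0, 9.0, 0.0])),
        Atom(7, "NZ", "N", np.array([0.0, 0.0, 3.0])),
    ])
    s = Structure(id="collapse", residues=[ra, rb, rc], assembly={"A": 0})
    bonds = detect_hbonds(s)
    # OG bonds to OD1 and OD2; NZ to OG: 3 atom pairs min
    assert len(bonds) >= 3
    g = build_graph(bonds, s)
    assert g.number_of_edges() == 2  # SER–ASP collapsed, SER–LYS
    assert g.edges["A:1:SER", "A:2:ASP"]["distance"] == pytest.approx(2.8)
    assert g.edges["A:1:SER", "A:2:ASP"]["strength"] == "strong"


def test_summary_counts_planted_partition():
    bonds = [
        PlantedBond(2, 21, 2.8),
        PlantedBond(6, None, 2.9),
        PlantedBond(30, None, 3.1, comp_a="TYR", atom_a="OH"),
        PlantedBond(52, None, 3.0, comp_a="LYS", atom_a="NZ"),
        PlantedBond(45, 62, 3.9, comp_a="MET", atom_a="SD", comp_b="THR", atom_b="OG1"),
    ]
    s, truth = make_fixture(FixtureSpec(seed=8, planted_hbonds=bonds))
    summary = summarize_graph(hbond_graph(s))
    assert summary["total_edges"] == 5
    assert summary["water_mediated_edges"] == 3
    assert summary["sidechain_sidechain_edges"] == 2
    assert summary["strong_edges"] == 4


def test_water_policy_flag_drops_water_water_edges():
    ra = Residue("A", 1, "", "SER", [
        Atom(1, "CA", "C", np.array([-1.5, 0.0, 0.0])),
        Atom(2, "OG", "O", np.array([0.0, 0.0, 0.0])),
    ])
    w1 = Residue("W", 1, "", "HOH", [Atom(3, "O", "O", np.array([2.8, 0.0, 0.0]))])
    w2 = Residue("W", 2, "", "HOH", [Atom(4, "O", "O", np.array([5.5, 0.0, 0.0]))])
    s = Structure(id="wchain", residues=[ra, w1, w2], assembly={"A": 0, "W": 0})
    bonds = detect_hbonds(s)
    incl = build_graph(bonds, s, "include_water_water")
    excl = build_graph(bonds, s, "exclude_water_water")
    assert summarize_graph(incl)["water_water_edges"] == 1
    assert summarize_graph(excl)["water_water_edges"] == 0
    assert summarize_graph(incl)["total_edges"] == summarize_graph(excl)["total_edges"] + 1


def test_difference_graph_self_is_all_conserved(basic_fixture):
    s, truth = basic_fixture
    g = hbond_graph(s)
    rmap = structure_residue_map(s, s)
    d = difference_graph(g, g, rmap)
    # the water-mediated bond never maps, everything else is conserved
    n_water = truth.n_water_mediated
    assert len(d.conserved_edges) == truth.n_bonds - n_water
    assert len(d.unique_a_edges) == n_water
    assert len(d.unique_b_edges) == n_water


def identity_residue_map(s: Structure):
    """Same-number pairing, as shared numbering between paralogs implies."""
    from poregraph.correspondence import ResidueMap

    keys = [r.key for r in s.protein_residues()]
    return ResidueMap([(k, k) for k in keys], 100.0, 100.0)


# well-separated planted pairs: helix 0 ↔ 1 levels 2,6,10,14,18 and
# helix 2 ↔ 3 levels 2,6,10 (z spacing 6 Å prevents accidental contacts)
POOL_01 = [(2 + 4 * k, 22 + 4 * k) for k in range(5)]
POOL_23 = [(42 + 4 * k, 62 + 4 * k) for k in range(3)]


@pytest.mark.parametrize("seed", range(5))
def test_difference_partition_identities_random_planted(seed):
    """conserved ∪ unique_A = edges(A); same for B; sets disjoint."""
    rng = random.Random(seed)
    k_shared = rng.randint(1, 5)
    bonds_a = [PlantedBond(a, b, 2.6 + 0.2 * i) for i, (a, b) in enumerate(POOL_01)]
    shared = rng.sample(POOL_01, k_shared)
    bonds_b = [PlantedBond(a, b, 2.7 + 0.1 * i) for i, (a, b) in enumerate(shared)]
    bonds_b += [PlantedBond(a, b, 3.0) for (a, b) in rng.sample(POOL_23, 2)]
    spec = FixtureSpec(seed=seed, n_helices=4, residues_per_helix=20,
                       planted_hbonds=bonds_a)
    from poregraph.synthetic import make_paralog_pair

    s_a, s_b, _ = make_paralog_pair(spec, planted_hbonds_b=bonds_b)
    g_a, g_b = hbond_graph(s_a), hbond_graph(s_b)
    d = difference_graph(g_a, g_b, identity_residue_map(s_a))

    edges_a = {frozenset(e) for e in g_a.edges()}
    edges_b = {frozenset(e) for e in g_b.edges()}
    cons_a = {frozenset(e) for e in d.conserved_edges}
    cons_b = {frozenset(e) for e in d.conserved_edges_b}
    uniq_a = {frozenset(e) for e in d.unique_a_edges}
    uniq_b = {frozenset(e) for e in d.unique_b_edges}
    assert cons_a | uniq_a == edges_a
    assert cons_b | uniq_b == edges_b
    assert cons_a & uniq_a == set()
    assert cons_b & uniq_b == set()
    assert len(d.conserved_edges) == k_shared


def test_difference_planted_4_of_7():
    bonds_a = [PlantedBond(a, b, 2.8) for (a, b) in POOL_01[:4]]
    bonds_a += [PlantedBond(a, b, 3.1) for (a, b) in POOL_23]
    bonds_b = [PlantedBond(a, b, 2.9) for (a, b) in POOL_01[:4]]
    bonds_b += [PlantedBond(a + 2, b + 2, 3.2) for (a, b) in POOL_23]
    from poregraph.synthetic import make_paralog_pair

    spec = FixtureSpec(seed=17, n_helices=4, residues_per_helix=20, planted_hbonds=bonds_a)
    s_a, s_b, _ = make_paralog_pair(spec, planted_hbonds_b=bonds_b)
    d = difference_graph(
        hbond_graph(s_a), hbond_graph(s_b), identity_residue_map(s_a)
    )
    assert len(d.conserved_edges) == 4
    assert len(d.unique_a_edges) == 3
    assert len(d.unique_b_edges) == 3


def _toy_graph(positions):
    g = nx.Graph()
    for i, p in enumerate(positions):
        g.add_node(f"n{i:02d}", kind="sidechain", comp_id="SER",
                   residue_key=("A", i, ""), position=tuple(p))
    return g


def test_projection_recovers_collinear_layout():
    pos = [(float(i) * 2.0, float(i) * 1.0, float(i)) for i in range(5)]
    proj = project_graph(_toy_graph(pos))
    xs = [proj.coords[f"n{i:02d}"][0] for i in range(5)]
    gaps = np.diff(xs)
    assert np.allclose(np.abs(gaps), np.linalg.norm([2.0, 1.0]), atol=1e-9)
    # z passes through untouched
    assert [proj.coords[f"n{i:02d}"][1] for i in range(5)] == [p[2] for p in pos]


def test_projection_matches_sklearn_pca():
    from sklearn.decomposition import PCA

    rng = np.random.default_rng(5)
    pts = rng.normal(size=(40, 3)) * [4.0, 1.5, 2.0]
    proj = project_graph(_toy_graph(pts))
    ours = np.array([proj.coords[f"n{i:02d}"][0] for i in range(40)])
    ref = PCA(n_components=1).fit_transform(pts[:, :2]).ravel()
    agree = min(np.abs(ours - ref).max(), np.abs(ours + ref).max())
    assert agree < 1e-9


def test_projection_z_is_exact_ca_z(basic_fixture):
    s, _ = basic_fixture
    g = hbond_graph(s)
    proj = project_graph(g)
    for n, data in g.nodes(data=True):
        if data["kind"] == "sidechain":
            r = s.find(data["residue_key"])
            assert proj.coords[n][1] == r.get_atom("CA").coords[2]
    with pytest.raises(ValueError):
        project_graph(_toy_graph([(0.0, 0.0, 0.0)]))


def test_min_sidechain_distance_planted(basic_fixture):
    s, truth = basic_fixture
    first = truth.planted_bonds[0]
    key_a = ("A", 3, "")  # residue index 2 → seq number 3
    key_b = ("A", 22, "")
    d = min_sidechain_distance(s, key_a, key_b)
    assert d == pytest.approx(first["distance"], abs=1e-9)
    # named-atom filter agrees with brute force over the same atoms
    d2 = min_sidechain_distance(s, key_a, key_b, (["OG"], ["OD1", "OD2"]))
    assert d2 == pytest.approx(d)
    with pytest.raises(ValueError):
        min_sidechain_distance(s, key_a, key_a)
    with pytest.raises(ValueError):
        min_sidechain_distance(s, key_a, key_b, ([], ["OD1"]))
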
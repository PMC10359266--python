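"""Hydrogen-bond network graphs and their conserved/difference comparison.

H-bonds are detected with a distance-only criterion: a donor and an
acceptor heteroatom within a cutoff (default 4.0 Å; bonds at most 3.5 Å
are classed "strong", longer ones "weak"). No angles and no hydrogens
are used — deposited cryo-EM models carry none, and the wider 4.0 Å
cutoff deliberately admits the weak interactions of Met thioether
sulfurs. Nodes are residue-level groups: H-bonding side chains, the
retinal Schiff base, and water molecules; multiple atom-pair contacts
between the same two groups collapse into a single edge annotated with
the minimum distance.

The difference graph of two homologous structures partitions each
structure's edges into conserved and structure-unique sets under a
residue correspondence. Waters never correspond across structures
(there is no canonical water numbering), so every water-mediated edge
is structure-specific by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from . import tables
from .correspondence import ResidueMap
from .structure import Residue, ResidueKey, Structure

STRONG_CUTOFF = 3.5
DEFAULT_CUTOFF = 4.0


@dataclass(frozen=True)
class AtomRef:
    residue_key: ResidueKey
    comp_id: str
    atom_name: str

    @property
    def label(self) -> str:
        c, n, i = self.residue_key
        return f"{c}:{n}{i}:{self.comp_id}:{self.atom_name}"


@dataclass
class HBond:
    donor: AtomRef
    acceptor: AtomRef
    distance: float

    def __post_init__(self) -> None:
        if not (0.0 < self.distance <= DEFAULT_CUTOFF + 1.0):
            raise ValueError(f"implausible H-bond distance {self.distance}")

    @property
    def strength_class(self) -> str:
        return "strong" if self.distance <= STRONG_CUTOFF else "weak"


class DonorAcceptorTable:
    """(comp_id, atom_name) → role table, extensible per instance."""

    def __init__(self, extra: dict[tuple[str, str], str] | None = None) -> None:
        self.roles = dict(tables.DEFAULT_DONOR_ACCEPTOR)
        if extra:
            self.roles.update(extra)

    def role(self, comp_id: str, atom_name: str) -> str | None:
        return self.roles.get((comp_id, atom_name))

    def polar_atom_names(self, comp_id: str) -> list[str]:
        return [a for (c, a), _ in self.roles.items() if c == comp_id]


DEFAULT_TABLE = DonorAcceptorTable()


def _polar_atoms(
    s: Structure, table: DonorAcceptorTable
) -> list[tuple[AtomRef, np.ndarray, str]]:
    out = []
    for r in s.residues:
        for a in r.atoms:
            role = table.role(r.comp_id, a.name)
            if role is not None:
                out.append((AtomRef(r.key, r.comp_id, a.name), a.coords, role))
    return out


def _roles_compatible(role_a: str, role_b: str) -> bool:
    can_donate_a = role_a in (tables.DONOR, tables.BOTH)
    can_accept_a = role_a in (tables.ACCEPTOR, tables.BOTH)
    can_donate_b = role_b in (tables.DONOR, tables.BOTH)
    can_accept_b = role_b in (tables.ACCEPTOR, tables.BOTH)
    return (can_donate_a and can_accept_b) or (can_donate_b and can_accept_a)


def detect_hbonds(
    s: Structure,
    cutoff: float = DEFAULT_CUTOFF,
    table: DonorAcceptorTable = DEFAULT_TABLE,
) -> list[HBond]:
    """All donor–acceptor heteroatom pairs within the cutoff.

    Pairs within one residue are excluded. Search uses a k-d tree; the
    result is ordered deterministically by atom labels.
    """
    if not (0.0 < cutoff <= 5.0):
        raise ValueError("cutoff must be in (0, 5] Å")
    atoms = _polar_atoms(s, table)
    if len(atoms) < 2:
        return []
    coords = np.array([c for _, c, _ in atoms])
    tree = cKDTree(coords)
    bonds: list[HBond] = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        ref_i, xyz_i, role_i = atoms[i]
        ref_j, xyz_j, role_j = atoms[j]
        if ref_i.residue_key == ref_j.residue_key:
            continue
        if not _roles_compatible(role_i, role_j):
            continue
        dist = float(np.linalg.norm(xyz_i - xyz_j))
        if dist > cutoff or dist <= 0.0:
            continue
        # orient donor→acceptor where determined; arbitrary but stable
        # when both atoms could play either role
        if role_i == tables.ACCEPTOR or role_j == tables.DONOR:
            donor, acceptor = ref_j, ref_i
        else:
            donor, acceptor = ref_i, ref_j
        bonds.append(HBond(donor, acceptor, dist))
    bonds.sort(key=lambda b: (b.donor.label, b.acceptor.label))
    return bonds


def detect_hbonds_bruteforce(
    s: Structure,
    cutoff: float = DEFAULT_CUTOFF,
    table: DonorAcceptorTable = DEFAULT_TABLE,
) -> list[HBond]:
    """All-pairs reference detection (no spatial index); for validation."""
    atoms = _polar_atoms(s, table)
    bonds: list[HBond] = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            ref_i, xyz_i, role_i = atoms[i]
            ref_j, xyz_j, role_j = atoms[j]
            if ref_i.residue_key == ref_j.residue_key:
                continue
            if not _roles_compatible(role_i, role_j):
                continue
            dist = float(np.linalg.norm(xyz_i - xyz_j))
            if not (0.0 < dist <= cutoff):
                continue
            if role_i == tables.ACCEPTOR or role_j == tables.DONOR:
                donor, acceptor = ref_j, ref_i
            else:
                donor, acceptor = ref_i, ref_j
            bonds.append(HBond(donor, acceptor, dist))
    bonds.sort(key=lambda b: (b.donor.label, b.acceptor.label))
    return bonds


# --- graphs -----------------------------------------------------------------

def node_id(residue: Residue) -> str:
    return residue.label


def _node_kind(comp_id: str) -> str:
    if comp_id in tables.WATER_CODES:
        return "water"
    if comp_id in tables.RETINAL_CODES:
        return "schiff_base"
    return "sidechain"


def build_graph(
    hbonds: list[HBond],
    s: Structure,
    water_policy: str = "include_water_water",
) -> nx.Graph:
    """Residue-level H-bond graph.

    Nodes carry ``kind`` (sidechain / water / schiff_base), the residue
    key and Cα (or water O) coordinates. Parallel atom-pair bonds
    between two groups collapse to one edge keeping the minimum
    distance; an edge is strong if any contributing pair is ≤3.5 Å.
    ``water_policy`` may exclude water–water edges.
    """
    if water_policy not in ("include_water_water", "exclude_water_water"):
        raise ValueError(f"unknown water policy {water_policy!r}")
    g = nx.Graph(water_policy=water_policy)
    res_by_key = {r.key: r for r in s.residues}

    def ensure_node(ref: AtomRef) -> str:
        r = res_by_key[ref.residue_key]
        nid = node_id(r)
        if nid not in g:
            kind = _node_kind(r.comp_id)
            anchor = r.get_atom("O") if kind == "water" else r.get_atom("CA")
            if anchor is None and r.atoms:
                anchor = r.atoms[0]
            g.add_node(
                nid,
                kind=kind,
                residue_key=r.key,
                comp_id=r.comp_id,
                position=tuple(anchor.coords) if anchor is not None else None,
            )
        return nid

    for b in hbonds:
        u = ensure_node(b.donor)
        v = ensure_node(b.acceptor)
        if u == v:
            continue
        if water_policy == "exclude_water_water" and (
            g.nodes[u]["kind"] == "water" and g.nodes[v]["kind"] == "water"
        ):
            continue
        if g.has_edge(u, v):
            e = g.edges[u, v]
            if b.distance < e["distance"]:
                e["distance"] = b.distance
                e["atoms"] = (b.donor.label, b.acceptor.label)
            e["strength"] = "strong" if e["distance"] <= STRONG_CUTOFF else "weak"
        else:
            g.add_edge(
                u, v,
                distance=b.distance,
                strength=b.strength_class,
                atoms=(b.donor.label, b.acceptor.label),
            )
    return g


def hbond_graph(
    s: Structure,
    cutoff: float = DEFAULT_CUTOFF,
    table: DonorAcceptorTable = DEFAULT_TABLE,
    water_policy: str = "include_water_water",
) -> nx.Graph:
    """Detect H-bonds and build the residue-level graph in one step."""
    return build_graph(detect_hbonds(s, cutoff, table), s, water_policy)


def summarize_graph(g: nx.Graph) -> dict[str, int]:
    """Edge totals partitioned by the kinds of their endpoints."""
    total = g.number_of_edges()
    water_mediated = 0
    water_water = 0
    sidechain_sidechain = 0
    strong = 0
    for u, v, data in g.edges(data=True):
        n_water = [g.nodes[u]["kind"], g.nodes[v]["kind"]].count("water")
        if n_water == 1:
            water_mediated += 1
        elif n_water == 2:
            water_water += 1
        else:
            sidechain_sidechain += 1
        if data["strength"] == "strong":
            strong += 1
    return {
        "total_edges": total,
        "water_mediated_edges": water_mediated,
        "water_water_edges": water_water,
        "sidechain_sidechain_edges": sidechain_sidechain,
        "strong_edges": strong,
    }


@dataclass
class DifferenceGraph:
    conserved_edges: list[tuple[str, str]]
    unique_a_edges: list[tuple[str, str]]
    unique_b_edges: list[tuple[str, str]]
    shared_nodes_a: set[str] = field(default_factory=set)
    shared_nodes_b: set[str] = field(default_factory=set)
    unique_nodes_a: set[str] = field(default_factory=set)
    unique_nodes_b: set[str] = field(default_factory=set)
    # conserved edges expressed in B's node ids, for rendering on B
    conserved_edges_b: list[tuple[str, str]] = field(default_factory=list)


def _edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def difference_graph(
    g_a: nx.Graph, g_b: nx.Graph, rmap: ResidueMap
) -> DifferenceGraph:
    """Partition two H-bond graphs into conserved and unique edges.

    Amino-acid (and Schiff-base) nodes map across structures through
    ``rmap`` (residue-key pairs); water nodes never map, so edges with a
    water endpoint are always structure-unique. An edge of A is
    conserved iff both endpoints map and the image pair is an edge of B.
    """
    if not rmap.pairs:
        raise ValueError("empty residue map")
    a2b_key = rmap.a_to_b()
    # node-id translation A→B via residue keys
    key_to_b_node = {
        data["residue_key"]: n for n, data in g_b.nodes(data=True)
        if data["kind"] != "water"
    }
    a_node_to_b: dict[str, str] = {}
    for n, data in g_a.nodes(data=True):
        if data["kind"] == "water":
            continue
        kb = a2b_key.get(data["residue_key"])
        if kb is not None and kb in key_to_b_node:
            a_node_to_b[n] = key_to_b_node[kb]

    b_edges = {_edge_key(u, v) for u, v in g_b.edges()}
    conserved: list[tuple[str, str]] = []
    conserved_b: list[tuple[str, str]] = []
    unique_a: list[tuple[str, str]] = []
    for u, v in sorted(_edge_key(u, v) for u, v in g_a.edges()):
        bu, bv = a_node_to_b.get(u), a_node_to_b.get(v)
        if bu is not None and bv is not None and _edge_key(bu, bv) in b_edges:
            conserved.append((u, v))
            conserved_b.append(_edge_key(bu, bv))
        else:
            unique_a.append((u, v))
    conserved_b_set = set(conserved_b)
    unique_b = sorted(
        e for e in b_edges if e not in conserved_b_set
    )

    shared_a = {n for e in conserved for n in e}
    shared_b = {n for e in conserved_b for n in e}
    return DifferenceGraph(
        conserved_edges=conserved,
        unique_a_edges=unique_a,
        unique_b_edges=unique_b,
        shared_nodes_a=shared_a,
        shared_nodes_b=shared_b,
        unique_nodes_a=set(g_a.nodes) - shared_a,
        unique_nodes_b=set(g_b.nodes) - shared_b,
        conserved_edges_b=conserved_b,
    )


# --- 2D projection ----------------------------------------------------------

@dataclass
class GraphProjection:
    """Per-node (x, z): membrane-plane PCA coordinate and height.

    z is the Cα z-coordinate of the residue (water O for waters); x is
    the first principal component of the node (x, y) positions, with the
    sign fixed so the node of largest |x| is positive.
    """

    coords: dict[str, tuple[float, float]]


def project_graph(g: nx.Graph, s: Structure | None = None) -> GraphProjection:
    """Project graph nodes to the (PCA-1, z) plane.

    Assumes the structure is oriented with the membrane normal on z.
    Node positions are taken from the graph's stored anchors (Cα for
    residues, O for waters).
    """
    nodes = sorted(g.nodes)
    if len(nodes) < 2:
        raise ValueError("projection needs at least 2 nodes")
    pos = np.array([g.nodes[n]["position"] for n in nodes], dtype=float)
    xy = pos[:, :2]
    centered = xy - xy.mean(axis=0)
    cov = centered.T @ centered / len(nodes)
    evals, evecs = np.linalg.eigh(cov)
    pc1 = evecs[:, int(np.argmax(evals))]
    x = centered @ pc1
    # deterministic sign: the node of largest |x| gets a positive value
    idx = int(np.argmax(np.abs(x)))
    if x[idx] < 0:
        x = -x
    return GraphProjection(
        coords={n: (float(xi), float(p[2])) for n, xi, p in zip(nodes, x, pos)}
    )


# --- key distances ----------------------------------------------------------

def min_sidechain_distance(
    s: Structure,
    res_a: ResidueKey,
    res_b: ResidueKey,
    atom_filter: str | tuple[list[str], list[str]] = "polar_heteroatoms",
    table: DonorAcceptorTable = DEFAULT_TABLE,
) -> float:
    """Minimum pairwise distance between filtered atom sets of two residues.

    ``atom_filter`` is either ``"polar_heteroatoms"`` (atoms in the
    donor/acceptor table for each residue's component) or a pair of
    explicit atom-name lists (names_a, names_b).
    """
    if res_a == res_b:
        raise ValueError("the two residues must differ")
    ra, rb = s.find(res_a), s.find(res_b)
    if ra is None or rb is None:
        raise KeyError(f"residue not found: {res_a if ra is None else res_b}")
    if atom_filter == "polar_heteroatoms":
        names_a = table.polar_atom_names(ra.comp_id)
        names_b = table.polar_atom_names(rb.comp_id)
    else:
        names_a, names_b = atom_filter
    atoms_a = [a for a in ra.atoms if a.name in names_a]
    atoms_b = [a for a in rb.atoms if a.name in names_b]
    if not atoms_a or not atoms_b:
        raise ValueError(
            f"empty atom filter for {ra.label} / {rb.label} ({names_a} / {names_b})"
        )
    return float(
        min(np.linalg.norm(a.coords - b.coords) for a in atoms_a for b in atoms_b)
    )


# --- serialization ----------------------------------------------------------

def graph_edge_list_json(g: nx.Graph) -> list[dict]:
    out = []
    for u, v in sorted(_edge_key(u, v) for u, v in g.edges()):
        data = g.edges[u, v]
        out.append(
            {
                "u": u,
                "v": v,
                "distance": round(data["distance"], 3),
                "strength": data["strength"],
            }
        )
    return out


def write_graphml(g: nx.Graph, path) -> None:
    h = nx.Graph()
    for n, data in g.nodes(data=True):
        h.add_node(
            n, kind=data["kind"], comp_id=data["comp_id"],
            x=float(data["position"][0]) if data["position"] else 0.0,
            y=float(data["position"][1]) if data["position"] else 0.0,
            z=float(data["position"][2]) if data["position"] else 0.0,
        )
    for u, v, data in g.edges(data=True):
        h.add_edge(u, v, distance=float(data["distance"]), strength=data["strength"])
    nx.write_graphml(h, str(path))
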
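"""Deterministic synthetic fixtures with planted ground truth.

Two families of fixtures cover the whole pipeline without any download:

* α-helical bundles with planted side-chain/side-chain and side-chain/
  water H-bonds at exact heteroatom distances, plus decoy entities
  (waters, monatomic ions, lipid- and sterol-like het groups) far from
  the bundle, for the H-bond, graph, census, alignment and superposition
  stages. Paralog pairs add point substitutions and a rigid helix shift
  of known magnitude.
* analytic cavity geometries (hollow shells with optional pinholes,
  slabs pierced by a cylindrical channel) with closed-form volumes and
  bottleneck radii, for the grid cavity and tunnel stages.

Backbones use idealized helix parameters (1.5 Å rise, 100° twist per
residue, 2.3 Å Cα radius); side chains carry only the heteroatoms the
donor/acceptor table needs, so placement at exact distances stays
tractable. All randomness flows through an explicit ``numpy`` generator
seeded from the spec; the same seed reproduces identical output bytes.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .hbond import DEFAULT_TABLE, detect_hbonds_bruteforce
from .structure import Atom, Residue, Structure

HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
CA_RADIUS = 2.3  # Å from the helix axis
AXIS_SPACING = 10.0  # Å between adjacent helix axes

NONPOLAR_COMPS = {"GLY", "ALA", "VAL", "LEU", "ILE", "PHE", "PRO"}


class InfeasiblePlacementError(ValueError):
    """A planted atom clashes with, or accidentally bonds to, another group."""


@dataclass
class PlantedBond:
    """One planted H-bond: two residues, or a residue and a new water."""

    res_a: int  # global residue index, 0-based
    res_b: int | None  # None → the partner is a planted water
    distance: float
    comp_a: str = "SER"
    atom_a: str = "OG"
    comp_b: str = "ASP"
    atom_b: str = "OD1"

    @property
    def water_mediated(self) -> bool:
        return self.res_b is None

    def __post_init__(self) -> None:
        if not (2.4 < self.distance < 4.5):
            raise ValueError(f"target distance {self.distance} outside (2.4, 4.5) Å")
        if self.res_b is not None and self.res_a == self.res_b:
            raise ValueError("planted bond needs two distinct residues")


@dataclass
class FixtureSpec:
    seed: int = 0
    n_helices: int = 4
    residues_per_helix: int = 18
    planted_hbonds: list[PlantedBond] = field(default_factory=list)
    n_decoy_waters: int = 0
    n_decoy_ions: int = 0
    n_decoy_lipids: int = 0
    n_decoy_sterols: int = 0

    @property
    def n_residues(self) -> int:
        return self.n_helices * self.residues_per_helix


@dataclass
class TruthRecord:
    """Everything a pipeline stage should recover from a fixture."""

    planted_bonds: list[dict]
    n_bonds: int
    n_water_mediated: int
    entity_counts: dict[str, int]
    sequence: str
    mutations: list[dict] = field(default_factory=list)
    displacement: dict | None = None
    planted_bonds_b: list[dict] = field(default_factory=list)
    expected_identity_pct: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


# --- helix bundle geometry --------------------------------------------------

def _helix_axes(n_helices: int) -> np.ndarray:
    if n_helices == 1:
        return np.zeros((1, 2))
    ring_r = AXIS_SPACING / (2.0 * math.sin(math.pi / n_helices))
    angles = [2 * math.pi * h / n_helices for h in range(n_helices)]
    return np.array([[ring_r * math.cos(a), ring_r * math.sin(a)] for a in angles])


def _backbone(spec: FixtureSpec) -> list[Residue]:
    axes = _helix_axes(spec.n_helices)
    z0 = -HELIX_RISE * (spec.residues_per_helix - 1) / 2.0
    residues: list[Residue] = []
    serial = 1
    num = 1
    for h in range(spec.n_helices):
        ax, ay = axes[h]
        # phase chosen so the θ=0 side-chain direction points at the
        # bundle axis, where planted bonds live
        inward = math.atan2(-ay, -ax) if spec.n_helices > 1 else 0.0
        for i in range(spec.residues_per_helix):
            theta = inward + math.radians(HELIX_TWIST) * i
            z = z0 + HELIX_RISE * i
            ca = np.array([ax + CA_RADIUS * math.cos(theta), ay + CA_RADIUS * math.sin(theta), z])
            n_at = np.array(
                [ax + 1.6 * math.cos(theta - 0.45), ay + 1.6 * math.sin(theta - 0.45), z - 0.6]
            )
            c_at = np.array(
                [ax + 1.7 * math.cos(theta + 0.45), ay + 1.7 * math.sin(theta + 0.45), z + 0.6]
            )
            o_at = c_at + np.array(
                [1.23 * math.cos(theta + 0.45), 1.23 * math.sin(theta + 0.45), 0.0]
            )
            atoms = [
                Atom(serial, "N", "N", n_at),
                Atom(serial + 1, "CA", "C", ca),
                Atom(serial + 2, "C", "C", c_at),
                Atom(serial + 3, "O", "O", o_at),
            ]
            serial += 4
            residues.append(Residue("A", num, "", "GLY", atoms))
            num += 1
    return residues


def _bundle_extent(residues: list[Residue]) -> float:
    xy = np.concatenate([r.coords() for r in residues])[:, :2]
    return float(np.linalg.norm(xy, axis=1).max())


def _place_planted(
    residues: list[Residue], spec: FixtureSpec
) -> tuple[list[Residue], list[dict]]:
    """Mutate planted residues and add exact-distance partner atoms."""
    waters: list[Residue] = []
    truth: list[dict] = []
    assigned: dict[int, str] = {}
    next_serial = max(a.serial for r in residues for a in r.atoms) + 1
    wat_num = 1
    for bond in spec.planted_hbonds:
        for idx, comp in ((bond.res_a, bond.comp_a), (bond.res_b, bond.comp_b)):
            if idx is None:
                continue
            if idx >= len(residues):
                raise ValueError(f"planted residue index {idx} outside the bundle")
            if idx in assigned and assigned[idx] != comp:
                raise InfeasiblePlacementError(
                    f"residue {idx} planted with conflicting components"
                )
        ra = residues[bond.res_a]
        ca_a = ra.get_atom("CA").coords
        if bond.water_mediated:
            # aim into the bundle lumen so the water sits in free space
            direction = np.array([-ca_a[0], -ca_a[1], 0.0])
            nrm = np.linalg.norm(direction)
            u = direction / nrm if nrm > 1e-6 else np.array([1.0, 0.0, 0.0])
        else:
            ca_b = residues[bond.res_b].get_atom("CA").coords
            u = (ca_b - ca_a) / np.linalg.norm(ca_b - ca_a)
        if bond.res_a not in assigned:
            ra.comp_id = bond.comp_a
            assigned[bond.res_a] = bond.comp_a
        existing = ra.get_atom(bond.atom_a)
        if existing is None:
            atom_a_pos = ca_a + 1.5 * u
            ra.atoms.append(Atom(next_serial, bond.atom_a, bond.atom_a[0], atom_a_pos))
            next_serial += 1
        else:
            # residue already donates elsewhere: measure from the real atom
            atom_a_pos = existing.coords
        partner_pos = atom_a_pos + bond.distance * u
        if bond.water_mediated:
            waters.append(
                Residue("W", wat_num, "", "HOH", [Atom(next_serial, "O", "O", partner_pos)])
            )
            partner_label = f"W:{wat_num}:HOH"
            next_serial += 1
            wat_num += 1
        else:
            rb = residues[bond.res_b]
            if bond.res_b not in assigned:
                rb.comp_id = bond.comp_b
                assigned[bond.res_b] = bond.comp_b
            if rb.get_atom(bond.atom_b) is not None:
                raise InfeasiblePlacementError(
                    f"residue {bond.res_b} already carries atom {bond.atom_b}"
                )
            rb.atoms.append(Atom(next_serial, bond.atom_b, bond.atom_b[0], partner_pos))
            next_serial += 1
            partner_label = rb.label
        truth.append(
            {
                "node_a": ra.label,
                "node_b": partner_label,
                "distance": bond.distance,
                "water_mediated": bond.water_mediated,
            }
        )
    return waters, truth


def _decoys(spec: FixtureSpec, rng: np.random.Generator, extent: float) -> list[Residue]:
    """Entity decoys on a wide ring, ≥6.5 Å apart, far from polar atoms."""
    n_total = (
        spec.n_decoy_waters + spec.n_decoy_ions + spec.n_decoy_lipids + spec.n_decoy_sterols
    )
    if n_total == 0:
        return []
    ring = extent + 14.0
    step = max(6.5 / ring, 2 * math.pi / max(n_total, 1))
    start = float(rng.uniform(0, 2 * math.pi))
    comps = (
        [("HOH", "water")] * spec.n_decoy_waters
        + [("NA", "ion")] * spec.n_decoy_ions
        + [("PEE", "lipid")] * spec.n_decoy_lipids
        + [("CLR", "sterol")] * spec.n_decoy_sterols
    )
    residues: list[Residue] = []
    serial = 100000
    counters = {"water": 0, "ion": 0, "lipid": 0, "sterol": 0}
    chains = {"water": "W", "ion": "I", "lipid": "L", "sterol": "S"}
    for k, (comp, kind) in enumerate(comps):
        ang = start + k * step
        z = float(rng.uniform(-6.0, 6.0))
        base = np.array([ring * math.cos(ang), ring * math.sin(ang), z])
        counters[kind] += 1
        num = 500 + counters[kind] if kind == "water" else counters[kind]
        if comp == "HOH":
            atoms = [Atom(serial, "O", "O", base)]
        elif comp == "NA":
            atoms = [Atom(serial, "NA", "NA", base)]
        elif comp == "PEE":
            atoms = [
                Atom(serial, "P", "P", base),
                Atom(serial + 1, "C1", "C", base + [1.5, 0, 0]),
                Atom(serial + 2, "C2", "C", base + [0, 1.5, 0]),
                Atom(serial + 3, "C3", "C", base + [0, 0, 1.5]),
            ]
        else:  # CLR
            atoms = [
                Atom(serial + j, f"C{j + 1}", "C", base + [1.2 * j, 0.0, 0.0])
                for j in range(4)
            ]
        serial += len(atoms)
        residues.append(Residue(chains[kind], num, "", comp, atoms))
    return residues


def _validate(s: Structure, truth_bonds: list[dict]) -> None:
    """Planted bonds, and only planted bonds, must exist (4.2 Å margin)."""
    found = detect_hbonds_bruteforce(s, cutoff=4.2, table=DEFAULT_TABLE)
    found_pairs = {
        frozenset((f"{b.donor.residue_key[0]}:{b.donor.residue_key[1]}",
                   f"{b.acceptor.residue_key[0]}:{b.acceptor.residue_key[1]}"))
        for b in found
    }
    planted_pairs = {
        frozenset((_short(t["node_a"]), _short(t["node_b"]))) for t in truth_bonds
    }
    extra = found_pairs - planted_pairs
    missing = planted_pairs - found_pairs
    if extra or missing:
        raise InfeasiblePlacementError(
            f"accidental or missing H-bonds; extra={sorted(map(sorted, extra))}, "
            f"missing={sorted(map(sorted, missing))}"
        )


def _short(label: str) -> str:
    chain, num, _comp = label.split(":")
    return f"{chain}:{num}"


def make_fixture(spec: FixtureSpec) -> tuple[Structure, TruthRecord]:
    """Build a helical-bundle fixture and its ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    residues = _backbone(spec)
    waters, truth_bonds = _place_planted(residues, spec)
    extent = _bundle_extent(residues)
    decoys = _decoys(spec, rng, extent)
    all_res = residues + waters + decoys
    s = Structure(id=f"fixture-{spec.seed}", residues=all_res)
    s.assembly = {ch: 0 for ch in s.chains()}
    _validate(s, truth_bonds)
    n_bond_waters = sum(1 for t in truth_bonds if t["water_mediated"])
    truth = TruthRecord(
        planted_bonds=truth_bonds,
        n_bonds=len(truth_bonds),
        n_water_mediated=n_bond_waters,
        entity_counts={
            "protein": spec.n_residues,
            "water": spec.n_decoy_waters + n_bond_waters,
            "monatomic_ion": spec.n_decoy_ions,
            "phospholipid": spec.n_decoy_lipids,
            "sterol": spec.n_decoy_sterols,
        },
        sequence=s.sequence("A"),
    )
    return s, truth


def make_paralog_pair(
    spec: FixtureSpec,
    mutations: list[tuple[int, str]] | None = None,
    displacement: tuple[int, float] | None = None,
    planted_hbonds_b: list[PlantedBond] | None = None,
) -> tuple[Structure, Structure, TruthRecord]:
    """A fixture and a paralog differing by substitutions and a helix shift.

    ``mutations`` are (global residue index, new component) pairs; the
    new component must be non-polar so no unplanned H-bonds appear.
    ``displacement`` rigidly shifts the helix containing the given
    residue along +x by the stated Å. ``planted_hbonds_b`` replaces the
    planted bond list for the second structure (same backbone), so the
    two graphs can share a controlled subset of edges.
    """
    s_a, truth = make_fixture(spec)
    spec_b = copy.deepcopy(spec)
    if planted_hbonds_b is not None:
        spec_b.planted_hbonds = planted_hbonds_b
    s_b, truth_b = make_fixture(spec_b)
    s_b.id = f"fixture-{spec.seed}-paralog"

    planted_b = {
        idx for bond in spec_b.planted_hbonds
        for idx in (bond.res_a, bond.res_b) if idx is not None
    }
    mut_records = []
    for idx, comp in mutations or []:
        if idx >= spec.n_residues:
            raise ValueError(f"mutation at unmodeled residue index {idx}")
        if idx in planted_b:
            raise InfeasiblePlacementError(
                f"mutation at residue {idx} would disturb a planted bond"
            )
        if comp not in NONPOLAR_COMPS:
            raise ValueError(f"mutations limited to non-polar components, got {comp}")
        r = s_b.residues[idx]
        old = r.comp_id
        r.comp_id = comp
        r.atoms = [a for a in r.atoms if a.name in ("N", "CA", "C", "O")]
        if comp != "GLY":
            ca = r.get_atom("CA").coords
            out_dir = np.array([ca[0], ca[1], 0.0])
            nrm = np.linalg.norm(out_dir)
            u = out_dir / nrm if nrm > 1e-6 else np.array([1.0, 0.0, 0.0])
            r.atoms.append(Atom(r.atoms[-1].serial + 1, "CB", "C", ca + 1.5 * u))
        mut_records.append({"index": idx, "from": old, "to": comp, "key": list(r.key)})

    disp_record = None
    if displacement is not None:
        idx, shift = displacement
        helix = idx // spec.residues_per_helix
        lo = helix * spec.residues_per_helix
        hi = lo + spec.residues_per_helix
        for r in s_b.residues[lo:hi]:
            for a in r.atoms:
                a.coords = a.coords + np.array([shift, 0.0, 0.0])
        disp_record = {
            "residue_key": list(s_b.residues[idx].key),
            "helix": helix,
            "shift": shift,
            "helix_residues": spec.residues_per_helix,
        }

    n = spec.n_residues
    truth.mutations = mut_records
    truth.displacement = disp_record
    truth.entity_counts["water_b"] = truth_b.entity_counts["water"]
    truth.planted_bonds_b = truth_b.planted_bonds
    truth.expected_identity_pct = 100.0 * (n - _n_seq_changes(s_a, s_b)) / n
    return s_a, s_b, truth


def _n_seq_changes(s_a: Structure, s_b: Structure) -> int:
    sa, sb = s_a.sequence("A"), s_b.sequence("A")
    return sum(1 for x, y in zip(sa, sb) if x != y)


# --- analytic cavity fixtures ----------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    y = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - y * y)
    return np.stack([r * np.cos(phi * k), y, r * np.sin(phi * k)], axis=1)


def _chunked_structure(points: np.ndarray, structure_id: str, comp: str = "SHL") -> Structure:
    residues = []
    serial = 1
    for ci in range(0, len(points), 50):
        atoms = [
            Atom(serial + j, f"C{j + 1}", "C", p)
            for j, p in enumerate(points[ci : ci + 50])
        ]
        serial += len(atoms)
        residues.append(Residue("X", ci // 50 + 1, "", comp, atoms))
    return Structure(id=structure_id, residues=residues, assembly={"X": 0})


def hollow_shell_structure(
    inner_radius: float = 6.0,
    pinhole_radius: float | None = None,
    atom_radius: float = 1.7,
    point_spacing: float = 0.9,
    center=(0.0, 0.0, 0.0),
) -> Structure:
    """Closed spherical shell of carbon pseudo-atoms; interior volume is
    analytic ((4/3)π·inner³). An optional pinhole of exact clearance
    ``pinhole_radius`` pierces the shell along +z."""
    center = np.asarray(center, dtype=float)
    shell_r = inner_radius + atom_radius
    n = int(math.ceil(4.0 * math.pi * shell_r**2 / point_spacing**2))
    pts = _fibonacci_sphere(n) * shell_r
    if pinhole_radius is not None:
        hole_r = pinhole_radius + atom_radius
        theta_h = math.asin(min(hole_r / shell_r, 1.0))
        polar = np.arccos(np.clip(pts[:, 2] / shell_r, -1, 1))
        pts = pts[polar > theta_h]
        # exact-rim ring fixes the clearance at the hole center
        m = int(math.ceil(2 * math.pi * hole_r / 0.6))
        ring_z = shell_r * math.cos(theta_h)
        ring_xy = shell_r * math.sin(theta_h)
        ring = np.array(
            [
                [ring_xy * math.cos(2 * math.pi * j / m), ring_xy * math.sin(2 * math.pi * j / m), ring_z]
                for j in range(m)
            ]
        )
        pts = np.concatenate([pts, ring])
    return _chunked_structure(pts + center, "hollow-shell")


def channel_slab_structure(
    channel_radius: float = 2.0,
    half_width: float = 9.0,
    thickness: float = 10.0,
    atom_radius: float = 1.7,
    lattice: float = 1.5,
) -> Structure:
    """Slab pierced by a cylindrical channel along z with exact wall
    clearance ``channel_radius`` on the axis."""
    wall_r = channel_radius + atom_radius
    pts = []
    zs = np.arange(-thickness / 2, thickness / 2 + 1e-6, 0.6)
    m = int(math.ceil(2 * math.pi * wall_r / 0.6))
    for z in zs:
        for j in range(m):
            a = 2 * math.pi * j / m
            pts.append([wall_r * math.cos(a), wall_r * math.sin(a), z])
    grid = np.arange(-half_width, half_width + 1e-6, lattice)
    gz = np.arange(-thickness / 2, thickness / 2 + 1e-6, lattice)
    for x in grid:
        for y in grid:
            if math.hypot(x, y) < wall_r + 1.2:
                continue
            for z in gz:
                pts.append([x, y, z])
    return _chunked_structure(np.array(pts), "channel-slab")


def solid_slab_structure(
    half_width: float = 8.0, thickness: float = 8.0, lattice: float = 1.5
) -> Structure:
    """Dense slab with no interior free space."""
    grid = np.arange(-half_width, half_width + 1e-6, lattice)
    gz = np.arange(-thickness / 2, thickness / 2 + 1e-6, lattice)
    pts = np.array([[x, y, z] for x in grid for y in grid for z in gz])
    return _chunked_structure(pts, "solid-slab")
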
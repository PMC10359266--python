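"""Grid-based cavity detection and bottleneck-radius tunnel search.

The structure is cast onto a cubic lattice (default spacing 0.5 Å);
voxels inside any atom's van der Waals sphere are protein. Bulk solvent
is the free region a surface probe (default 1.4 Å) can reach from the
box boundary, found by probe-erosion, boundary flood-fill and dilation
back into the free space — the grid analogue of rolling-probe surface
programs. The remaining free components are interior cavities, which
can be emitted as dummy pseudo-atoms for visualization.

Tunnels are searched on an exact clearance field (distance to the
nearest atom's vdW surface) with a widest-path Dijkstra that maximizes
the minimum clearance from a seed to bulk solvent; a tunnel admits a
probe (default 0.9 Å) iff its bottleneck radius is at least the probe
radius. Ties are broken by path length, then lexicographic voxel order,
so results are deterministic.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure import Atom, Residue, Structure
from .tables import vdw_radius

DEFAULT_SPACING = 0.5
DEFAULT_SURFACE_PROBE = 1.4
DEFAULT_TUNNEL_PROBE = 0.9

_NEIGHBORS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


@dataclass
class CavityGrid:
    origin: np.ndarray  # (3,) Å, center of voxel (0,0,0)
    spacing: float
    protein: np.ndarray  # bool (nx,ny,nz)
    atom_coords: np.ndarray  # (n,3)
    atom_radii: np.ndarray  # (n,)
    _clearance: np.ndarray | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.protein.shape

    @property
    def free(self) -> np.ndarray:
        return ~self.protein

    def voxel_center(self, idx) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(idx, dtype=float)

    def index_of(self, point) -> tuple[int, int, int]:
        idx = np.rint((np.asarray(point, dtype=float) - self.origin) / self.spacing)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise ValueError(f"point {point} lies outside the grid")
        return tuple(int(v) for v in idx)

    def clearance(self) -> np.ndarray:
        """Distance (Å) from each voxel center to the nearest vdW surface.

        Exact min over atoms of (center distance − vdW radius), computed
        with one k-d tree per distinct radius. Negative inside atoms.
        """
        if self._clearance is None:
            shape = self.shape
            centers = (
                self.origin[None, :]
                + self.spacing
                * np.stack(
                    np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
                ).reshape(-1, 3)
            )
            out = np.full(centers.shape[0], np.inf)
            for r in np.unique(self.atom_radii):
                sel = self.atom_radii == r
                tree = cKDTree(self.atom_coords[sel])
                d, _ = tree.query(centers, k=1)
                np.minimum(out, d - r, out=out)
            self._clearance = out.reshape(shape)
        return self._clearance


def rasterize(
    s: Structure,
    spacing: float = DEFAULT_SPACING,
    padding: float = 6.0,
    radii: dict[str, float] | None = None,
) -> CavityGrid:
    """Cast a structure onto a boolean occupancy lattice.

    A voxel is protein when its center lies within the vdW radius of
    any atom (element-wise radii from the package table, overridable).
    ``padding`` adds free space around the bounding box so bulk solvent
    surrounds the molecule.
    """
    if not (0.1 < spacing <= 2.0):
        raise ValueError("spacing must be in (0.1, 2.0] Å")
    coords = s.atom_coords()
    if coords.size == 0:
        raise ValueError("structure has no atoms")
    elements = [a.element for r in s.residues for a in r.atoms]
    rad = np.array(
        [
            (radii or {}).get(e.upper(), vdw_radius(e)) for e in elements
        ],
        dtype=float,
    )
    # snap the origin to a global lattice so results are translation-
    # independent up to the spacing and symmetric fixtures stay symmetric
    lo = np.floor((coords.min(axis=0) - padding) / spacing) * spacing
    hi = coords.max(axis=0) + padding
    shape = tuple(int(np.floor((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    protein = np.zeros(shape, dtype=bool)
    for xyz, r in zip(coords, rad):
        lo_idx = np.maximum(np.floor((xyz - r - lo) / spacing).astype(int), 0)
        hi_idx = np.minimum(
            np.ceil((xyz - lo + r) / spacing).astype(int) + 1, np.array(shape)
        )
        ranges = [np.arange(lo_idx[d], hi_idx[d]) for d in range(3)]
        if any(len(rg) == 0 for rg in ranges):
            continue
        gx, gy, gz = np.meshgrid(*ranges, indexing="ij")
        cx = lo[0] + gx * spacing
        cy = lo[1] + gy * spacing
        cz = lo[2] + gz * spacing
        mask = (cx - xyz[0]) ** 2 + (cy - xyz[1]) ** 2 + (cz - xyz[2]) ** 2 <= r * r
        protein[gx[mask], gy[mask], gz[mask]] = True
    return CavityGrid(
        origin=lo, spacing=spacing, protein=protein,
        atom_coords=coords, atom_radii=rad,
    )


@dataclass
class Cavity:
    label: int
    n_voxels: int
    volume: float  # Å³
    centroid: np.ndarray  # Å
    voxel_indices: np.ndarray  # (n,3) int


@dataclass
class CavityResult:
    grid: CavityGrid
    probe: float
    bulk: np.ndarray  # bool mask
    labels: np.ndarray  # int: 0 bulk/protein-free none, >0 cavity id
    cavities: list[Cavity]


def find_cavities(
    grid: CavityGrid, probe: float = DEFAULT_SURFACE_PROBE, min_volume: float = 1.0
) -> CavityResult:
    """Separate free space into probe-accessible bulk and interior cavities.

    Bulk is the set of free voxels reachable from the box boundary by a
    sphere of the probe radius: the free space is eroded by the probe
    (exact clearance to the vdW surface ≥ probe), components touching
    the boundary are flood-filled, and the result is dilated by the
    probe within the free space. Everything free but not bulk forms
    cavities, labeled by 6-connectivity; volume is voxel count ×
    spacing³. Components below ``min_volume`` (Å³) are inter-atom
    surface crevices too small for any solvent and are dropped from the
    cavity list (they stay visible in ``labels``).
    """
    free = grid.free
    spacing = grid.spacing
    eroded = free & (grid.clearance() >= probe)
    structure6 = ndimage.generate_binary_structure(3, 1)
    lab, n = ndimage.label(eroded, structure=structure6)
    boundary_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(lab, sl, axis=axis)
            boundary_labels.update(np.unique(face[face > 0]).tolist())
    bulk_core = np.isin(lab, sorted(boundary_labels)) if boundary_labels else np.zeros_like(eroded)
    if bulk_core.any():
        dist_to_core = ndimage.distance_transform_edt(
            ~bulk_core, sampling=(spacing,) * 3
        )
        # the probe center is quantized to voxel centers, so its true
        # continuous position may sit up to half a voxel diagonal closer
        # to the surface; widen the dilation by that slack
        slack = spacing * np.sqrt(3.0) / 2.0
        bulk = free & (dist_to_core <= probe + slack + 1e-9)
    else:
        bulk = np.zeros_like(free)

    cavity_mask = free & ~bulk
    cav_lab, n_cav = ndimage.label(cavity_mask, structure=structure6)
    cavities: list[Cavity] = []
    for i in range(1, n_cav + 1):
        idx = np.argwhere(cav_lab == i)
        volume = len(idx) * spacing**3
        if volume < min_volume:
            continue
        centroid = grid.origin + spacing * idx.mean(axis=0)
        cavities.append(
            Cavity(
                label=i,
                n_voxels=len(idx),
                volume=volume,
                centroid=centroid,
                voxel_indices=idx,
            )
        )
    cavities.sort(key=lambda c: -c.volume)
    return CavityResult(grid=grid, probe=probe, bulk=bulk, labels=cav_lab, cavities=cavities)


def dummy_atom_structure(result: CavityResult, structure_id: str = "cavities") -> Structure:
    """One pseudo-atom (O) per cavity voxel, one residue per cavity."""
    residues = []
    serial = 1
    num = 1
    for cav in result.cavities:
        # chunk voxels into residues of ≤50 dummies with unique atom names
        for start in range(0, cav.n_voxels, 50):
            chunk = cav.voxel_indices[start : start + 50]
            atoms = [
                Atom(serial + j, f"O{j + 1}", "O", result.grid.voxel_center(idx))
                for j, idx in enumerate(chunk)
            ]
            serial += len(atoms)
            residues.append(
                Residue(chain_id="Z", seq_num=num, icode="", comp_id="DUM", atoms=atoms)
            )
            num += 1
    return Structure(id=structure_id, residues=residues, assembly={"Z": 0})


@dataclass
class Tunnel:
    path: np.ndarray  # (n,3) voxel centers, Å
    bottleneck_radius: float
    probe: float
    start: np.ndarray
    reaches_bulk: bool


def tunnel_search(
    grid: CavityGrid,
    seed,
    probe: float = DEFAULT_TUNNEL_PROBE,
    surface_probe: float = DEFAULT_SURFACE_PROBE,
    bulk: np.ndarray | None = None,
) -> Tunnel | None:
    """Widest-bottleneck path from a seed point to bulk solvent.

    Runs a max-min Dijkstra over the clearance field restricted to
    voxels where the probe fits. Returns None when no such path exists.
    ``bulk`` may be passed in to reuse a previous find_cavities result.
    """
    seed = np.asarray(seed, dtype=float)
    start = grid.index_of(seed)
    if grid.protein[start]:
        raise ValueError(f"seed {seed} lies inside the protein")
    if bulk is None:
        bulk = find_cavities(grid, surface_probe).bulk
    clearance = grid.clearance()
    allowed = grid.free & (clearance >= probe)
    if not allowed[start]:
        return None
    shape = grid.shape

    best: dict[tuple[int, int, int], float] = {start: float(clearance[start])}
    prev: dict[tuple[int, int, int], tuple[int, int, int] | None] = {start: None}
    heap = [(-float(clearance[start]), 0, start)]
    goal = None
    while heap:
        neg_bn, length, vox = heapq.heappop(heap)
        bn = -neg_bn
        if bn < best.get(vox, -np.inf) - 1e-12:
            continue
        if bulk[vox]:
            goal = vox
            break
        for dx, dy, dz in _NEIGHBORS:
            nb = (vox[0] + dx, vox[1] + dy, vox[2] + dz)
            if not (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1] and 0 <= nb[2] < shape[2]):
                continue
            if not allowed[nb]:
                continue
            nb_bn = min(bn, float(clearance[nb]))
            if nb_bn > best.get(nb, -np.inf) + 1e-12:
                best[nb] = nb_bn
                prev[nb] = vox
                heapq.heappush(heap, (-nb_bn, length + 1, nb))
    if goal is None:
        return None
    path_idx = []
    cur: tuple[int, int, int] | None = goal
    while cur is not None:
        path_idx.append(cur)
        cur = prev[cur]
    path_idx.reverse()
    path = np.array([grid.voxel_center(i) for i in path_idx])
    return Tunnel(
        path=path,
        bottleneck_radius=float(min(clearance[i] for i in path_idx)),
        probe=probe,
        start=seed,
        reaches_bulk=True,
    )


def clearance_bruteforce(grid: CavityGrid) -> np.ndarray:
    """Per-voxel min over atoms of (distance − vdW radius); O(voxels×atoms)."""
    shape = grid.shape
    out = np.full(shape, np.inf)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                c = grid.voxel_center((i, j, k))
                d = np.linalg.norm(grid.atom_coords - c, axis=1) - grid.atom_radii
                out[i, j, k] = d.min()
    return out


def auto_seed(s: Structure, schiff_residue: int = 233,
              aromatic_residues: tuple[int, ...] = (102, 210, 221, 222),
              chain: str | None = None) -> np.ndarray:
    """Seed for the ion-pathway tunnel search, computed from coordinates.

    Midpoint between the retinal Schiff-base nitrogen (lysine NZ of the
    retinylidene lysine) and the centroid of the extracellular aromatic
    cluster side chains.
    """
    chain = chain or s.protein_chains()[0]
    schiff = None
    for r in s.protein_residues(chain):
        if r.seq_num == schiff_residue:
            schiff = r.get_atom("NZ")
    if schiff is None:
        raise ValueError(f"no Schiff-base NZ found at residue {schiff_residue}")
    cluster = []
    for r in s.protein_residues(chain):
        if r.seq_num in aromatic_residues:
            side = [a.coords for a in r.atoms if a.name not in ("N", "CA", "C", "O")]
            if side:
                cluster.append(np.mean(side, axis=0))
    if not cluster:
        raise ValueError("aromatic cluster residues not found")
    return (schiff.coords + np.mean(cluster, axis=0)) / 2.0


def cavity_volume_tsv(result: CavityResult) -> str:
    lines = ["cavity\tn_voxels\tvolume_A3\tcentroid_x\tcentroid_y\tcentroid_z"]
    for c in result.cavities:
        lines.append(
            f"{c.label}\t{c.n_voxels}\t{c.volume:.2f}\t"
            f"{c.centroid[0]:.2f}\t{c.centroid[1]:.2f}\t{c.centroid[2]:.2f}"
        )
    return "\n".join(lines) + "\n"
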
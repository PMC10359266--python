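"""Grid casting, cavity detection, and tunnel search on analytic geometry."""

import numpy as np
import pytest

from poregraph import (
    Atom,
    Residue,
    Structure,
    channel_slab_structure,
    find_cavities,
    hollow_shell_structure,
    parse_structure,
    rasterize,
    solid_slab_structure,
    tunnel_search,
    write_structure,
)
from poregraph.pore import clearance_bruteforce, dummy_atom_structure

SHELL_ANALYTIC = 4.0 / 3.0 * np.pi * 6.0**3  # ≈ 904.8 Å³


def single_atom_structure(element="C", xyz=(0.0, 0.0, 0.0)):
    r = Residue("A", 1, "", "XXX", [Atom(1, element, element, np.array(xyz))])
    return Structure(id="one", residues=[r], assembly={"A": 0})


def test_single_atom_occupied_volume_matches_sphere():
    s = single_atom_structure("C")  # vdW 1.70 Å
    grid = rasterize(s, spacing=0.5, padding=4.0)
    occupied = grid.protein.sum() * grid.spacing**3
    sphere = 4.0 / 3.0 * np.pi * 1.70**3
    assert occupied == pytest.approx(sphere, rel=0.10)


def test_padding_region_is_free():
    s = single_atom_structure()
    grid = rasterize(s, spacing=0.5, padding=5.0)
    assert not grid.protein[0, :, :].any()
    assert not grid.protein[-1, :, :].any()
    assert grid.protein.any()


def test_two_overlapping_atoms_occupy_union():
    # coordinates incommensurate with the lattice so no voxel center sits
    # exactly on a vdW surface (where float ties are representation-dependent)
    both = Structure(
        id="two",
        residues=[
            Residue("A", 1, "", "XXX", [Atom(1, "C", "C", np.array([0.1, 0.2, 0.3])),
                                        Atom(2, "C2", "C", np.array([1.3, 0.2, 0.3]))])
        ],
        assembly={"A": 0},
    )
    g_both = rasterize(both, 0.5, 4.0)
    # per-voxel oracle: occupied iff within 1.7 of either center
    centers = np.array([[0.1, 0.2, 0.3], [1.3, 0.2, 0.3]])
    for idx in np.ndindex(*g_both.shape):
        c = g_both.voxel_center(idx)
        expect = bool((np.linalg.norm(centers - c, axis=1) <= 1.7).any())
        assert bool(g_both.protein[idx]) == expect


def test_solid_slab_has_no_cavities():
    grid = rasterize(solid_slab_structure(), spacing=0.5, padding=5.0)
    assert find_cavities(grid, 1.4).cavities == []


@pytest.fixture(scope="module")
def shell_grid():
    return rasterize(hollow_shell_structure(inner_radius=6.0), spacing=0.5, padding=5.0)


def test_shell_cavity_volume_within_10pct(shell_grid):
    result = find_cavities(shell_grid, 1.4)
    big = [c for c in result.cavities if c.volume > 100.0]
    assert len(big) == 1
    assert big[0].volume == pytest.approx(SHELL_ANALYTIC, rel=0.10)
    assert np.allclose(big[0].centroid, 0.0, atol=0.5)


def test_shell_volume_converges_when_spacing_halves(shell_grid):
    v_05 = max(c.volume for c in find_cavities(shell_grid, 1.4).cavities)
    fine = rasterize(hollow_shell_structure(inner_radius=6.0), spacing=0.25, padding=5.0)
    v_025 = max(c.volume for c in find_cavities(fine, 1.4).cavities)
    assert abs(v_025 - v_05) / v_025 <= 0.05


@pytest.fixture(scope="module")
def pinhole_grid():
    return rasterize(
        hollow_shell_structure(inner_radius=6.0, pinhole_radius=1.0),
        spacing=0.5, padding=5.0,
    )


def test_pinhole_blocks_large_probe_but_not_small(pinhole_grid):
    big_14 = [c for c in find_cavities(pinhole_grid, 1.4).cavities if c.volume > 100]
    assert len(big_14) == 1  # 1.4 Å probe cannot enter: interior is a cavity
    big_09 = [c for c in find_cavities(pinhole_grid, 0.9).cavities if c.volume > 100]
    assert big_09 == []  # 0.9 Å probe enters: interior merges with bulk


def test_tunnel_through_pinhole_and_monotonicity(pinhole_grid):
    bulk = find_cavities(pinhole_grid, 1.4).bulk
    found = {}
    for probe in (1.4, 1.1, 0.9, 0.6, 0.3):
        t = tunnel_search(pinhole_grid, (0, 0, 0), probe=probe, bulk=bulk)
        found[probe] = t
    assert found[1.4] is None
    assert found[0.9] is not None
    assert found[0.9].bottleneck_radius == pytest.approx(1.0, abs=0.25)
    # monotonicity: found at p ⇒ found at every smaller probe, and the
    # widest-bottleneck path is probe-independent while it fits
    probes = sorted(found)
    for small, large in zip(probes, probes[1:]):
        if found[large] is not None:
            assert found[small] is not None
            assert found[small].bottleneck_radius == pytest.approx(
                found[large].bottleneck_radius, abs=1e-9
            )


def test_sealed_shell_has_no_tunnel(shell_grid):
    result = find_cavities(shell_grid, 1.4)
    assert tunnel_search(shell_grid, (0, 0, 0), probe=0.9, bulk=result.bulk) is None
    with pytest.raises(ValueError):
        # a point inside the shell wall is protein
        tunnel_search(shell_grid, (0, 0, 7.7), probe=0.9, bulk=result.bulk)


def test_open_channel_bottleneck_matches_radius():
    grid = rasterize(channel_slab_structure(channel_radius=2.0), 0.5, 5.0)
    result = find_cavities(grid, 1.4)
    t = tunnel_search(grid, (0, 0, 0), probe=0.9, bulk=result.bulk)
    assert t is not None and t.reaches_bulk
    assert t.bottleneck_radius == pytest.approx(2.0, abs=grid.spacing)
    # path is 6-connected
    steps = np.abs(np.diff(t.path, axis=0))
    assert np.allclose(steps.sum(axis=1), grid.spacing)


def test_clearance_field_matches_bruteforce():
    s = single_atom_structure("C")
    extra = Residue("B", 1, "", "XXX", [Atom(2, "N", "N", np.array([3.0, 1.0, -1.0]))])
    s2 = Structure(id="clr", residues=s.residues + [extra], assembly={"A": 0, "B": 0})
    grid = rasterize(s2, spacing=0.8, padding=3.0)
    assert np.allclose(grid.clearance(), clearance_bruteforce(grid), atol=1e-9)


def test_dummy_atoms_one_per_cavity_voxel(tmp_path, shell_grid):
    result = find_cavities(shell_grid, 1.4)
    dummies = dummy_atom_structure(result)
    assert dummies.n_atoms() == sum(c.n_voxels for c in result.cavities)
    out = tmp_path / "dummies.pdb"
    write_structure(dummies, out, "PDB")
    reparsed = parse_structure(out)
    assert reparsed.n_atoms() == dummies.n_atoms()


def test_rasterize_rejects_bad_spacing():
    with pytest.raises(ValueError):
        rasterize(single_atom_structure(), spacing=5.0)
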
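"""Pore profiling, water densities, pathway connectivity, OpenDX I/O."""

import math

import numpy as np
import pytest

from gateworks import dx, pathways as pw, synthetic as syn
from gateworks.pathways import (BULK_WATER_NUMBER_DENSITY, ScalarField3D,
                                pathway_connected, pore_profile,
                                pore_radius_at, water_density)
from gateworks.structio import Atom, MembraneFrame, Structure


def _ring(radius, n=12, vdw=1.5, z=0.0, start_id=1):
    return [Atom("C", "C", "RNG", start_id + i, "A",
                 [radius * np.cos(t), radius * np.sin(t), z], vdw)
            for i, t in enumerate(np.linspace(0, 2 * np.pi, n, endpoint=False))]


def test_ring_radius_matches_geometry():
    r, c = pore_radius_at(Structure(_ring(5.0)), 0.0)
    assert r == pytest.approx(5.0 - 1.5, abs=0.1)
    assert np.linalg.norm(c) < 0.1


def test_concentric_rings_inner_controls():
    s = Structure(_ring(5.0) + _ring(9.0, n=18, start_id=100))
    r, _ = pore_radius_at(s, 0.0)
    assert r == pytest.approx(3.5, abs=0.1)


def test_ring_rotation_invariance():
    base = Structure(_ring(5.0))
    r0, _ = pore_radius_at(base, 0.0)
    rot = Structure(_ring(5.0, n=12))
    coords = rot.coords
    ang = 0.37
    R = np.array([[np.cos(ang), -np.sin(ang), 0],
                  [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
    r1, _ = pore_radius_at(rot.with_coords(coords @ R.T), 0.0)
    assert r1 == pytest.approx(r0, abs=0.1)


def test_empty_slab_is_unbounded():
    s = Structure(_ring(5.0, z=30.0))
    r, _ = pore_radius_at(s, 0.0)
    assert math.isinf(r)


def test_far_single_atom_is_boundary_limited():
    s = Structure([Atom("C", "C", "X", 1, "A", [50, 0, 0], 1.7)])
    r, _ = pore_radius_at(s, 0.0)
    assert r == pw.MAX_RADIUS


def test_profile_single_frame_sd_zero(occluded_bundle):
    ens = syn.make_transition(occluded_bundle, occluded_bundle, 2, 0.0)
    prof = pore_profile(ens, [-4.0, 0.0, 4.0], box_half=6.0, stride=2)
    assert np.all(prof.sd_radius == 0)
    assert np.all(prof.n_frames == 1)


def test_profile_two_point_statistics():
    f1 = Structure(_ring(4.5))
    f2 = Structure(_ring(6.5))
    ens = syn.make_transition(f1, f2, 2, 0.0)  # frames are exactly f1, f2
    prof = pore_profile(ens, [0.0], box_half=4.0)
    assert prof.mean_radius[0] == pytest.approx(4.0, abs=0.1)
    assert prof.sd_radius[0] == pytest.approx(1.0, abs=0.1)


def test_occluded_bundle_pinches_below_water_radius(occluded_bundle):
    ens = syn.make_transition(occluded_bundle, occluded_bundle, 2, 0.0)
    z = np.arange(-14.0, 14.1, 2.0)
    prof = pore_profile(ens, z, box_half=6.0, stride=2)
    cyt_band = prof.mean_radius[z <= -10]
    peri_band = prof.mean_radius[z >= 10]
    assert np.nanmin(cyt_band) < 1.4
    assert np.nanmin(peri_band) < 1.4
    # while the central cavity stays wider than a water molecule
    assert np.nanmax(prof.mean_radius[np.abs(z) <= 4]) > 1.4


def test_profile_membrane_frame_axis_permutation(occluded_bundle):
    # same geometry viewed with the membrane normal on x
    ens = syn.make_transition(occluded_bundle, occluded_bundle, 2, 0.0)
    swapped = ens.frames[:, :, [2, 1, 0]]
    from gateworks.structio import Ensemble
    ens_x = Ensemble(occluded_bundle.with_coords(swapped[0]), swapped)
    prof_z = pore_profile(ens, [0.0], box_half=6.0, stride=2)
    prof_x = pore_profile(ens_x, [0.0], box_half=6.0, stride=2,
                          membrane=MembraneFrame("x"))
    assert prof_x.mean_radius[0] == pytest.approx(prof_z.mean_radius[0], abs=0.1)


# ---------------------------------------------------------------------------
# water density
# ---------------------------------------------------------------------------

def test_bulk_number_density_conversion():
    # 0.970 g/cm³ / 18.0154 g/mol × N_A, in Å⁻³
    assert BULK_WATER_NUMBER_DENSITY == pytest.approx(0.0324, abs=2e-4)


def test_density_no_waters_is_zero():
    f = water_density([np.empty((0, 3))], (0, 0, 0), 1.0, (5, 5, 5))
    assert np.all(f.values == 0)


def test_density_single_voxel_arithmetic():
    pts = np.array([[0.5, 0.5, 0.5]] * 7)
    f = water_density([pts], (0, 0, 0), 1.0, (3, 3, 3), bulk_number_density=0.0334)
    expected = 7 / (1.0 * 0.0334)
    assert f.values[0, 0, 0] == pytest.approx(expected)
    assert f.values.sum() == pytest.approx(expected)


def test_density_uniform_bulk_mean_near_one(rng):
    lam = BULK_WATER_NUMBER_DENSITY * 20.0 ** 3
    waters = [rng.uniform(0, 20, size=(rng.poisson(lam), 3)) for _ in range(30)]
    f = water_density(waters, (0, 0, 0), 2.0, (10, 10, 10))
    assert f.values.mean() == pytest.approx(1.0, abs=0.05)


def test_density_count_conservation_with_dropped(rng):
    inside = rng.uniform(0, 10, size=(50, 3))
    outside = rng.uniform(20, 30, size=(13, 3))
    f = water_density([np.vstack([inside, outside])], (0, 0, 0), 1.0,
                      (10, 10, 10), bulk_number_density=1.0)
    total_counted = f.values.sum() * 1.0 * 1.0  # rel * voxvol * bulk * frames
    assert total_counted + f.n_dropped == 63
    assert f.n_dropped == 13


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def _floodfill_connected(mask, regionA_idx, regionB_idx, six=True):
    """Independent BFS oracle for component connectivity."""
    from collections import deque

    shape = mask.shape
    if six:
        steps = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                 (0, 0, 1), (0, 0, -1)]
    else:
        steps = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                 for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    targets = {t for t in regionB_idx if mask[t]}
    seen = set()
    q = deque(t for t in regionA_idx if mask[t])
    seen.update(q)
    while q:
        cur = q.popleft()
        if cur in targets:
            return True
        for s in steps:
            nxt = tuple(np.add(cur, s))
            if (all(0 <= n < d for n, d in zip(nxt, shape))
                    and nxt not in seen and mask[nxt]):
                seen.add(nxt)
                q.append(nxt)
    return bool(targets & seen)


def test_solid_column_connects():
    vals = np.zeros((5, 5, 9))
    vals[2, 2, :] = 2.0
    f = ScalarField3D((0, 0, 0), 1.0, vals)
    ok, _ = pathway_connected(f, 1.0, ((0, 0, 0), (5, 5, 1)),
                              ((0, 0, 8), (5, 5, 9)))
    assert ok


def test_broken_column_disconnected_under_6():
    vals = np.zeros((5, 5, 9))
    vals[2, 2, :] = 2.0
    vals[2, 2, 4] = 0.0
    f = ScalarField3D((0, 0, 0), 1.0, vals)
    ok, _ = pathway_connected(f, 1.0, ((0, 0, 0), (5, 5, 1)),
                              ((0, 0, 8), (5, 5, 9)), connectivity=6)
    assert not ok


@pytest.mark.parametrize("connectivity", [6, 26])
def test_random_fields_match_floodfill_oracle(rng, connectivity):
    for _ in range(25):
        vals = rng.random((6, 6, 6))
        f = ScalarField3D((0, 0, 0), 1.0, vals)
        thr = rng.uniform(0.3, 0.7)
        got, _ = pathway_connected(f, thr, ((0, 0, 0), (6, 6, 1)),
                                   ((0, 0, 5), (6, 6, 6)), connectivity)
        mask = vals >= thr
        regA = [(i, j, 0) for i in range(6) for j in range(6)]
        regB = [(i, j, 5) for i in range(6) for j in range(6)]
        want = _floodfill_connected(mask, regA, regB, six=connectivity == 6)
        assert got == want


def test_threshold_monotonicity(rng):
    vals = rng.random((6, 6, 6))
    f = ScalarField3D((0, 0, 0), 1.0, vals)
    regA, regB = ((0, 0, 0), (6, 6, 1)), ((0, 0, 5), (6, 6, 6))
    prev = True
    for thr in np.linspace(0.0, 1.0, 11):
        ok, _ = pathway_connected(f, thr, regA, regB)
        assert not (ok and not prev)  # raising threshold never reconnects
        prev = ok


def test_open_face_connected_occluded_face_not(occluded_bundle, open_cyt_bundle):
    lo, hi = np.array([-6.0, -6.0, -19.0]), np.array([6.0, 6.0, 19.0])
    verdicts = {}
    for label, b in [("occluded", occluded_bundle), ("open", open_cyt_bundle)]:
        waters = [syn.fill_cavity_waters(b, (lo, hi), 0.05, seed=s)
                  for s in range(8)]
        f = water_density(waters, lo, 2.0, (7, 7, 20))
        ok, _ = pathway_connected(f, 0.5, ((-6, -6, -19), (6, 6, -15)),
                                  ((-6, -6, -3), (6, 6, 3)))
        verdicts[label] = ok
    assert verdicts == {"occluded": False, "open": True}


# ---------------------------------------------------------------------------
# OpenDX
# ---------------------------------------------------------------------------

def test_dx_roundtrip(tmp_path, rng):
    vals = rng.random((4, 5, 6))
    p = tmp_path / "f.dx"
    dx.write_dx(p, np.array([-1.0, 2.0, 3.5]), 0.75, vals, comment="test field")
    origin, spacing, back = dx.read_dx(p)
    np.testing.assert_allclose(origin, [-1.0, 2.0, 3.5])
    assert spacing == pytest.approx(0.75)
    np.testing.assert_allclose(back, vals, atol=1e-6)
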
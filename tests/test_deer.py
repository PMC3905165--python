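"""Rotamer attachment, clash filtering and distance-distribution convolution."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gateworks import deer, synthetic as syn
from gateworks.deer import (LabelSite, attach_rotamers, clash_filter,
                            default_bins, ensemble_distribution,
                            pair_distribution)
from gateworks.structio import Atom, Structure
from gateworks.synthetic import RotamerLibrary


def _residue(chain, resid, origin, rot=None):
    """A backbone triad (plus CB) at an arbitrary pose."""
    local = {
        "N": np.array([1.46, 0.0, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([-0.55, 1.42, 0.0]),
        "O": np.array([-1.6, 1.9, 0.5]),
    }
    R = np.eye(3) if rot is None else rot
    return [Atom(n, n[0], "ALA", resid, chain, origin + R @ v, 1.6)
            for n, v in local.items()]


def _single_rotamer_library(spin_local=(3.0, 2.0, 1.0)):
    spin = np.asarray(spin_local, dtype=float)
    coords = np.array([[1.0, 0.0, 0.0], spin - [0, 0.5, 0], spin + [0, 0.5, 0]])
    return RotamerLibrary(
        [{"local_coords": coords, "weight": 1.0}],
        atom_names=["C1", "N1", "O1"],
    )


def test_attach_identity_when_library_in_site_frame():
    s = Structure(_residue("A", 1, np.zeros(3)))
    site = LabelSite("A", 1)
    lib = _single_rotamer_library()
    placed = attach_rotamers(s, site, lib)
    # recover local coordinates through the frame transform and compare
    origin, R = deer._site_frame(s, site, lib.anchor_names)
    back = (placed.rotamer_coords[0] - origin) @ R
    np.testing.assert_allclose(back, lib.coords[0], atol=1e-9)


def test_attach_translation_covariance():
    t = np.array([7.0, -3.0, 11.0])
    s0 = Structure(_residue("A", 1, np.zeros(3)))
    s1 = Structure(_residue("A", 1, t))
    lib = _single_rotamer_library()
    p0 = attach_rotamers(s0, LabelSite("A", 1), lib)
    p1 = attach_rotamers(s1, LabelSite("A", 1), lib)
    np.testing.assert_allclose(p1.rotamer_coords, p0.rotamer_coords + t,
                               atol=1e-9)


def test_attach_rotation_covariance():
    R = Rotation.from_euler("xyz", [30, 45, -60], degrees=True).as_matrix()
    s0 = Structure(_residue("A", 1, np.zeros(3)))
    s1 = Structure(_residue("A", 1, np.zeros(3), rot=R))
    lib = _single_rotamer_library()
    p0 = attach_rotamers(s0, LabelSite("A", 1), lib)
    p1 = attach_rotamers(s1, LabelSite("A", 1), lib)
    np.testing.assert_allclose(p1.spin_positions,
                               p0.spin_positions @ R.T, atol=1e-9)


def test_attach_missing_anchor_raises():
    atoms = [a for a in _residue("A", 1, np.zeros(3)) if a.name != "C"]
    with pytest.raises(ValueError, match="anchor"):
        attach_rotamers(Structure(atoms), LabelSite("A", 1),
                        _single_rotamer_library())


# ---------------------------------------------------------------------------
# clash filtering
# ---------------------------------------------------------------------------

def _clash_fixture(cutoff):
    """One rotamer whose nearest protein approach is exactly 1.9 Å."""
    res = _residue("A", 1, np.zeros(3))
    lib = _single_rotamer_library(spin_local=(6.0, 0.0, 0.0))
    s_probe = Structure(res)
    placed = attach_rotamers(s_probe, LabelSite("A", 1, cutoff), lib)
    # place a CB-like protein atom 1.9 Å from the rotamer's first atom
    target = placed.rotamer_coords[0][0] + np.array([0.0, 1.9, 0.0])
    full = Structure(res + [Atom("CB", "C", "VAL", 2, "A", target, 1.7)])
    placed = attach_rotamers(full, LabelSite("A", 1, cutoff), lib)
    return clash_filter(placed, full)


def test_clash_cutoff_two_removes_nearest_1p9():
    assert _clash_fixture(2.0).empty


def test_clash_cutoff_1p5_keeps_nearest_1p9():
    out = _clash_fixture(1.5)
    assert not out.empty
    assert out.weights.sum() == pytest.approx(1.0)


def test_no_nearby_protein_keeps_all_weights(occluded_bundle):
    lib = syn.make_rotamer_library(6, seed=4)
    site = LabelSite("A", 110)
    placed = attach_rotamers(occluded_bundle, site, lib)
    far = Structure([Atom("CA", "C", "ALA", 999, "Z", [500, 500, 500], 1.7)]
                    + occluded_bundle.atoms[:0])
    kept = clash_filter(placed, far, excluded=np.array([], dtype=int))
    np.testing.assert_allclose(kept.weights, placed.weights)


def test_removing_clash_atom_never_decreases_survivors(occluded_bundle):
    lib = syn.make_rotamer_library(10, seed=8)
    site = LabelSite("A", 110)
    placed = attach_rotamers(occluded_bundle, site, lib)
    full = clash_filter(placed, occluded_bundle)
    # drop the protein atom closest to any rotamer atom, refilter
    from scipy.spatial import cKDTree
    excl = set(deer.site_excluded_indices(occluded_bundle, site).tolist())
    keep = [i for i in range(len(occluded_bundle)) if i not in excl]
    tree = cKDTree(placed.rotamer_coords.reshape(-1, 3))
    d, _ = tree.query(occluded_bundle.coords[keep])
    nearest_atom = keep[int(np.argmin(d))]
    reduced = Structure([a for i, a in enumerate(occluded_bundle.atoms)
                         if i != nearest_atom])
    relaxed = clash_filter(attach_rotamers(reduced, site, lib), reduced)
    assert len(relaxed.weights) >= len(full.weights)


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

def _placed(spins, weights, site=None):
    spins = np.asarray(spins, dtype=float)
    w = np.asarray(weights, dtype=float)
    return deer.PlacedRotamers(site or LabelSite("A", 1),
                               spins[:, None, :], w, spins)


def test_delta_distribution_single_pair():
    a = _placed([[0, 0, 0]], [1.0])
    b = _placed([[25.0, 0, 0]], [1.0], LabelSite("B", 2))
    d = pair_distribution(a, b)
    assert d.probabilities[25] == pytest.approx(1.0)
    assert d.probabilities.sum() == pytest.approx(1.0)


def test_four_term_hand_enumeration():
    a = _placed([[0, 0, 0], [0, 0, 10]], [0.5, 0.5])
    b = _placed([[20.5, 0, 0], [0, 0, -20.5]], [0.5, 0.5], LabelSite("B", 2))
    # pairs: |a0-b0|=20.5, |a0-b1|=20.5, |a1-b0|=sqrt(20.5²+10²)=22.8,
    # |a1-b1|=30.5 — masses 0.25+0.25, 0.25, 0.25
    d = pair_distribution(a, b)
    assert d.probabilities[20] == pytest.approx(0.5, abs=1e-12)
    assert d.probabilities[22] == pytest.approx(0.25, abs=1e-12)
    assert d.probabilities[30] == pytest.approx(0.25, abs=1e-12)


def test_product_weights():
    a = _placed([[0, 0, 0], [0, 0, 10]], [0.9, 0.1])
    b = _placed([[0, 0, -20.5]], [1.0], LabelSite("B", 2))
    d = pair_distribution(a, b)
    assert d.probabilities[20] == pytest.approx(0.9, abs=1e-12)
    assert d.probabilities[30] == pytest.approx(0.1, abs=1e-12)


def test_distribution_site_exchange_symmetry():
    a = _placed([[0, 0, 0], [1, 0, 0]], [0.3, 0.7])
    b = _placed([[20, 0, 0], [25, 0, 0]], [0.6, 0.4], LabelSite("B", 2))
    np.testing.assert_allclose(pair_distribution(a, b).probabilities,
                               pair_distribution(b, a).probabilities,
                               atol=1e-15)


def test_empty_site_flagged():
    a = _placed(np.empty((0, 3)), np.empty(0))
    b = _placed([[0, 0, 0]], [1.0], LabelSite("B", 2))
    d = pair_distribution(a, b)
    assert d.empty
    assert np.all(d.probabilities == 0)


def test_distribution_rigid_motion_invariance(occluded_bundle):
    lib = syn.make_rotamer_library(5, seed=6)
    sA, sB = LabelSite("A", 110), LabelSite("B", 10)
    d0 = pair_distribution(attach_rotamers(occluded_bundle, sA, lib),
                           attach_rotamers(occluded_bundle, sB, lib))
    R = Rotation.from_euler("zxz", [15, 75, -40], degrees=True)
    moved = occluded_bundle.with_coords(R.apply(occluded_bundle.coords) + 5.0)
    d1 = pair_distribution(attach_rotamers(moved, sA, lib),
                           attach_rotamers(moved, sB, lib))
    np.testing.assert_allclose(d0.probabilities, d1.probabilities, atol=1e-9)


def test_single_rotamer_mean_matches_geometry(occluded_bundle):
    lib = syn.make_rotamer_library(1, seed=1)
    sA, sB = LabelSite("A", 110), LabelSite("B", 10)
    pa = attach_rotamers(occluded_bundle, sA, lib)
    pb = attach_rotamers(occluded_bundle, sB, lib)
    d = pair_distribution(pa, pb)
    true = np.linalg.norm(pa.spin_positions[0] - pb.spin_positions[0])
    assert d.mean == pytest.approx(true, abs=0.5)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def test_ensemble_single_frame_equals_pair(occluded_bundle):
    lib = syn.make_rotamer_library(4, seed=2)
    sA, sB = LabelSite("A", 110), LabelSite("B", 10)
    ens = syn.make_transition(occluded_bundle, occluded_bundle, 2, 0.0)
    d_ens = ensemble_distribution(ens, sA, sB, lib, stride=2)
    pa = clash_filter(attach_rotamers(occluded_bundle, sA, lib), occluded_bundle)
    pb = clash_filter(attach_rotamers(occluded_bundle, sB, lib), occluded_bundle)
    d_one = pair_distribution(pa, pb)
    np.testing.assert_allclose(d_ens.probabilities, d_one.probabilities,
                               atol=1e-12)


def test_ensemble_rigid_frames_equal_single(occluded_bundle):
    lib = syn.make_rotamer_library(4, seed=2)
    sA, sB = LabelSite("A", 110), LabelSite("B", 10)
    ens = syn.make_transition(occluded_bundle, occluded_bundle, 5, 0.0)
    d5 = ensemble_distribution(ens, sA, sB, lib)
    d1 = ensemble_distribution(ens, sA, sB, lib, stride=5)
    np.testing.assert_allclose(d5.probabilities, d1.probabilities, atol=1e-12)


def test_ensemble_two_disjoint_frames_mix_half_half():
    res1 = _residue("A", 1, np.zeros(3))
    res2 = _residue("B", 2, np.array([25.0, 0, 0]))
    s = Structure(res1 + res2)
    shifted = s.with_coords(np.vstack([
        np.array([a.xyz for a in res1]),
        np.array([a.xyz for a in res2]) + np.array([10.0, 0, 0]),
    ]))
    from gateworks.structio import Ensemble
    ens = Ensemble(s, np.stack([s.coords, shifted.coords]))
    lib = _single_rotamer_library()
    d = ensemble_distribution(ens, LabelSite("A", 1), LabelSite("B", 2), lib,
                              apply_clash_filter=False)
    occupied = np.where(d.probabilities > 0)[0]
    assert len(occupied) == 2
    assert d.probabilities[occupied].tolist() == pytest.approx([0.5, 0.5])


def test_total_probability_one_whenever_any_pair_survives(occluded_bundle):
    lib = syn.make_rotamer_library(12, seed=9)
    sA, sB = LabelSite("A", 110), LabelSite("B", 10)
    pa = clash_filter(attach_rotamers(occluded_bundle, sA, lib), occluded_bundle)
    pb = clash_filter(attach_rotamers(occluded_bundle, sB, lib), occluded_bundle)
    assert not pa.empty and not pb.empty
    d = pair_distribution(pa, pb)
    assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


def test_default_bins_cover_display_range():
    edges = default_bins()
    assert edges[0] == 0.0 and edges[-1] == 80.0 and len(edges) == 81
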
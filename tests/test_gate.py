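"""Lateral-gate separation, projected CV, H-bond counting, register states."""

import numpy as np
import pytest

from barrelmetrics.categories import Category
from barrelmetrics.gate import (GateSpec, NATIVE, OPEN, SHIFTED,
                                classify_register, count_hbonds,
                                count_seam_hbonds, gate_series, projected_cv,
                                strand_separation)
from barrelmetrics.geometry import minimum_image
from barrelmetrics.model import Frame, Topology
from barrelmetrics.synth import gen_barrel, gen_hbond_set

BOX = np.array([100.0, 100.0, 100.0])


def _frame(atoms):
    """atoms: list of (name, residue, xyz)."""
    names, res, xyz = zip(*atoms)
    n = len(atoms)
    return Frame(
        coords=np.asarray(xyz, float),
        box=BOX,
        atom_ids=np.arange(1, n + 1),
        atom_names=np.array(names),
        elements=np.array([nm[0] for nm in names]),
        residue_index=np.array(res),
        residue_names=np.full(n, "ALA"),
        segids=np.full(n, "X"),
        categories=np.full(n, int(Category.PROTEIN), dtype=np.int8),
    )


def _gate_frame(oa, na, nb, ob):
    return _frame([("O", 1, oa), ("N", 1, na), ("N", 2, nb), ("O", 2, ob)])


def test_separation_is_mean_of_cross_distances():
    fr = _gate_frame(oa=(0, 0, 0), na=(0, 1, 0), nb=(3, 0, 0), ob=(3, 1, 0))
    spec = GateSpec(residue_a=1, residue_b=2)
    assert strand_separation(fr, spec) == pytest.approx(3.0, abs=1e-12)


def test_separation_zero_for_coincident_pairs():
    fr = _gate_frame(oa=(5, 5, 5), na=(6, 5, 5), nb=(5, 5, 5), ob=(6, 5, 5))
    spec = GateSpec(residue_a=1, residue_b=2)
    assert strand_separation(fr, spec) == 0.0


def test_separation_uses_minimum_image():
    # the pair straddles the periodic boundary: 99 -> 1 is 2 Å, not 98
    fr = _gate_frame(oa=(99, 0, 0), na=(99, 1, 0), nb=(1, 0, 0), ob=(1, 1, 0))
    spec = GateSpec(residue_a=1, residue_b=2)
    assert strand_separation(fr, spec) == pytest.approx(2.0)


def test_separation_matches_direct_recomputation():
    rng = np.random.default_rng(31)
    spec = GateSpec(residue_a=1, residue_b=2)
    for _ in range(50):
        pts = rng.uniform(0, 100, (4, 3))
        fr = _gate_frame(*pts)
        d1 = np.linalg.norm(minimum_image(pts[2] - pts[0], BOX))
        d2 = np.linalg.norm(minimum_image(pts[3] - pts[1], BOX))
        assert strand_separation(fr, spec) == pytest.approx(
            0.5 * (d1 + d2), abs=1e-9)


def test_projected_cv_examples():
    spec = GateSpec(residue_a=1, residue_b=2,
                    opening_direction=(1.0, 0.0, 0.0))
    fr = _gate_frame(oa=(0, 0, 0), na=(0, 1, 0), nb=(2, 0, 0), ob=(2, 1, 0))
    assert projected_cv(fr, spec) == pytest.approx(2.0, abs=1e-12)
    fr = _gate_frame(oa=(0, 0, 0), na=(0, 0, 0), nb=(0, 5, 0), ob=(0, 5, 0))
    assert projected_cv(fr, spec) == pytest.approx(0.0, abs=1e-12)


def test_projected_cv_matches_dot_product_and_is_bounded():
    rng = np.random.default_rng(32)
    for _ in range(50):
        pts = rng.uniform(40, 60, (4, 3))
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        spec = GateSpec(residue_a=1, residue_b=2, opening_direction=d)
        fr = _gate_frame(*pts)
        expected = 0.5 * (np.dot(pts[2] - pts[0], d) + np.dot(pts[3] - pts[1], d))
        cv = projected_cv(fr, spec)
        assert cv == pytest.approx(expected, abs=1e-9)
        # mean projection can never exceed the mean distance
        assert abs(cv) <= strand_separation(fr, spec) + 1e-9


def test_metrics_invariant_under_rigid_motion():
    rng = np.random.default_rng(33)
    pts = rng.uniform(40, 60, (4, 3))
    d = np.array([1.0, 0.0, 0.0])
    spec = GateSpec(residue_a=1, residue_b=2, opening_direction=d)
    fr = _gate_frame(*pts)
    sep0, cv0 = strand_separation(fr, spec), projected_cv(fr, spec)

    shift = np.array([3.0, -2.0, 7.0])
    fr_t = _gate_frame(*(pts + shift))
    assert strand_separation(fr_t, spec) == pytest.approx(sep0, abs=1e-9)
    assert projected_cv(fr_t, spec) == pytest.approx(cv0, abs=1e-9)

    ang = 0.7
    rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                    [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
    center = pts.mean(axis=0)
    pts_r = (pts - center) @ rot.T + center
    fr_r = _gate_frame(*pts_r)
    spec_r = GateSpec(residue_a=1, residue_b=2, opening_direction=rot @ d)
    assert strand_separation(fr_r, spec) == pytest.approx(sep0, abs=1e-9)
    # rotating the opening direction with the system leaves the CV unchanged
    assert projected_cv(fr_r, spec_r) == pytest.approx(cv0, abs=1e-9)


# --- hydrogen bonds --------------------------------------------------------

def test_linear_geometry_at_29_is_one_bond():
    fr = _frame([("N", 1, (0, 0, 0)), ("HN", 1, (1.0, 0, 0)),
                 ("O", 2, (2.9, 0, 0))])
    assert count_hbonds(fr, [(0, 1)], [2]) == 1


def test_bent_geometry_at_140_degrees_is_no_bond():
    # D-H...A angle of 140° deviates 40° from linear: rejected
    h = np.array([1.0, 0.0, 0.0])
    ang = np.radians(180 - 140)
    a = h + 1.9 * np.array([np.cos(ang), np.sin(ang), 0.0])
    fr = _frame([("N", 1, (0, 0, 0)), ("HN", 1, tuple(h)), ("O", 2, tuple(a))])
    assert np.linalg.norm(a) <= 3.5  # distance criterion alone would pass
    assert count_hbonds(fr, [(0, 1)], [2]) == 0


def brute_force_hbonds(frame, donors, acceptors, cutoff=3.5, angle_tol=30.0):
    """Independent O(n²) oracle with its own geometry code."""
    count = 0
    box = frame.box
    for d_idx, h_idx in donors:
        for a_idx in acceptors:
            if a_idx in (d_idx, h_idx):
                continue
            dv = frame.coords[a_idx] - frame.coords[d_idx]
            dv -= box * np.round(dv / box)
            if np.sqrt((dv**2).sum()) > cutoff:
                continue
            v1 = frame.coords[d_idx] - frame.coords[h_idx]
            v2 = frame.coords[a_idx] - frame.coords[h_idx]
            v1 -= box * np.round(v1 / box)
            v2 -= box * np.round(v2 / box)
            cosang = (v1 @ v2) / np.sqrt((v1**2).sum() * (v2**2).sum())
            theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if theta >= 180.0 - angle_tol:
                count += 1
    return count


def test_hbond_fixture_count_matches_oracle():
    top, fr = gen_hbond_set(7, 9, seed=5)
    assert count_hbonds(fr, top.hbond_donors, top.hbond_acceptors) == 7
    assert brute_force_hbonds(fr, top.hbond_donors, top.hbond_acceptors) == 7


def test_hbond_module_equals_brute_force_on_random_fixtures():
    rng = np.random.default_rng(55)
    for trial in range(25):
        nv, ni = int(rng.integers(0, 10)), int(rng.integers(0, 10))
        top, fr = gen_hbond_set(nv, ni, seed=1000 + trial)
        ours = count_hbonds(fr, top.hbond_donors, top.hbond_acceptors)
        assert ours == brute_force_hbonds(fr, top.hbond_donors,
                                          top.hbond_acceptors)
        assert ours == nv


# --- register classification -----------------------------------------------

def _seam_system(native_sep, native_bonded, partner_bonded):
    """Residue 1 (β1 gate), residue 2 (native β16 partner), residue 3
    (sliding partner below it)."""
    atoms = []
    # residue 1: donor N-H pointing +x, acceptor O
    atoms += [("N", 1, (0, 0, 0)), ("HN", 1, (1, 0, 0)), ("O", 1, (0, 0, 1.2))]
    # residue 2 at native_sep along +x
    x2 = native_sep if not native_bonded else 2.9
    atoms += [("N", 2, (x2, 0, 0.5)), ("HN", 2, (x2 - 1, 0, 0.5)),
              ("O", 2, (x2, 0, 0))]
    # residue 3: acceptor placed bonded to residue 1's N-H if requested
    x3 = 2.9 if partner_bonded else 20.0
    atoms += [("N", 3, (x3, 0, -3.0)), ("HN", 3, (x3 - 1, 0, -3.0)),
              ("O", 3, (x3, 0, 0) if partner_bonded else (x3, 0, -3.0))]
    fr = _frame(atoms)
    top = Topology(
        n_atoms=fr.n_atoms,
        hbond_donors=[(0, 1), (3, 4), (6, 7)],
        hbond_acceptors=[2, 5, 8],
        sliding_partners=(3,),
    )
    spec = GateSpec(residue_a=1, residue_b=2)
    return fr, top, spec


def test_native_pair_bonded_is_native():
    fr, top, spec = _seam_system(2.9, native_bonded=True, partner_bonded=False)
    assert strand_separation(fr, spec) < 8.0
    assert classify_register(fr, top, spec) == NATIVE


def test_separated_with_partner_bond_is_shifted():
    fr, top, spec = _seam_system(9.0, native_bonded=False, partner_bonded=True)
    assert strand_separation(fr, spec) >= 8.0
    assert classify_register(fr, top, spec) == SHIFTED


def test_separated_without_bonds_is_open():
    fr, top, spec = _seam_system(9.0, native_bonded=False,
                                 partner_bonded=False)
    assert classify_register(fr, top, spec) == OPEN


# --- series over the synthetic barrel --------------------------------------

def test_gate_series_on_synthetic_barrel():
    top, fr = gen_barrel(seed=7)
    spec = GateSpec(residue_a=top.gate_pair[0], residue_b=top.gate_pair[1],
                    opening_direction=(1.0, 0.0, 0.0))
    series = gate_series([fr, fr], top, spec)
    assert series.separation.shape == (2,)
    assert np.all(series.separation >= 0)
    assert series.separation[0] == series.separation[1]
    assert series.hbonds[0] == count_seam_hbonds(fr, top, spec)
    df = series.to_dataframe()
    assert list(df.columns) == ["frame", "separation_A", "hbonds", "cv_A",
                                "register"]


def test_missing_backbone_atom_is_an_error():
    fr = _frame([("O", 1, (0, 0, 0)), ("N", 1, (0, 1, 0)),
                 ("N", 2, (3, 0, 0))])  # residue 2 lacks O
    spec = GateSpec(residue_a=1, residue_b=2)
    with pytest.raises(ValueError, match="backbone"):
        strand_separation(fr, spec)


def test_spec_validation():
    with pytest.raises(ValueError):
        GateSpec(residue_a=1, residue_b=2, opening_direction=(0, 0, 0))
    with pytest.raises(ValueError):
        GateSpec(residue_a=1, residue_b=2, hbond_angle_tol=95.0)
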
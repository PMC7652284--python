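"""Thickness mapping, per-strand averages and the thinned-area statistic."""

import numpy as np
import pytest

from barrelmetrics.categories import Category
from barrelmetrics.model import Frame, Topology
from barrelmetrics.synth import (BilayerSpec, GaussianDefect,
                                 embed_barrel_in_bilayer, gen_barrel,
                                 gen_bilayer)
from barrelmetrics.thickness import (PolarGridSpec, assign_leaflets,
                                     per_strand_thickness, thickness_map,
                                     thinned_area)


def _tiny_frame(zs):
    n = len(zs)
    return Frame(
        coords=np.column_stack([np.zeros(n), np.zeros(n), np.asarray(zs)]),
        box=np.array([50.0, 50.0, 100.0]),
        atom_ids=np.arange(1, n + 1),
        atom_names=np.full(n, "CB"),
        elements=np.full(n, "C"),
        residue_index=np.arange(1, n + 1),
        residue_names=np.full(n, "LIP"),
        segids=np.full(n, "X"),
        categories=np.full(n, int(Category.PL_TAIL), dtype=np.int8),
    )


def test_symmetric_bilayer_splits_evenly():
    top, frames = gen_bilayer(BilayerSpec(box_xy=(30.0, 30.0), noise_std=0.0))
    labels = assign_leaflets(frames[0])
    assert (labels == 1).sum() == (labels == -1).sum() == top.n_atoms // 2


def test_midplane_tie_breaks_outward():
    # boundary atoms at -1, +1 and exactly on the midplane (0)
    fr = _tiny_frame([-1.0, 1.0, 0.0])
    labels = assign_leaflets(fr)
    assert list(labels) == [-1, 1, 1]


def test_leaflet_assignment_matches_sign_oracle():
    rng = np.random.default_rng(21)
    zs = np.concatenate([rng.normal(15, 1, 40), rng.normal(-15, 1, 40)])
    fr = _tiny_frame(zs)
    labels = assign_leaflets(fr)
    np.testing.assert_array_equal(labels, np.where(zs >= zs.mean(), 1, -1))


def test_monolayer_is_rejected():
    fr = _tiny_frame([10.0, 10.0, 10.0])
    with pytest.raises(ValueError, match="one side"):
        assign_leaflets(fr)


# --- thickness map ---------------------------------------------------------

def test_flat_noiseless_map_is_exactly_base_thickness():
    top, frames = gen_bilayer(BilayerSpec(noise_std=0.0, seed=0))
    tmap = thickness_map(frames, top)
    vals = tmap.thickness[~tmap.missing]
    assert vals.size > 0
    np.testing.assert_allclose(vals, 30.0, atol=1e-9)


def test_map_invariant_under_rigid_translation():
    defect = GaussianDefect(center=(50.0, 50.0), depth=12.0, sigma=8.0)
    top, frames = gen_bilayer(BilayerSpec(noise_std=0.0, defect=defect))
    tmap = thickness_map(frames, top)
    shifted = [f.replace_coords(f.coords + np.array([13.0, -7.0, 23.0]))
               for f in frames]
    # translate the axis reference along: no barrel, so shift the defect too
    tmap2 = thickness_map(
        [f.replace_coords(f.coords - np.array([13.0, -7.0, 23.0]))
         for f in shifted], top)
    np.testing.assert_allclose(tmap.thickness, tmap2.thickness, equal_nan=True)


def test_map_equivariant_under_rotation_by_whole_bins():
    defect = GaussianDefect(center=(65.0, 50.0), depth=12.0, sigma=8.0)
    top, frames = gen_bilayer(BilayerSpec(noise_std=0.0, defect=defect))
    grid = PolarGridSpec(n_theta=36)  # 10° bins
    tmap = thickness_map(frames, top, grid)
    # rotate the whole system about the box centre by exactly two bins
    ang = np.radians(20.0)
    rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                    [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
    center = np.array([50.0, 50.0, 0.0])
    rframes = [f.replace_coords((f.coords - center) @ rot.T + center)
               for f in frames]
    tmap_rot = thickness_map(rframes, top, grid)
    rolled = np.roll(tmap.thickness, 2, axis=1)
    both = ~np.isnan(rolled) & ~np.isnan(tmap_rot.thickness)
    # lattice atoms exactly on a bin edge may hop bins under rotation, so
    # definedness can differ in a handful of boundary bins
    assert both.sum() >= 0.9 * max((~np.isnan(rolled)).sum(), 1)
    diff = np.abs(rolled[both] - tmap_rot.thickness[both])
    assert np.mean(diff <= 1e-9) >= 0.95   # almost every bin maps exactly
    assert diff.max() <= 1.0               # edge-hopping bins stay close


def test_defect_bin_reports_reduced_thickness():
    # defect centred inside the radial bin [12, 16) at the first angular
    # bin's centre (11.25° of a 16-sector grid)
    phi = np.radians(11.25)
    defect = GaussianDefect(center=(50.0 + 14.0 * np.cos(phi),
                                    50.0 + 14.0 * np.sin(phi)),
                            depth=12.0, sigma=8.0)
    top, frames = gen_bilayer(BilayerSpec(noise_std=0.0, defect=defect))
    grid = PolarGridSpec(r_edges=np.arange(0.0, 44.0, 4.0), n_theta=16)
    tmap = thickness_map(frames, top, grid)
    ri = np.searchsorted(grid.r_edges, 14.0) - 1
    val = tmap.thickness[ri, 0]
    # bin atoms lie within ~4 Å of the defect centre: field in [18, ~21]
    assert 18.0 <= val <= 21.0


def test_empty_frames_rejected():
    top = Topology(n_atoms=0)
    with pytest.raises(ValueError, match="empty"):
        thickness_map([], top)


# --- per-strand ------------------------------------------------------------

@pytest.fixture(scope="module")
def barrel_in_flat_bilayer():
    btop, bframe = gen_barrel(n_strands=16, radius=13.0, seed=2,
                              placement_noise=0.0)
    spec = BilayerSpec(noise_std=0.0, seed=2)
    _, bil_frames = gen_bilayer(spec, n_frames=1)
    return embed_barrel_in_bilayer(btop, bframe, Topology(n_atoms=0),
                                   bil_frames)


def test_all_strands_see_flat_membrane(barrel_in_flat_bilayer):
    top, frames = barrel_in_flat_bilayer
    tmap = thickness_map(frames, top)
    strands = per_strand_thickness(tmap, top, frames)
    assert sorted(strands) == list(range(1, 17))
    for v in strands.values():
        assert v == pytest.approx(30.0, abs=1e-9)


def test_strand_relabeling_permutes_outputs(barrel_in_flat_bilayer):
    top, frames = barrel_in_flat_bilayer
    tmap = thickness_map(frames, top)
    base = per_strand_thickness(tmap, top, frames)
    perm = {k: top.strands[1 + (k + 4) % 16] for k in range(1, 17)}
    top_perm = Topology(
        n_atoms=top.n_atoms, strands=perm, residue_class=top.residue_class,
        sidechain_atoms=top.sidechain_atoms,
        barrel_backbone=top.barrel_backbone)
    permuted = per_strand_thickness(tmap, top_perm, frames)
    for k in range(1, 17):
        assert permuted[k] == pytest.approx(base[1 + (k + 4) % 16])


def test_defect_at_gate_azimuth_makes_gate_strands_thinnest():
    btop, bframe = gen_barrel(n_strands=16, radius=13.0, seed=2,
                              placement_noise=0.0)
    # gate seam sits between strand 16 (azimuth 0) and strand 1 (22.5°)
    phi = np.radians(11.25)
    center = (50.0 + 18.0 * np.cos(phi), 50.0 + 18.0 * np.sin(phi))
    spec = BilayerSpec(noise_std=0.0, seed=2,
                       defect=GaussianDefect(center=center, depth=12.0,
                                             sigma=8.0))
    _, bil_frames = gen_bilayer(spec, n_frames=1)
    top, frames = embed_barrel_in_bilayer(btop, bframe, Topology(n_atoms=0),
                                          bil_frames)
    strands = per_strand_thickness(thickness_map(frames, top), top, frames)
    ranking = sorted(strands, key=strands.get)
    assert set(ranking[:2]) == {1, 16}


# --- thinned area ----------------------------------------------------------

def test_uniform_bilayer_has_zero_thinned_area():
    top, frames = gen_bilayer(BilayerSpec(base_thickness=30.0, noise_std=0.0))
    res = thinned_area(frames, top, threshold=20.0)
    assert res.area == 0.0


def test_threshold_is_strict():
    top, frames = gen_bilayer(BilayerSpec(base_thickness=20.0, noise_std=0.0))
    res = thinned_area(frames, top, threshold=20.0)
    assert res.area == 0.0


def test_gaussian_defect_area_matches_level_set():
    defect = GaussianDefect(center=(50.0, 50.0), depth=12.0, sigma=8.0)
    spec = BilayerSpec(base_thickness=30.0, noise_std=0.0, seed=1,
                       defect=defect)
    top, frames = gen_bilayer(spec)
    res = thinned_area(frames, top, threshold=20.0, cell=1.0)
    expected = defect.level_set_area(30.0, 20.0)
    assert res.area == pytest.approx(expected, rel=0.10)


def test_thinned_area_monotone_in_threshold():
    defect = GaussianDefect(center=(50.0, 50.0), depth=12.0, sigma=8.0)
    top, frames = gen_bilayer(BilayerSpec(noise_std=0.0, defect=defect))
    areas = [thinned_area(frames, top, threshold=t).area
             for t in (18.0, 20.0, 22.0, 25.0)]
    assert all(a <= b for a, b in zip(areas, areas[1:]))


def test_protein_footprint_is_excluded(barrel_in_flat_bilayer):
    # a thin membrane everywhere: without the exclusion every in-plane cell
    # would count, with it the barrel footprint is carved out
    btop, bframe = gen_barrel(n_strands=16, radius=13.0, seed=2)
    spec = BilayerSpec(base_thickness=15.0, noise_std=0.0, seed=2)
    _, bil_frames = gen_bilayer(spec, n_frames=1)
    top, frames = embed_barrel_in_bilayer(btop, bframe, Topology(n_atoms=0),
                                          bil_frames)
    with_protein = thinned_area(frames, top, threshold=20.0)
    box_area = frames[0].box[0] * frames[0].box[1]
    assert 0 < with_protein.area < box_area


def test_bad_cell_size_rejected():
    top, frames = gen_bilayer(BilayerSpec(noise_std=0.0))
    with pytest.raises(ValueError):
        thinned_area(frames, top, cell=0.0)
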
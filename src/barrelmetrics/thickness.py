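"""Local hydrophobic membrane thickness around a β-barrel.

"Hydrophobic thickness" is operationalised as the vertical distance between
the hydrophobic boundary atoms of the two leaflets (default: the first
acyl-chain carbon of each lipid — a config knob).  Thickness is mapped on a
polar grid centred on the barrel axis (the membrane normal through the xy
centroid of the barrel backbone), averaged per strand, and summarised as
the area of membrane thinner than a threshold (default 20 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .categories import Category
from .geometry import minimum_image_xy
from .model import Frame, Topology

BoundarySelection = Callable[[Frame], np.ndarray]

#: default boundary-atom names: CB for synthetic pseudo-lipids, C22 (first
#: acyl carbon of the sn-2 chain) for CHARMM lipids
DEFAULT_BOUNDARY_NAMES = ("CB", "C22")

OUTER, INNER = 1, -1


def default_boundary(frame: Frame) -> np.ndarray:
    """Boolean mask of hydrophobic boundary atoms: lipid-tail category
    atoms carrying one of the configured boundary names."""
    tails = np.isin(frame.categories,
                    [int(Category.LIPIDA_TAIL), int(Category.PL_TAIL)])
    return tails & np.isin(frame.atom_names, list(DEFAULT_BOUNDARY_NAMES))


def boundary_by_name(*names: str) -> BoundarySelection:
    def select(frame: Frame) -> np.ndarray:
        return np.isin(frame.atom_names, list(names))
    return select


def assign_leaflets(frame: Frame,
                    boundary_selection: BoundarySelection = default_boundary,
                    ) -> np.ndarray:
    """Label boundary atoms OUTER (+1) / INNER (−1) by side of the midplane.

    The midplane is the mean z of all boundary atoms; atoms exactly on it
    count as OUTER.  Returns a full-length array with 0 for non-boundary
    atoms; raises if the boundary atoms do not form two leaflets.
    """
    mask = np.asarray(boundary_selection(frame), bool)
    if mask.sum() < 2:
        raise ValueError("need at least one boundary atom per leaflet")
    z = frame.coords[mask, 2]
    mid = z.mean()
    labels = np.zeros(frame.n_atoms, dtype=int)
    side = np.where(z >= mid, OUTER, INNER)
    if np.all(side == side[0]):
        raise ValueError("all boundary atoms lie on one side: no bilayer")
    labels[np.flatnonzero(mask)] = side
    return labels


@dataclass
class PolarGridSpec:
    """Polar binning around the barrel axis."""

    r_edges: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 42.0, 2.0))
    n_theta: int = 36

    @property
    def theta_edges(self) -> np.ndarray:
        return np.linspace(0.0, 2.0 * np.pi, self.n_theta + 1)


@dataclass
class ThicknessMap:
    """Frame-averaged thickness field on a polar grid."""

    r_edges: np.ndarray
    theta_edges: np.ndarray
    thickness: np.ndarray        # (n_r, n_theta), NaN where missing
    frame_counts: np.ndarray     # frames contributing per bin
    atom_counts: np.ndarray      # boundary atoms accumulated per bin
    axis_xy: np.ndarray          # frame-mean axis position
    n_frames: int

    @property
    def missing(self) -> np.ndarray:
        return self.frame_counts == 0

    def to_dataframe(self) -> pd.DataFrame:
        nr, nt = self.thickness.shape
        ri, ti = np.meshgrid(np.arange(nr), np.arange(nt), indexing="ij")
        return pd.DataFrame({
            "r_lo": self.r_edges[ri.ravel()],
            "r_hi": self.r_edges[ri.ravel() + 1],
            "theta_lo": self.theta_edges[ti.ravel()],
            "theta_hi": self.theta_edges[ti.ravel() + 1],
            "thickness": self.thickness.ravel(),
            "count": self.atom_counts.ravel(),
        })


def barrel_axis_xy(frame: Frame, topology: Topology) -> np.ndarray:
    """Membrane-normal axis position: xy centroid of the barrel backbone,
    or the box centre when the system holds no barrel."""
    if topology.barrel_backbone is not None and topology.barrel_backbone.size:
        return frame.coords[topology.barrel_backbone, :2].mean(axis=0)
    return frame.box[:2] / 2.0


def thickness_map(frames: Sequence[Frame], topology: Topology,
                  grid: PolarGridSpec | None = None,
                  boundary_selection: BoundarySelection = default_boundary,
                  ) -> ThicknessMap:
    """Per-bin inter-leaflet distance, averaged over frames.

    In each frame and polar bin, thickness is the mean z of outer-leaflet
    boundary atoms minus the mean z of inner-leaflet ones; a bin missing
    either leaflet in a frame contributes nothing for that frame, and bins
    never populated are masked NaN.
    """
    if not frames:
        raise ValueError("empty frame sequence")
    grid = grid or PolarGridSpec()
    r_edges = np.asarray(grid.r_edges, float)
    t_edges = grid.theta_edges
    nr, nt = r_edges.size - 1, t_edges.size - 1

    t_sum = np.zeros((nr, nt))
    f_cnt = np.zeros((nr, nt), dtype=int)
    a_cnt = np.zeros((nr, nt), dtype=int)
    axes = []
    for frame in frames:
        labels = assign_leaflets(frame, boundary_selection)
        axis = barrel_axis_xy(frame, topology)
        axes.append(axis)
        sel = np.flatnonzero(labels != 0)
        dxy = minimum_image_xy(frame.coords[sel, :2] - axis, frame.box)
        r = np.hypot(dxy[:, 0], dxy[:, 1])
        theta = np.mod(np.arctan2(dxy[:, 1], dxy[:, 0]), 2.0 * np.pi)
        ri = np.digitize(r, r_edges) - 1
        ti = np.clip(np.digitize(theta, t_edges) - 1, 0, nt - 1)
        ok = (ri >= 0) & (ri < nr)

        z_sum = np.zeros((2, nr, nt))
        z_cnt = np.zeros((2, nr, nt), dtype=int)
        leaf = (labels[sel] == INNER).astype(int)  # 0 outer, 1 inner
        np.add.at(z_sum, (leaf[ok], ri[ok], ti[ok]), frame.coords[sel[ok], 2])
        np.add.at(z_cnt, (leaf[ok], ri[ok], ti[ok]), 1)
        both = (z_cnt[0] > 0) & (z_cnt[1] > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_frame = z_sum[0] / z_cnt[0] - z_sum[1] / z_cnt[1]
        t_sum[both] += t_frame[both]
        f_cnt[both] += 1
        a_cnt[both] += z_cnt[0][both] + z_cnt[1][both]

    with np.errstate(invalid="ignore"):
        thickness = np.where(f_cnt > 0, t_sum / np.maximum(f_cnt, 1), np.nan)
    return ThicknessMap(
        r_edges=r_edges, theta_edges=t_edges, thickness=thickness,
        frame_counts=f_cnt, atom_counts=a_cnt,
        axis_xy=np.mean(axes, axis=0), n_frames=len(frames),
    )


def strand_azimuths(frames: Sequence[Frame], topology: Topology) -> dict[int, float]:
    """Circular-mean azimuth of each strand's backbone centroid, about the
    barrel axis, in [0, 2π)."""
    out: dict[int, float] = {}
    for s, residues in topology.strands.items():
        sin_sum = cos_sum = 0.0
        for frame in frames:
            axis = barrel_axis_xy(frame, topology)
            in_strand = np.isin(frame.residue_index, residues)
            bb = np.zeros(frame.n_atoms, bool)
            if topology.barrel_backbone is not None:
                bb[topology.barrel_backbone] = True
            sel = in_strand & bb
            if not sel.any():
                continue
            c = frame.coords[sel, :2].mean(axis=0) - axis
            phi = np.arctan2(c[1], c[0])
            sin_sum += np.sin(phi)
            cos_sum += np.cos(phi)
        out[s] = float(np.mod(np.arctan2(sin_sum, cos_sum), 2.0 * np.pi))
    return out


def barrel_wall_radius(frames: Sequence[Frame], topology: Topology) -> float:
    """Mean radial distance of barrel backbone atoms from the axis."""
    radii = []
    for frame in frames:
        axis = barrel_axis_xy(frame, topology)
        d = frame.coords[topology.barrel_backbone, :2] - axis
        radii.append(np.hypot(d[:, 0], d[:, 1]).mean())
    return float(np.mean(radii))


def per_strand_thickness(tmap: ThicknessMap, topology: Topology,
                         frames: Sequence[Frame],
                         radial_band: float = 10.0) -> dict[int, float]:
    """Count-weighted mean thickness of the angular sector facing each strand.

    Each angular bin is attributed to the strand whose backbone-centroid
    azimuth is circularly nearest; only radial bins within ``radial_band``
    outward of the barrel wall enter the average.  Strands with no
    populated bins report NaN (missing), never 0.
    """
    if not topology.strands:
        raise ValueError("topology carries no strand assignments")
    azimuths = strand_azimuths(frames, topology)
    r_wall = barrel_wall_radius(frames, topology)
    r_centers = 0.5 * (tmap.r_edges[:-1] + tmap.r_edges[1:])
    t_centers = 0.5 * (tmap.theta_edges[:-1] + tmap.theta_edges[1:])
    in_band = (r_centers >= r_wall) & (r_centers <= r_wall + radial_band)

    strand_ids = sorted(azimuths)
    phis = np.array([azimuths[s] for s in strand_ids])
    # circular distance of every angular bin to every strand azimuth
    d = np.abs(np.angle(np.exp(1j * (t_centers[:, None] - phis[None, :]))))
    nearest = np.argmin(d, axis=1)

    result: dict[int, float] = {}
    for k, s in enumerate(strand_ids):
        cols = np.flatnonzero(nearest == k)
        block_t = tmap.thickness[np.ix_(in_band, cols)]
        block_w = tmap.atom_counts[np.ix_(in_band, cols)].astype(float)
        ok = ~np.isnan(block_t) & (block_w > 0)
        if not ok.any():
            result[s] = float("nan")
        else:
            result[s] = float(np.average(block_t[ok], weights=block_w[ok]))
    return result


@dataclass
class ThinnedAreaResult:
    """Area of membrane thinner than a threshold."""

    threshold: float
    cell: float
    per_frame: np.ndarray   # Å² per frame
    area: float             # mean over frames, Å²

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(self.per_frame.size),
                             "thinned_area_A2": self.per_frame})


def thinned_area(frames: Sequence[Frame], topology: Topology,
                 threshold: float = 20.0, cell: float = 1.0,
                 boundary_selection: BoundarySelection = default_boundary,
                 idw_cutoff: float = 10.0, idw_power: float = 4.0,
                 protein_exclusion: float = 2.0) -> ThinnedAreaResult:
    """Membrane area with thickness strictly below ``threshold``.

    Per frame, each leaflet's boundary surface z(x, y) is interpolated onto
    a Cartesian grid of ``cell`` Å cells by inverse-distance weighting
    (in-plane, periodic, ``idw_cutoff`` neighbourhood); cells with no
    neighbour in either leaflet are left undefined, and cells whose centre
    lies within ``protein_exclusion`` Å (xy) of any protein heavy atom are
    excluded so the barrel footprint never counts as thin membrane.
    """
    if cell <= 0:
        raise ValueError("cell size must be > 0")
    if not frames:
        raise ValueError("empty frame sequence")
    per_frame = []
    for frame in frames:
        lx, ly = frame.box[0], frame.box[1]
        nx, ny = max(1, int(lx // cell)), max(1, int(ly // cell))
        xs = (np.arange(nx) + 0.5) * (lx / nx)
        ys = (np.arange(ny) + 0.5) * (ly / ny)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        cells = np.column_stack([gx.ravel(), gy.ravel()])

        labels = assign_leaflets(frame, boundary_selection)
        surfaces = []
        for leaf in (OUTER, INNER):
            idx = np.flatnonzero(labels == leaf)
            z = _idw_surface(cells, frame.coords[idx, :2],
                             frame.coords[idx, 2], (lx, ly),
                             idw_cutoff, idw_power)
            surfaces.append(z)
        thickness = surfaces[0] - surfaces[1]

        valid = np.isfinite(thickness)
        prot = np.flatnonzero(
            (frame.categories == int(Category.PROTEIN))
            & (frame.elements != "H"))
        if prot.size and protein_exclusion > 0:
            tree = cKDTree(np.mod(frame.coords[prot, :2], (lx, ly)),
                           boxsize=(lx, ly))
            near = tree.query_ball_point(np.mod(cells, (lx, ly)),
                                         r=protein_exclusion)
            excluded = np.array([len(n) > 0 for n in near])
            valid &= ~excluded
        # strictly below threshold; the 1e-9 guard keeps exact ties (a
        # uniform membrane at the threshold) from counting through fp noise
        n_thin = int(np.sum(valid & (thickness < threshold - 1e-9)))
        per_frame.append(n_thin * (lx / nx) * (ly / ny))
    per_frame = np.asarray(per_frame)
    return ThinnedAreaResult(threshold=threshold, cell=cell,
                             per_frame=per_frame,
                             area=float(per_frame.mean()))


def _idw_surface(cells: np.ndarray, atom_xy: np.ndarray, atom_z: np.ndarray,
                 box_xy: tuple[float, float], cutoff: float,
                 power: float) -> np.ndarray:
    """Inverse-distance-weighted z at cell centres (periodic in-plane)."""
    if atom_xy.shape[0] == 0:
        return np.full(cells.shape[0], np.nan)
    tree_a = cKDTree(np.mod(atom_xy, box_xy), boxsize=box_xy)
    tree_c = cKDTree(np.mod(cells, box_xy), boxsize=box_xy)
    pairs = tree_c.sparse_distance_matrix(tree_a, cutoff, output_type="coo_matrix")
    w = 1.0 / np.maximum(pairs.data, 1e-6) ** power
    num = np.zeros(cells.shape[0])
    den = np.zeros(cells.shape[0])
    np.add.at(num, pairs.row, w * atom_z[pairs.col])
    np.add.at(den, pairs.row, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)
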
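"""Solvent-accessible surface areas, water exposure and contact areas.

SASA uses a deterministic Shrake–Rupley scheme: a fixed Fibonacci-spiral
point set on each atom's probe-expanded sphere is tested against the
probe-expanded spheres of neighbouring occluders; the accessible fraction
times the sphere area is the atom's SASA.  Point count is the accuracy
knob (default 960; quadrature error scales ~1/√n).

Built on it:

* water-exposure fraction of a residue's side chain — its SASA with all
  non-water, non-ion atoms occluding, divided by its SASA with only
  protein atoms occluding, per frame, binned into deciles over the
  trajectory;
* contact area between two disjoint atom groups,
  (SASA(A) + SASA(B) − SASA(A∪B)) / 2 — used for POTRA-domain/leaflet
  contacts;
* the isolated surface area of a domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .categories import Category
from .model import Frame, Topology

#: Bondi van der Waals radii (Å)
DEFAULT_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}

DEFAULT_PROBE = 1.4      # Å, water-sized probe
DEFAULT_N_POINTS = 960


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii_for(frame: Frame, indices: np.ndarray,
               radii_table: dict[str, float]) -> np.ndarray:
    out = np.empty(indices.size)
    for k, i in enumerate(indices):
        el = str(frame.elements[i]).upper()
        if el not in radii_table:
            raise KeyError(f"no van der Waals radius for element {el!r}")
        out[k] = radii_table[el]
    return out


@dataclass
class SasaResult:
    """Per-atom accessible areas (Å²)."""

    atom_indices: np.ndarray
    areas: np.ndarray
    probe: float
    n_points: int
    radii_table_id: str = "bondi"

    @property
    def total(self) -> float:
        return float(self.areas.sum())


def sasa(frame: Frame, selection: np.ndarray | None = None,
         occluders: np.ndarray | None = None,
         probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS,
         radii_table: dict[str, float] | None = None) -> SasaResult:
    """Accessible surface area of ``selection`` against ``occluders``.

    Both arguments are atom-index arrays; ``occluders`` defaults to the
    selection itself (the usual single-group SASA).  Surface points of one
    atom are blocked by any occluder sphere other than the atom itself.
    """
    radii_table = radii_table or DEFAULT_RADII
    if selection is None:
        selection = np.arange(frame.n_atoms)
    selection = np.asarray(selection, dtype=int)
    if occluders is None:
        occluders = selection
    occluders = np.asarray(occluders, dtype=int)

    unit = _fibonacci_sphere(n_points)
    sel_r = _radii_for(frame, selection, radii_table) + probe
    occ_r = _radii_for(frame, occluders, radii_table) + probe
    occ_xyz = frame.coords[occluders]
    tree = cKDTree(occ_xyz)
    max_occ_r = occ_r.max() if occ_r.size else 0.0

    areas = np.empty(selection.size)
    for k, i in enumerate(selection):
        center = frame.coords[i]
        ri = sel_r[k]
        neigh = tree.query_ball_point(center, r=ri + max_occ_r)
        neigh = [j for j in neigh if occluders[j] != i
                 and np.linalg.norm(occ_xyz[j] - center) < ri + occ_r[j]]
        if not neigh:
            areas[k] = 4.0 * np.pi * ri * ri
            continue
        pts = center + ri * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - occ_xyz[j]) ** 2, axis=1)
            accessible &= d2 > occ_r[j] ** 2
        areas[k] = accessible.mean() * 4.0 * np.pi * ri * ri
    return SasaResult(atom_indices=selection, areas=areas, probe=probe,
                      n_points=n_points)


def contact_area(frame: Frame, group_a: np.ndarray, group_b: np.ndarray,
                 probe: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_N_POINTS) -> float:
    """Buried-interface area between two disjoint groups (Å²):
    (SASA(A) + SASA(B) − SASA(A∪B)) / 2."""
    group_a = np.asarray(group_a, int)
    group_b = np.asarray(group_b, int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")
    sa = sasa(frame, group_a, probe=probe, n_points=n_points).total
    sb = sasa(frame, group_b, probe=probe, n_points=n_points).total
    both = np.concatenate([group_a, group_b])
    sab = sasa(frame, both, probe=probe, n_points=n_points).total
    return (sa + sb - sab) / 2.0


def domain_surface_area(frame: Frame, domain_residues: np.ndarray,
                        probe: float = DEFAULT_PROBE,
                        n_points: int = DEFAULT_N_POINTS) -> float:
    """SASA of a domain's atoms computed in isolation (Å²)."""
    domain_residues = np.asarray(domain_residues)
    atoms = np.flatnonzero(np.isin(frame.residue_index, domain_residues))
    if atoms.size == 0:
        raise ValueError("domain selects no atoms")
    return sasa(frame, atoms, probe=probe, n_points=n_points).total


@dataclass
class ExposureSeries:
    """Per-residue water-exposure fractions over frames, plus deciles."""

    residues: np.ndarray
    fractions: np.ndarray        # (n_res, n_frames), NaN where BURIED
    decile_edges: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 11))

    @property
    def deciles(self) -> np.ndarray:
        """(n_res, 10) histogram of fractions; counts sum to the number of
        frames with a defined (non-buried) fraction."""
        out = np.zeros((self.residues.size, 10), dtype=int)
        for i in range(self.residues.size):
            f = self.fractions[i]
            f = f[np.isfinite(f)]
            h, _ = np.histogram(np.clip(f, 0.0, 1.0), bins=self.decile_edges)
            out[i] = h
        return out

    def to_dataframe(self) -> pd.DataFrame:
        dec = self.deciles
        df = pd.DataFrame(dec, columns=[f"decile_{d}" for d in range(10)])
        df.insert(0, "residue", self.residues)
        return df


def water_exposure_fraction(frames: Sequence[Frame], topology: Topology,
                            residues: Sequence[int],
                            probe: float = DEFAULT_PROBE,
                            n_points: int = DEFAULT_N_POINTS) -> ExposureSeries:
    """Fraction of each residue's side-chain surface accessible to water.

    Numerator: side-chain SASA with every non-water, non-ion atom
    occluding (what a water probe can still reach).  Denominator: the
    same SASA with only protein atoms occluding.  The ratio is clamped to
    [0, 1]; frames where the denominator vanishes flag the residue BURIED
    (NaN) and are excluded from the deciles.
    """
    residues = np.asarray(sorted(residues), dtype=int)
    fractions = np.full((residues.size, len(frames)), np.nan)
    for fi, frame in enumerate(frames):
        non_water = np.flatnonzero(
            ~np.isin(frame.categories, [int(Category.WATER), int(Category.ION)]))
        protein = np.flatnonzero(frame.categories == int(Category.PROTEIN))
        for ri, res in enumerate(residues):
            sc = topology.sidechain_atoms.get(int(res))
            if sc is None or sc.size == 0:
                continue
            num = sasa(frame, sc, occluders=non_water,
                       probe=probe, n_points=n_points).total
            den = sasa(frame, sc, occluders=protein,
                       probe=probe, n_points=n_points).total
            if den <= 0:
                continue  # BURIED this frame
            fractions[ri, fi] = min(1.0, max(0.0, num / den))
    return ExposureSeries(residues=residues, fractions=fractions)
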
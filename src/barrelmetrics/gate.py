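"""Lateral-gate metrics for the β1–β16 seam.

Strand separation is the mean of the two cross distances between the
backbone N and O atoms of the gate residue pair (O_A–N_B and N_A–O_B).
The umbrella-sampling collective variable is the same pair of displacement
vectors projected onto the gate-opening direction taken from a maximally
open reference state, so a sliding (register-shifted) seam does not read
as opening.  Hydrogen bonds use the geometric criterion: donor–acceptor
heavy-atom distance ≤ 3.5 Å and D–H···A within 30° of linear.  A seam
whose native pair has separated beyond 8 Å while the β1 gate residue
hydrogen-bonds an alternative β16 partner is classified as register-shifted
("sliding"); separated with no bonds is open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import angle_deg, distance, minimum_image
from .model import Frame, Topology


@dataclass
class GateSpec:
    """Gate definition: the residue pair, opening direction, thresholds."""

    residue_a: int                       # on β1
    residue_b: int                       # on β16
    opening_direction: np.ndarray | None = None   # unit 3-vector
    hbond_cutoff: float = 3.5            # Å, donor–acceptor
    hbond_angle_tol: float = 30.0        # degrees off linear
    sliding_threshold: float = 8.0       # Å

    def __post_init__(self) -> None:
        if self.opening_direction is not None:
            d = np.asarray(self.opening_direction, float)
            n = np.linalg.norm(d)
            if n == 0:
                raise ValueError("opening direction must be non-zero")
            self.opening_direction = d / n
        if self.hbond_cutoff <= 0:
            raise ValueError("h-bond cutoff must be > 0")
        if not 0 < self.hbond_angle_tol < 90:
            raise ValueError("h-bond angle tolerance must be in (0, 90)")


#: Gate residue pairs of the simulated Omp85-family proteins
#: (residue on β1, residue on β16).
SPECIES_GATE_PAIRS: dict[str, tuple[int, int]] = {
    "EcBamA": (432, 806),
    "SeBamA": (432, 800),
    "HdBamA": (429, 789),
    "NgBamA": (432, 788),
    "EcTamA": (274, 571),
    "BpFhaC": (219, 548),
}


def _backbone_atom(frame: Frame, residue: int, name: str) -> int:
    hits = np.flatnonzero((frame.residue_index == residue)
                          & (frame.atom_names == name))
    if hits.size == 0:
        raise ValueError(f"residue {residue} has no backbone atom {name}")
    return int(hits[0])


def _cross_pairs(frame: Frame, spec: GateSpec):
    o_a = frame.coords[_backbone_atom(frame, spec.residue_a, "O")]
    n_a = frame.coords[_backbone_atom(frame, spec.residue_a, "N")]
    o_b = frame.coords[_backbone_atom(frame, spec.residue_b, "O")]
    n_b = frame.coords[_backbone_atom(frame, spec.residue_b, "N")]
    return (o_a, n_b), (n_a, o_b)


def strand_separation(frame: Frame, spec: GateSpec) -> float:
    """Mean of the two cross distances O_A–N_B and N_A–O_B (Å)."""
    (oa, nb), (na, ob) = _cross_pairs(frame, spec)
    return float(0.5 * (distance(oa, nb, frame.box)
                        + distance(na, ob, frame.box)))


def projected_cv(frame: Frame, spec: GateSpec) -> float:
    """Signed gate-opening collective variable (Å).

    Mean over the two cross pairs of the displacement vector projected on
    the opening direction; closing past the native register goes negative.
    """
    if spec.opening_direction is None:
        raise ValueError("gate spec has no opening direction")
    (oa, nb), (na, ob) = _cross_pairs(frame, spec)
    d1 = minimum_image(nb - oa, frame.box)
    d2 = minimum_image(ob - na, frame.box)
    return float(0.5 * (np.dot(d1, spec.opening_direction)
                        + np.dot(d2, spec.opening_direction)))


def count_hbonds(frame: Frame,
                 donors: Sequence[tuple[int, int]],
                 acceptors: Sequence[int],
                 cutoff: float = 3.5,
                 angle_tol: float = 30.0) -> int:
    """Geometric hydrogen-bond count over donor/acceptor lists.

    A donor (D, H) and acceptor A bond when the minimum-image D···A
    distance is ≤ cutoff and the D–H···A angle deviates from linear by at
    most ``angle_tol`` degrees.  Each (donor-H, acceptor) pair contributes
    at most one bond.
    """
    count = 0
    for d_idx, h_idx in donors:
        d = frame.coords[d_idx]
        h = frame.coords[h_idx]
        for a_idx in acceptors:
            if a_idx in (d_idx, h_idx):
                continue
            a = frame.coords[a_idx]
            if distance(d, a, frame.box) > cutoff:
                continue
            if 180.0 - angle_deg(d, h, a, frame.box) <= angle_tol:
                count += 1
    return count


def count_seam_hbonds(frame: Frame, topology: Topology,
                      spec: GateSpec) -> int:
    """H-bonds across the β1–β16 seam from the topology's donor/acceptor
    lists (which are restricted to the two gate strands)."""
    if not topology.hbond_donors:
        raise ValueError("topology lists no hydrogen-bond donors")
    return count_hbonds(frame, topology.hbond_donors, topology.hbond_acceptors,
                        spec.hbond_cutoff, spec.hbond_angle_tol)


def _residue_hbonds(frame: Frame, topology: Topology, spec: GateSpec,
                    res_x: int, res_y: int) -> int:
    """H-bond count restricted to donor/acceptor atoms of two residues."""
    in_pair = {res_x, res_y}
    donors = [(d, h) for d, h in topology.hbond_donors
              if frame.residue_index[d] in in_pair]
    acceptors = [a for a in topology.hbond_acceptors
                 if frame.residue_index[a] in in_pair]
    # only cross-residue bonds count
    count = 0
    for d_idx, h_idx in donors:
        rd = frame.residue_index[d_idx]
        d = frame.coords[d_idx]
        h = frame.coords[h_idx]
        for a_idx in acceptors:
            if frame.residue_index[a_idx] == rd:
                continue
            a = frame.coords[a_idx]
            if distance(d, a, frame.box) > spec.hbond_cutoff:
                continue
            if 180.0 - angle_deg(d, h, a, frame.box) <= spec.hbond_angle_tol:
                count += 1
    return count


NATIVE, SHIFTED, OPEN = "NATIVE", "SHIFTED", "OPEN"


def classify_register(frame: Frame, topology: Topology,
                      spec: GateSpec) -> str:
    """Register state of the seam in one frame.

    NATIVE: the native pair is closer than the sliding threshold and still
    hydrogen-bonded.  SHIFTED: the native pair has separated past the
    threshold while the β1 residue bonds one of the alternative β16
    partners.  OPEN: anything else.
    """
    sep = strand_separation(frame, spec)
    native_hb = _residue_hbonds(frame, topology, spec,
                                spec.residue_a, spec.residue_b)
    if sep < spec.sliding_threshold and native_hb >= 1:
        return NATIVE
    if sep >= spec.sliding_threshold:
        for partner in topology.sliding_partners:
            if _residue_hbonds(frame, topology, spec,
                               spec.residue_a, partner) >= 1:
                return SHIFTED
    return OPEN


@dataclass
class GateSeries:
    """Per-frame gate metrics over a trajectory."""

    separation: np.ndarray
    hbonds: np.ndarray
    cv: np.ndarray
    register: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(self.separation.size),
            "separation_A": self.separation,
            "hbonds": self.hbonds,
            "cv_A": self.cv,
            "register": self.register,
        })


def gate_series(frames: Sequence[Frame], topology: Topology,
                spec: GateSpec) -> GateSeries:
    """Evaluate all gate metrics frame by frame."""
    sep, hb, cv, reg = [], [], [], []
    for frame in frames:
        sep.append(strand_separation(frame, spec))
        hb.append(count_seam_hbonds(frame, topology, spec))
        cv.append(projected_cv(frame, spec)
                  if spec.opening_direction is not None else np.nan)
        reg.append(classify_register(frame, topology, spec))
    return GateSeries(separation=np.array(sep), hbonds=np.array(hb),
                      cv=np.array(cv), register=reg)
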
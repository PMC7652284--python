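"""Per-residue interaction census and the cross-protein difference metric.

For every barrel residue, atoms of each molecular category (water, LPS core,
lipid A head/tail, PL tail/head, protein) within 4 Å of its side chain are
accumulated over all frames and normalised to fractions.  The protein
category excludes backbone atoms of sequence neighbours (±2 by default) and
the probed residue's own atoms; ions belong to none of the seven categories
and never enter the totals.

Two proteins are compared through a pairwise alignment: the difference
metric is the Euclidean distance between the two residues' fraction
vectors, averaged over all aligned residue pairs.  It is 0 for identical
propensities and bounded above by √2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .categories import Category, PROPENSITY_CATEGORIES
from .model import BACKBONE_NAMES, Frame, PairAlignment, Topology

N_CATEGORIES = len(PROPENSITY_CATEGORIES)
_CAT_POS = {int(c): i for i, c in enumerate(PROPENSITY_CATEGORIES)}


@dataclass
class PropensityProfile:
    """Per-residue category-contact counts and fractions."""

    residues: np.ndarray                 # residue indices, sorted
    counts: np.ndarray                   # (n_res, 7) raw atom contacts
    n_frames: int
    glycine_proxy: set[int] = field(default_factory=set)

    @property
    def fractions(self) -> np.ndarray:
        tot = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.counts / tot, np.nan)

    @property
    def no_contact(self) -> np.ndarray:
        """Residues that never contacted anything (NO_CONTACT flag)."""
        return self.counts.sum(axis=1) == 0

    def fraction_of(self, residue: int) -> np.ndarray:
        i = int(np.searchsorted(self.residues, residue))
        if i >= self.residues.size or self.residues[i] != residue:
            raise KeyError(f"residue {residue} not in profile")
        return self.fractions[i]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=[c.name for c in PROPENSITY_CATEGORIES])
        df.insert(0, "residue", self.residues)
        frac = self.fractions
        for i, c in enumerate(PROPENSITY_CATEGORIES):
            df[f"frac_{c.name}"] = frac[:, i]
        df["no_contact"] = self.no_contact
        return df


def contact_census(frames, topology: Topology, cutoff: float = 4.0,
                   exclude_backbone_within: int = 2) -> PropensityProfile:
    """Count category atoms within ``cutoff`` of each residue's side chain.

    Distances are minimum-image, atom-to-atom over the side chain.
    Residues without side-chain atoms use the α-carbon as a proxy and are
    flagged.  Counts are additive over frames.
    """
    if not topology.sidechain_atoms:
        raise ValueError("topology defines no side-chain atom sets")
    residues = np.array(sorted(topology.sidechain_atoms), dtype=int)
    counts = np.zeros((residues.size, N_CATEGORIES), dtype=np.int64)
    glycine_proxy: set[int] = set()

    for frame in frames:
        is_bb = np.isin(frame.atom_names, list(BACKBONE_NAMES)) \
            & (frame.categories == int(Category.PROTEIN))
        box_xy_z = frame.box
        tree = cKDTree(np.mod(frame.coords, box_xy_z), boxsize=box_xy_z)
        for ri, res in enumerate(residues):
            sc = topology.sidechain_atoms[int(res)]
            if sc.size == 1 and frame.atom_names[sc[0]] == "CA":
                glycine_proxy.add(int(res))
            near: set[int] = set()
            for lst in tree.query_ball_point(
                    np.mod(frame.coords[sc], box_xy_z), r=cutoff):
                near.update(lst)
            own = np.flatnonzero(frame.residue_index == res)
            near.difference_update(own.tolist())
            for j in near:
                cat = int(frame.categories[j])
                if cat == int(Category.ION):
                    continue
                if cat == int(Category.PROTEIN) and is_bb[j] and \
                        abs(int(frame.residue_index[j]) - int(res)) <= exclude_backbone_within:
                    continue
                counts[ri, _CAT_POS[cat]] += 1
    return PropensityProfile(residues=residues, counts=counts,
                             n_frames=len(frames),
                             glycine_proxy=glycine_proxy)


def propensity_difference(a: PropensityProfile, b: PropensityProfile,
                          alignment: PairAlignment,
                          return_skipped: bool = False):
    """Mean Euclidean distance between aligned residues' fraction vectors.

    Aligned pairs where either residue carries the NO_CONTACT flag are
    skipped (and reported when ``return_skipped``).  The metric is
    symmetric under swapping the profiles with the reversed alignment.
    """
    if not alignment.pairs:
        raise ValueError("alignment maps no residue pairs")
    fa, fb = a.fractions, b.fractions
    nca, ncb = a.no_contact, b.no_contact
    dists = []
    skipped: list[tuple[int, int]] = []
    for pa, pb in alignment.pairs:
        ia = int(np.searchsorted(a.residues, pa))
        ib = int(np.searchsorted(b.residues, pb))
        if ia >= a.residues.size or a.residues[ia] != pa:
            raise KeyError(f"aligned residue {pa} missing from first profile")
        if ib >= b.residues.size or b.residues[ib] != pb:
            raise KeyError(f"aligned residue {pb} missing from second profile")
        if nca[ia] or ncb[ib]:
            skipped.append((pa, pb))
            continue
        dists.append(float(np.linalg.norm(fa[ia] - fb[ib])))
    if not dists:
        raise ValueError("every aligned pair was NO_CONTACT")
    value = float(np.mean(dists))
    if return_skipped:
        return value, skipped
    return value


def self_alignment(profile: PropensityProfile) -> PairAlignment:
    """Identity alignment of a profile's residues onto themselves."""
    n = profile.residues.size
    seq = "X" * n
    return PairAlignment(seq_a=seq, seq_b=seq,
                         pairs=[(int(r), int(r)) for r in profile.residues])


def difference_matrix(profiles: dict[str, PropensityProfile],
                      alignments: dict[tuple[str, str], PairAlignment],
                      ) -> pd.DataFrame:
    """Symmetric pairwise difference matrix over a set of systems.

    Diagonal entries use the identity self-alignment and are exactly 0.
    """
    names = sorted(profiles)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for x in names:
        mat.loc[x, x] = propensity_difference(
            profiles[x], profiles[x], self_alignment(profiles[x]))
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            if (x, y) in alignments:
                d = propensity_difference(profiles[x], profiles[y],
                                          alignments[(x, y)])
            elif (y, x) in alignments:
                d = propensity_difference(profiles[y], profiles[x],
                                          alignments[(y, x)])
            else:
                raise KeyError(f"no alignment for pair ({x}, {y})")
            mat.loc[x, y] = mat.loc[y, x] = d
    return mat
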
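"""Shared data model: frames, topology annotations, alignments.

A :class:`Frame` is one time point: coordinates plus per-atom metadata and
the orthorhombic box.  Metadata arrays are shared by reference between the
frames of one trajectory, so a frame list is cheap.  A :class:`Topology`
carries the static structural annotations the analyses need — strand
assignments, the lateral-gate residue pair, side-chain membership, POTRA
ranges, and hydrogen-bond donor/acceptor lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .categories import Category

BACKBONE_NAMES = {"N", "CA", "C", "O", "HN", "H", "HA", "OXT", "HA1", "HA2"}


@dataclass
class Frame:
    """Atoms of one trajectory frame.

    coords are in Å; ``box`` holds three orthorhombic edge lengths (Å).
    ``categories`` is an integer array of :class:`~barrelmetrics.categories.Category`.
    """

    coords: np.ndarray
    box: np.ndarray
    atom_ids: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    residue_index: np.ndarray
    residue_names: np.ndarray
    segids: np.ndarray
    categories: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def select_category(self, cat: Category) -> np.ndarray:
        """Indices of atoms in one category."""
        return np.flatnonzero(self.categories == int(cat))

    def replace_coords(self, coords: np.ndarray, box: np.ndarray | None = None
                       ) -> "Frame":
        """New frame sharing metadata arrays with updated coordinates."""
        return Frame(
            coords=np.asarray(coords, float),
            box=self.box if box is None else np.asarray(box, float),
            atom_ids=self.atom_ids,
            atom_names=self.atom_names,
            elements=self.elements,
            residue_index=self.residue_index,
            residue_names=self.residue_names,
            segids=self.segids,
            categories=self.categories,
        )


@dataclass
class Topology:
    """Structural annotations shared by all frames of one system."""

    n_atoms: int
    #: strand index (1-based) -> sorted array of residue indices
    strands: dict[int, np.ndarray] = field(default_factory=dict)
    #: residue index -> one of "strand", "loop", "turn", "periplasmic"
    residue_class: dict[int, str] = field(default_factory=dict)
    #: lateral gate: (residue on β1, residue on β16)
    gate_pair: tuple[int, int] | None = None
    #: alternative β16-side partners for register-shift detection
    sliding_partners: tuple[int, ...] = ()
    #: residue index -> atom indices of its side chain
    sidechain_atoms: dict[int, np.ndarray] = field(default_factory=dict)
    #: POTRA domain name -> array of residue indices
    potra_domains: dict[str, np.ndarray] = field(default_factory=dict)
    #: hydrogen-bond donors as (heavy-atom index, bonded-H index) pairs
    hbond_donors: list[tuple[int, int]] = field(default_factory=list)
    #: hydrogen-bond acceptor atom indices
    hbond_acceptors: list[int] = field(default_factory=list)
    #: indices of barrel backbone atoms (defines the barrel axis)
    barrel_backbone: np.ndarray | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for s, residues in self.strands.items():
            residues = np.asarray(residues)
            overlap = seen.intersection(residues.tolist())
            if overlap:
                raise ValueError(f"strand {s} overlaps residues {sorted(overlap)}")
            seen.update(residues.tolist())
            self.strands[s] = residues

    def strand_of(self, residue: int) -> int | None:
        for s, residues in self.strands.items():
            if residue in residues:
                return s
        return None


@dataclass
class PairAlignment:
    """A pairwise alignment: gapped sequences plus the residue-pair map.

    ``pairs`` maps 1-based ungapped residue positions of sequence A to those
    of sequence B, skipping every column with a gap in either sequence.
    """

    seq_a: str
    seq_b: str
    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")

    @classmethod
    def from_gapped(cls, seq_a: str, seq_b: str, gap: str = "-") -> "PairAlignment":
        if len(seq_a) != len(seq_b):
            raise ValueError("aligned sequences must have equal length")
        pairs = []
        ia = ib = 0
        for ca, cb in zip(seq_a, seq_b):
            if ca != gap:
                ia += 1
            if cb != gap:
                ib += 1
            if ca != gap and cb != gap:
                pairs.append((ia, ib))
        return cls(seq_a=seq_a, seq_b=seq_b, pairs=pairs)

    @classmethod
    def identity(cls, n: int) -> "PairAlignment":
        seq = "X" * n
        return cls(seq_a=seq, seq_b=seq, pairs=[(i, i) for i in range(1, n + 1)])

    def reversed(self) -> "PairAlignment":
        return PairAlignment(
            seq_a=self.seq_b, seq_b=self.seq_a,
            pairs=[(j, i) for i, j in self.pairs],
        )


def backbone_mask(frame: Frame) -> np.ndarray:
    """Boolean mask of protein-backbone atoms (by atom name)."""
    is_protein = frame.categories == int(Category.PROTEIN)
    is_bb = np.isin(frame.atom_names, list(BACKBONE_NAMES))
    return is_protein & is_bb
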
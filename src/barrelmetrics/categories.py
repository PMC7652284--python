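"""Molecular category assignment.

Every atom in a frame belongs to one of eight categories (water, LPS core
sugars, lipid A head/tail, phospholipid head/tail, protein, ion).  The
interaction census uses seven of them (ions are excluded from totals).
Assignment is a pure function of (residue name, atom name) given a mapping
table; the default table covers common CHARMM residue names for outer-membrane
systems plus the pseudo-residues emitted by the synthetic generators, and is
user-editable through the run configuration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import IntEnum


class Category(IntEnum):
    WATER = 0
    LPS_CORE = 1
    LIPIDA_HEAD = 2
    LIPIDA_TAIL = 3
    PL_HEAD = 4
    PL_TAIL = 5
    PROTEIN = 6
    ION = 7


#: Category order used for propensity vectors (ions carry no propensity).
PROPENSITY_CATEGORIES: tuple[Category, ...] = (
    Category.WATER,
    Category.LPS_CORE,
    Category.LIPIDA_HEAD,
    Category.LIPIDA_TAIL,
    Category.PL_TAIL,
    Category.PL_HEAD,
    Category.PROTEIN,
)

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}

_WATERS = {"TIP3", "TIP3P", "HOH", "WAT", "SOL", "SPC", "TIP4"}

_IONS = {"K", "CL", "NA", "MG", "CA", "POT", "CLA", "SOD", "MGA", "CAL", "ZN"}

# CHARMM-style phospholipid residue names (PE/PG/PC/cardiolipin families).
_PHOSPHOLIPIDS = {
    "POPE", "POPG", "POPC", "PPPE", "PVPG", "PMPE", "PMPG", "DPPE", "DPPG",
    "PYPE", "PYPG", "YOPE", "QMPE", "PVCL2", "TYCL2", "PMCL1", "LIP",
}

_LIPID_A = {"LIPA", "KLA", "ELIPA", "HLIPA", "NLIPA", "BLIPA"}

# LPS inner/outer-core saccharide residue names (Kdo, heptoses, hexoses...).
_LPS_CORE = {
    "KDO", "HEP", "GLA", "GLC", "GAL", "HEX", "LKDO", "LHEP", "LGLC",
    "AGAL", "BGAL", "AGLC", "BGLC", "PEA", "GALN", "GLCN", "CORE",
}

# Acyl-chain atoms in CHARMM lipids: carbons C2x/C3x (x >= 2) and their
# hydrogens; for lipid A also C1'..C6' chain naming with primes stripped.
_TAIL_ATOM = re.compile(r"^(C[2-6]\d{1,2}|H\d+[RSTXYZ]?|CB)$")


@dataclass
class CategoryTable:
    """Residue-name → category map with atom-name tail overrides for lipids.

    ``tail_pattern`` decides, inside a lipid residue, which atoms belong to
    the hydrophobic tails; everything else in that residue is head-group.
    """

    residue_map: dict[str, Category] = field(default_factory=dict)
    phospholipids: set[str] = field(default_factory=lambda: set(_PHOSPHOLIPIDS))
    lipid_a: set[str] = field(default_factory=lambda: set(_LIPID_A))
    tail_pattern: str = _TAIL_ATOM.pattern

    def __post_init__(self) -> None:
        if not self.residue_map:
            m: dict[str, Category] = {}
            for r in _WATERS:
                m[r] = Category.WATER
            for r in _IONS:
                m[r] = Category.ION
            for r in _AMINO_ACIDS:
                m[r] = Category.PROTEIN
            for r in _LPS_CORE:
                m[r] = Category.LPS_CORE
            self.residue_map = m
        self._tail_re = re.compile(self.tail_pattern)

    def assign(self, residue_name: str, atom_name: str) -> Category:
        """Category of one atom; raises ``KeyError`` for unknown residues."""
        rn = residue_name.strip().upper()
        an = atom_name.strip().upper()
        if rn in self.phospholipids:
            return Category.PL_TAIL if self._tail_re.match(an) else Category.PL_HEAD
        if rn in self.lipid_a:
            return (
                Category.LIPIDA_TAIL if self._tail_re.match(an) else Category.LIPIDA_HEAD
            )
        try:
            return self.residue_map[rn]
        except KeyError:
            raise KeyError(
                f"residue name {residue_name!r} has no category mapping; "
                "add it to the category table in the config"
            ) from None


DEFAULT_CATEGORY_TABLE = CategoryTable()
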
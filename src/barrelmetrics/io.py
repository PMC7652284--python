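"""Readers and writers: PDB structures, trajectories, alignments, tables.

Structures are read with MDAnalysis (one :class:`Frame` per MODEL record).
Trajectories come either from a standard binary format (DCD, via MDAnalysis)
or from the plain-text CSV dialect ``frame,atom_id,x,y,z`` (Å) that the
synthetic generators write.  Pairwise alignments are aligned-FASTA with
exactly two records.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .categories import CategoryTable, DEFAULT_CATEGORY_TABLE
from .model import BACKBONE_NAMES, Frame, PairAlignment, Topology

#: padding added around the coordinate extent when a PDB has no CRYST1 record,
#: making minimum-image corrections a no-op for non-periodic structures
_NONPERIODIC_PAD = 500.0


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "X"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    return name[:1].upper()


def read_structure(path: str | Path,
                   table: CategoryTable = DEFAULT_CATEGORY_TABLE,
                   ) -> tuple[Topology, list[Frame]]:
    """Read a PDB file into a topology and one frame per MODEL.

    Atoms are categorised through ``table``; any residue name the table does
    not know raises a ``KeyError`` naming every offender.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = u.atoms
    names = np.array([n.strip() for n in atoms.names])
    resnames = np.array([r.strip() for r in atoms.resnames])
    resids = np.asarray(atoms.resids, dtype=int)
    try:
        segids = np.array([s.strip() for s in atoms.segids])
    except Exception:
        segids = np.array([""] * len(atoms))
    try:
        elements = np.array([e.strip() or _guess_element(n)
                             for e, n in zip(atoms.elements, names)])
    except Exception:
        elements = np.array([_guess_element(n) for n in names])

    categories = np.empty(len(atoms), dtype=np.int8)
    unknown: set[str] = set()
    for i, (rn, an) in enumerate(zip(resnames, names)):
        try:
            categories[i] = int(table.assign(rn, an))
        except KeyError:
            unknown.add(rn)
    if unknown:
        raise KeyError(
            "no category mapping for residue name(s): "
            + ", ".join(sorted(unknown))
        )

    frames: list[Frame] = []
    for ts in u.trajectory:
        dims = ts.dimensions
        if dims is None or np.any(np.asarray(dims[:3]) <= 0):
            lo = ts.positions.min(axis=0)
            hi = ts.positions.max(axis=0)
            box = (hi - lo) + _NONPERIODIC_PAD
        else:
            box = np.asarray(dims[:3], dtype=float)
        frames.append(Frame(
            coords=ts.positions.astype(float).copy(),
            box=box,
            atom_ids=np.arange(1, len(atoms) + 1),
            atom_names=names,
            elements=elements,
            residue_index=resids,
            residue_names=resnames,
            segids=segids,
            categories=categories,
        ))

    topology = topology_from_frame(frames[0])
    return topology, frames


def topology_from_frame(frame: Frame) -> Topology:
    """Minimal topology: side-chain membership and backbone atom indices.

    Strand/loop assignments, the gate pair and donor/acceptor lists are
    structure-specific and are applied afterwards from the run config.
    """
    from .categories import Category

    sidechains: dict[int, np.ndarray] = {}
    is_protein = frame.categories == int(Category.PROTEIN)
    is_bb = np.isin(frame.atom_names, list(BACKBONE_NAMES))
    for res in np.unique(frame.residue_index[is_protein]):
        in_res = is_protein & (frame.residue_index == res)
        sc = np.flatnonzero(in_res & ~is_bb)
        if sc.size == 0:  # glycine: α-carbon stands in, flagged downstream
            sc = np.flatnonzero(in_res & (frame.atom_names == "CA"))
        sidechains[int(res)] = sc
    return Topology(
        n_atoms=frame.n_atoms,
        sidechain_atoms=sidechains,
        barrel_backbone=np.flatnonzero(is_protein & is_bb),
    )


def write_trajectory_csv(frames: list[Frame], path: str | Path) -> None:
    """Write frames in the plain-text dialect ``frame,atom_id,x,y,z``."""
    rows = []
    for f_idx, fr in enumerate(frames):
        rows.append(pd.DataFrame({
            "frame": f_idx,
            "atom_id": fr.atom_ids,
            "x": fr.coords[:, 0],
            "y": fr.coords[:, 1],
            "z": fr.coords[:, 2],
        }))
    pd.concat(rows).to_csv(path, index=False, float_format="%.4f")


def read_trajectory(topology: Topology, path: str | Path,
                    template: Frame) -> list[Frame]:
    """Read a trajectory (CSV dialect or DCD) against a known topology.

    ``template`` supplies the per-atom metadata (and the box, for formats
    that do not carry one); a frame whose atom count disagrees with the
    topology is an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_trajectory_csv(topology, path, template)
    return _read_trajectory_mda(topology, path, template)


def _read_trajectory_csv(topology: Topology, path: Path,
                         template: Frame) -> list[Frame]:
    df = pd.read_csv(path)
    required = {"frame", "atom_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    frames = []
    for f_idx, grp in df.groupby("frame", sort=True):
        if len(grp) != topology.n_atoms:
            raise ValueError(
                f"frame {f_idx}: {len(grp)} atoms, topology has "
                f"{topology.n_atoms}"
            )
        grp = grp.sort_values("atom_id")
        frames.append(template.replace_coords(grp[["x", "y", "z"]].to_numpy()))
    if not frames:
        raise ValueError(f"no frames in {path}")
    return frames


def _read_trajectory_mda(topology: Topology, path: Path,
                         template: Frame) -> list[Frame]:
    import MDAnalysis as mda

    reader = mda.coordinates.core.reader(str(path), n_atoms=topology.n_atoms)
    if reader.n_atoms != topology.n_atoms:
        raise ValueError(
            f"trajectory has {reader.n_atoms} atoms, topology has "
            f"{topology.n_atoms}"
        )
    frames = []
    for ts in reader:
        dims = ts.dimensions
        box = None
        if dims is not None and np.all(np.asarray(dims[:3]) > 0):
            box = np.asarray(dims[:3], dtype=float)
        frames.append(template.replace_coords(
            ts.positions.astype(float).copy(), box=box))
    return frames


def read_alignment(path: str | Path) -> PairAlignment:
    """Read a pairwise aligned-FASTA file (exactly two records)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 records, found {len(records)}")
    a, b = (str(r.seq) for r in records)
    if len(a) != len(b):
        raise ValueError(
            f"aligned lengths differ: {len(a)} vs {len(b)}"
        )
    return PairAlignment.from_gapped(a, b)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def write_windows(windows, directory: str | Path) -> Path:
    """Write umbrella windows as per-window CSVs plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(windows):
        p = directory / f"window_{i:03d}.csv"
        t = w.time_ns if w.time_ns is not None else np.arange(len(w.samples), dtype=float)
        pd.DataFrame({"time_ns": t, "cv_A": w.samples}).to_csv(p, index=False)
        rows.append({"center": w.center, "force_constant": w.force_constant,
                     "path": p.name})
    manifest = directory / "windows.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_windows(manifest_path: str | Path):
    """Read umbrella windows from a manifest CSV (center, force_constant, path)."""
    from .wham import UmbrellaWindow

    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path)
    windows = []
    for _, row in man.iterrows():
        df = pd.read_csv(manifest_path.parent / row["path"])
        windows.append(UmbrellaWindow(
            center=float(row["center"]),
            force_constant=float(row["force_constant"]),
            samples=df["cv_A"].to_numpy(),
            time_ns=df["time_ns"].to_numpy() if "time_ns" in df else None,
        ))
    return windows
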
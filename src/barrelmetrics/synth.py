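"""Synthetic fixtures with analytically known ground truth.

The multi-microsecond trajectories this package was written to analyse are
not deposited anywhere, so every analysis stage is validated against
generated systems whose answer is known in closed form:

* an asymmetric bilayer of pseudo-lipids whose hydrophobic boundary atoms
  trace a prescribed thickness field t(x, y), optionally with a Gaussian
  thinning defect;
* a pseudo-β-barrel with labelled strands, a lateral-gate residue pair and
  per-residue backbone/side-chain atoms;
* exact Boltzmann samples from harmonically biased umbrella windows over a
  known 1-D potential (inverse-CDF on a fine grid — no Markov chain, so no
  burn-in or autocorrelation to reason about);
* per-residue molecular environments with prescribed category propensities;
* donor–H–acceptor geometries with a known number of valid hydrogen bonds.

Every generator is deterministic given its seed; pseudo-lipids carry exactly
one hydrophobic-boundary atom each, which makes the thickness definition in
the fixtures unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .categories import DEFAULT_CATEGORY_TABLE, Category, PROPENSITY_CATEGORIES
from .model import Frame, Topology
from .wham import KB_KCAL, UmbrellaWindow


# --------------------------------------------------------------------------
# bilayer

@dataclass
class GaussianDefect:
    """Localised thinning: depth·exp(−((x−cx)²+(y−cy)²)/(2σ²))."""

    center: tuple[float, float] = (0.0, 0.0)
    depth: float = 12.0       # Å
    sigma: float = 8.0        # Å

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("defect depth must be >= 0")
        if self.sigma <= 0:
            raise ValueError("defect sigma must be > 0")

    def thinning(self, xy: np.ndarray) -> np.ndarray:
        d = np.asarray(xy, float) - np.asarray(self.center)
        r2 = np.sum(d * d, axis=-1)
        return self.depth * np.exp(-r2 / (2.0 * self.sigma**2))

    def level_set_area(self, base_thickness: float, threshold: float) -> float:
        """Analytic area where base − thinning < threshold (Å²)."""
        drop = base_thickness - threshold
        if drop >= self.depth:
            return 0.0
        if drop <= 0:
            return float("inf")
        return float(np.pi * self.sigma**2 * 2.0 * np.log(self.depth / drop))


@dataclass
class BilayerSpec:
    """Pseudo-bilayer: a lattice of hydrophobic-boundary marker atoms.

    The markers sample the thickness field t(x, y); they are not a packing
    model.  The default density of 1/15 markers/Å² (≈3.9 Å spacing) keeps
    thickness features of σ ≳ 8 Å resolvable by the interpolating
    analyses; real per-acyl-chain packing (~1/30 Å²) would undersample
    them.
    """

    base_thickness: float = 30.0        # Å
    areal_density: float = 1.0 / 15.0   # boundary atoms per Å² per leaflet
    box_xy: tuple[float, float] = (100.0, 100.0)
    defect: GaussianDefect | None = None
    noise_std: float = 0.5              # Å, out-of-plane positional noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_thickness <= 0:
            raise ValueError("base thickness must be > 0")

    def thickness_field(self, xy: np.ndarray) -> np.ndarray:
        t = np.full(np.asarray(xy).shape[:-1], self.base_thickness)
        if self.defect is not None:
            t = t - self.defect.thinning(xy)
        return t


def gen_bilayer(spec: BilayerSpec, n_frames: int = 1) -> tuple[Topology, list[Frame]]:
    """Two leaflets of boundary atoms at z = ±t(x,y)/2 + noise.

    Outer-leaflet pseudo-residues are named LIPA (lipid A tails), inner
    ones LIP (phospholipid tails), matching the asymmetric outer membrane.
    The membrane midplane sits at z = 0.
    """
    lx, ly = spec.box_xy
    spacing = 1.0 / np.sqrt(spec.areal_density)
    nx, ny = int(lx // spacing), int(ly // spacing)
    if nx < 1 or ny < 1:
        raise ValueError("box too small to hold a single lipid")
    xs = (np.arange(nx) + 0.5) * (lx / nx)
    ys = (np.arange(ny) + 0.5) * (ly / ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    n_per_leaflet = xy.shape[0]
    half_t = spec.thickness_field(xy) / 2.0

    n_atoms = 2 * n_per_leaflet
    box = np.array([lx, ly, 4.0 * spec.base_thickness])
    names = np.full(n_atoms, "CB")
    resnames = np.array(["LIPA"] * n_per_leaflet + ["LIP"] * n_per_leaflet)
    cats = np.array(
        [int(DEFAULT_CATEGORY_TABLE.assign(r, "CB")) for r in resnames],
        dtype=np.int8,
    )
    meta = dict(
        atom_ids=np.arange(1, n_atoms + 1),
        atom_names=names,
        elements=np.full(n_atoms, "C"),
        residue_index=np.arange(1, n_atoms + 1),
        residue_names=resnames,
        segids=np.array(["OUT"] * n_per_leaflet + ["INN"] * n_per_leaflet),
        categories=cats,
    )

    rng = np.random.default_rng(spec.seed)
    frames = []
    for _ in range(n_frames):
        z_out = half_t + rng.normal(0.0, spec.noise_std, n_per_leaflet) \
            if spec.noise_std > 0 else half_t.copy()
        z_in = -half_t + rng.normal(0.0, spec.noise_std, n_per_leaflet) \
            if spec.noise_std > 0 else -half_t.copy()
        coords = np.vstack([
            np.column_stack([xy, z_out]),
            np.column_stack([xy, z_in]),
        ])
        frames.append(Frame(coords=coords, box=box, **meta))
    topology = Topology(n_atoms=n_atoms)
    return topology, frames


# --------------------------------------------------------------------------
# barrel

def gen_barrel(n_strands: int = 16, radius: float = 13.0, height: float = 30.0,
               seed: int = 0, residues_per_strand: int = 6,
               placement_noise: float = 0.3) -> tuple[Topology, Frame]:
    """Pseudo-β-barrel: strands of residues on a cylinder about the z axis.

    Strand k is centred at azimuth 2πk/n_strands; each residue carries a
    backbone N (with bonded HN), a backbone O, and a CB side-chain atom
    pointing outward.  The lateral-gate pair is the mid-height residue of
    strand 1 and of strand n_strands; that residue's strand-n neighbours
    are registered as sliding partners.  Backbone N–H donors and O
    acceptors of the two gate strands populate the H-bond lists.
    """
    if n_strands < 2:
        raise ValueError("need at least 2 strands")
    rng = np.random.default_rng(seed)
    coords, names, elements, resindex, resnames = [], [], [], [], []
    strands: dict[int, list[int]] = {}
    residue_class: dict[int, str] = {}
    sidechain: dict[int, np.ndarray] = {}
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    res = 0
    atom = 0
    zs = np.linspace(-height / 2.0, height / 2.0, residues_per_strand)
    for k in range(1, n_strands + 1):
        phi = 2.0 * np.pi * k / n_strands
        strands[k] = []
        for z in zs:
            res += 1
            strands[k].append(res)
            residue_class[res] = "strand"
            base = np.array([radius * np.cos(phi), radius * np.sin(phi), z])
            outward = np.array([np.cos(phi), np.sin(phi), 0.0])
            inward = -outward
            n_pos = base + rng.normal(0, placement_noise, 3)
            h_pos = n_pos + 1.0 * inward
            o_pos = base + np.array([0, 0, 1.2]) + rng.normal(0, placement_noise, 3)
            cb_pos = base + 1.5 * outward
            for pos, nm, el in ((n_pos, "N", "N"), (h_pos, "HN", "H"),
                                (o_pos, "O", "O"), (cb_pos, "CB", "C")):
                coords.append(pos)
                names.append(nm)
                elements.append(el)
                resindex.append(res)
                resnames.append("ALA")
            sidechain[res] = np.array([atom + 3])
            if k in (1, n_strands):
                donors.append((atom, atom + 1))
                acceptors.append(atom + 2)
            atom += 4

    coords = np.asarray(coords)
    n_atoms = coords.shape[0]
    box = np.array([4 * radius + 60.0, 4 * radius + 60.0, height + 60.0])
    # recentre so the periodic box holds the barrel comfortably;
    # the xy centroid stays at the origin by construction
    frame = Frame(
        coords=coords,
        box=box,
        atom_ids=np.arange(1, n_atoms + 1),
        atom_names=np.array(names),
        elements=np.array(elements),
        residue_index=np.array(resindex),
        residue_names=np.array(resnames),
        segids=np.full(n_atoms, "BRL"),
        categories=np.full(n_atoms, int(Category.PROTEIN), dtype=np.int8),
    )
    mid = residues_per_strand // 2
    gate_a = strands[1][mid]
    gate_b = strands[n_strands][mid]
    partners = tuple(r for r in (gate_b - 1, gate_b + 1)
                     if r in strands[n_strands])
    bb = np.flatnonzero(np.isin(frame.atom_names, ["N", "O"]))
    topology = Topology(
        n_atoms=n_atoms,
        strands={k: np.array(v) for k, v in strands.items()},
        residue_class=residue_class,
        gate_pair=(gate_a, gate_b),
        sliding_partners=partners,
        sidechain_atoms=sidechain,
        hbond_donors=donors,
        hbond_acceptors=acceptors,
        barrel_backbone=bb,
    )
    return topology, frame


def embed_barrel_in_bilayer(barrel_top: Topology, barrel_frame: Frame,
                            bilayer_top: Topology, bilayer_frames: list[Frame],
                            clearance: float = 2.0,
                            ) -> tuple[Topology, list[Frame]]:
    """Place a pseudo-barrel through a pseudo-bilayer.

    The barrel (built about the origin) is moved to the bilayer box centre;
    bilayer atoms within ``clearance`` Å (xy) of any barrel atom are removed
    so lipids never occupy the protein footprint.  Residue indices of the
    bilayer are offset by 10000 to stay clear of the protein's.
    """
    box = np.array([bilayer_frames[0].box[0], bilayer_frames[0].box[1],
                    max(bilayer_frames[0].box[2], barrel_frame.box[2])])
    center = np.array([box[0] / 2.0, box[1] / 2.0, 0.0])
    prot_xy = barrel_frame.coords[:, :2] + center[:2]

    from scipy.spatial import cKDTree
    keep_cache: np.ndarray | None = None
    frames_out = []
    res_offset = 10000
    for bf in bilayer_frames:
        if keep_cache is None:
            tree = cKDTree(prot_xy)
            d, _ = tree.query(bf.coords[:, :2], k=1)
            keep_cache = d > clearance
        keep = keep_cache
        coords = np.vstack([barrel_frame.coords + center, bf.coords[keep]])
        frames_out.append(Frame(
            coords=coords,
            box=box,
            atom_ids=np.arange(1, coords.shape[0] + 1),
            atom_names=np.concatenate([barrel_frame.atom_names,
                                       bf.atom_names[keep]]),
            elements=np.concatenate([barrel_frame.elements,
                                     bf.elements[keep]]),
            residue_index=np.concatenate(
                [barrel_frame.residue_index,
                 bf.residue_index[keep] + res_offset]),
            residue_names=np.concatenate([barrel_frame.residue_names,
                                          bf.residue_names[keep]]),
            segids=np.concatenate([barrel_frame.segids, bf.segids[keep]]),
            categories=np.concatenate([barrel_frame.categories,
                                       bf.categories[keep]]),
        ))
    topology = Topology(
        n_atoms=frames_out[0].n_atoms,
        strands=barrel_top.strands,
        residue_class=barrel_top.residue_class,
        gate_pair=barrel_top.gate_pair,
        sliding_partners=barrel_top.sliding_partners,
        sidechain_atoms=barrel_top.sidechain_atoms,
        potra_domains=barrel_top.potra_domains,
        hbond_donors=barrel_top.hbond_donors,
        hbond_acceptors=barrel_top.hbond_acceptors,
        barrel_backbone=barrel_top.barrel_backbone,
    )
    return topology, frames_out


# --------------------------------------------------------------------------
# umbrella sampling

@dataclass
class TruePotentialSpec:
    """A known 1-D potential U(x) (kcal/mol over Å) at a temperature."""

    u: Callable[[np.ndarray], np.ndarray]
    x_min: float
    x_max: float
    temperature: float = 310.0

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature


def double_well(barrier: float = 2.5, center: float = 7.0,
                half_separation: float = 3.0,
                x_range: tuple[float, float] = (2.0, 12.0),
                temperature: float = 310.0) -> TruePotentialSpec:
    """Quartic double well U = barrier·(((x−c)/a)² − 1)², wells at c ± a."""

    def u(x: np.ndarray) -> np.ndarray:
        y = (np.asarray(x, float) - center) / half_separation
        return barrier * (y * y - 1.0) ** 2

    return TruePotentialSpec(u=u, x_min=x_range[0], x_max=x_range[1],
                             temperature=temperature)


def gen_umbrella_samples(true: TruePotentialSpec,
                         centers: Sequence[float],
                         force_constants: Sequence[float],
                         n_per_window: int = 5000,
                         seed: int = 0,
                         grid_step: float = 0.005) -> list[UmbrellaWindow]:
    """Exact samples from each biased density by inverse-CDF on a fine grid.

    Window i draws from p_i(x) ∝ exp(−[U(x) + ½k_i(x−c_i)²]/k_BT) on
    [x_min, x_max].  Per-window RNG streams are derived from the seed, so
    the sample set is bit-reproducible and windows are independent.
    """
    centers = list(centers)
    force_constants = list(force_constants)
    if len(centers) != len(force_constants):
        raise ValueError("need one force constant per center")
    if n_per_window < 1:
        raise ValueError("n_per_window must be >= 1")
    grid = np.arange(true.x_min, true.x_max + grid_step / 2, grid_step)
    u_grid = np.asarray(true.u(grid), dtype=float)
    if not np.all(np.isfinite(u_grid)):
        raise ValueError("potential diverges on the sampling domain")
    windows = []
    for i, (c, k) in enumerate(zip(centers, force_constants)):
        energy = u_grid + 0.5 * k * (grid - c) ** 2
        dens = np.exp(-(energy - energy.min()) / true.kT)
        cdf = cumulative_trapezoid(dens, grid, initial=0.0)
        if cdf[-1] <= 0 or not np.isfinite(cdf[-1]):
            raise ValueError("biased density is not integrable")
        cdf /= cdf[-1]
        rng = np.random.default_rng([seed, i])
        samples = np.interp(rng.random(n_per_window), cdf, grid)
        windows.append(UmbrellaWindow(
            center=float(c), force_constant=float(k), samples=samples,
            time_ns=0.01 * np.arange(n_per_window),
        ))
    return windows


def reus_window_layout(n_windows: int = 18,
                       x_range: tuple[float, float] = (2.0, 12.0),
                       force_constant: float = 20.0,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced window centers over the gate-opening range with a
    uniform force constant (kcal/mol/Å²)."""
    centers = np.linspace(x_range[0], x_range[1], n_windows)
    return centers, np.full(n_windows, force_constant)


# --------------------------------------------------------------------------
# contact environments

_NEIGHBOR_ATOM = {
    Category.WATER: ("TIP3", "OH2", "O"),
    Category.LPS_CORE: ("KDO", "C1", "C"),
    Category.LIPIDA_HEAD: ("LIPA", "C1", "C"),
    Category.LIPIDA_TAIL: ("LIPA", "C22", "C"),
    Category.PL_HEAD: ("LIP", "P", "P"),
    Category.PL_TAIL: ("LIP", "C22", "C"),
    Category.PROTEIN: ("ALA", "CB", "C"),
}


def gen_contact_frames(target_profile: dict[int, np.ndarray],
                       n_frames: int, seed: int = 0,
                       neighbors_per_residue: int = 20,
                       ) -> tuple[Topology, list[Frame]]:
    """Probe residues surrounded by category-labelled neighbour atoms.

    ``target_profile`` maps residue index (1-based, consecutive) to a
    7-vector of category fractions in the census order (water, LPS core,
    lipid A head, lipid A tail, PL tail, PL head, protein).  Each frame
    places ``neighbors_per_residue`` atoms uniformly on shells 2.2–3.8 Å
    from the residue's side-chain atom, with categories drawn from a
    multinomial on the target fractions.  Probe residues sit on a 40 Å
    grid so environments never overlap.
    """
    residues = sorted(target_profile)
    for r, frac in target_profile.items():
        frac = np.asarray(frac, float)
        if frac.shape != (7,) or not np.isclose(frac.sum(), 1.0):
            raise ValueError(f"residue {r}: fractions must be 7 values summing to 1")
    n_res = len(residues)
    spacing = 40.0
    side = int(np.ceil(np.sqrt(n_res)))
    box = np.array([side * spacing, side * spacing, spacing])
    probe_xyz = np.array([
        [(i % side + 0.5) * spacing, (i // side + 0.5) * spacing, spacing / 2]
        for i in range(n_res)
    ])

    # atoms: per residue a backbone N and a CB side chain, then neighbours
    n_atoms = n_res * 2 + n_res * neighbors_per_residue
    sidechain = {}
    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n_frames):
        coords, names, elements, resindex, resnames, cats = [], [], [], [], [], []
        for i, r in enumerate(residues):
            coords += [probe_xyz[i] + np.array([0, 0, 1.5]), probe_xyz[i]]
            names += ["N", "CB"]
            elements += ["N", "C"]
            resindex += [r, r]
            resnames += ["ALA", "ALA"]
            cats += [int(Category.PROTEIN)] * 2
            sidechain[r] = np.array([2 * i + 1])
        neighbor_res = 1000  # far from probes in sequence: ±2 rule inert
        for i, r in enumerate(residues):
            frac = np.asarray(target_profile[r], float)
            counts = rng.multinomial(neighbors_per_residue, frac)
            for cat_pos, cnt in enumerate(counts):
                cat = PROPENSITY_CATEGORIES[cat_pos]
                resname, aname, el = _NEIGHBOR_ATOM[cat]
                for _ in range(cnt):
                    v = rng.normal(size=3)
                    v /= np.linalg.norm(v)
                    d = rng.uniform(2.2, 3.8)
                    neighbor_res += 1
                    coords.append(probe_xyz[i] + d * v)
                    names.append(aname)
                    elements.append(el)
                    resindex.append(neighbor_res)
                    resnames.append(resname)
                    cats.append(int(cat))
        frames.append(Frame(
            coords=np.asarray(coords),
            box=box,
            atom_ids=np.arange(1, n_atoms + 1),
            atom_names=np.array(names),
            elements=np.array(elements),
            residue_index=np.array(resindex),
            residue_names=np.array(resnames),
            segids=np.full(n_atoms, "SYN"),
            categories=np.array(cats, dtype=np.int8),
        ))
    topology = Topology(n_atoms=n_atoms, sidechain_atoms=sidechain)
    return topology, frames


# --------------------------------------------------------------------------
# hydrogen-bond geometries

def gen_hbond_set(n_valid: int, n_invalid: int, seed: int = 0,
                  cutoff: float = 3.5, angle_tol: float = 30.0,
                  ) -> tuple[Topology, Frame]:
    """Donor–H–acceptor triples with exactly ``n_valid`` true hydrogen bonds.

    Valid triples satisfy D···A ≤ cutoff − 0.1 Å and D–H···A within
    angle_tol − 2° of linear; invalid ones violate at least one criterion
    with the same margins.  Sites sit on a 25 Å grid, so no cross-site pair
    can come near the cutoff.
    """
    if n_valid < 0 or n_invalid < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    n_sites = n_valid + n_invalid
    spacing = 25.0
    side = max(1, int(np.ceil(np.sqrt(max(n_sites, 1)))))
    box = np.array([side * spacing, side * spacing, spacing])

    coords, names, elements, resindex, resnames = [], [], [], [], []
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    for i in range(n_sites):
        origin = np.array([(i % side + 0.5) * spacing,
                           (i // side + 0.5) * spacing, spacing / 2])
        valid = i < n_valid
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        if valid:
            d_da = rng.uniform(2.6, cutoff - 0.1)
            bend_max = angle_tol - 2.0
        elif rng.random() < 0.5:   # distance violation, geometry straight
            d_da = rng.uniform(cutoff + 0.1, 6.0)
            bend_max = angle_tol - 2.0
        else:                      # angle violation at valid distance
            d_da = rng.uniform(2.6, cutoff - 0.1)
            bend_max = None
        d_pos = origin
        a_pos = origin + d_da * u
        h_pos = _place_hydrogen(rng, d_pos, a_pos, bend_max, angle_tol)
        base = len(coords)
        coords += [d_pos, h_pos, a_pos]
        names += ["N", "HN", "O"]
        elements += ["N", "H", "O"]
        resindex += [i + 1] * 3
        resnames += ["ALA"] * 3
        donors.append((base, base + 1))
        acceptors.append(base + 2)

    n_atoms = max(len(coords), 0)
    if n_atoms == 0:
        coords = np.zeros((0, 3))
    frame = Frame(
        coords=np.asarray(coords, float).reshape(-1, 3),
        box=box,
        atom_ids=np.arange(1, n_atoms + 1),
        atom_names=np.array(names, dtype="U4"),
        elements=np.array(elements, dtype="U2"),
        residue_index=np.array(resindex, dtype=int),
        residue_names=np.array(resnames, dtype="U4"),
        segids=np.full(n_atoms, "HBX"),
        categories=np.full(n_atoms, int(Category.PROTEIN), dtype=np.int8),
    )
    topology = Topology(n_atoms=n_atoms, hbond_donors=donors,
                        hbond_acceptors=acceptors)
    return topology, frame


def _place_hydrogen(rng: np.random.Generator, d_pos: np.ndarray,
                    a_pos: np.ndarray, bend_max: float | None,
                    angle_tol: float) -> np.ndarray:
    """Put H at 1.0 Å from D so the D–H···A linearity deviation is below
    ``bend_max`` degrees, or above angle_tol + 2° when ``bend_max`` is None."""
    from .geometry import angle_deg

    u = a_pos - d_pos
    u = u / np.linalg.norm(u)
    # a perpendicular direction for controlled bending
    p = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(p) < 1e-6:
        p = np.cross(u, [0.0, 1.0, 0.0])
    p /= np.linalg.norm(p)
    for _ in range(1000):
        if bend_max is None:
            tilt = np.radians(rng.uniform(60.0, 110.0))
        else:
            tilt = np.radians(rng.uniform(0.0, 0.45 * bend_max))
        direction = np.cos(tilt) * u + np.sin(tilt) * p
        h = d_pos + 1.0 * direction
        deviation = 180.0 - angle_deg(d_pos, h, a_pos)
        if bend_max is not None and deviation <= bend_max:
            return h
        if bend_max is None and deviation >= angle_tol + 2.0:
            return h
    raise RuntimeError("could not place hydrogen with requested geometry")
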
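# barrelmetrics

Trajectory analysis of lateral gating and membrane thinning for
Omp85-family outer-membrane β-barrels (BamA, TamA, and the FhaC control).

## The scientific problem

BamA, the central insertase of the β-barrel assembly machinery (BAM),
folds nascent outer-membrane proteins into the asymmetric LPS/phospholipid
outer membrane. Two mechanistic pictures coexist: a *hybrid-barrel* model,
in which the seam between strands β1 and β16 (the **lateral gate**) opens
and templates the substrate, and a *passive* model, in which the barrel's
narrowed hydrophobic belt locally thins and destabilises the membrane so
substrates can insert into it directly. Testing either picture against
molecular-dynamics trajectories requires a consistent set of geometric and
thermodynamic observables. This package computes them:

- **Hydrophobic thickness maps** — the vertical distance between the
  hydrophobic boundary atoms of the two leaflets, binned on a polar grid
  about the barrel axis, with per-strand sector averages and the *thinned
  area* `A(τ) = ∫ 1[t(x, y) < τ] dx dy` below a threshold (default
  τ = 20 Å).
- **Lateral-gate metrics** — strand separation
  `d = ½(|O_A − N_B| + |N_A − O_B|)` over the gate residue pair; hydrogen
  bonds by the geometric criterion (donor–acceptor ≤ 3.5 Å, D–H···A within
  30° of linear); the umbrella-sampling collective variable, the same two
  displacements projected on the gate-opening direction; and a
  register-state classifier (native / shifted / open) that detects seam
  *sliding* to an alternative β16 partner once the native pair exceeds 8 Å.
- **WHAM free-energy profiles** — the weighted histogram analysis method
  solves `p(x_b) = Σ_i n_ib / Σ_j N_j e^{(f_j − U_j(x_b))/k_BT}` with
  harmonic biases `U_i = ½k_i(x − c_i)²` self-consistently and returns
  `W(x) = −k_BT ln p(x)` (min 0), plus the endpoint convergence rule
  (an added sampling block must move the endpoint by < 0.2 kcal/mol) and
  local-well detection in the 3.5–5.5 Å range.
- **Interaction propensities** — a per-residue census of atoms within 4 Å
  of each side chain across seven molecular categories (water, LPS core,
  lipid A head/tail, PL tail/head, protein), and the cross-protein
  difference metric: the Euclidean distance between aligned residues'
  fraction vectors averaged over a pairwise alignment.
- **Exposure and contact areas** — deterministic Shrake–Rupley SASA
  (Fibonacci point set), per-residue water-exposure fractions binned into
  deciles, and buried-interface areas
  `(SASA(A) + SASA(B) − SASA(A∪B))/2` for POTRA-domain/leaflet contacts.

Because multi-microsecond membrane-protein trajectories are rarely
deposited, the package ships first-class synthetic generators whose ground
truth is analytic: bilayers with a Gaussian thinning defect of known
level-set area, pseudo-barrels with labelled strands, exact inverse-CDF
Boltzmann samples from biased umbrella windows, prescribed contact
environments, and hydrogen-bond geometries with a known valid count.

## Worked example

```python
import numpy as np
from barrelmetrics.synth import (BilayerSpec, GaussianDefect, double_well,
                                 gen_bilayer, gen_umbrella_samples,
                                 reus_window_layout)
from barrelmetrics.thickness import thinned_area
from barrelmetrics.wham import wham_pmf, locate_well

# a 30 Å bilayer with a Gaussian thinning defect (depth 12 Å, σ = 8 Å)
defect = GaussianDefect(center=(50.0, 50.0), depth=12.0, sigma=8.0)
spec = BilayerSpec(base_thickness=30.0, noise_std=0.0, seed=0, defect=defect)
top, frames = gen_bilayer(spec)
res = thinned_area(frames, top, threshold=20.0, cell=1.0)
print(f"thinned area: {res.area:.1f} A^2 "
      f"(analytic {defect.level_set_area(30.0, 20.0):.1f} A^2)")

# WHAM reconstruction of a known double-well gate-opening potential
true = double_well()
centers, ks = reus_window_layout(18)
windows = gen_umbrella_samples(true, centers, ks, n_per_window=5000, seed=0)
pmf = wham_pmf(windows)
well = locate_well(pmf, (3.0, 5.0))
print(f"WHAM: {pmf.iterations} iterations; "
      f"well at {well[0]:.2f} A, depth {well[1]:.2f} kcal/mol")
```

prints

```
thinned area: 72.0 A^2 (analytic 73.3 A^2)
WHAM: 4368 iterations; well at 4.05 A, depth 2.50 kcal/mol
```

The measured thinned area recovers the closed-form level-set area of the
defect (π·σ²·2·ln(depth/(base − τ)) ≈ 73.3 Å²) to within the 1 Å grid
resolution, and the reconstructed profile finds the true potential's well
(minimum at 4.0 Å, barrier 2.5 kcal/mol) to within one 0.1 Å bin.

The same stages are scriptable from the shell:

```sh
barrelmetrics synth --kind umbrella --out win/
barrelmetrics pmf --windows win/windows.csv --out pmf.csv
barrelmetrics run --config demo.yaml && barrelmetrics summarize --run-dir out/
```

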
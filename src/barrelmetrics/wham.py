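"""Weighted histogram analysis method (WHAM) for umbrella-sampling PMFs.

Umbrella sampling biases the gate-opening collective variable x with
harmonic restraints U_i(x) = ½ k_i (x − c_i)² in a set of windows.  WHAM
combines the biased histograms into one unbiased density p(x) by solving
the self-consistency equations

    p(x_b) = Σ_i n_ib / Σ_j N_j exp[(f_j − U_j(x_b)) / k_B T]
    exp(−f_i / k_B T) = Σ_b p(x_b) exp(−U_i(x_b) / k_B T)

iterated until the window free energies f_i stop moving.  The PMF is
W(x) = −k_B T ln p(x), shifted so its minimum is zero.  Replica-exchange
structure in the source data is ignored: samples are pooled per window.

Defaults follow the simulations being analysed: T = 310 K, bins of 0.1 Å
over the 2–12 Å gate-separation range, convergence when an extra sampling
block changes the PMF endpoint by less than 0.2 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KB_KCAL = 0.0019872041  # kcal/mol/K
DEFAULT_TEMPERATURE = 310.0

_MAX_ITER = 1_000_000


@dataclass
class UmbrellaWindow:
    """One umbrella window: bias parameters and pooled CV samples."""

    center: float            # Å
    force_constant: float    # kcal/mol/Å²
    samples: np.ndarray      # Å
    time_ns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")
        if self.samples.size < 1:
            raise ValueError("window must contain at least one sample")

    def bias(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.force_constant * (np.asarray(x, float) - self.center) ** 2


@dataclass
class PMFProfile:
    """Free-energy profile over the collective variable."""

    bin_centers: np.ndarray
    free_energy: np.ndarray          # kcal/mol, min 0 on populated bins
    counts: np.ndarray               # total samples per bin
    temperature: float
    iterations: int
    converged: bool
    bin_edges: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def populated(self) -> np.ndarray:
        return self.counts > 0

    def endpoint_value(self, other: "PMFProfile | None" = None) -> float:
        """W at the endpoint: the last populated bin (of the common range
        when compared against another profile)."""
        pop = self.populated
        if other is not None:
            pop = pop & other.populated
        idx = np.flatnonzero(pop)
        if idx.size == 0:
            raise ValueError("no common populated bin")
        return float(self.free_energy[idx[-1]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center": self.bin_centers,
            "free_energy_kcal_mol": self.free_energy,
            "counts": self.counts,
        })


def wham_pmf(windows: list[UmbrellaWindow],
             temperature: float = DEFAULT_TEMPERATURE,
             bins: np.ndarray | None = None,
             tol: float = 1e-8) -> PMFProfile:
    """Reconstruct the PMF from umbrella windows by WHAM iteration.

    ``bins`` are histogram edges (default 0.1 Å over 2–12 Å).  ``tol`` is
    the convergence threshold on max|Δf_i| in kcal/mol.  A histogram whose
    populated bins split into disconnected segments is an error — the
    windows do not jointly cover the range and the profile pieces would
    float freely relative to each other.
    """
    if not windows:
        raise ValueError("no umbrella windows")
    if bins is None:
        bins = np.arange(2.0, 12.0 + 1e-9, 0.1)
    bins = np.asarray(bins, dtype=float)
    kT = KB_KCAL * temperature
    centers = 0.5 * (bins[:-1] + bins[1:])
    n_bins = centers.size
    n_win = len(windows)

    hist = np.empty((n_win, n_bins))
    for i, w in enumerate(windows):
        hist[i], _ = np.histogram(w.samples, bins=bins)
    counts = hist.sum(axis=0)
    pop = counts > 0

    seg = np.flatnonzero(pop)
    if seg.size == 0:
        raise ValueError("no sample falls inside the bin range")
    if np.any(np.diff(seg) > 1):
        raise ValueError(
            "populated bins form disconnected segments; windows do not "
            "jointly cover the range"
        )
    _warn_nonoverlapping(windows, hist)

    # bias energy of every window at every bin center, in kT units
    bias = np.empty((n_win, n_bins))
    for i, w in enumerate(windows):
        bias[i] = w.bias(centers) / kT
    n_samples = np.array([w.samples.size for w in windows], dtype=float)

    f = np.zeros(n_win)  # window free energies in kT units
    tol_kt = tol / kT
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        # denominator: Σ_j N_j exp(f_j − U_j(x_b))
        denom = np.exp(f[:, None] - bias).T @ n_samples
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(pop, counts / denom, 0.0)
        # f_i = −ln Σ_b p_b exp(−U_i(x_b))
        new_f = -np.log(np.exp(-bias) @ p)
        new_f -= new_f[0]
        delta = np.max(np.abs(new_f - f))
        f = new_f
        if delta < tol_kt:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"WHAM did not converge within {_MAX_ITER} iterations "
            f"(last max|Δf| = {delta * kT:.3g} kcal/mol)"
        )

    with np.errstate(divide="ignore"):
        w_profile = np.where(pop, -kT * np.log(np.where(pop, p, 1.0)), np.nan)
    w_profile -= np.nanmin(w_profile)
    return PMFProfile(
        bin_centers=centers,
        free_energy=w_profile,
        counts=counts,
        temperature=temperature,
        iterations=it,
        converged=converged,
        bin_edges=bins,
    )


def _warn_nonoverlapping(windows, hist) -> None:
    import warnings

    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((hist[a] > 0) & (hist[b] > 0)):
            warnings.warn(
                f"adjacent windows centred at {windows[a].center:.2f} and "
                f"{windows[b].center:.2f} Å share no populated bin",
                stacklevel=3,
            )


def convergence_check(pmf_by_time: list[tuple[float, PMFProfile]],
                      tol: float = 0.2) -> list[tuple[float, bool]]:
    """Endpoint-stability convergence rule for nested sampling intervals.

    For each consecutive pair of profiles (computed on growing sampling
    intervals, e.g. 5 ns blocks), reports |ΔW| at the endpoint — the last
    populated bin of the common range — and whether it is strictly below
    ``tol`` (default 0.2 kcal/mol).
    """
    if len(pmf_by_time) < 2:
        raise ValueError("need at least two profiles to assess convergence")
    out = []
    for (_, p0), (_, p1) in zip(pmf_by_time[:-1], pmf_by_time[1:]):
        delta = abs(p1.endpoint_value(p0) - p0.endpoint_value(p1))
        out.append((delta, delta < tol))
    return out


def locate_well(pmf: PMFProfile,
                search_range: tuple[float, float] = (3.5, 5.5),
                ) -> tuple[float, float] | None:
    """Find a local PMF well inside ``search_range`` (Å).

    Returns (well position, depth) where depth is measured against the
    lower of the two flanking local maxima (profile ends count as maxima);
    ``None`` if the profile is monotone inside the range.
    """
    lo, hi = search_range
    pop = np.flatnonzero(pmf.populated)
    if pop.size == 0:
        raise ValueError("empty PMF")
    x = pmf.bin_centers[pop]
    w = pmf.free_energy[pop]
    if lo < x[0] and hi < x[0] or lo > x[-1] and hi > x[-1]:
        raise ValueError("search range lies outside the PMF domain")
    in_range = np.flatnonzero((x >= lo) & (x <= hi))
    if in_range.size == 0:
        raise ValueError("no populated bin inside the search range")

    # interior local minima within the range
    best = None
    for i in in_range:
        left = w[i - 1] if i > 0 else np.inf
        right = w[i + 1] if i < w.size - 1 else np.inf
        if w[i] < left and w[i] < right:
            if best is None or w[i] < w[best]:
                best = i
    if best is None:
        return None

    # climb both flanks while the profile keeps rising; the turning point
    # (or the profile end) is the flanking maximum
    j = best
    while j > 0 and w[j - 1] >= w[j]:
        j -= 1
    left_max = w[j]
    k = best
    while k < w.size - 1 and w[k + 1] >= w[k]:
        k += 1
    right_max = w[k]
    depth = float(min(left_max, right_max) - w[best])
    return float(x[best]), depth
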
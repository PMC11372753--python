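"""Umbrella sampling → potential of mean force via WHAM.

The free-energy cost of moving a molecule along a reaction coordinate
(e.g. pulling a fatty acid out of a monolayer along z) is estimated from a
set of umbrella windows — simulations biased by harmonic restraints
U_i(x) = ½ k_i (x − x0_i)² — combined with the Weighted Histogram Analysis
Method.  WHAM self-consistently solves

    P(x_b)      = Σ_i h_i(x_b) / Σ_i n_i · exp(−β (U_i(x_b) − f_i))
    exp(−β f_i) = Σ_b P(x_b) · exp(−β U_i(x_b))

for the unbiased probability P and per-window free-energy shifts f_i, then
G(x) = −kT ln P(x), referenced to min G = 0.  All accumulation is done in
the log domain (log-sum-exp), so force constants up to the hundreds of
kJ/mol/nm² used in practice do not underflow.

Internal units: Å for the coordinate, kT for energies (T = 298.15 K by
default); file I/O accepts GROMACS-convention kJ/mol and nm with exact
conversion.  A 1D overdamped Langevin sampler generates synthetic windows
for validation, replacing MD trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "KT_KJ_PER_MOL_298",
    "UmbrellaWindow",
    "PMFProfile",
    "harmonic_potential",
    "double_well_potential",
    "langevin_windows",
    "wham",
    "delta_g",
    "write_window",
    "read_window",
    "write_manifest",
    "read_windows",
]

#: kT at 298.15 K in kJ/mol (k_B·N_A·T)
KT_KJ_PER_MOL_298 = 8.31446261815324e-3 * 298.15  # = 2.4789 kJ/mol


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class UmbrellaWindow:
    """Biased samples of a 1D reaction coordinate.

    ``center`` (Å) and ``k`` (kT/Å², internal units) define the harmonic
    bias U(x) = ½ k (x − center)²; ``samples`` are coordinate values in Å.
    """

    center: float
    k: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if len(self.samples) < 1:
            raise ValueError("window must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.k < 0:
            raise ValueError("force constant must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.samples)

    def bias(self, x: np.ndarray) -> np.ndarray:
        """Bias energy in kT at positions x (Å)."""
        return 0.5 * self.k * (np.asarray(x) - self.center) ** 2

    @classmethod
    def from_gromacs_units(cls, center_nm_or_A: float, k_kj_mol_nm2: float,
                           samples: np.ndarray, *, coords_in_nm: bool = False,
                           kT_kj_mol: float = KT_KJ_PER_MOL_298) -> "UmbrellaWindow":
        """Build a window from kJ/mol/nm² force constants (and optionally nm).

        k [kT/Å²] = k [kJ/mol/nm²] / kT[kJ/mol] / 100.
        """
        scale = 10.0 if coords_in_nm else 1.0
        return cls(center=center_nm_or_A * scale,
                   k=k_kj_mol_nm2 / kT_kj_mol / 100.0,
                   samples=np.asarray(samples) * scale)


@dataclass
class PMFProfile:
    """Free energy vs coordinate, minimum-referenced.

    ``g`` is in kT with min over defined bins = 0; bins never visited by any
    window are masked (NaN), not interpolated.  ``shifts`` are the converged
    per-window free energies f_i (kT); ``residual`` is the final max |Δf|.
    """

    x: np.ndarray
    g: np.ndarray
    shifts: np.ndarray
    residual: float
    iterations: int
    kT: float = 1.0  # energies are in kT units; kT stores the kJ/mol scale used for I/O

    def g_kj_per_mol(self, kT_kj_mol: float = KT_KJ_PER_MOL_298) -> np.ndarray:
        return self.g * kT_kj_mol

    def interp(self, x: float) -> float:
        """Linear interpolation of G at x (kT), NaN outside defined bins."""
        ok = np.isfinite(self.g)
        return float(np.interp(x, self.x[ok], self.g[ok]))


# ---------------------------------------------------------------------------
# Named test potentials
# ---------------------------------------------------------------------------

def harmonic_potential(kappa: float) -> Callable[[np.ndarray], np.ndarray]:
    """U(x) = ½ κ x² (κ in kT/Å²)."""
    def u(x):
        return 0.5 * kappa * np.square(x)
    u.grad = lambda x: kappa * np.asarray(x)
    return u


def double_well_potential(barrier: float, half_width: float) -> Callable[[np.ndarray], np.ndarray]:
    """Symmetric double well U(x) = h·((x/b)² − 1)² with wells at ±b.

    ``barrier`` h (kT) is the exact analytic barrier between the wells.
    """
    b2 = half_width**2

    def u(x):
        return barrier * (np.square(x) / b2 - 1.0) ** 2

    u.grad = lambda x: 4.0 * barrier * np.asarray(x) * (np.square(x) / b2 - 1.0) / b2
    return u


_NAMED = {"flat": lambda: _flat(), "harmonic": harmonic_potential, "double_well": double_well_potential}


def _flat() -> Callable[[np.ndarray], np.ndarray]:
    def u(x):
        return np.zeros_like(np.asarray(x, dtype=float))
    u.grad = lambda x: np.zeros_like(np.asarray(x, dtype=float))
    return u


# ---------------------------------------------------------------------------
# Synthetic umbrella windows from overdamped Langevin dynamics
# ---------------------------------------------------------------------------

def langevin_windows(
    potential: Callable[[np.ndarray], np.ndarray] | str,
    centers: Sequence[float],
    k: float | Sequence[float],
    n_steps: int = 20000,
    dt: float = 0.005,
    friction: float = 1.0,
    kT: float = 1.0,
    seed: int = 0,
    burn_in: float = 0.1,
    sample_stride: int = 1,
    **potential_kwargs,
) -> list[UmbrellaWindow]:
    """Sample umbrella windows with overdamped (Euler–Maruyama) Langevin dynamics.

    dx = −(U'(x) + k_i (x − x0_i)) dt/γ + sqrt(2 kT dt/γ) ξ, run for all
    windows in parallel, each started at its bias center.  The first
    ``burn_in`` fraction of steps is discarded.  ``potential`` may be a
    callable with a ``.grad`` attribute or one of the names
    ``"flat"``, ``"harmonic"`` (kwarg kappa), ``"double_well"`` (kwargs
    barrier, half_width).  Deterministic per seed.

    Raises ``ValueError`` for an unstable time step (dt·k/γ ≥ 0.1) and
    ``RuntimeError`` on coordinate divergence.
    """
    if isinstance(potential, str):
        if potential not in _NAMED:
            raise ValueError(f"unknown potential {potential!r}; choose from {sorted(_NAMED)}")
        potential = _NAMED[potential](**potential_kwargs)
    centers = np.asarray(centers, dtype=float)
    ks = np.broadcast_to(np.asarray(k, dtype=float), centers.shape).copy()
    if n_steps < 10:
        raise ValueError("n_steps must be at least 10")
    k_max = float(ks.max()) if ks.size else 0.0
    if dt * k_max / friction >= 0.1:
        raise ValueError(
            f"dt={dt} unstable for stiffest bias k={k_max} (need dt·k/friction < 0.1)"
        )
    rng = np.random.default_rng(seed)
    x = centers.copy()
    noise_amp = math.sqrt(2.0 * kT * dt / friction)
    keep_from = int(burn_in * n_steps)
    grad = getattr(potential, "grad", None)
    if grad is None:
        eps = 1e-5

        def grad(y, _u=potential):  # central finite difference fallback
            return (_u(y + eps) - _u(y - eps)) / (2 * eps)

    traj = np.empty((n_steps, len(centers)))
    for t in range(n_steps):
        force = -(grad(x) + ks * (x - centers))
        x = x + force * dt / friction + noise_amp * rng.standard_normal(len(centers))
        traj[t] = x
    if not np.all(np.isfinite(traj)) or np.abs(traj).max() > 1e6:
        raise RuntimeError("Langevin integration diverged; reduce dt or increase friction")
    kept = traj[keep_from::sample_stride]
    return [UmbrellaWindow(center=float(c), k=float(kk), samples=kept[:, i])
            for i, (c, kk) in enumerate(zip(centers, ks))]


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def wham(
    windows: Sequence[UmbrellaWindow],
    grid: tuple[float, float, int],
    kT: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 100000,
) -> PMFProfile:
    """Solve the WHAM equations over the given grid and return the PMF.

    ``grid`` is (xmin, xmax, n_bins); ``kT`` rescales window biases if they
    are expressed in other energy units (windows built in kT use kT=1).
    Plain Jacobi fixed-point iteration from f_i = 0 until
    max |Δf_i| < tol (kT) or ``max_iter``.  Bins with zero total counts are
    masked NaN.  Non-overlapping windows are reported via a diagnostic in
    the raised error.
    """
    if len(windows) == 0:
        raise ValueError("need at least one window")
    xmin, xmax, n_bins = grid
    if not (xmax > xmin and n_bins >= 1):
        raise ValueError("grid must satisfy xmax > xmin and n_bins >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    edges = np.linspace(xmin, xmax, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    beta = 1.0 / kT

    n_w = len(windows)
    hist = np.empty((n_w, n_bins))
    n_i = np.empty(n_w)
    log_bias = np.empty((n_w, n_bins))  # β·U_i(x_b)
    for i, w in enumerate(windows):
        hist[i], _ = np.histogram(w.samples, bins=edges)
        n_i[i] = w.n
        log_bias[i] = beta * w.bias(centers)

    total_counts = hist.sum(axis=0)
    defined = total_counts > 0
    if not np.any(defined):
        raise ValueError("no samples fall inside the grid")

    # windows whose occupied bins never touch cannot be stitched together:
    # the relative shifts f_i are then undetermined, so fail loudly with
    # pairwise overlap diagnostics instead of returning a disjoint profile
    if n_w > 1:
        occ = hist > 0
        parent = list(range(n_w))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(n_w):
            for j in range(i + 1, n_w):
                if np.any(occ[i] & occ[j]):
                    parent[find(i)] = find(j)
        if len({find(i) for i in range(n_w)}) > 1:
            order = np.argsort([w.center for w in windows])
            raise RuntimeError(
                "windows do not overlap: histogram supports fall into disjoint "
                "groups, so the window free energies cannot be aligned; "
                f"neighbor overlap fractions (by center order): "
                f"{_overlap_diagnostics(hist[order])}"
            )

    log_hist_tot = np.where(defined, np.log(np.maximum(total_counts, 1)), -np.inf)
    log_n = np.log(n_i)

    log_f = np.zeros(n_w)  # β f_i
    residual = math.inf
    it = 0
    for it in range(1, max_iter + 1):
        # log P(x_b) = log Σ_i h_i − logsumexp_i[ log n_i − βU_i + βf_i ]
        denom = logsumexp(log_n[:, None] - log_bias + log_f[:, None], axis=0)
        log_p = np.where(defined, log_hist_tot - denom, -np.inf)
        # normalize P each pass: fixes the gauge freedom (P·c, f_i + ln c)
        log_p = log_p - logsumexp(log_p[defined])
        # β f_i = −log Σ_b P(x_b) exp(−βU_i(x_b))
        new_log_f = -logsumexp(log_p[None, :] - log_bias, axis=1)
        residual = float(np.max(np.abs(new_log_f - log_f)))  # Δ(βf), i.e. kT units
        log_f = new_log_f
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations (residual {residual:.3g} kT); "
            f"window overlap (fraction of bins shared with a neighbor): "
            f"{_overlap_diagnostics(hist)}"
        )

    log_p = np.where(defined, log_hist_tot - logsumexp(
        log_n[:, None] - log_bias + log_f[:, None], axis=0), -np.inf)
    # normalize and convert to free energy
    log_p = log_p - logsumexp(log_p[defined])
    g = np.full(n_bins, np.nan)
    g[defined] = -log_p[defined]  # in kT
    g -= np.nanmin(g)
    return PMFProfile(x=centers, g=g, shifts=log_f / beta, residual=residual,
                      iterations=it, kT=kT)


def _overlap_diagnostics(hist: np.ndarray) -> list[float]:
    occ = hist > 0
    out = []
    for i in range(len(hist) - 1):
        inter = np.logical_and(occ[i], occ[i + 1]).sum()
        union = np.logical_or(occ[i], occ[i + 1]).sum()
        out.append(round(inter / union, 3) if union else 0.0)
    return out


def delta_g(
    pmf: PMFProfile,
    region_a: tuple[float, float] | float,
    region_b: tuple[float, float] | float,
) -> float:
    """Free-energy difference G(b) − G(a) between two coordinate regions (kT).

    Each region is an (xlo, xhi) interval (its minimum defined G is used) or
    a single coordinate (interpolated).  Positive means b is uphill of a.
    Raises ``ValueError`` if a region contains no defined bins.
    """
    def region_g(region) -> float:
        if np.isscalar(region):
            lo = hi = float(region)
        else:
            lo, hi = region
        mask = (pmf.x >= lo - 1e-12) & (pmf.x <= hi + 1e-12) & np.isfinite(pmf.g)
        if np.any(mask):
            return float(np.min(pmf.g[mask]))
        if lo == hi:
            ok = np.isfinite(pmf.g)
            if ok.any() and pmf.x[ok].min() <= lo <= pmf.x[ok].max():
                return pmf.interp(lo)
        raise ValueError(f"region {region} contains no defined PMF bins")

    return region_g(region_b) - region_g(region_a)


# ---------------------------------------------------------------------------
# Window file I/O (plain text) — GROMACS-convention units on disk
# ---------------------------------------------------------------------------

def write_window(path, window: UmbrellaWindow, kT_kj_mol: float = KT_KJ_PER_MOL_298) -> None:
    """Write one window: header `#center <Å>`, `#k <kJ/mol/nm^2>`, samples in Å."""
    k_disk = window.k * kT_kj_mol * 100.0  # kT/Å² -> kJ/mol/nm²
    with open(path, "w") as fh:
        fh.write(f"#center {window.center:.6f}\n")
        fh.write(f"#k {k_disk:.6f}\n")
        for s in window.samples:
            fh.write(f"{s:.6f}\n")


def read_window(path, kT_kj_mol: float = KT_KJ_PER_MOL_298) -> UmbrellaWindow:
    """Read a window file written by :func:`write_window`."""
    center = k_disk = None
    samples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#center"):
                center = float(line.split()[1])
            elif line.startswith("#k"):
                k_disk = float(line.split()[1])
            elif line.startswith("#"):
                continue
            else:
                try:
                    samples.append(float(line))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed sample {line!r}") from exc
    if center is None or k_disk is None:
        raise ValueError(f"{path}: missing #center or #k header")
    return UmbrellaWindow(center=center, k=k_disk / kT_kj_mol / 100.0,
                          samples=np.asarray(samples))


def write_manifest(path, window_paths: Sequence, relative_to=None) -> None:
    """Write a manifest TSV (single column `file`) listing window files."""
    with open(path, "w") as fh:
        fh.write("file\n")
        for p in window_paths:
            p = Path(p)
            if relative_to is not None:
                p = p.relative_to(relative_to)
            fh.write(f"{p}\n")


def read_windows(manifest_path) -> list[UmbrellaWindow]:
    """Read all windows listed in a manifest TSV (paths relative to it)."""
    manifest_path = Path(manifest_path)
    windows = []
    with open(manifest_path) as fh:
        header = fh.readline()
        if header.strip() != "file":
            raise ValueError(f"{manifest_path}: manifest must start with a 'file' header")
        for line in fh:
            line = line.strip()
            if line:
                p = Path(line)
                if not p.is_absolute():
                    p = manifest_path.parent / p
                windows.append(read_window(p))
    if not windows:
        raise ValueError(f"{manifest_path}: no windows listed")
    return windows
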
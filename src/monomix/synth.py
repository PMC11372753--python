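"""Synthetic monolayer frames and trajectories.

Generates headgroup-resolution monolayer configurations with the structural
features the downstream analyses assume, so that no molecular-dynamics
engine is needed to exercise them:

* periodic hexagonal headgroup lattices at a prescribed mean molecular area
  (MMA, Å²/molecule) — condensed fatty-acid monolayers pack hexagonally with
  six nearest neighbors;
* controlled lateral mixing/demixing of species labels via label-swap
  Metropolis Monte Carlo with a same-type affinity J;
* vertical staggering of headgroups by species and protonation state;
* stochastic desorption (molecules flagged as having left the interface).

Each molecule is represented by a single headgroup (C1 carbon) site.  The
box is periodic in x and y only; z points toward vacuum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .protonation import MixtureComposition, fraction_protonated

__all__ = [
    "MonolayerFrame",
    "Trajectory",
    "build_hexagonal_monolayer",
    "hexagonal_neighbor_table",
    "demix_labels",
    "apply_staggering",
    "desorb",
    "make_trajectory",
    "valid_lattice_sizes",
]


# ---------------------------------------------------------------------------
# Frame model
# ---------------------------------------------------------------------------

@dataclass
class MonolayerFrame:
    """Labeled headgroup coordinates in a box periodic in x and y.

    Attributes
    ----------
    ids : (n,) int array — stable molecule identifiers.
    species : (n,) unicode array — species labels (e.g. "LA", "PA").
    protonated : (n,) bool array.
    positions : (n, 3) float array, Å; x and y wrapped into [0, L).
    box : (3,) float array (Lx, Ly, Lz), Å; periodic in x, y only.
    leaflet : (n,) unicode array, "upper" or "lower".
    present : (n,) bool array; False marks a desorbed molecule, which is
        kept (identity preserved across frames) but excluded from analyses.
    """

    ids: np.ndarray
    species: np.ndarray
    protonated: np.ndarray
    positions: np.ndarray
    box: np.ndarray
    leaflet: np.ndarray
    present: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.species = np.asarray(self.species, dtype="U8")
        self.protonated = np.asarray(self.protonated, dtype=bool)
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.leaflet = np.asarray(self.leaflet, dtype="U8")
        self.present = np.asarray(self.present, dtype=bool)
        for name in ("species", "protonated", "leaflet", "present"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must be (n, 3), got {self.positions.shape}")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        self.wrap()

    @property
    def n_molecules(self) -> int:
        return len(self.ids)

    def wrap(self) -> None:
        """Wrap x, y into [0, L); z is non-periodic and left unchanged."""
        self.positions[:, 0] %= self.box[0]
        self.positions[:, 1] %= self.box[1]

    def copy(self) -> "MonolayerFrame":
        return MonolayerFrame(
            ids=self.ids.copy(),
            species=self.species.copy(),
            protonated=self.protonated.copy(),
            positions=self.positions.copy(),
            box=self.box.copy(),
            leaflet=self.leaflet.copy(),
            present=self.present.copy(),
        )

    def select(self, species: str | None = None, leaflet: str | None = None,
               present_only: bool = True) -> np.ndarray:
        """Boolean mask over molecules matching the given filters."""
        mask = np.ones(self.n_molecules, dtype=bool)
        if present_only:
            mask &= self.present
        if species is not None and species != "all":
            mask &= self.species == species
        if leaflet is not None:
            mask &= self.leaflet == leaflet
        return mask

    def pair_distances_xy(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Minimum-image xy distances between molecules i and j (index arrays)."""
        d = self.positions[i, :2] - self.positions[j, :2]
        L = self.box[:2]
        d -= L * np.round(d / L)
        return np.sqrt((d**2).sum(axis=-1))


@dataclass
class Trajectory:
    """Ordered frames with constant molecule identity and box."""

    frames: list[MonolayerFrame]
    frame_interval_ps: float = 1.0  # metadata only

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("trajectory must contain at least one frame")
        ref = self.frames[0]
        for f in self.frames[1:]:
            if not np.array_equal(f.ids, ref.ids):
                raise ValueError("molecule identity must be constant across frames")
            if not np.allclose(f.box, ref.box):
                raise ValueError("box must be constant across frames")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> MonolayerFrame:
        return self.frames[i]


# ---------------------------------------------------------------------------
# Hexagonal lattice construction
# ---------------------------------------------------------------------------

def _factor_lattice(n: int) -> tuple[int, int] | None:
    """Pick (rows, cols) with rows even and the embedding box closest to square.

    The rectangular embedding places rows a distance sqrt(3)/2·a apart, so a
    near-square box has rows ≈ cols·2/sqrt(3).  Periodicity in y requires an
    even row count.
    """
    best = None
    best_score = math.inf
    for rows in range(2, n + 1, 2):
        if n % rows:
            continue
        cols = n // rows
        # box aspect ratio: Ly/Lx = rows·(sqrt(3)/2) / cols
        score = abs(math.log(rows * math.sqrt(3) / 2 / cols))
        if score < best_score:
            best, best_score = (rows, cols), score
    return best


def valid_lattice_sizes(near: int, width: int = 10) -> list[int]:
    """Tileable site counts within ``width`` of ``near`` (rows even)."""
    out = []
    for n in range(max(2, near - width), near + width + 1):
        if _factor_lattice(n) is not None:
            out.append(n)
    return out


def hexagonal_lattice_constant(mma: float) -> float:
    """Lattice constant a = sqrt(2·MMA/sqrt(3)) of a triangular lattice.

    Each site of a triangular lattice occupies an area (sqrt(3)/2)·a², so a
    prescribed area per molecule fixes a.
    """
    if mma <= 0:
        raise ValueError(f"mma must be positive, got {mma}")
    return math.sqrt(2.0 * mma / math.sqrt(3.0))


def build_hexagonal_monolayer(
    n: int,
    mma: float,
    composition: MixtureComposition,
    seed: int = 0,
    pH: float | None = None,
    leaflet: str = "upper",
    z0: float | None = None,
    lz: float = 160.0,
) -> MonolayerFrame:
    """Build a periodic hexagonal monolayer of ``n`` headgroups at the given MMA.

    Species labels are assigned i.i.d. by mole fraction (seeded).  If ``pH``
    is given, each molecule's protonation state is drawn from its species'
    Henderson-Hasselbalch protonated fraction; otherwise all molecules are
    protonated.  All headgroups start at height ``z0`` (flat monolayer); use
    :func:`apply_staggering` for vertical structure.

    Raises ``ValueError`` when ``n`` does not tile a rectangular periodic
    hexagonal cell (even rows × cols), listing valid nearby sizes.
    """
    if z0 is None:
        # place each leaflet on its side of the box midplane so that leaflet
        # identity survives a write→read round trip (readers assign leaflet
        # by z relative to Lz/2)
        z0 = 0.75 * lz if leaflet == "upper" else 0.25 * lz
    if n == 1:
        # degenerate single-molecule frame: box from the molecular area
        a = hexagonal_lattice_constant(mma)
        rng = np.random.default_rng(seed)
        names = [sp.name for sp in composition.species]
        lab = rng.choice(names, p=composition.mole_fractions)
        return MonolayerFrame(
            ids=np.array([0]),
            species=np.array([lab]),
            protonated=np.array([True]),
            positions=np.array([[0.0, 0.0, z0]]),
            box=np.array([a, a * math.sqrt(3.0) / 2.0, lz]),
            leaflet=np.array([leaflet]),
            present=np.array([True]),
        )
    fac = _factor_lattice(n)
    if fac is None:
        raise ValueError(
            f"n={n} does not tile an even-row periodic hexagonal lattice; "
            f"valid nearby sizes: {valid_lattice_sizes(n)}"
        )
    rows, cols = fac
    a = hexagonal_lattice_constant(mma)
    dy = a * math.sqrt(3.0) / 2.0
    xs = np.empty((n, 3), dtype=float)
    k = 0
    for r in range(rows):
        off = (a / 2.0) * (r % 2)
        for c in range(cols):
            xs[k] = (off + c * a, r * dy, z0)
            k += 1
    box = np.array([cols * a, rows * dy, lz])

    rng = np.random.default_rng(seed)
    names = [sp.name for sp in composition.species]
    labels = rng.choice(names, size=n, p=composition.mole_fractions)
    if pH is None:
        prot = np.ones(n, dtype=bool)
    else:
        fr = {sp.name: fraction_protonated(sp.pKa, pH) for sp in composition.species}
        prot = rng.random(n) < np.array([fr[s] for s in labels])

    return MonolayerFrame(
        ids=np.arange(n),
        species=labels,
        protonated=prot,
        positions=xs,
        box=box,
        leaflet=np.full(n, leaflet),
        present=np.ones(n, dtype=bool),
    )


def hexagonal_neighbor_table(frame: MonolayerFrame, cutoff: float | None = None) -> np.ndarray:
    """(n, 6) first-shell neighbor indices of a hexagonal-lattice frame.

    ``cutoff`` defaults to halfway between the first (a) and second (√3·a)
    neighbor shells, estimated from the site density.
    """
    n = frame.n_molecules
    area = frame.box[0] * frame.box[1]
    a = hexagonal_lattice_constant(area / n)
    if cutoff is None:
        cutoff = a * (1.0 + math.sqrt(3.0)) / 2.0
    from scipy.spatial import cKDTree

    tree = cKDTree(frame.positions[:, :2], boxsize=frame.box[:2])
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    counts = np.zeros(n, dtype=int)
    table = np.full((n, 6), -1, dtype=np.int64)
    for i, j in pairs:
        if counts[i] >= 6 or counts[j] >= 6:
            raise ValueError("frame is not a first-shell hexagonal lattice at this cutoff")
        table[i, counts[i]] = j
        table[j, counts[j]] = i
        counts[i] += 1
        counts[j] += 1
    if np.any(counts != 6):
        raise ValueError("frame is not 6-coordinated at the given cutoff")
    return table


# ---------------------------------------------------------------------------
# Label demixing (Metropolis label-swap Monte Carlo)
# ---------------------------------------------------------------------------

def _demix_python(codes, neighbors, J, n_steps, u01, picks_i, picks_j):
    """Pure-Python Metropolis fallback (identical arithmetic to the jitted path)."""
    n = len(codes)
    for t in range(n_steps):
        i = picks_i[t]
        j = picks_j[t]
        ci = codes[i]
        cj = codes[j]
        if ci == cj:
            continue
        d_same = 0
        for m in range(neighbors.shape[1]):
            nb = neighbors[i, m]
            if nb != j:
                if codes[nb] == cj:
                    d_same += 1
                if codes[nb] == ci:
                    d_same -= 1
            nb = neighbors[j, m]
            if nb != i:
                if codes[nb] == ci:
                    d_same += 1
                if codes[nb] == cj:
                    d_same -= 1
        # energy is -J per same-type neighbor pair; dE = -J * d_same
        if d_same >= 0 or u01[t] < math.exp(J * d_same):
            codes[i] = cj
            codes[j] = ci
    return codes


try:  # jitted kernel; falls back to Python if numba is unavailable
    from numba import njit

    _demix_kernel = njit(cache=False)(_demix_python)
except Exception:  # pragma: no cover
    _demix_kernel = _demix_python


def demix_labels(
    frame: MonolayerFrame,
    J: float,
    n_sweeps: int,
    seed: int = 0,
    cutoff: float | None = None,
) -> MonolayerFrame:
    """Drive lateral demixing by label-swap Metropolis Monte Carlo.

    The energy is −J per same-type nearest-neighbor pair on the fixed
    first-shell lattice adjacency (J dimensionless, in units of kT).  One
    sweep attempts n swaps of two uniformly chosen sites.  Swap dynamics
    conserve species counts exactly; J=0 leaves the label distribution
    exchangeable, while large J (≳1.5) grows connected same-type domains —
    the synthetic analogue of pressure-driven phase separation.
    """
    if J < 0:
        raise ValueError(f"J must be nonnegative, got {J}")
    if n_sweeps < 0:
        raise ValueError(f"n_sweeps must be nonnegative, got {n_sweeps}")
    out = frame.copy()
    if n_sweeps == 0 or frame.n_molecules < 2:
        return out
    neighbors = hexagonal_neighbor_table(frame, cutoff)
    uniq, codes = np.unique(out.species, return_inverse=True)
    codes = codes.astype(np.int64)
    n = frame.n_molecules
    n_steps = n_sweeps * n
    rng = np.random.default_rng(seed)
    picks_i = rng.integers(0, n, size=n_steps)
    picks_j = rng.integers(0, n, size=n_steps)
    u01 = rng.random(n_steps)
    codes = _demix_kernel(codes, neighbors, float(J), n_steps, u01, picks_i, picks_j)
    out.species = uniq[codes]
    return out


# ---------------------------------------------------------------------------
# Vertical staggering and desorption
# ---------------------------------------------------------------------------

def apply_staggering(
    frame: MonolayerFrame,
    z_offsets: Mapping,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> MonolayerFrame:
    """Offset headgroup heights by (species, protonation) plus Gaussian jitter.

    ``z_offsets`` maps either ``(species, protonated)`` tuples or bare
    protonation flags (applied to every species) to offsets in Å; negative
    offsets point toward the aqueous side (more hydrated) for the upper
    leaflet.  x, y are unchanged.  Raises ``KeyError`` if any (species,
    protonation) combination present in the frame has no offset.
    """
    out = frame.copy()
    rng = np.random.default_rng(seed)

    def offset_for(sp: str, prot: bool) -> float:
        for key in ((sp, prot), (sp, bool(prot)), prot, bool(prot)):
            if key in z_offsets:
                return float(z_offsets[key])
        raise KeyError(f"no z offset for species={sp!r}, protonated={prot}")

    # sign convention: for the lower leaflet "toward water" is +z, so flip
    dz = np.array([
        offset_for(sp, prot) * (1.0 if lf == "upper" else -1.0)
        for sp, prot, lf in zip(out.species, out.protonated, out.leaflet)
    ])
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be nonnegative")
    if jitter_sd > 0:
        dz = dz + rng.normal(0.0, jitter_sd, size=out.n_molecules)
    out.positions[:, 2] += dz
    return out


def desorb(
    frame: MonolayerFrame,
    fraction: float,
    species: str = "all",
    seed: int = 0,
) -> MonolayerFrame:
    """Mark ``floor(fraction · n_species)`` molecules as desorbed.

    Molecules are chosen uniformly at random among the present molecules of
    the given species ("all" for any species).  Desorbed molecules keep
    their identity and coordinates but are flagged ``present=False`` and
    excluded from all analyses — the synthetic analogue of expulsion from
    the interface under compression.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    pool = np.flatnonzero(frame.select(species=None if species == "all" else species))
    if species != "all" and not np.any(frame.species == species):
        raise ValueError(f"unknown species {species!r}")
    out = frame.copy()
    k = math.floor(fraction * len(pool))
    if k > 0:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(pool, size=k, replace=False)
        out.present[chosen] = False
    return out


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def make_trajectory(
    frame: MonolayerFrame,
    n_frames: int,
    xy_jitter_sd: float = 0.0,
    z_jitter_sd: float = 0.0,
    seed: int = 0,
    frame_interval_ps: float = 1.0,
) -> Trajectory:
    """Emulate a trajectory by perturbing a base frame with i.i.d. jitter.

    Frame 0 equals the input frame; frames 1..n-1 add independent Gaussian
    displacements to the base coordinates (not a random walk), so the
    ensemble is stationary around the lattice, mimicking thermal vibration
    of a condensed monolayer.  Deterministic for a given seed.
    """
    if n_frames <= 0:
        raise ValueError(f"n_frames must be positive, got {n_frames}")
    rng = np.random.default_rng(seed)
    frames = [frame.copy()]
    for _ in range(1, n_frames):
        f = frame.copy()
        if xy_jitter_sd > 0:
            f.positions[:, :2] += rng.normal(0.0, xy_jitter_sd, size=(f.n_molecules, 2))
        if z_jitter_sd > 0:
            f.positions[:, 2] += rng.normal(0.0, z_jitter_sd, size=f.n_molecules)
        f.wrap()
        frames.append(f)
    return Trajectory(frames=frames, frame_interval_ps=frame_interval_ps)
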
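"""Vertical structure of the monolayer interface.

Headgroups in chain-length- and protonation-heterogeneous monolayers do not
sit at a common height: deprotonated (charged) headgroups sink toward the
aqueous side, and shorter-chain acids sit higher (less hydrated), producing
a staggered arrangement that maximizes tail-tail dispersion contacts.  This
module measures that structure:

* vertical deviations of headgroup C1 carbons from the per-leaflet mean
  headgroup height, grouped by species × protonation state (negative =
  toward water = more hydrated);
* z-density profiles of selected molecules;
* geometric hydrogen-bond counting on explicit donor/H/acceptor triples
  (distance + angle criterion), classed as head-head same-species,
  head-head cross-species, or head-water.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .synth import MonolayerFrame, Trajectory

logger = logging.getLogger("monomix")

__all__ = [
    "VerticalDeviationProfile",
    "HBondCriterion",
    "HBondSites",
    "vertical_deviations",
    "density_profile",
    "DensityProfile",
    "count_hbonds",
]


# ---------------------------------------------------------------------------
# Vertical deviations (headgroup staggering)
# ---------------------------------------------------------------------------

@dataclass
class VerticalDeviationProfile:
    """Deviation statistics for one (species, protonated) group.

    Deviations are z minus the per-leaflet, per-frame mean headgroup height,
    sign-fixed so that negative = toward the aqueous side for both leaflets.
    The histogram is density-normalized (integrates to 1).
    """

    species: str
    protonated: bool
    bin_centers: np.ndarray   # Å
    density: np.ndarray       # 1/Å
    mean: float               # Å
    sd: float                 # Å
    n_samples: int

    @property
    def standard_error(self) -> float:
        return self.sd / math.sqrt(self.n_samples) if self.n_samples else math.nan


def vertical_deviations(
    traj: Trajectory | Iterable[MonolayerFrame] | MonolayerFrame,
    bin_width: float = 0.1,
    bound: float | None = None,
) -> list[VerticalDeviationProfile]:
    """Per-group vertical deviations of headgroups from mean headgroup height.

    The reference height is the mean z of all present headgroups in the same
    leaflet of the same frame (computed per frame so slow drift cannot bias
    the deviations).  For the lower leaflet the deviation sign is flipped so
    that negative always means toward water.  Deviations are pooled over
    frames, then histogrammed per (species, protonated) group.
    """
    if isinstance(traj, MonolayerFrame):
        traj = [traj]
    samples: dict[tuple[str, bool], list[np.ndarray]] = {}
    for frame in traj:
        for leaflet in np.unique(frame.leaflet):
            mask = frame.select(leaflet=leaflet)
            if not np.any(mask):
                continue
            ref = frame.positions[mask, 2].mean()
            dev = frame.positions[mask, 2] - ref
            if leaflet == "lower":
                dev = -dev  # water side is +z below the midplane
            for sp in np.unique(frame.species[mask]):
                for prot in (True, False):
                    sel = mask & (frame.species == sp) & (frame.protonated == prot)
                    if np.any(sel):
                        key = (str(sp), prot)
                        d = frame.positions[sel, 2] - ref
                        if leaflet == "lower":
                            d = -d
                        samples.setdefault(key, []).append(d)

    profiles = []
    for (sp, prot), chunks in sorted(samples.items()):
        dev = np.concatenate(chunks)
        if bound is None:
            lim = max(1.0, float(np.abs(dev).max()) * 1.2)
        else:
            lim = bound
        edges = np.arange(-lim, lim + bin_width, bin_width)
        dens, _ = np.histogram(dev, bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        profiles.append(VerticalDeviationProfile(
            species=sp, protonated=prot,
            bin_centers=centers, density=dens,
            mean=float(dev.mean()), sd=float(dev.std(ddof=1)) if len(dev) > 1 else 0.0,
            n_samples=len(dev),
        ))
    return profiles


# ---------------------------------------------------------------------------
# z-density profiles
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Frame-averaged count density of selected molecules vs z (per leaflet)."""

    leaflet: str
    bin_centers: np.ndarray  # Å
    density: np.ndarray      # molecules / Å (per frame)
    selection: str

    @property
    def integral(self) -> float:
        """Mean number of selected molecules per frame (conservation check)."""
        if len(self.bin_centers) < 2:
            return float(self.density.sum())
        dz = self.bin_centers[1] - self.bin_centers[0]
        return float(self.density.sum() * dz)


def density_profile(
    traj: Trajectory | Iterable[MonolayerFrame] | MonolayerFrame,
    species: str = "all",
    bin_width: float = 0.5,
) -> list[DensityProfile]:
    """Histogram of molecule z positions, averaged over frames, per leaflet.

    The integral of each profile equals the mean selected-molecule count per
    frame.  An empty selection yields an all-zero profile.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(traj, MonolayerFrame):
        traj = [traj]
    frames = list(traj)
    out = []
    for leaflet in sorted({lf for f in frames for lf in np.unique(f.leaflet)}):
        zs = []
        for frame in frames:
            mask = frame.select(species=species, leaflet=leaflet)
            zs.append(frame.positions[mask, 2])
        allz = np.concatenate(zs) if zs else np.array([])
        if allz.size == 0:
            centers = np.array([0.0])
            dens = np.array([0.0])
        else:
            lo = math.floor(allz.min() / bin_width) * bin_width - bin_width
            hi = math.ceil(allz.max() / bin_width) * bin_width + bin_width
            edges = np.arange(lo, hi + bin_width, bin_width)
            counts, _ = np.histogram(allz, bins=edges)
            centers = 0.5 * (edges[:-1] + edges[1:])
            dens = counts / (len(frames) * bin_width)
        out.append(DensityProfile(leaflet=leaflet, bin_centers=centers,
                                  density=dens, selection=species))
    return out


# ---------------------------------------------------------------------------
# Hydrogen-bond counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriterion:
    """Geometric H-bond definition: D–A distance and D–H–A angle thresholds.

    Defaults (3.5 Å, 150°) are a standard geometric choice for O–H···O
    bonds; both are freely overridable.
    """

    max_distance: float = 3.5   # donor-acceptor, Å
    min_angle: float = 150.0    # donor-H-acceptor, degrees

    def __post_init__(self) -> None:
        if not 0 < self.max_distance <= 5.0:
            raise ValueError("max_distance must be in (0, 5] Å")
        if not 90.0 <= self.min_angle <= 180.0:
            raise ValueError("min_angle must be in [90, 180] degrees")


@dataclass
class HBondSites:
    """Explicit donor/H/acceptor geometry for one frame.

    ``donor_xyz``/``h_xyz`` are (n_d, 3) arrays of donor heavy atoms and
    their hydrogens; ``acceptor_xyz`` is (n_a, 3).  ``donor_group`` and
    ``acceptor_group`` label each site with a species name or ``"water"``.
    Coordinates are taken as given (no periodic imaging): synthetic fixtures
    and pre-imaged MD frames supply them.
    """

    donor_xyz: np.ndarray
    h_xyz: np.ndarray
    donor_group: np.ndarray
    acceptor_xyz: np.ndarray
    acceptor_group: np.ndarray
    donor_acceptor_index: np.ndarray | None = None  # acceptor index of each donor's own O, to skip self

    def __post_init__(self) -> None:
        self.donor_xyz = np.atleast_2d(np.asarray(self.donor_xyz, dtype=float))
        self.h_xyz = np.atleast_2d(np.asarray(self.h_xyz, dtype=float))
        self.acceptor_xyz = np.atleast_2d(np.asarray(self.acceptor_xyz, dtype=float))
        self.donor_group = np.asarray(self.donor_group, dtype="U16")
        self.acceptor_group = np.asarray(self.acceptor_group, dtype="U16")
        if self.donor_xyz.shape != self.h_xyz.shape or self.donor_xyz.shape[1] != 3:
            raise ValueError("donor and H coordinate arrays must both be (n_d, 3)")
        if len(self.donor_group) != len(self.donor_xyz):
            raise ValueError("donor_group length mismatch")
        if len(self.acceptor_group) != len(self.acceptor_xyz):
            raise ValueError("acceptor_group length mismatch")


def _pair_class(dg: str, ag: str) -> str:
    if dg == "water" or ag == "water":
        return "head-water"
    return "head-head-same" if dg == ag else "head-head-cross"


def count_hbonds(
    sites: HBondSites,
    criterion: HBondCriterion = HBondCriterion(),
) -> dict[str, int]:
    """Count geometric H-bonds, classed by donor/acceptor group.

    A bond is counted iff the donor-acceptor distance is ≤
    ``criterion.max_distance`` and the donor-H-acceptor angle is ≥
    ``criterion.min_angle``.  Returns counts for the classes
    ``head-head-same`` (same species), ``head-head-cross``, ``head-water``,
    and ``total``.  A donor's own heavy atom can be excluded from its
    acceptor candidates via ``sites.donor_acceptor_index``.
    """
    counts = {"head-head-same": 0, "head-head-cross": 0, "head-water": 0}
    d = sites.donor_xyz[:, None, :] - sites.acceptor_xyz[None, :, :]
    dist = np.sqrt((d**2).sum(axis=-1))
    # D-H-A angle at the hydrogen
    v_hd = sites.donor_xyz[:, None, :] - sites.h_xyz[:, None, :]
    v_ha = sites.acceptor_xyz[None, :, :] - sites.h_xyz[:, None, :]
    num = (v_hd * v_ha).sum(axis=-1)
    den = np.linalg.norm(v_hd, axis=-1) * np.linalg.norm(v_ha, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(num / den, -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    ok = (dist <= criterion.max_distance) & (angle >= criterion.min_angle)
    if sites.donor_acceptor_index is not None:
        for di, ai in enumerate(np.asarray(sites.donor_acceptor_index)):
            if 0 <= ai < ok.shape[1]:
                ok[di, ai] = False
    else:
        # self-pairs: donor heavy atom coinciding with an acceptor position
        ok &= dist > 1e-9
    for di, ai in zip(*np.nonzero(ok)):
        counts[_pair_class(str(sites.donor_group[di]), str(sites.acceptor_group[ai]))] += 1
    counts["total"] = sum(counts.values())
    return counts
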
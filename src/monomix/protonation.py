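"""Surface-pKa protonation model for fatty-acid monolayers.

Carboxylic acids at the air-water interface dissociate with an effective
(surface) pKa well above the bulk value.  Given a surface pKa and a subphase
pH, the Henderson-Hasselbalch relation fixes the acid:conjugate-base ratio

    [HA]/[A-] = 10**(pKa - pH)

and hence the protonated fraction of each species.  For a mixture the
overall protonation percentage is the mole-fraction-weighted average of the
per-species fractions.  These numbers parameterize monolayer compositions at
the pH values relevant to sea-spray aerosol: pH 2 (aged aerosol, fully
protonated), pH 7 (stand-in for the experimental pH 5.6, since at the scale
of ~100 molecules the two are indistinguishable), and pH 8.2 (seawater).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FattyAcidSpecies",
    "MixtureComposition",
    "ProtonationAssignment",
    "acid_base_ratio",
    "fraction_protonated",
    "fraction_deprotonated",
    "mixture_protonation_percent",
    "assign_residue_counts",
    "load_species_table",
    "default_species",
    "load_table_counts",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FattyAcidSpecies:
    """A saturated fatty acid identified by name, chain length and surface pKa.

    Parameters
    ----------
    name:
        Short label, e.g. ``"LA"`` (lauric, C12), ``"MA"`` (myristic, C14),
        ``"PA"`` (palmitic, C16), ``"SA"`` (stearic, C18).
    n_carbons:
        Total carbon chain length (>= 2: the headgroup carbon plus tail).
    pKa:
        Surface acid dissociation constant (log10 scale, dimensionless).
    """

    name: str
    n_carbons: int
    pKa: float

    def __post_init__(self) -> None:
        if self.n_carbons < 2:
            raise ValueError(f"n_carbons must be >= 2, got {self.n_carbons}")
        if not math.isfinite(self.pKa):
            raise ValueError(f"pKa must be finite, got {self.pKa}")


@dataclass(frozen=True)
class MixtureComposition:
    """Ordered list of (species, mole ratio) entries.

    Ratios are arbitrary nonnegative weights (e.g. 1:2:4:3); mole fractions
    are obtained by normalization and are invariant under rescaling.
    """

    entries: tuple[tuple[FattyAcidSpecies, float], ...]

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError("composition must contain at least one entry")
        names = [sp.name for sp, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate species in composition: {names}")
        for sp, ratio in self.entries:
            if not math.isfinite(ratio) or ratio < 0:
                raise ValueError(f"mole ratio for {sp.name} must be a finite nonnegative number")
        if sum(r for _, r in self.entries) <= 0:
            raise ValueError("mole ratios must not all be zero")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[FattyAcidSpecies, float]]) -> "MixtureComposition":
        return cls(tuple((sp, float(r)) for sp, r in pairs))

    @property
    def species(self) -> tuple[FattyAcidSpecies, ...]:
        return tuple(sp for sp, _ in self.entries)

    @property
    def mole_fractions(self) -> tuple[float, ...]:
        total = sum(r for _, r in self.entries)
        return tuple(r / total for _, r in self.entries)


@dataclass(frozen=True)
class ProtonationAssignment:
    """Integer acid/base split per species for a finite monolayer patch."""

    counts: Mapping[str, tuple[int, int]]  # name -> (n_acid, n_base)
    pH: float
    policy: str

    def __post_init__(self) -> None:
        for name, (n_acid, n_base) in self.counts.items():
            if n_acid < 0 or n_base < 0:
                raise ValueError(f"negative count for {name}")

    def total(self, name: str) -> int:
        n_acid, n_base = self.counts[name]
        return n_acid + n_base


# ---------------------------------------------------------------------------
# Henderson-Hasselbalch core
# ---------------------------------------------------------------------------

def acid_base_ratio(pKa: float, pH: float) -> float:
    """Acid:base mole ratio ``10**(pKa - pH)`` of a weak acid at given pH.

    Strictly decreasing in pH and equal to 1 at pH == pKa.
    """
    if not (math.isfinite(pKa) and math.isfinite(pH)):
        raise ValueError(f"pKa and pH must be finite, got pKa={pKa}, pH={pH}")
    return 10.0 ** (pKa - pH)


def fraction_protonated(pKa: float, pH: float) -> float:
    """Protonated (neutral acid) fraction ``r / (1 + r)`` with ``r = 10**(pKa-pH)``.

    Computed in the numerically stable logistic form, so it never overflows
    even for pKa - pH of hundreds of log units.
    """
    if not (math.isfinite(pKa) and math.isfinite(pH)):
        raise ValueError(f"pKa and pH must be finite, got pKa={pKa}, pH={pH}")
    # r/(1+r) = 1/(1 + 10**(pH - pKa)), the logistic of (pKa-pH)·ln10
    x = (pH - pKa) * math.log(10.0)
    if x > 0:
        e = math.exp(-x)
        return e / (1.0 + e)
    return 1.0 / (1.0 + math.exp(x))


def fraction_deprotonated(pKa: float, pH: float) -> float:
    """Complement of :func:`fraction_protonated`."""
    return fraction_protonated(pH, pKa)  # logistic symmetry: swap roles


def mixture_protonation_percent(
    mix: MixtureComposition,
    pH: float,
    rounding: str = "none",
) -> float:
    """Overall protonation percentage of a mixture at the given pH.

    The mole-fraction-weighted average of per-species protonated fractions,
    times 100.  ``rounding`` is one of ``"none"`` (exact value), ``"floor"``
    (integer percent, rounded down — the convention behind printed integer
    percentages like "60 and 65% protonated"), or ``"nearest"``.
    """
    if rounding not in ("none", "floor", "nearest"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    percent = 100.0 * sum(
        x * fraction_protonated(sp.pKa, pH)
        for (sp, _), x in zip(mix.entries, mix.mole_fractions)
    )
    if rounding == "floor":
        return float(math.floor(percent))
    if rounding == "nearest":
        return float(math.floor(percent + 0.5))
    return percent


def assign_residue_counts(
    mix: MixtureComposition,
    totals: Mapping[str, int],
    pH: float,
    policy: str = "nearest",
    override: Mapping[str, tuple[int, int]] | None = None,
) -> ProtonationAssignment:
    """Split integer residue totals into protonated/deprotonated counts.

    Policies
    --------
    ``"nearest"``
        Round ``fraction * total`` to the nearest integer, half up.
    ``"floor"``
        Round down.
    ``"table_override"``
        Accept a user-supplied ``{name: (n_acid, n_base)}`` split; required
        because published residue tables do not always follow a single
        rounding rule.  The split must be consistent with ``totals``.
    """
    if policy not in ("nearest", "floor", "table_override"):
        raise ValueError(f"unknown policy {policy!r}")
    counts: dict[str, tuple[int, int]] = {}
    for sp, _ in mix.entries:
        if sp.name not in totals:
            raise ValueError(f"no total supplied for species {sp.name}")
        total = int(totals[sp.name])
        if total <= 0:
            raise ValueError(f"total for {sp.name} must be positive, got {total}")
        if policy == "table_override":
            if override is None or sp.name not in override:
                raise ValueError(f"table_override policy requires an override entry for {sp.name}")
            n_acid, n_base = override[sp.name]
            if n_acid + n_base != total:
                raise ValueError(
                    f"override for {sp.name} sums to {n_acid + n_base}, expected {total}"
                )
        else:
            ideal = fraction_protonated(sp.pKa, pH) * total
            n_acid = math.floor(ideal) if policy == "floor" else math.floor(ideal + 0.5)
            n_acid = min(max(int(n_acid), 0), total)
            n_base = total - n_acid
        counts[sp.name] = (int(n_acid), int(n_base))
    return ProtonationAssignment(counts=counts, pH=pH, policy=policy)


# ---------------------------------------------------------------------------
# Packaged species table
# ---------------------------------------------------------------------------

def load_species_table(path=None) -> dict[str, FattyAcidSpecies]:
    """Load a species table (TSV: name, n_carbons, pKa) into a dict by name.

    With no argument, the packaged default (LA/MA/PA/SA surface pKa values)
    is returned.
    """
    if path is None:
        src = resources.files("monomix.data").joinpath("species.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"name", "n_carbons", "pKa"}
    if not required.issubset(df.columns):
        raise ValueError(f"species table must have columns {sorted(required)}")
    out: dict[str, FattyAcidSpecies] = {}
    for row in df.itertuples(index=False):
        sp = FattyAcidSpecies(name=str(row.name), n_carbons=int(row.n_carbons), pKa=float(row.pKa))
        if sp.name in out:
            raise ValueError(f"duplicate species name {sp.name}")
        out[sp.name] = sp
    return out


def default_species() -> dict[str, FattyAcidSpecies]:
    """The packaged LA/MA/PA/SA species with their surface pKa values."""
    return load_species_table()


def load_table_counts() -> dict[float, dict[str, tuple[int, int]]]:
    """Packaged published per-pH residue splits ``{pH: {name: (acid, base)}}``.

    These integer counts come from a published residue table whose rounding
    does not follow a single rule; they are intended for use with the
    ``table_override`` policy of :func:`assign_residue_counts`.
    """
    src = resources.files("monomix.data").joinpath("residue_counts.tsv")
    with resources.as_file(src) as p:
        df = pd.read_csv(p, sep="\t")
    out: dict[float, dict[str, tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(float(row.pH), {})[str(row.name)] = (int(row.n_acid), int(row.n_base))
    return out
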
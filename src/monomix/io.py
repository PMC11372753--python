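"""Coordinate-file I/O, run configuration, and the end-to-end pipeline.

Frames are stored in standard coordinate formats (GRO, PDB, XYZ) through
MDAnalysis.  Species and protonation state ride in the residue name:
``LAU``/``MYR``/``PLM``/``STE`` for LA/MA/PA/SA, suffixed ``H`` (protonated)
or ``-`` (deprotonated); the headgroup atom is named ``C1`` while desorbed
molecules carry the atom name ``DUM``.  All in-memory coordinates are Å; GRO
files are nm on disk and converted exactly (×10).  Leaflets are assigned on
read by z relative to the box midplane.

The run configuration is a versioned YAML document (unknown keys rejected);
:func:`run_pipeline` executes the full analysis sequence — protonation
tables, synthetic trajectory generation, RDF + cutoff, graph metrics,
vertical structure, and a synthetic umbrella→WHAM stage — writing TSV
outputs plus a machine-readable JSON summary.
"""

from __future__ import annotations

import json
import logging
import math
import sys
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import network, protonation, structure
from .wham import langevin_windows as _langevin_windows
from .wham import wham as _solve_wham
from .protonation import MixtureComposition, default_species
from .synth import (MonolayerFrame, Trajectory, apply_staggering,
                    build_hexagonal_monolayer, demix_labels, desorb,
                    make_trajectory)

logger = logging.getLogger("monomix")

__all__ = [
    "SPECIES_TO_RESNAME",
    "RESNAME_TO_SPECIES",
    "write_frames",
    "read_frames",
    "RunConfig",
    "run_pipeline",
    "setup_logging",
]

SPECIES_TO_RESNAME = {"LA": "LAU", "MA": "MYR", "PA": "PLM", "SA": "STE"}
RESNAME_TO_SPECIES = {v: k for k, v in SPECIES_TO_RESNAME.items()}

PROTONATED_SUFFIX = "H"
DEPROTONATED_SUFFIX = "-"


def setup_logging(level: int = logging.INFO, logfile: Path | None = None) -> None:
    """Log to stderr, and optionally to a run log file."""
    logger.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(h)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
        logger.addHandler(fh)


# ---------------------------------------------------------------------------
# Residue-name encoding
# ---------------------------------------------------------------------------

def _encode_resname(species: str, protonated: bool) -> str:
    base = SPECIES_TO_RESNAME.get(species, species[:3].upper())
    return base + (PROTONATED_SUFFIX if protonated else DEPROTONATED_SUFFIX)


def _decode_resname(resname: str) -> tuple[str, bool]:
    resname = resname.strip()
    prot = True
    if resname.endswith(DEPROTONATED_SUFFIX):
        prot = False
        base = resname[:-1]
    elif resname.endswith(PROTONATED_SUFFIX) and resname[:-1] in RESNAME_TO_SPECIES:
        base = resname[:-1]
    else:
        base = resname
    if base in RESNAME_TO_SPECIES:
        return RESNAME_TO_SPECIES[base], prot
    warnings.warn(f"unknown residue name {resname!r}; treating as species 'other'")
    return "other", prot


# ---------------------------------------------------------------------------
# Frame writing / reading (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _xyz_name(species: str, protonated: bool, present: bool) -> str:
    # XYZ has no residue column: the whole label rides in the atom name,
    # with a trailing "X" marking a desorbed molecule
    return _encode_resname(species, protonated) + ("" if present else "X")


def _decode_xyz_name(name: str) -> tuple[str, bool, bool]:
    present = not name.endswith("X")
    base = name[:-1] if not present else name
    species, prot = _decode_resname(base)
    return species, prot, present


def _universe_from_frame(frame: MonolayerFrame, fmt: str = "gro"):
    import MDAnalysis as mda

    n = frame.n_molecules
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           residue_segindex=np.zeros(n, dtype=int), trajectory=True)
    if fmt == "xyz":
        names = [_xyz_name(s, pr, p) for s, pr, p in
                 zip(frame.species, frame.protonated, frame.present)]
    else:
        names = ["C1" if p else "DUM" for p in frame.present]
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", [_encode_resname(s, pr)
                                    for s, pr in zip(frame.species, frame.protonated)])
    u.add_TopologyAttr("resids", (frame.ids + 1).astype(int))
    u.dimensions = [frame.box[0], frame.box[1], frame.box[2], 90.0, 90.0, 90.0]
    u.atoms.positions = frame.positions
    return u


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("gro", "pdb", "xyz"):
        return suffix
    raise ValueError(f"cannot infer format from {path}; pass format explicitly")


def write_frames(traj: Trajectory | MonolayerFrame, path, format: str = "auto") -> None:
    """Write a frame or trajectory to GRO, PDB or XYZ.

    GRO holds a single frame; PDB (MODEL records) and XYZ accept
    trajectories.  XYZ does not store the box.
    """
    import MDAnalysis as mda

    if isinstance(traj, MonolayerFrame):
        traj = Trajectory(frames=[traj])
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "gro" and len(traj) > 1:
        raise ValueError("GRO holds a single frame; use PDB or XYZ for trajectories")
    u = _universe_from_frame(traj[0], fmt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # element guessing / resname truncation chatter
        with mda.Writer(str(path), n_atoms=u.atoms.n_atoms) as w:
            for frame in traj:
                u.atoms.positions = frame.positions
                w.write(u.atoms)


def read_frames(path, format: str = "auto",
                box: Sequence[float] | None = None) -> Trajectory:
    """Read a GRO/PDB/XYZ file into a :class:`Trajectory` (coordinates in Å).

    Species/protonation are decoded from residue names per the documented
    mapping, presence from the atom name, and leaflet from z relative to the
    box midplane.  XYZ carries no box or residue topology: supply ``box``
    (Å) or one is estimated from the coordinate extent, and species default
    to "other".
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))

    n = len(u.atoms)
    names = u.atoms.names if hasattr(u.atoms, "names") else np.array(["C1"] * n)
    if fmt == "xyz":
        decoded = [_decode_xyz_name(str(nm)) for nm in names]
        species = np.array([d[0] for d in decoded], dtype="U8")
        prot = np.array([d[1] for d in decoded], dtype=bool)
        present = np.array([d[2] for d in decoded], dtype=bool)
    else:
        if hasattr(u.atoms, "resnames"):
            decoded = [_decode_resname(rn) for rn in u.atoms.resnames]
        else:
            decoded = [("other", True)] * n
        species = np.array([d[0] for d in decoded], dtype="U8")
        prot = np.array([d[1] for d in decoded], dtype=bool)
        present = np.array([not str(nm).upper().startswith("DUM") for nm in names])
    ids = (u.atoms.resids - 1).astype(np.int64) if hasattr(u.atoms, "resids") else np.arange(n)

    # multi-MODEL PDB files carry one CRYST1 for all frames, which the
    # per-frame reader does not surface; grab it from the header directly
    file_box = None
    try:
        if u.dimensions is not None and u.dimensions[:3].min() > 0:
            file_box = np.array(u.dimensions[:3], dtype=float)
    except Exception:
        pass
    if file_box is None and fmt == "pdb":
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    abc = np.array([float(line[6:15]), float(line[15:24]),
                                    float(line[24:33])])
                    if abc.min() > 0:
                        file_box = abc
                    break

    frames = []
    for ts in u.trajectory:
        pos = u.atoms.positions.astype(float).copy()
        if ts.dimensions is not None and ts.dimensions[:3].min() > 0:
            b = np.array(ts.dimensions[:3], dtype=float)
        elif file_box is not None:
            b = file_box.copy()
        elif box is not None:
            b = np.asarray(box, dtype=float)
        else:
            span = pos.max(axis=0) - pos.min(axis=0)
            b = np.maximum(span + 1.0, 1.0)
            logger.warning("%s: no box information; estimated %s Å from extent", path, b.round(2))
        leaflet = np.where(pos[:, 2] >= b[2] / 2.0, "upper", "lower")
        frames.append(MonolayerFrame(
            ids=ids.copy(), species=species.copy(), protonated=prot.copy(),
            positions=pos, box=b.copy(), leaflet=leaflet, present=present.copy(),
        ))
    return Trajectory(frames=frames)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1

_ALLOWED_KEYS = {
    "": {"schema_version", "seed", "output_dir", "protonation", "synth",
         "network", "structure", "wham"},
    "protonation": {"pH_values", "composition", "totals"},
    "synth": {"n", "mma", "composition", "pH", "demix_J", "demix_sweeps",
              "stagger_protonated", "stagger_deprotonated", "stagger_jitter_sd",
              "desorb_fraction", "desorb_species", "n_frames", "xy_jitter_sd"},
    "network": {"species", "cutoff", "rdf_r_max", "rdf_bin_width", "connectivity"},
    "structure": {"deviation_bin", "density_bin"},
    "wham": {"potential", "kappa", "barrier", "half_width", "centers", "k",
             "n_steps", "dt", "grid"},
}


@dataclass
class RunConfig:
    """Validated, fully serializable pipeline configuration."""

    seed: int
    output_dir: Path
    protonation: dict
    synth: dict
    network: dict
    structure: dict
    wham: dict

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        unknown = set(raw) - _ALLOWED_KEYS[""]
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if int(raw.get("schema_version", _SCHEMA_VERSION)) != _SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {raw.get('schema_version')}")
        for section in ("protonation", "synth", "network", "structure", "wham"):
            extra = set(raw.get(section, {})) - _ALLOWED_KEYS[section]
            if extra:
                raise ValueError(f"unknown keys in [{section}]: {sorted(extra)}")
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", "monomix_out")),
            protonation=dict(raw.get("protonation", {})),
            synth=dict(raw.get("synth", {})),
            network=dict(raw.get("network", {})),
            structure=dict(raw.get("structure", {})),
            wham=dict(raw.get("wham", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {
            "schema_version": _SCHEMA_VERSION,
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "protonation": self.protonation,
            "synth": self.synth,
            "network": self.network,
            "structure": self.structure,
            "wham": self.wham,
        }


def default_demo_config() -> RunConfig:
    """The packaged demo configuration (small enough for a laptop minute)."""
    from importlib import resources

    src = resources.files("monomix.data").joinpath("demo_config.yaml")
    with resources.as_file(src) as p:
        return RunConfig.from_yaml(p)


def _composition_from_mapping(mapping: Mapping[str, float]) -> MixtureComposition:
    species = default_species()
    entries = []
    for name, ratio in mapping.items():
        if name not in species:
            raise ValueError(f"unknown species {name!r} (have {sorted(species)})")
        entries.append((species[name], float(ratio)))
    return MixtureComposition.from_pairs(entries)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Run generate → rdf → graph → structure → wham and write a report bundle.

    Outputs (TSV tables + ``summary.json``) land in ``config.output_dir``.
    Returns the summary dict.  Any stage failure raises after a ``FAILED``
    marker file is written; partial outputs are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "FAILED").unlink(missing_ok=True)
    setup_logging(logfile=out / "run.log")
    logger.info("pipeline start: seed=%d, output=%s", config.seed, out)
    summary: dict[str, Any] = {"seed": config.seed, "config": config.to_dict()}
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))

    try:
        # -- protonation tables -------------------------------------------
        p = config.protonation
        comp_map = p.get("composition", {"LA": 1, "MA": 2, "PA": 4, "SA": 3})
        mix = _composition_from_mapping(comp_map)
        ph_values = p.get("pH_values", [2.0, 7.0, 8.2])
        totals = p.get("totals")
        rows = []
        for ph in ph_values:
            for sp, _ in mix.entries:
                ratio = protonation.acid_base_ratio(sp.pKa, ph)
                frac = protonation.fraction_protonated(sp.pKa, ph)
                row = {"pH": ph, "species": sp.name, "pKa": sp.pKa,
                       "acid_base_ratio": ratio, "fraction_protonated": frac}
                rows.append(row)
            percent = protonation.mixture_protonation_percent(mix, ph)
            summary.setdefault("protonation", {})[str(ph)] = {
                "mixture_percent_protonated": percent,
                "mixture_percent_floor": math.floor(percent),
            }
        if totals:
            for ph in ph_values:
                asn = protonation.assign_residue_counts(mix, totals, ph, policy="nearest")
                for name, (na, nb) in asn.counts.items():
                    summary["protonation"][str(ph)].setdefault("counts", {})[name] = [na, nb]
        pd.DataFrame(rows).to_csv(out / "protonation.tsv", sep="\t", index=False)
        logger.info("protonation tables written (%d pH values)", len(ph_values))

        # -- synthetic trajectory -----------------------------------------
        s = config.synth
        mix_s = _composition_from_mapping(s.get("composition", {"LA": 1, "PA": 1}))
        frame = build_hexagonal_monolayer(
            n=int(s.get("n", 256)), mma=float(s.get("mma", 20.0)),
            composition=mix_s, seed=config.seed, pH=s.get("pH"),
        )
        if float(s.get("demix_J", 0.0)) > 0 and int(s.get("demix_sweeps", 0)) > 0:
            frame = demix_labels(frame, J=float(s["demix_J"]),
                                 n_sweeps=int(s["demix_sweeps"]), seed=config.seed + 1)
        offsets = {True: float(s.get("stagger_protonated", 0.0)),
                   False: float(s.get("stagger_deprotonated", -1.0))}
        frame = apply_staggering(frame, offsets,
                                 jitter_sd=float(s.get("stagger_jitter_sd", 0.3)),
                                 seed=config.seed + 2)
        if float(s.get("desorb_fraction", 0.0)) > 0:
            frame = desorb(frame, float(s["desorb_fraction"]),
                           species=s.get("desorb_species", "all"), seed=config.seed + 3)
        traj = make_trajectory(frame, n_frames=int(s.get("n_frames", 10)),
                               xy_jitter_sd=float(s.get("xy_jitter_sd", 0.4)),
                               seed=config.seed + 4)
        write_frames(traj, out / "trajectory.pdb")
        summary["synth"] = {"n_molecules": frame.n_molecules, "n_frames": len(traj),
                            "box": frame.box.tolist()}
        logger.info("generated %d frames of %d molecules", len(traj), frame.n_molecules)

        # -- RDF + cutoff ---------------------------------------------------
        nw = config.network
        r_max = float(nw.get("rdf_r_max", min(frame.box[0], frame.box[1]) / 2 - 0.01))
        r_max = min(r_max, min(frame.box[0], frame.box[1]) / 2 - 1e-9)
        rdf = network.compute_rdf(traj, ("all", "all"), r_max=r_max,
                                  bin_width=float(nw.get("rdf_bin_width", 0.1)))
        pd.DataFrame({"r": rdf.r, "g": rdf.g}).to_csv(out / "rdf.tsv", sep="\t", index=False)
        cutoff_cfg = nw.get("cutoff", "auto")
        if cutoff_cfg == "auto":
            cutoff = network.select_cutoff(rdf)
        else:
            cutoff = float(cutoff_cfg)
        summary["network"] = {"cutoff": cutoff}
        logger.info("cutoff: %.2f Å", cutoff)

        # -- graph metrics --------------------------------------------------
        species_list = nw.get("species") or sorted(set(frame.species.tolist()))
        metrics = network.metrics_over_trajectory(
            traj, species_list, cutoff=cutoff,
            connectivity=bool(nw.get("connectivity", True)))
        metrics.to_dataframe().to_csv(out / "graph_metrics.tsv", sep="\t", index=False)
        summary["network"]["summary"] = {
            sp: {m: list(v) for m, v in d.items()} for sp, d in metrics.summary.items()}
        logger.info("graph metrics written for %s", species_list)

        # -- vertical structure ---------------------------------------------
        st = config.structure
        profiles = structure.vertical_deviations(traj, bin_width=float(st.get("deviation_bin", 0.1)))
        dev_rows = [{"species": pr.species, "protonated": pr.protonated,
                     "mean": pr.mean, "sd": pr.sd, "n": pr.n_samples} for pr in profiles]
        pd.DataFrame(dev_rows).to_csv(out / "vertical_deviations.tsv", sep="\t", index=False)
        summary["structure"] = {"deviations": dev_rows}
        dens = structure.density_profile(traj, "all", bin_width=float(st.get("density_bin", 0.5)))
        pd.concat([pd.DataFrame({"leaflet": d.leaflet, "z": d.bin_centers, "density": d.density})
                   for d in dens]).to_csv(out / "density_profile.tsv", sep="\t", index=False)

        # -- umbrella → WHAM ------------------------------------------------
        w = config.wham
        pot_name = w.get("potential", "harmonic")
        pot_kwargs = {}
        if pot_name == "harmonic":
            pot_kwargs["kappa"] = float(w.get("kappa", 2.0))
        elif pot_name == "double_well":
            pot_kwargs["barrier"] = float(w.get("barrier", 4.0))
            pot_kwargs["half_width"] = float(w.get("half_width", 2.0))
        c = w.get("centers", {"start": -3.0, "stop": 3.0, "step": 0.5})
        centers = np.arange(float(c["start"]), float(c["stop"]) + 1e-9, float(c["step"]))
        windows = _langevin_windows(
            pot_name, centers, k=float(w.get("k", 10.0)),
            n_steps=int(w.get("n_steps", 5000)), dt=float(w.get("dt", 0.005)),
            seed=config.seed + 5, **pot_kwargs)
        grid = w.get("grid", {"xmin": -3.5, "xmax": 3.5, "bins": 100})
        pmf = _solve_wham(windows, (float(grid["xmin"]), float(grid["xmax"]), int(grid["bins"])))
        pd.DataFrame({"x": pmf.x, "G_kT": pmf.g}).to_csv(out / "pmf.tsv", sep="\t", index=False)
        summary["wham"] = {"iterations": pmf.iterations, "residual": pmf.residual,
                           "n_windows": len(windows)}
        logger.info("WHAM converged in %d iterations (residual %.2e kT)",
                    pmf.iterations, pmf.residual)

        summary["status"] = "ok"
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        logger.info("pipeline complete")
        return summary
    except Exception:
        (out / "FAILED").write_text("pipeline failed; see run.log\n")
        (out / "summary.json").write_text(json.dumps({**summary, "status": "failed"},
                                                     indent=2, default=str))
        logger.exception("pipeline failed")
        raise
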
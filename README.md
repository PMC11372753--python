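# monomix

Analysis toolkit for **mixed fatty-acid Langmuir monolayers** — the
surfactant films that coat sea-spray aerosol and the sea-surface
microlayer. It is written for researchers who simulate or model these
films (lauric/myristic/palmitic/stearic acid mixtures at
20–23 Å²/molecule, subphase pH 2–8.2) and need the standard computational
analyses as tested, reusable library code rather than one-off scripts:

- **Surface-pKa protonation model** — Henderson–Hasselbalch at the
  interface: acid:base ratio r = 10^(pKa−pH), protonated fraction
  r/(1+r), mole-fraction-weighted mixture percentages, and integer residue
  assignment for finite simulation patches.
- **Graph-network aggregation metrics** — 2D-periodic radial distribution
  functions of headgroup carbons, first-shell cutoff selection at the
  g(r) minimum between the first two peaks, per-species neighbor graphs,
  mean node degree and pair-averaged node connectivity κ.
- **Interface structure** — vertical deviations of headgroup C1 carbons
  from mean headgroup height by species × protonation (staggering),
  z-density profiles, geometric hydrogen-bond counting.
- **Umbrella sampling → PMF** — log-domain WHAM
  (P(x) = Σᵢhᵢ(x) / Σᵢnᵢe^{−β(Uᵢ(x)−fᵢ)}, G = −kT ln P), GROMACS-unit
  window files, and an overdamped-Langevin window sampler for validation.
- **Synthetic monolayer generator** — periodic hexagonal lattices at a
  prescribed mean molecular area, tunable demixing (label-swap Metropolis
  MC), vertical staggering, stochastic desorption, and GRO/PDB/XYZ I/O —
  so every analysis can be exercised end-to-end without an MD engine.

## Worked example

Protonation states of the quaternary 1:2:4:3 LA:MA:PA:SA aerosol proxy at
pH 7, with residue counts for a 200-molecule patch:

```sh
$ monomix protonate --ph 7 --composition LA:1,MA:2,PA:4,SA:3 \
    --totals LA:20,MA:40,PA:80,SA:60
species  pKa   mole_fraction  acid_base_ratio  fraction_protonated  n_acid  n_base
LA       7.44  0.1            2.754228703      0.733633702          15      5
MA       7.88  0.2            7.585775750      0.883528288          35      5
PA       8.34  0.4            21.87761624      0.956289152          77      3
SA       9.89  0.3            776.2471166      0.998713408          60      0
# mixture_percent_protonated  93.2199  (floor: 93)
```

Each row is one acid: its surface pKa, the Henderson–Hasselbalch acid:base
ratio at pH 7 (e.g. SA 776:1 — effectively fully protonated), the
protonated fraction, and a nearest-integer split of the requested residue
total. The mixture as a whole is 93.2 % protonated; the LA-free control
(`MA:2,PA:4,SA:3`) gives 95.4 %.

The same model from Python, plus the lattice-graph baseline:

```python
>>> from monomix import *
>>> from monomix.protonation import default_species, MixtureComposition
>>> sp = default_species()
>>> pure = MixtureComposition.from_pairs([(sp["LA"], 1)])
>>> frame = build_hexagonal_monolayer(100, 20.0, pure, seed=1)
>>> g = build_same_type_graph(frame, "LA", cutoff=7.2)
>>> mean_node_degree(g), mean_connectivity(g)
(6.0, 6.0)
```

A condensed hexagonal monolayer gives every molecule exactly 6 first-shell
neighbors; with random equimolar binary labels the *same-type* mean degree
drops to ≈ 3, rises toward 6 when demixing is switched on
(`demix_labels`, J ≳ 1.5 kT), and collapses toward 0 as one species
desorbs — the signatures the graph metrics are built to detect.

The full demo pipeline (generate → RDF → graph → structure → WHAM) runs
from the packaged configuration in well under a minute:

```sh
monomix run --out demo_out       # writes TSVs + summary.json + run.log
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline lattice-graph
quantities from scratch — the mean node degree of a 100-site
single-species hexagonal monolayer at 20 Å²/molecule (cutoff 7.2 Å), and
the seed-averaged same-type mean degree of random equimolar binary
labelings of a 1024-site lattice — and writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/monomix/protonation.py` — surface-pKa acid/base model
- `src/monomix/synth.py` — synthetic frames and trajectories
- `src/monomix/network.py` — RDF, cutoff, graphs, degree/connectivity
- `src/monomix/structure.py` — staggering, density, H-bonds
- `src/monomix/wham.py` — Langevin windows, WHAM, ΔG
- `src/monomix/io.py`, `cli.py` — formats, config, pipeline, CLI
- `docs/methods.md` — model and algorithm documentation
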
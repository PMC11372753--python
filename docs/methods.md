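# Methods

`monomix` analyzes mixed fatty-acid Langmuir monolayers of the kind used as
proxies for the organic films coating sea-spray aerosol: saturated acids of
mixed chain length (lauric C12, myristic C14, palmitic C16, stearic C18)
spread at an air–water interface, at mean molecular areas (MMA) around
20–23 Å²/molecule and subphase pH between 2 (aged aerosol) and 8.2
(seawater). The package implements four analyses — surface-pKa protonation
modelling, graph-network aggregation metrics, vertical headgroup structure,
and umbrella-sampling → WHAM free-energy profiles — together with a
synthetic-configuration generator that replaces molecular-dynamics output
for testing and validation.

## Protonation model

A carboxylic headgroup at the interface dissociates with an effective
*surface* pKa well above the bulk value. Given pKa and pH, the
Henderson–Hasselbalch relation fixes the acid:base mole ratio

    r = [HA]/[A⁻] = 10^(pKa − pH),   f_protonated = r / (1 + r).

The packaged species table carries the surface pKa values LA 7.44, MA 7.88,
PA 8.34, SA 9.89. The protonated fraction is evaluated in logistic form, so
it is exact and overflow-free for any pKa − pH. For a mixture, the overall
protonation percentage is the mole-fraction-weighted mean of per-species
fractions; a `floor` rounding mode matches the convention behind printed
integer percentages, and the unrounded value is always available.

Two conventions deserve note. First, monolayers on a pH 5.6 subphase are
conventionally *simulated* at pH 7 protonation fractions: with ~100
molecules per leaflet, acid:base ratios of 69:1 (LA) and larger are
indistinguishable from fully protonated, so pH 7 (~95 % protonated) is used
as an intermediate stage between pH 2 and pH 8.2. The package keeps pH a
free parameter and leaves this substitution to the caller. Second,
converting fractions to integer residue counts for a finite patch is
rounding-rule dependent, and published count tables do not follow any single
rule (counts also vary with MMA); `assign_residue_counts` defaults to
nearest-integer (half-up) rounding and offers a `table_override` policy,
with one published split packaged as a TSV fixture.

## Synthetic monolayer generator

The generator produces the *stated world* the analyses assume, not MD
physics:

- **Lattice.** Condensed fatty-acid monolayers pack hexagonally, so frames
  are triangular lattices with lattice constant a = √(2·MMA/√3) (4.81 Å at
  20 Å²/molecule), embedded in a rectangular periodic cell (rows √3·a/2
  apart, even row count) — rectangular minimum-image code is simpler than a
  rhombic cell and the analyses only need the periodic metric. Every site
  has exactly 6 first-shell neighbors. Site counts must tile
  (rows × cols); the error for an untileable n lists nearby valid sizes.
- **Mixing/demixing.** Species labels are assigned i.i.d. by mole fraction,
  then optionally driven toward same-type domains by label-swap Metropolis
  Monte Carlo with energy −J per same-type first-shell pair (J in kT).
  Swap dynamics conserve composition exactly; J = 0 is measure-preserving
  (checked by chi-square over seeds), J ≳ 1.5 forms connected domains. The
  inner loop is numba-jitted with a pure-Python fallback.
- **Staggering.** Vertical offsets per (species, protonation) plus Gaussian
  jitter model the chain-length- and charge-dependent headgroup heights of
  real mixed films (deprotonated headgroups sit toward the water). For the
  lower leaflet the offset sign is flipped so "negative = toward water"
  holds in both leaflets.
- **Desorption.** A seeded uniform choice of molecules is flagged
  `present = False` rather than deleted, preserving identity across frames
  the way molecules leaving/rejoining the interface do.
- **Trajectories.** Frames 1..n−1 add independent Gaussian jitter to the
  base frame (a stationary ensemble around the lattice, mimicking thermal
  vibration of a condensed film) — there is no actual dynamics, so time
  correlations of real MD are *not* emulated. Frame 0 is the input frame.

Defaults (MMA 20 Å², equimolar or 1:2:4:3 compositions, 0.3–0.4 Å jitter)
mirror the condensed-phase systems the analyses target. A green test on
this generator establishes correctness of the analysis code on
lattice-like, uncorrelated-frame data; it does not validate force-field
realism, tail packing, tilt, or ion effects, none of which are modelled.

All randomness flows from one explicit integer seed per operation (numpy
`default_rng`); no global state.

## Aggregation networks

The pipeline mirrors standard practice for quantifying lateral aggregation:

1. **RDF.** g(r) between headgroup positions, minimum-image distances in
   the xy plane only, each leaflet pooled separately, standard 2D annulus
   normalization. z is excluded deliberately: staggered headgroups would
   distort neighbor shells, and lateral organization is the target
   quantity.
2. **Cutoff.** The first-shell cutoff is the g(r) minimum strictly between
   the first two peaks (moving-average smoothing, window 5 bins of 0.1 Å;
   scipy peak finding with prominence 0.2). For condensed monolayers this
   lands between the shells at a and √3·a (7.2/7.4 Å are the established
   values at high/low surface pressure, packaged as defaults). A
   structureless profile raises `NoCutoffError` — the caller must supply a
   cutoff.
3. **Graphs.** Per frame, per species: nodes are present molecules, edges
   all pairs within the cutoff (periodic k-d tree; an O(n²) brute-force
   oracle backs it in the tests).
4. **Metrics.** Mean node degree (2E/N; 0 for an empty graph) and mean
   connectivity. "Connectivity" is implemented as the pair-averaged local
   node connectivity — for each unordered node pair the maximum number of
   internally vertex-disjoint paths, 0 for pairs in different components —
   because the per-node edge-cut reading of the phrase ("edges removed to
   disconnect a node") collapses onto the degree and would duplicate the
   other metric. Both readings are exposed (`mean_connectivity`,
   `min_edge_cut_per_node`); the pair-averaged one is the default and is
   O(n² max-flow), the cost driver for large frames (`connectivity=False`
   skips it).

On a 6-coordinated lattice with random equimolar binary labels the expected
same-type degree is 6·(n/2−1)/(n−1) → 3, the well-mixed baseline;
demixing pushes it toward 6 and desorption drives degree and connectivity
toward 0.

## Vertical structure

Headgroup staggering is measured as the deviation of each headgroup z from
the per-leaflet, per-frame mean headgroup height (per frame so drift cannot
bias it), sign-fixed so negative means toward the aqueous side. Deviations
are pooled over frames and histogrammed by species × protonation.
z-density profiles are frame-averaged per leaflet and integrate to the mean
selected-molecule count.

Hydrogen bonds are counted geometrically on explicit donor/H/acceptor
triples: donor–acceptor distance ≤ 3.5 Å and donor–H–acceptor angle ≥ 150°
by default — a standard geometric criterion chosen because published H-bond
counts for these systems do not state one; both thresholds are
user-overridable. Counts are classed head–head same-species, head–head
cross-species, and head–water.

## Umbrella sampling → WHAM

Windows biased by U_i(x) = ½k_i(x − x0_i)² are combined by iterating the
standard WHAM equations

    P(x_b) = Σ_i h_i(x_b) / Σ_i n_i e^{−β(U_i(x_b) − f_i)},
    e^{−βf_i} = Σ_b P(x_b) e^{−βU_i(x_b)}

(Jacobi fixed point from f_i = 0, tolerance 1e-6 kT on max |Δf|, max 1e5
iterations), then G = −kT ln P shifted so min G = 0. All sums are
log-domain (log-sum-exp), so force constants up to the hundreds of
kJ mol⁻¹ nm⁻² used in practice cannot underflow. P is renormalized every
pass, which fixes the gauge freedom (P·c, f_i + ln c) that otherwise lets
the shifts drift and stalls convergence. Bins never visited stay masked
(NaN), not interpolated. Windows whose histogram supports split into
disjoint groups are rejected up front with pairwise overlap diagnostics:
the fixed point would still converge within each group, but the relative
shifts are undetermined, so returning a stitched profile would be wrong.

Internal units are Å and kT at 298.15 K (kT = 2.4789 kJ/mol); window files
on disk use the GROMACS conventions (kJ mol⁻¹ nm⁻² force constants,
conversion exact). Synthetic windows come from overdamped Langevin
(Euler–Maruyama) dynamics under a named test potential (flat, harmonic ½κx²,
or the double well h((x/b)² − 1)² whose analytic barrier is h), started at
each bias center, default dt 0.005 with a stability guard dt·k/γ < 0.1, and
the first 10 % of steps discarded as burn-in. Because overdamped Langevin
sampling is exactly Boltzmann, the recovered PMF must match the generating
potential — the package's validation route for the WHAM stage (harmonic
RMSE < 0.1 kT; double-well barrier within 5 %).

`delta_g` reports G(b) − G(a) using the minimum defined G within each
region (or interpolation at a point), positive meaning b uphill of a.

## File formats and pipeline

GRO, PDB and XYZ I/O is delegated to MDAnalysis. Species and protonation
ride in the residue name (LAU/MYR/PLM/STE + suffix `H`/`-`), presence in
the atom name (`C1` vs `DUM`); XYZ, having no residue column, carries the
whole label in the atom name with a trailing `X` for desorbed molecules.
Coordinates are Å in memory (GRO nm on disk, exact ×10); leaflets are
assigned on read by z relative to the box midplane, and the generator
places leaflets on the matching side so round trips preserve them. GRO
holds one frame; PDB (MODEL records) and XYZ hold trajectories. XYZ loses
the box — pass one explicitly or an extent-based estimate is used with a
warning.

The run configuration is versioned YAML with unknown keys rejected
(fail-fast); `run_pipeline` executes protonation → generate → RDF/cutoff →
graph metrics → vertical structure → Langevin/WHAM, writing TSVs, a
`summary.json`, a copy of the config, and a run log; any failure leaves a
`FAILED` marker with partial outputs retained. The packaged demo config
(144 sites, 5 frames, 13 umbrella windows of 4000 steps) runs in ~15 s on
one CPU; the scale is chosen so the max-flow connectivity metric stays
cheap, and every conclusion it illustrates is re-checked at larger n in the
test suite.

## Numerical choices and limitations

- Rounding: `nearest` residue assignment breaks ties half-up,
  deterministically.
- The equimolar-degree baseline and all stochastic tests use fixed seeds;
  tolerances are 3-standard-error bands or the stated acceptance bands.
- Tilted condensed phases (MMA 23 Å²) are represented only by their lower
  site density; molecular tilt itself is not modelled, as only headgroup
  positions enter the in-scope analyses.
- The steered-MD and adaptive-biasing protocols that produce real umbrella
  start configurations are out of scope; only their documented parameters
  appear as window metadata. Bootstrap error bars on PMFs are not
  implemented.
- Pair-averaged connectivity is exact, not sampled; its O(n² max-flow)
  cost limits routine use to a few hundred nodes per species per frame.
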
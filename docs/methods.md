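# Methods

## The model

`ctdphase` represents a CTD construct as one bead per residue (plus one side
bead per phosphoserine) and evolves it with underdamped Langevin dynamics.
The model is a deliberately minimal sticker-and-spacer analog of
residue-resolved coarse-grained simulation: it is built to reproduce
*orderings* — which variants condense, which dissolve, which chain is more
compact — and to feed the same analysis layer (scaling fits, clustering,
turn classification) that full-resolution trajectories would, not to be
quantitative about free energies.

Units: nm, kJ/mol, ps, amu, elementary charges, K. With these units
1 amu·nm²/ps² = 1 kJ/mol.

### Nonbonded interactions

For beads i, j at distance r:

U(r) = U_rep(r) + ε_ij·u_att(r) + U_elec(r), each term exactly zero at and
beyond the 1.1 nm cutoff.

- **U_rep** — Weeks–Chandler–Andersen core (the repulsive branch of a 12-6
  potential truncated at its minimum and shifted up), depth `eps_rep` = 1
  kJ/mol, identical for all types. Pair contact diameters are
  Lorentz-combined from per-type values (default σ = 0.40 nm).
- **u_att** — the attractive branch of the 12-6 shape, cut and shifted so it
  reaches zero continuously at the cutoff; at the potential minimum the pair
  energy is −ε_ij plus the (small, positive) cutoff shift.
- **ε_ij** — geometric mean of per-type well depths, divided by
  `solvation_scale`. The per-type depths carry the sticker hierarchy:
  tyrosine 9.5, phenylalanine 6.8, spacers (S, P, T, hydroxyproline) 1.0,
  glycine 0.6, alanine 0 kJ/mol. Alanine is purely repulsive, which is what
  makes the Y1A variant a non-sticker chain.
- **U_elec** — Debye–Hückel screened Coulomb, shifted to zero at the cutoff.
  The screening length (0.788 nm) comes from 150 mM 1:1 salt in water at
  300 K; the Coulomb prefactor uses a reduced implicit-medium dielectric
  (ε_r = 15, the value residue-resolved coarse-grained force fields use for
  implicit screening). Only phosphate side beads carry charge (−1 or −1.5 e,
  the singly/doubly-deprotonated approximations).

### Bonded terms and construct chemistry

- Backbone bonds: harmonic, r₀ = 0.38 nm, k = 10⁴ kJ/mol/nm². The stiff
  constant keeps every bond within 20% of r₀ in every saved frame (the
  thermal fluctuation is ~4.8 σ below that band).
- Phosphoserine: an extra side bead bonded at 0.319 nm (the lengthened
  phospho side-chain bond; the unmodified side-chain value would be
  0.287 nm). The bead is non-sticky, charged, and bulky (σ = 0.95 nm),
  representing the intense hydration shell of the dianionic phosphate.
  Phosphorylated constructs are additionally simulated with
  `solvation_scale` raised from 1.1 to 1.35
  (`InteractionParams.with_phospho_solvation()`): preferential hydration of
  the phosphate weakens effective protein–protein attraction of the whole
  chain, the same lever (in the same direction) as the protein–water
  upscaling used to de-compact disordered proteins in coarse-grained force
  fields. This combination — sterics, charge, solvation — is what makes
  phospho-S5/S7 droplets dissolve; the screened charges alone are
  energetically negligible at droplet densities (tens of kJ/mol against
  thousands of cohesion), which is expected when counterion entropy, the
  dominant physical driver, is integrated out.
- Cis-proline β-turn bias: every SPXX motif whose proline/hydroxyproline is
  flagged cis carries a harmonic restraint between the motif's first and
  fourth backbone beads (k = 100 kJ/mol/nm², r₀ = 0.5 nm) — the
  conformational consequence of the cis isomer, which compacts the chain.
  Isomer states are fixed per run, never dynamic.
- Hydroxyproline ('O') has proline's interaction parameters; its distinct
  behaviour enters only through which isomer states one assigns (it
  disfavours cis), not through extra chemistry.

All defaults live in `src/ctdphase/data/default_params.toml` (version
1.0.0). They were calibrated once, against the qualitative panel below at
the default desk-scale conditions, then frozen.

### Integrator and initial conditions

BAOAB splitting of Langevin dynamics (friction default 0.15–1.0 /ps,
timestep 0.01 ps, bead mass 100 amu), chosen because its sampled kinetic
temperature can be tested directly against the thermostat target (the
time-averaged kinetic temperature stays within 3% after burn-in). A short
clamped steepest-descent minimization precedes dynamics so freshly inserted
configurations do not inject placement strain as heat. Identical seed and
configuration give bit-identical trajectories.

Initial conditions: `random_insertion` grows chains as non-overlapping
random walks in the box; `make_preformed_condensate` grows all chains
round-robin inside a sphere sized for ~4 beads/nm³ so chains interpenetrate.
A *preformed condensate* for dissolution runs is always the final frame of a
consensus relaxation run started from that ball; phosphorylated systems
inherit the backbone frame and attach their side beads to it
(`initial_from_backbone`). NVT only; orthorhombic periodic boxes;
minimum-image convention everywhere.

### Calibrated qualitative panel

At 10 chains × 4 heptads (12 nm box for preformed runs, 9 nm for spontaneous
condensation; 15–20k steps):

- consensus chains condense from random insertion, Y1A chains do not;
- a preformed consensus condensate persists (mean largest-cluster fraction
  ≥ 0.8 at contact cutoff 0.6 nm, cluster threshold 20) while Y1A and
  phospho-S5 systems decay below 0.5;
- cis-proline di-heptads have smaller mean Rg than trans.

These are direction-of-effect statements; the desk-scale model makes no
claim about absolute densities, time scales or phase boundaries.

## Analyses

### Internal-distance scaling and the Flory exponent

`internal_distance_profile` reports, per residue separation s, the
root-mean-square distance over all conformations and residue pairs. RMS
(rather than the arithmetic mean distance) is the default because the
ideal-chain relation r(s) = b·√s is then exact, so the two-parameter fit
recovers the generating Kuhn length without the √(8/3π) ≈ 0.92 amplitude
bias the mean carries; `statistic="mean"` is available.

`fit_flory` fits log r = log b + ν·log s by weighted least squares:

- *paper* mode clamps b (default 0.55 nm, the standard Kuhn length for
  disordered proteins) and uses only separations above 200 peptide bonds;
- *free* mode fits (b, ν) jointly, default window s > 10;
- weights ∝ n_pairs/s approximate the number of statistically independent
  segments contributing at each separation. They leave noiseless power laws
  exact (the fit is machine-precision exact on constructed profiles) and
  stabilise the noisy large-s tail; without them the recovered Kuhn length
  scatters by ±0.03 nm at a few hundred chains.
- an optional `max_sep` restricts the window; for self-avoiding statistics
  the asymptotic internal regime requires s ≪ N (chain-end corrections pull
  the apparent slope down toward s → N), and a cap near N/6 is the
  recommended window. Replica lists produce mean ± SD of the fitted
  parameters.

Reference ensembles provide ground truth without dynamics: Gaussian-step
ideal chains (ν = 1/2 exactly in expectation), cubic-lattice self-avoiding
walks sampled by the pivot algorithm (24 proper octahedral rotations;
ν ≈ 0.588), collapsed chains built as random contiguous segments of a 3-D
Hilbert curve through a close-packed lattice region, randomly rotated and
jittered (exact r ~ s^(1/3) locality at all scales, which a greedy path
through a sphere does not have), and rods (ν = 1 exactly).

### β-turn (SPXX) classification

A motif's compactness is the distance between its first and fourth backbone
beads (the Cα1–Cα4 distance at bead resolution): strictly below 0.7 nm is
*compact*, at or above is *extended*. The AUC ratio is the empirical
count-below over count-above (∞, flagged, when nothing lies above) — counts
rather than a smoothed density, because no smoothing kernel choice can then
change the number. The synthetic mixture generator truncates its compact
component to (0, 0.7) nm and its extended component to (0.7, ∞), so the
expected below-cutoff fraction equals the mixing weight exactly and the
classifier's recovery can be tested to binomial precision.

### Energy maps

`residue_energy_map` time-averages the full nonbonded pair energy
(attraction + excluded volume + electrostatics) and aggregates beads to
residues, phospho side beads onto their serine. The map is symmetric, zero
for pairs never within the cutoff, its upper-triangle sum equals the
trajectory-averaged nonbonded + electrostatic total, and entries at or below
−7.0 kJ/mol are flagged (boundary inclusive).

### Chain clustering

A contact is a bead pair from distinct chains with minimum-image distance
*strictly* below 0.6 nm; chains are joined when their pair count *strictly*
exceeds the threshold (20/50/80), both boundaries read literally from
"within" and "more than". Clusters are connected components of that graph
(scipy's csgraph; tests cross-check against networkx exhaustively up to 12
chains). The alternative reading — a chain joining when its contacts summed
over cluster members exceed the threshold — is available as
`mode="aggregate"` (order-independent hierarchical merging). The first half
of condensed-phase trajectories is discarded as equilibration by default.
`dissolution_metric` summarises a largest-cluster series with its mean
fraction, a two-sided Mann–Kendall trend and the first frame at or below
half the chains (NaN when never reached).

### Droplet imaging

The synthetic generator renders elliptical intensity plateaus with a
quarter-pixel logistic edge (sharp enough that any mid-range global
threshold reproduces the rasterized pixel-count truth; real diffraction
blur is *not* emulated), constant background and Gaussian noise, clipped to
[0, 1], with the rasterized area of each droplet as ground truth.
Quantification: min–max normalization, Otsu threshold on a 256-bin
histogram (tests verify equality with an exhaustive between-class-variance
search), 8-connected labelling, equivalent-diameter window 4–70 px,
eccentricity ≤ 0.6 (moment-ellipse definition: 0 = circle, 1 = line
segment; elongated aggregates are discarded), median normalized intensity
in 0.1–1, area × 0.010645 µm²/px, median and integrated intensity per
object. An optional distance-transform watershed (`declump=True`, logged)
splits touching droplets; it is off by default because the synthetic
fixtures are generated well-separated and watershed can oversplit noisy
discs. Assay statistics are computed from per-measurement medians — never
pooled droplets — with mean ± SD of the medians and a pooled-variance
unpaired two-sided t-test (`welch=True` for the unequal-variance form);
significance tiers ns/*/**/***/**** at 0.05/0.01/0.001/0.0001. The
intensity filters apply to per-image normalized intensities; droplet "size"
is area in µm² (equivalent diameter is also emitted).

## Problem sizes

Defaults throughout target a laptop CPU: condensed-phase checks run
10 chains × 4 heptads (302 beads with phospho side beads) for 15–20k steps;
scaling benchmarks use 366-residue ensembles of 150–1000 conformations;
micrograph fixtures are 512² px (the full-frame default is 2048²). Larger
systems only change wall time, not code paths.

## Known limitations

- One bead per residue: no hydrogen bonds, no secondary structure, no
  backbone/side-chain energy decomposition; the β-turn bias is imposed, not
  emergent.
- Implicit solvent with Debye–Hückel screening integrates out counterions;
  phospho-driven dissolution therefore leans on the solvation scaling (see
  above) rather than on explicit electrostatic self-energy.
- NVT only, no barostat; cis/trans states are fixed inputs, so isomerization
  kinetics and isomerase action are out of scope.
- Cluster-fraction time series at 10 chains are intrinsically coarse (one
  chain = 0.1); the calibrated panel compares second-half means under
  pinned seeds.
- The micrograph generator does not emulate diffraction blur, uneven
  illumination or camera noise statistics; passing its recovery tests shows
  the pipeline's bookkeeping is right, not that it is robust to real optics.
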
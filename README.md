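# ctdphase

Desk-scale modelling and analysis of RNA polymerase II CTD phase separation.

The carboxy-terminal domain (CTD) of the largest RNA polymerase II subunit is
an intrinsically disordered tail of 52 tandem heptad repeats with consensus
Y1-S2-P3-T4-S5-P6-S7. Its liquid–liquid phase separation follows a
sticker-and-spacer grammar: uniformly spaced tyrosines act as the attractive
*stickers*, while the serine/proline/threonine *spacers* tune those
interactions — through the β-turn-forming SPXX motifs, the cis/trans
isomerization of the prolines, and phosphorylation of serine-5/7, which
dissolves CTD condensates. `ctdphase` packages the computational side of this
problem for laptop-scale work:

- **Construct building** (`ctdphase.sequences`) — the consensus and the full
  variant panel (Y1F, Y1A, P3G, T4G, serine→alanine singles/doubles/triple,
  hydroxyproline, phospho-S5/S7), with phospho-charge, isomer-state and SPXX
  motif annotation.
- **A bead-per-residue sticker-and-spacer simulator**
  (`ctdphase.forcefield`, `ctdphase.simulate`) — WCA excluded volume plus a
  cut-and-shifted attractive well with the Y > F > spacer hierarchy,
  Debye–Hückel electrostatics for phosphoserine side beads, harmonic β-turn
  biases for cis-proline SPXX motifs, and a BAOAB Langevin integrator in an
  orthorhombic periodic box.
- **Reference ensembles** (`ctdphase.ensembles`) — ideal chains, pivot-sampled
  self-avoiding walks, Hilbert-curve globules and rods with known scaling
  exponents, plus a truncated-normal generator for SPXX Cα1–Cα4 distances.
- **Single-chain analyses** (`ctdphase.chain_analysis`) — internal-distance
  profiles and the Flory scaling fit r(s) = b·s^ν (prefactor clamped to the
  0.55 nm Kuhn length or fitted freely), radius of gyration, per-residue
  interaction-energy maps (−7.0 kJ/mol highlight), and the strict-0.7 nm
  compact/extended β-turn classifier with AUC ratios.
- **Condensed-phase analyses** (`ctdphase.condensate`) — inter-chain contact
  counting (strict 0.6 nm cutoff), threshold clustering (edges where a chain
  pair shares *more than* 20/50/80 contacts), largest-cluster time series and
  dissolution summaries.
- **Droplet imaging** (`ctdphase.imaging`) — a synthetic fluorescence
  micrograph generator with rasterized ground truth, and the quantification
  pipeline: global Otsu threshold, 4–70 px diameter window, eccentricity ≤ 0.6
  and median-intensity filters, px → µm² conversion (0.010645 µm²/px),
  per-measurement medians and unpaired two-sided t-tests.
- **I/O** (`ctdphase.trajio`) — annotated XYZ trajectories, PDB export, TOML
  run configs with content hashes and provenance logging.

Everything runs on synthetic data generated by the package itself; no
external datasets are required.

## Worked example

`examples/condensate_dissolution.py` relaxes a ten-chain consensus droplet
(4 heptads per chain, 12 nm box), then restarts it either unchanged or with
every serine-5 phosphorylated (−1.5 e side beads, enhanced solvation):

```
relaxing a 10-chain consensus condensate ...
 cons: largest-cluster fraction start 1.00, steady-state 0.85
  pS5: largest-cluster fraction start 0.70, steady-state 0.35
```

The consensus droplet stays one cluster holding ~85% of the chains (largest
cluster at the 0.6 nm contact cutoff, >20-contact edges), while the
phosphorylated system falls apart into small clusters — the simulated
counterpart of kinase-driven droplet dissolution. The other examples print,
among others:

```
ensemble  nu_fit  b_fit   nominal          # examples/flory_scaling.py
   ideal   0.505  0.542   1/2
     rod   1.000  0.550   1
 globule   0.334  0.673   1/3
     saw   0.595  0.610   ~0.588 (3/5)

  cons: nu = 0.473                         # examples/single_chain_compaction.py
   Y1A: nu = 0.739
  trans-trans: Rg = 0.647 +/- 0.125 nm
      cis-cis: Rg = 0.577 +/- 0.043 nm
```

i.e. the scaling machinery recovers each reference exponent, losing the
tyrosine sticker swells a single chain, and cis-proline β-turn biases
compact it.

## Layout

```
src/ctdphase/        library modules (+ data/default_params.toml, the frozen
                     calibrated force-field defaults)
examples/            one narrative script per capability
tests/               pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py
docs/methods.md      model assumptions, parameter choices, limitations
```
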
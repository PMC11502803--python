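# Versioned default interaction parameters for the desk-scale
# sticker-and-spacer CTD model.  Energies kJ/mol, lengths nm.
#
# The type epsilons encode the sticker hierarchy Y > F > spacers, with
# alanine fully non-sticky; pair well depths are geometric means divided
# by the solvation scaling.  The phosphate side bead ('p') is modelled as
# a charged, strongly hydrated, bulky group: zero attraction, enlarged
# contact diameter, and - applied per construct - an increased solvation
# scaling (phospho_solvation_scale) in the spirit of the protein-water
# upscaling the reference coarse-grained model uses.  The Coulomb
# prefactor uses a Martini-like implicit-medium dielectric; the Debye
# screening length comes from 150 mM aqueous salt.
#
# Calibrated once so the qualitative condensation/dissolution and
# compactness orderings hold at the default desk-scale conditions
# (10 chains x 4 heptads, 12 nm box), then frozen.

[meta]
version = "1.0.0"

[type_eps]
Y = 9.5
F = 6.8
S = 1.0
P = 1.0
O = 1.0
T = 1.0
G = 0.6
A = 0.0
p = 0.0

[type_sigma]
p = 0.95

[interaction]
sigma = 0.40
cutoff = 1.1
eps_rep = 1.0
solvation_scale = 1.1
phospho_solvation_scale = 1.35
temperature = 300.0
dielectric = 15.0
solvent_dielectric = 78.5
ionic_strength = 0.15
bond_length = 0.38
phospho_bond_length = 0.319
bond_k = 10000.0
turn_bias_strength = 100.0
turn_bias_r0 = 0.5
bead_mass = 100.0
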
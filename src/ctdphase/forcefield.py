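"""Sticker-and-spacer interaction model and per-chain topology.

One bead per residue.  The nonbonded potential between beads i and j is

    U(r) = U_rep(r) + eps_ij * u_att(r) + U_elec(r)

where U_rep is a Weeks-Chandler-Andersen repulsive core (excluded volume,
identical for all bead types), u_att is the attractive branch of a 12-6
potential cut and shifted to reach exactly zero at the cutoff, and U_elec
is a Debye-Hueckel screened Coulomb term (also shifted to zero at the
cutoff).  The pair well depths eps_ij carry the sticker hierarchy
tyrosine > phenylalanine > spacer residues, with alanine fully non-sticky;
they are divided by ``solvation_scale`` to mimic enhanced protein solvation
(the analog of upscaling protein-water attraction in the reference
coarse-grained model).

Phosphoserine carries an extra charged side bead bonded at 0.319 nm (vs
the 0.287 nm plain side-chain bond the reference model uses), and SPXX
motifs whose proline is in the cis state carry a harmonic bias pulling the
motif's first and fourth backbone beads together — the beta-turn-forming
effect of the cis isomer.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .core import KE, debye_length
from .sequences import CTDSequence, find_spxx_motifs

_TWO16 = 2.0 ** (1.0 / 6.0)


def load_default_params() -> dict:
    """Raw contents of the versioned default parameter file."""
    text = resources.files("ctdphase.data").joinpath("default_params.toml").read_text()
    return tomllib.loads(text)


@dataclass
class InteractionParams:
    """Interaction parameters (lengths nm, energies kJ/mol).

    type_eps : per-bead-type attractive well depth; pair depths are the
        geometric mean, overridable via ``pair_eps_overrides``.
    sigma : default bead contact diameter; per-type overrides in
        ``type_sigma`` combine by the arithmetic (Lorentz) mean, letting a
        bulky hydrated group (the phosphate side bead) exclude more volume.
    cutoff : nonbonded cutoff; every nonbonded term is exactly 0 beyond it.
    eps_rep : depth scale of the WCA excluded-volume core.
    solvation_scale : divides all pair well depths (>1 weakens effective
        protein-protein attraction, the direction of the reference model's
        1.1x protein-water upscaling).
    debye_len : screening length from 150 mM salt unless overridden.
    turn_bias_strength : harmonic constant (kJ/mol/nm^2) of the cis-proline
        beta-turn bias on SPXX Ca1-Ca4 analog distances.
    turn_bias_r0 : rest length of that bias (compact turn geometry).
    """

    type_eps: dict = field(default_factory=dict)
    pair_eps_overrides: dict = field(default_factory=dict)
    type_sigma: dict = field(default_factory=dict)
    sigma: float = 0.45
    cutoff: float = 1.1
    eps_rep: float = 1.0
    solvation_scale: float = 1.1
    phospho_solvation_scale: float = 1.35
    temperature: float = 300.0
    dielectric: float = 78.5
    solvent_dielectric: float = 78.5
    ionic_strength: float = 0.150
    debye_len: float | None = None
    bond_length: float = 0.38
    phospho_bond_length: float = 0.319
    bond_k: float = 10000.0
    turn_bias_strength: float = 100.0
    turn_bias_r0: float = 0.50
    bead_mass: float = 100.0
    version: str = "unversioned"

    def __post_init__(self):
        if not (self.cutoff > self.sigma > 0):
            raise ValueError("require cutoff > sigma > 0")
        if self.debye_len is None:
            # screening length set by the salt in the aqueous phase; the
            # Coulomb prefactor uses `dielectric`, which may be lowered to
            # mimic the weaker dielectric response of the protein-rich medium
            self.debye_len = debye_length(self.ionic_strength, self.temperature,
                                          self.solvent_dielectric)

    @classmethod
    def default(cls) -> "InteractionParams":
        """Parameters from the versioned default parameter file."""
        raw = load_default_params()
        kw = dict(raw.get("interaction", {}))
        kw["type_eps"] = dict(raw.get("type_eps", {}))
        kw["type_sigma"] = dict(raw.get("type_sigma", {}))
        kw["pair_eps_overrides"] = {
            tuple(sorted(k.split(","))): v
            for k, v in raw.get("pair_eps_overrides", {}).items()
        }
        kw["version"] = raw.get("meta", {}).get("version", "unversioned")
        return cls(**kw)

    def eps(self, type_i: str, type_j: str) -> float:
        """Effective pair well depth, solvation scaling applied."""
        key = tuple(sorted((type_i, type_j)))
        if key in self.pair_eps_overrides:
            raw = self.pair_eps_overrides[key]
        else:
            ei = self.type_eps.get(type_i, 0.0)
            ej = self.type_eps.get(type_j, 0.0)
            raw = float(np.sqrt(ei * ej))
        return raw / self.solvation_scale

    def eps_matrix(self, types: list[str]) -> np.ndarray:
        uniq = sorted(set(types))
        table = {(a, b): self.eps(a, b) for a in uniq for b in uniq}
        n = len(types)
        out = np.empty((n, n))
        for i, ti in enumerate(types):
            for j, tj in enumerate(types):
                out[i, j] = table[(ti, tj)]
        return out

    def with_phospho_solvation(self) -> "InteractionParams":
        """Copy of the parameters with the phospho solvation scaling.

        Phosphorylated constructs are simulated with
        ``solvation_scale = phospho_solvation_scale``: the dianionic,
        heavily hydrated phosphate increases preferential solvation of
        the whole chain, weakening effective protein-protein attraction
        the same way the reference model's protein-water upscaling does.
        """
        from dataclasses import replace
        return replace(self, solvation_scale=self.phospho_solvation_scale)

    def sigma_of(self, type_i: str) -> float:
        return self.type_sigma.get(type_i, self.sigma)

    def pair_sigma(self, type_i: str, type_j: str) -> float:
        return 0.5 * (self.sigma_of(type_i) + self.sigma_of(type_j))

    def sigma_matrix(self, types: list[str]) -> np.ndarray:
        s = np.array([self.sigma_of(t) for t in types])
        return 0.5 * (s[:, None] + s[None, :])

    def param_hash(self) -> str:
        """Stable short hash of all parameter values."""
        items = []
        for k, v in sorted(vars(self).items()):
            items.append(f"{k}={sorted(v.items()) if isinstance(v, dict) else v}")
        return hashlib.sha256(";".join(items).encode()).hexdigest()[:12]


def _u126(r, sigma):
    sr6 = (sigma / r) ** 6
    return 4.0 * (sr6 * sr6 - sr6)


def _du126(r, sigma):
    """d/dr of the 12-6 shape."""
    sr6 = (sigma / r) ** 6
    return (-48.0 * sr6 * sr6 + 24.0 * sr6) / r


def pair_potential(type_i: str, type_j: str, charge_i: float, charge_j: float,
                   r: float | np.ndarray, params: InteractionParams):
    """Nonbonded pair energy in kJ/mol (scalar or elementwise on arrays).

    Continuous in r and exactly zero for r >= cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    eps_ij = params.eps(type_i, type_j)
    qq = charge_i * charge_j
    sig = params.pair_sigma(type_i, type_j)
    out = _pair_energy_arrays(r, np.full(r.shape, eps_ij), np.full(r.shape, qq),
                              params, sigma=np.full(r.shape, sig))
    return float(out) if out.ndim == 0 else out


def _pair_energy_arrays(r, eps_ij, qq, params: InteractionParams, sigma=None):
    """Vectorized total nonbonded pair energy."""
    rc = params.cutoff
    sigma = params.sigma if sigma is None else sigma
    rmin = _TWO16 * sigma
    u_rc = _u126(rc, sigma)
    inside = r < rc
    core = r < rmin
    rs = np.where(r > 0, r, 1.0)

    u = np.zeros_like(rs)
    # WCA repulsive core
    u = np.where(core, params.eps_rep * _u126(rs, sigma) + params.eps_rep, u)
    # attractive branch, shifted so the pair term vanishes at the cutoff
    att = np.where(core, -1.0 - u_rc, _u126(rs, sigma) - u_rc)
    u = u + np.where(inside, eps_ij * att, 0.0)
    # screened electrostatics, shifted to zero at the cutoff
    ke = KE / params.dielectric
    lam = params.debye_len
    elec = ke * qq * (np.exp(-rs / lam) / rs - np.exp(-rc / lam) / rc)
    u = u + np.where(inside, elec, 0.0)
    return np.where(inside, u, 0.0)


def _pair_force_arrays(r, eps_ij, qq, params: InteractionParams, sigma=None):
    """-dU/dr for the vectorized pair energy (same masking as the energy)."""
    rc = params.cutoff
    sigma = params.sigma if sigma is None else sigma
    rmin = _TWO16 * sigma
    inside = r < rc
    core = r < rmin
    rs = np.where(r > 0, r, 1.0)

    du = np.zeros_like(rs)
    du = np.where(core, params.eps_rep * _du126(rs, sigma), du)
    du = du + np.where(inside & ~core, eps_ij * _du126(rs, sigma), 0.0)
    ke = KE / params.dielectric
    lam = params.debye_len
    delec = -ke * qq * np.exp(-rs / lam) * (1.0 / rs ** 2 + 1.0 / (lam * rs))
    du = du + np.where(inside, delec, 0.0)
    return np.where(inside, -du, 0.0)


@dataclass
class Topology:
    """Beads, bonds and bias terms of one chain.

    Backbone beads come first (bead index == residue index); phospho side
    beads follow, each bonded to its serine's backbone bead.
    """

    sequence: CTDSequence
    types: list[str]
    charges: np.ndarray
    masses: np.ndarray
    residue_index: np.ndarray
    bonds: np.ndarray          # (n_bonds, 2) int
    bond_r0: np.ndarray
    bond_k: np.ndarray
    turn_bias: np.ndarray      # (n_bias, 2) int bead pairs (i, i+3)
    turn_bias_r0: float
    turn_bias_k: float

    @property
    def n_beads(self) -> int:
        return len(self.types)

    @property
    def n_backbone(self) -> int:
        return len(self.sequence)


#: bead type used for the phosphate side bead
PHOSPHO_SIDE_TYPE = "p"


def build_topology(seq: CTDSequence, params: InteractionParams) -> Topology:
    """One backbone bead per residue, side beads for phosphoserines, and a
    turn bias for every SPXX motif whose (hydroxy)proline is cis."""
    n = len(seq)
    types = [r.code for r in seq.residues]
    charges = [0.0] * n
    masses = [params.bead_mass] * n
    residx = list(range(n))
    bonds, r0s, ks = [], [], []
    for i in range(n - 1):
        bonds.append((i, i + 1))
        r0s.append(params.bond_length)
        ks.append(params.bond_k)
    for i, r in enumerate(seq.residues):
        if r.is_phospho:
            j = len(types)
            types.append(PHOSPHO_SIDE_TYPE)
            charges.append(r.phospho_charge)
            masses.append(params.bead_mass)
            residx.append(i)
            bonds.append((i, j))
            r0s.append(params.phospho_bond_length)
            ks.append(params.bond_k)
    bias = []
    for m in find_spxx_motifs(seq):
        if seq.residues[m + 1].isomer == "cis":
            bias.append((m, m + 3))
    return Topology(
        sequence=seq, types=types,
        charges=np.array(charges), masses=np.array(masses, dtype=float),
        residue_index=np.array(residx, dtype=int),
        bonds=np.array(bonds, dtype=int).reshape(-1, 2),
        bond_r0=np.array(r0s), bond_k=np.array(ks),
        turn_bias=np.array(bias, dtype=int).reshape(-1, 2),
        turn_bias_r0=params.turn_bias_r0, turn_bias_k=params.turn_bias_strength,
    )
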
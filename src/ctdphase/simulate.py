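"""Langevin dynamics of the bead-per-residue sticker-and-spacer model.

The integrator is the BAOAB splitting of underdamped Langevin dynamics,
chosen because its sampled kinetic temperature is directly testable
against the thermostat target.  NVT only, orthorhombic periodic box (or
open boundaries), minimum-image convention throughout.  A run is fully
determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import KB, KE, Trajectory, minimum_image
from .forcefield import (InteractionParams, Topology, _pair_energy_arrays,
                         _pair_force_arrays)


@dataclass
class SimulationConfig:
    """Run settings.

    box : edge lengths in nm (None = open boundaries, single-chain work).
    n_steps : integration steps; 0 returns the initial configuration.
    timestep : ps.  friction : 1/ps.  temperature : K.
    init_mode : 'random' (random non-overlapping insertion) or 'preformed'
        (caller supplies a condensed configuration).
    save_every : store a frame every this many steps (frame 0 included).
    """

    box: tuple[float, float, float] | None = None
    n_steps: int = 10000
    timestep: float = 0.01
    friction: float = 0.5
    temperature: float = 300.0
    seed: int = 0
    init_mode: str = "random"
    save_every: int = 200
    minimize_steps: int = 200

    def __post_init__(self):
        if self.init_mode not in ("random", "preformed"):
            raise ValueError("init_mode must be 'random' or 'preformed'")
        if self.box is not None:
            self.box = tuple(float(b) for b in self.box)


class System:
    """Topologies of all chains merged into flat per-bead arrays."""

    def __init__(self, topologies: list[Topology], params: InteractionParams):
        if isinstance(topologies, Topology):
            topologies = [topologies]
        self.topologies = topologies
        self.params = params
        types, charges, masses, chain_id, residx = [], [], [], [], []
        bonds, bond_r0, bond_k, bias = [], [], [], []
        offset = 0
        for c, top in enumerate(topologies):
            types += top.types
            charges.append(top.charges)
            masses.append(top.masses)
            chain_id += [c] * top.n_beads
            residx.append(top.residue_index)
            bonds.append(top.bonds + offset)
            bond_r0.append(top.bond_r0)
            bond_k.append(top.bond_k)
            if len(top.turn_bias):
                bias.append(top.turn_bias + offset)
            offset += top.n_beads
        self.types = types
        self.charges = np.concatenate(charges)
        self.masses = np.concatenate(masses)
        self.chain_id = np.array(chain_id, dtype=int)
        self.residue_index = np.concatenate(residx)
        self.bonds = np.concatenate(bonds, axis=0)
        self.bond_r0 = np.concatenate(bond_r0)
        self.bond_k = np.concatenate(bond_k)
        self.bias = (np.concatenate(bias, axis=0) if bias
                     else np.zeros((0, 2), dtype=int))
        self.bias_r0 = params.turn_bias_r0
        self.bias_k = params.turn_bias_strength
        self.n_beads = offset

        self.eps_matrix = params.eps_matrix(types)
        self.sigma_pair_matrix = params.sigma_matrix(types)
        self.qq_matrix = np.outer(self.charges, self.charges)
        # nonbonded exclusions: self pairs and directly bonded pairs
        excl = np.eye(self.n_beads, dtype=bool)
        excl[self.bonds[:, 0], self.bonds[:, 1]] = True
        excl[self.bonds[:, 1], self.bonds[:, 0]] = True
        self.exclusions = excl
        # compressed upper-triangle pair arrays for the dynamics kernel
        iu, ju = np.triu_indices(self.n_beads, 1)
        keep = ~excl[iu, ju]
        self._iu, self._ju = iu[keep], ju[keep]
        self._eps_flat = self.eps_matrix[self._iu, self._ju]
        self._sigma_flat = self.sigma_pair_matrix[self._iu, self._ju]
        self._qq_flat = self.qq_matrix[self._iu, self._ju]

    @property
    def n_chains(self) -> int:
        return len(self.topologies)


def _pair_distance_matrix(pos, box):
    dx = pos[None, :, :] - pos[:, None, :]
    dx = minimum_image(dx, None if box is None else np.asarray(box))
    r = np.sqrt(np.einsum("ijk,ijk->ij", dx, dx))
    return dx, r


def _harmonic_terms(pos, pairs, r0, k, box):
    """Energy and per-bead forces of harmonic pair terms."""
    if len(pairs) == 0:
        return 0.0, np.zeros_like(pos)
    dx = pos[pairs[:, 0]] - pos[pairs[:, 1]]
    dx = minimum_image(dx, None if box is None else np.asarray(box))
    r = np.linalg.norm(dx, axis=1)
    energy = float(np.sum(0.5 * k * (r - r0) ** 2))
    fmag = -k * (r - r0) / np.where(r > 0, r, 1.0)
    fvec = fmag[:, None] * dx
    forces = np.zeros_like(pos)
    np.add.at(forces, pairs[:, 0], fvec)
    np.add.at(forces, pairs[:, 1], -fvec)
    return energy, forces


def _nonbonded(pos, system: System, box, want_forces=True):
    """Pairwise nonbonded + electrostatic energy (and forces)."""
    params = system.params
    dx, r = _pair_distance_matrix(pos, box)
    np.fill_diagonal(r, np.inf)
    r = np.where(system.exclusions, np.inf, r)
    # split the energy so the electrostatic part can be reported separately
    u_nb = _pair_energy_arrays(r, system.eps_matrix, np.zeros_like(r), params,
                               sigma=system.sigma_pair_matrix)
    u_all = _pair_energy_arrays(r, system.eps_matrix, system.qq_matrix, params,
                                sigma=system.sigma_pair_matrix)
    e_nb = 0.5 * float(np.sum(u_nb))
    e_elec = 0.5 * float(np.sum(u_all - u_nb))
    if not want_forces:
        return e_nb, e_elec, None
    f = _pair_force_arrays(r, system.eps_matrix, system.qq_matrix, params,
                           sigma=system.sigma_pair_matrix)
    rs = np.where(np.isfinite(r), r, 1.0)
    fvec = (f / rs)[:, :, None] * dx
    forces = -np.sum(fvec, axis=1)
    return e_nb, e_elec, forces


def total_energy(frame: np.ndarray, system: System,
                 box=None) -> dict[str, float]:
    """Decomposed potential energy of one frame.

    Returns bonded (harmonic bonds + turn-bias restraints), nonbonded
    (excluded volume + sticker attraction), electrostatic, and their total.
    """
    pos = np.asarray(frame, dtype=float)
    e_bond, _ = _harmonic_terms(pos, system.bonds, system.bond_r0,
                                system.bond_k, box)
    e_bias, _ = _harmonic_terms(pos, system.bias, system.bias_r0,
                                system.bias_k, box)
    e_nb, e_elec, _ = _nonbonded(pos, system, box, want_forces=False)
    return {
        "bonded": e_bond + e_bias,
        "nonbonded": e_nb,
        "electrostatic": e_elec,
        "total": e_bond + e_bias + e_nb + e_elec,
    }


def _nb_forces_fast(pos, system: System, box):
    """Nonbonded forces via compressed in-cutoff pair lists."""
    params = system.params
    rc = params.cutoff
    dx = pos[system._iu] - pos[system._ju]
    if box is not None:
        dx -= box * np.round(dx / box)
    r2 = np.einsum("ij,ij->i", dx, dx)
    idx = np.flatnonzero(r2 < rc * rc)
    if idx.size == 0:
        return np.zeros_like(pos)
    r = np.sqrt(r2[idx])
    eps = system._eps_flat[idx]
    qq = system._qq_flat[idx]
    sigma = system._sigma_flat[idx]
    rmin = 2.0 ** (1.0 / 6.0) * sigma
    sr6 = (sigma / r) ** 6
    du_shape = (-48.0 * sr6 * sr6 + 24.0 * sr6) / r   # d/dr of 12-6 shape
    core = r < rmin
    du = np.where(core, params.eps_rep * du_shape, eps * du_shape)
    charged = qq != 0.0
    if np.any(charged):
        ke = KE / params.dielectric
        lam = params.debye_len
        rq = r[charged]
        du_el = -ke * qq[charged] * np.exp(-rq / lam) * (
            1.0 / rq ** 2 + 1.0 / (lam * rq))
        du[charged] += du_el
    fvec = (-du / r)[:, None] * dx[idx]
    forces = np.zeros_like(pos)
    np.add.at(forces, system._iu[idx], fvec)
    np.add.at(forces, system._ju[idx], -fvec)
    return forces


def _forces(pos, system: System, box):
    _, fb = _harmonic_terms(pos, system.bonds, system.bond_r0, system.bond_k, box)
    _, fr = _harmonic_terms(pos, system.bias, system.bias_r0, system.bias_k, box)
    return fb + fr + _nb_forces_fast(pos, system, box)


def minimize(pos, system: System, box=None, n_steps: int = 200,
             max_disp: float = 0.02) -> np.ndarray:
    """Clamped steepest-descent relaxation of steric clashes.

    Each step moves every bead along the force, displacement capped at
    ``max_disp`` nm.  Used to relax freshly inserted configurations before
    dynamics so the thermostat does not have to absorb the placement
    strain.
    """
    pos = np.array(pos, dtype=float)
    for _ in range(n_steps):
        f = _forces(pos, system, box)
        fmax = np.abs(f).max()
        if fmax < 1.0:
            break
        step = f * (max_disp / max(fmax, 1e-12))
        pos += np.clip(step, -max_disp, max_disp)
    return pos


def _grow_chain(top: Topology, start, rng, params, occupied, region=None,
                box=None, max_retries=200):
    """Grow one chain as a bond-length random walk avoiding placed beads.

    ``occupied`` is a list of positions to avoid (min distance 0.7 sigma).
    ``region`` = (center, radius) confines backbone beads to a sphere.
    Returns (n_beads, 3) positions or None on failure.
    """
    min_d2 = (0.7 * params.sigma) ** 2
    nb = top.n_backbone
    pos = np.empty((top.n_beads, 3))
    pos[0] = start
    occ = occupied
    bx = None if box is None else np.asarray(box)

    def clashes(p):
        if not len(occ):
            return False
        d = minimum_image(np.asarray(occ) - p, bx)
        return bool(np.any(np.einsum("ij,ij->i", d, d) < min_d2))

    placed = [pos[0]]
    for i in range(1, nb):
        ok = False
        for _ in range(max_retries):
            step = rng.normal(size=3)
            step *= params.bond_length / np.linalg.norm(step)
            cand = pos[i - 1] + step
            if region is not None:
                c, rad = region
                if np.linalg.norm(cand - c) > rad:
                    continue
            d = np.asarray(placed[max(0, i - 40):]) - cand
            if np.any(np.einsum("ij,ij->i", d, d) < min_d2):
                continue
            if clashes(cand):
                continue
            pos[i] = cand
            placed.append(cand)
            ok = True
            break
        if not ok:
            return None
    # phospho side beads sit a bond length off their backbone bead
    for j in range(nb, top.n_beads):
        i = top.residue_index[j]
        for _ in range(max_retries):
            step = rng.normal(size=3)
            step *= params.phospho_bond_length / np.linalg.norm(step)
            cand = pos[i] + step
            if not clashes(cand):
                break
        pos[j] = cand
        placed.append(cand)
    return pos


def random_insertion(system: System, box, seed=0, max_retries=60):
    """Randomly insert chains as non-overlapping random walks in the box."""
    rng = np.random.default_rng(seed)
    bx = np.asarray(box, dtype=float)
    occupied: list[np.ndarray] = []
    coords = []
    for top in system.topologies:
        placed = None
        for _ in range(max_retries):
            start = rng.uniform(0, 1, size=3) * bx
            placed = _grow_chain(top, start, rng, system.params, occupied,
                                 box=bx)
            if placed is not None:
                break
        if placed is None:
            raise RuntimeError(
                "could not place chains without overlap; enlarge the box or "
                "reduce the chain count"
            )
        occupied.extend(list(placed))
        coords.append(placed)
    return np.concatenate(coords, axis=0)


def make_preformed_condensate(system: System, box, seed=0,
                              bead_density=4.0, max_retries=400):
    """Construct a dense, chain-interleaved droplet at the box centre.

    All chains are grown round-robin (one bead per chain per round) as
    confined random walks inside a sphere whose radius gives the requested
    bead number density (beads/nm^3), so chains interpenetrate the way a
    relaxed condensate's do.  Used as the 'preformed' initial condition
    for dissolution runs.
    """
    rng = np.random.default_rng(seed)
    params = system.params
    bx = np.asarray(box, dtype=float)
    n_total = system.n_beads
    radius = (3.0 * n_total / (4.0 * np.pi * bead_density)) ** (1.0 / 3.0)
    center = bx / 2.0
    min_d2 = (0.7 * params.sigma) ** 2
    tops = system.topologies
    chains = []
    for _ in tops:
        u = rng.normal(size=3)
        u *= 0.8 * radius * rng.uniform() ** (1.0 / 3.0) / max(np.linalg.norm(u), 1e-12)
        chains.append([center + u])
    occupied = list(c[0] for c in chains)

    def clashes(p):
        d = np.asarray(occupied) - p
        return bool(np.any(np.einsum("ij,ij->i", d, d) < min_d2))

    n_backbone = max(t.n_backbone for t in tops)
    for i in range(1, n_backbone):
        for c, top in enumerate(tops):
            if i >= top.n_backbone:
                continue
            ok = False
            for _ in range(max_retries):
                step = rng.normal(size=3)
                step *= params.bond_length / np.linalg.norm(step)
                cand = chains[c][-1] + step
                if np.linalg.norm(cand - center) > radius:
                    continue
                if clashes(cand):
                    continue
                ok = True
                break
            if not ok:
                raise RuntimeError("could not build the preformed condensate; "
                                   "lower bead_density")
            chains[c].append(cand)
            occupied.append(cand)
    coords = []
    for c, top in enumerate(tops):
        pos = np.asarray(chains[c])
        extra = []
        for j in range(top.n_backbone, top.n_beads):
            i = top.residue_index[j]
            cand = None
            for _ in range(max_retries):
                step = rng.normal(size=3)
                step *= params.phospho_bond_length / np.linalg.norm(step)
                cand = pos[i] + step
                if not clashes(cand):
                    break
            extra.append(cand)
            occupied.append(cand)
        if extra:
            pos = np.concatenate([pos, np.asarray(extra)], axis=0)
        coords.append(pos)
    return np.concatenate(coords, axis=0)


def initial_from_backbone(backbone_frame, system: System, seed=0) -> np.ndarray:
    """Initial coordinates for ``system`` from a backbone-only frame.

    Takes a frame whose beads are the backbone beads of the same chains
    (e.g. the final frame of an unphosphorylated run) and attaches any
    side beads of the new topology at their bond length in random
    directions.  This is how a phosphorylated system inherits a preformed
    condensate from the run that produced it.
    """
    rng = np.random.default_rng(seed)
    frame = np.asarray(backbone_frame, dtype=float)
    n_backbone = sum(t.n_backbone for t in system.topologies)
    if frame.shape != (n_backbone, 3):
        raise ValueError("backbone frame does not match the system's chains")
    coords = []
    offset = 0
    for top in system.topologies:
        bb = frame[offset:offset + top.n_backbone]
        offset += top.n_backbone
        extra = []
        for j in range(top.n_backbone, top.n_beads):
            i = top.residue_index[j]
            step = rng.normal(size=3)
            step *= system.params.phospho_bond_length / np.linalg.norm(step)
            extra.append(bb[i] + step)
        coords.append(bb if not extra
                      else np.concatenate([bb, np.asarray(extra)], axis=0))
    return np.concatenate(coords, axis=0)


def run_dynamics(topologies, config: SimulationConfig,
                 params: InteractionParams | None = None,
                 initial: np.ndarray | None = None) -> Trajectory:
    """Integrate the system and return the stored trajectory.

    ``initial`` supplies starting coordinates; it is required when
    ``config.init_mode == 'preformed'``.  With ``n_steps == 0`` the initial
    configuration is returned unchanged as a single frame.
    """
    if params is None:
        params = InteractionParams.default()
    system = topologies if isinstance(topologies, System) else System(
        topologies if isinstance(topologies, list) else [topologies], params)
    if config.box is not None and min(config.box) <= 2 * params.cutoff:
        raise ValueError("box lengths must exceed twice the cutoff")

    rng = np.random.default_rng(config.seed)
    if initial is not None:
        pos = np.array(initial, dtype=float)
        if pos.shape != (system.n_beads, 3):
            raise ValueError("initial coordinates have the wrong shape")
    elif config.init_mode == "preformed":
        raise ValueError("preformed init requires supplied coordinates "
                         "(e.g. the final frame of a previous run or "
                         "make_preformed_condensate)")
    else:
        if config.box is None:
            raise ValueError("random insertion requires a box; pass initial "
                             "coordinates for open-boundary runs")
        pos = random_insertion(system, config.box, seed=rng.integers(2**31))

    box = None if config.box is None else np.asarray(config.box)
    if config.n_steps > 0 and config.minimize_steps > 0:
        pos = minimize(pos, system, box, n_steps=config.minimize_steps)
    dt, gamma = config.timestep, config.friction
    kT = KB * config.temperature
    m = system.masses[:, None]
    vel = rng.normal(size=pos.shape) * np.sqrt(kT / m)

    frames = [pos.copy()]
    temps = []
    if config.n_steps == 0:
        return Trajectory(np.array(frames), system.chain_id,
                          system.residue_index, box=box,
                          sampling_interval=0.0,
                          kinetic_temperature=np.array([]))

    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    forces = _forces(pos, system, box)
    ndof = 3 * system.n_beads
    for step in range(1, config.n_steps + 1):
        vel += 0.5 * dt * forces / m
        pos += 0.5 * dt * vel
        vel = c1 * vel + c2 * np.sqrt(kT / m) * rng.normal(size=pos.shape)
        pos += 0.5 * dt * vel
        forces = _forces(pos, system, box)
        vel += 0.5 * dt * forces / m
        if step % config.save_every == 0 or step == config.n_steps:
            frames.append(pos.copy())
            ke = 0.5 * float(np.sum(system.masses[:, None] * vel * vel))
            temps.append(2.0 * ke / (ndof * KB))
    return Trajectory(np.array(frames), system.chain_id, system.residue_index,
                      box=box, sampling_interval=config.save_every * dt,
                      kinetic_temperature=np.array(temps))
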
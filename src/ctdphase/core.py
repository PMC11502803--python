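"""Shared containers and physical constants.

Units throughout the package: length nm, energy kJ/mol, time ps, mass amu,
charge in elementary charges, temperature K.  With these units
1 amu nm^2/ps^2 = 1 kJ/mol, so kinetic and potential energies add directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Boltzmann constant, kJ/mol/K.
KB = 0.008314462618

#: Coulomb constant 1/(4 pi eps0), kJ/mol * nm / e^2 (vacuum).
KE = 138.935458


def debye_length(ionic_strength: float = 0.150, temperature: float = 300.0,
                 dielectric: float = 78.5) -> float:
    """Debye screening length in nm.

    Parameters
    ----------
    ionic_strength : molar ionic strength (mol/L) of a 1:1 salt.
    temperature : K.
    dielectric : relative permittivity of the solvent.

    At 150 mM NaCl and 300 K in water this evaluates to ~0.78 nm.
    """
    if ionic_strength <= 0:
        return np.inf
    # number density of charge pairs, nm^-3
    rho = ionic_strength * 6.02214076e23 * 1e-24
    lam2 = dielectric * KB * temperature / (8.0 * np.pi * KE * rho)
    return float(np.sqrt(lam2))


@dataclass
class Trajectory:
    """Bead coordinates over time.

    frames : (F, B, 3) array, nm.  Coordinates are stored unwrapped; the
        periodic box (if any) applies through the minimum-image convention
        in energy and contact calculations.
    chain_id : (B,) int array, chain index of each bead.
    residue_index : (B,) int array, residue index of each bead within its
        chain (a phospho side bead carries the residue index of its serine).
    box : (3,) array of box edge lengths in nm, or None for open boundaries.
    sampling_interval : simulated time between stored frames, ps.
    """

    frames: np.ndarray
    chain_id: np.ndarray
    residue_index: np.ndarray
    box: np.ndarray | None = None
    sampling_interval: float = 1.0
    kinetic_temperature: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        self.chain_id = np.asarray(self.chain_id, dtype=int)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1 if self.n_beads else 0


def minimum_image(dx: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Orthorhombic boxes only.  ``dx`` may have any leading shape with the
    Cartesian axis last; returns an array of the same shape.
    """
    if box is None:
        return dx
    return dx - box * np.round(dx / box)
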
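"""Reference polymer ensembles with known scaling ground truth.

These generators validate the scaling analyses without any dynamics:

ideal   : Gaussian-step chain, nu = 1/2 and RMS internal distances exactly
          b * sqrt(s).
saw     : self-avoiding walk on the cubic lattice, sampled with the pivot
          algorithm; nu ~ 0.588, the excluded-volume (expanded coil) limit.
globule : a random contiguous segment of a 3-D Hilbert curve through a
          close-packed lattice region, randomly rotated and jittered; a
          space-filling (collapsed) chain with r(s) ~ s^(1/3).
rod     : collinear beads, nu = 1.

All return (n_conformations, n_residues, 3) coordinate arrays in nm, the
same frame layout the simulator produces, so every analysis consumes
either source identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

#: the 24 proper rotations of the cube, used by the pivot algorithm
def _octahedral_rotations():
    mats = []
    for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
        for sx in (1, -1):
            for sy in (1, -1):
                for sz in (1, -1):
                    m = np.zeros((3, 3), dtype=int)
                    for row, (col, s) in enumerate(zip(perm, (sx, sy, sz))):
                        m[row, col] = s
                    if round(np.linalg.det(m)) == 1:
                        mats.append(m)
    return np.array(mats)


_ROTATIONS = _octahedral_rotations()


@dataclass
class EnsembleSpec:
    """Recipe for a reference ensemble."""

    n_residues: int
    n_conformations: int
    kind: str = "ideal"
    segment_length: float = 0.55
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")
        if self.kind not in ("ideal", "saw", "globule", "rod"):
            raise ValueError(f"unknown ensemble kind {self.kind!r}")


def generate_ensemble(spec: EnsembleSpec) -> np.ndarray:
    """Generate the ensemble described by ``spec`` (reproducible from seed)."""
    rng = np.random.default_rng(spec.seed)
    n, m, b = spec.n_residues, spec.n_conformations, spec.segment_length
    if spec.kind == "ideal":
        steps = rng.normal(scale=b / np.sqrt(3.0), size=(m, n - 1, 3))
        coords = np.concatenate(
            [np.zeros((m, 1, 3)), np.cumsum(steps, axis=1)], axis=1)
        return coords
    if spec.kind == "rod":
        axes = rng.normal(size=(m, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        s = b * np.arange(n)
        return axes[:, None, :] * s[None, :, None]
    if spec.kind == "saw":
        return _saw_ensemble(n, m, b, rng)
    return _globule_ensemble(n, m, b, rng)


# ---------------------------------------------------------------- SAW ----

def _pivot_saw(n, rng, n_samples, equil_attempts, gap_attempts):
    """Sample lattice SAWs of n sites with the pivot algorithm."""
    coords = np.zeros((n, 3), dtype=np.int64)
    coords[:, 0] = np.arange(n)
    samples = []
    accepted = attempts = 0
    total_attempts = equil_attempts + n_samples * gap_attempts
    next_sample = equil_attempts
    while len(samples) < n_samples:
        attempts += 1
        k = int(rng.integers(1, n - 1))
        rot = _ROTATIONS[rng.integers(len(_ROTATIONS))]
        pivot = coords[k]
        tail = (coords[k + 1:] - pivot) @ rot.T + pivot
        head_set = set(map(tuple, coords[:k + 1]))
        ok = True
        seen = set()
        for site in map(tuple, tail):
            if site in head_set or site in seen:
                ok = False
                break
            seen.add(site)
        if ok:
            coords = np.concatenate([coords[:k + 1], tail])
            accepted += 1
        if attempts >= next_sample:
            samples.append(coords.copy())
            next_sample += gap_attempts
        if attempts > 50 * total_attempts:
            raise RuntimeError(
                f"pivot algorithm failed to decorrelate: {accepted} accepted "
                f"of {attempts} attempted moves for n={n}"
            )
    return np.array(samples, dtype=float)


def _saw_ensemble(n, m, b, rng):
    walks = _pivot_saw(n, rng, m, equil_attempts=20 * n, gap_attempts=2 * n)
    return walks * b


# ------------------------------------------------------------- globule ----

def _hilbert_curve(order: int) -> np.ndarray:
    """Coordinates of the 3-D Hilbert curve of the given order.

    Skilling's transpose algorithm; returns (8**order, 3) int array in which
    consecutive points are unit-lattice neighbours.
    """
    p = order
    npts = 1 << (3 * p)
    out = np.empty((npts, 3), dtype=np.int64)
    for h in range(npts):
        x = [0, 0, 0]
        for bit in range(3 * p):
            x[bit % 3] |= ((h >> (3 * p - 1 - bit)) & 1) << (p - 1 - bit // 3)
        # Gray decode
        t = x[2] >> 1
        for i in (2, 1):
            x[i] ^= x[i - 1]
        x[0] ^= t
        # undo excess work
        q = 2
        while q != (1 << p):
            pmask = q - 1
            for i in (2, 1, 0):
                if x[i] & q:
                    x[0] ^= pmask
                else:
                    t = (x[0] ^ x[i]) & pmask
                    x[0] ^= t
                    x[i] ^= t
            q <<= 1
        out[h] = x
    return out


_HILBERT_CACHE: dict[int, np.ndarray] = {}


def _globule_ensemble(n, m, b, rng, jitter=0.08):
    order = 1
    while (1 << (3 * order)) < 2 * n:
        order += 1
    if order not in _HILBERT_CACHE:
        _HILBERT_CACHE[order] = _hilbert_curve(order)
    curve = _HILBERT_CACHE[order]
    confs = np.empty((m, n, 3))
    for i in range(m):
        start = int(rng.integers(0, len(curve) - n + 1))
        seg = curve[start:start + n].astype(float)
        seg = seg - seg.mean(axis=0)
        rot = _ROTATIONS[rng.integers(len(_ROTATIONS))].astype(float)
        seg = seg @ rot.T
        seg += rng.normal(scale=jitter, size=seg.shape)
        confs[i] = seg * b
    return confs


# ----------------------------------------------------- turn distances ----

def turn_distance_mixture(n_samples: int, compact_fraction: float,
                          compact_mean: float = 0.55, compact_sd: float = 0.07,
                          extended_mean: float = 0.95, extended_sd: float = 0.12,
                          seed: int = 0, cutoff: float = 0.7) -> np.ndarray:
    """Synthetic SPXX Ca1-Ca4 distance samples with known compact fraction.

    A two-component truncated-normal mixture: the compact component lives
    on (0, cutoff), the extended one on (cutoff, inf), so the expected
    fraction of samples below the cutoff equals ``compact_fraction``
    exactly and the empirical fraction converges to it as n grows.
    """
    if not 0.0 <= compact_fraction <= 1.0:
        raise ValueError("compact_fraction must be in [0, 1]")
    if not (compact_mean < cutoff < extended_mean):
        raise ValueError("component means must lie on opposite sides of the cutoff")
    rng = np.random.default_rng(seed)
    n_compact = int(rng.binomial(n_samples, compact_fraction))
    a_c, b_c = (0.0 - compact_mean) / compact_sd, (cutoff - compact_mean) / compact_sd
    compact = truncnorm.rvs(a_c, b_c, loc=compact_mean, scale=compact_sd,
                            size=n_compact, random_state=rng)
    a_e = (cutoff - extended_mean) / extended_sd
    extended = truncnorm.rvs(a_e, np.inf, loc=extended_mean, scale=extended_sd,
                             size=n_samples - n_compact, random_state=rng)
    samples = np.concatenate([compact, extended])
    rng.shuffle(samples)
    return samples
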
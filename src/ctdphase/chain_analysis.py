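"""Single-chain structural analyses.

Internal-distance scaling and the Flory exponent, radius of gyration,
per-residue interaction-energy maps, and SPXX beta-turn classification.

The scaling relation fitted here is r(s) = b * s**nu with s = |i - j| the
residue separation; nu = 1/3 marks a globule, 1/2 an ideal chain, and 3/5
an expanded coil.  In 'paper' mode the Kuhn length b is clamped (0.55 nm)
and only separations above 200 peptide bonds enter the fit; 'free' mode
fits (b, nu) jointly.  The profile statistic is the root-mean-square
internal distance, for which the ideal-chain relation r(s) = b*sqrt(s) is
exact and the two-parameter fit recovers the generating Kuhn length;
the arithmetic mean is available via ``statistic='mean'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Trajectory, minimum_image
from .forcefield import _pair_energy_arrays
from .simulate import System


@dataclass
class ScalingProfile:
    """Mean internal distance per residue separation."""

    separation: np.ndarray   # s = 1 .. N-1
    distance: np.ndarray     # r(s), nm
    n_pairs: np.ndarray      # pairs * conformations entering each s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"separation": self.separation,
                             "distance_nm": self.distance,
                             "n_pairs": self.n_pairs})


@dataclass
class ScalingResult:
    """Fitted Flory exponent (and prefactor)."""

    nu: float
    b: float
    mode: str
    min_sep: int
    r_squared: float
    nu_sd: float | None = None
    b_sd: float | None = None


def internal_distance_profile(ensemble, statistic: str = "rms") -> ScalingProfile:
    """Average internal distance r(s) over all conformations and pairs.

    ``ensemble`` is a (F, N, 3) array (or (N, 3) single conformation).
    ``statistic`` is 'rms' (default, sqrt of the mean squared distance) or
    'mean' (arithmetic mean distance).
    """
    coords = np.asarray(ensemble, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.ndim != 3 or coords.shape[1] < 2:
        raise ValueError("ensemble must be (F, N>=2, 3)")
    if statistic not in ("rms", "mean"):
        raise ValueError("statistic must be 'rms' or 'mean'")
    n = coords.shape[1]
    seps = np.arange(1, n)
    dist = np.empty(n - 1)
    npairs = np.empty(n - 1, dtype=int)
    for s in seps:
        d = coords[:, s:, :] - coords[:, :-s, :]
        r2 = np.einsum("fij,fij->fi", d, d)
        npairs[s - 1] = r2.size
        if statistic == "rms":
            dist[s - 1] = np.sqrt(r2.mean())
        else:
            dist[s - 1] = np.sqrt(r2).mean()
    return ScalingProfile(seps, dist, npairs)


def fit_flory(profile, mode: str = "paper", b_fixed: float = 0.55,
              min_sep: int | None = None, max_sep: int | None = None,
              weighted: bool = True) -> ScalingResult:
    """Fit r(s) = b * s**nu to a scaling profile in log-log space.

    ``profile`` is a ScalingProfile or a list of them (independent
    replicas; the result then reports the replica mean and SD of the
    fitted parameters).  'paper' mode clamps b = b_fixed and uses only
    s > min_sep (default 200); 'free' mode fits (b, nu) jointly with
    default min_sep 10.  ``max_sep`` optionally caps the window: for
    statistics with chain-end corrections (self-avoiding walks) the
    asymptotic internal regime requires s much smaller than the chain
    length, and a cap near N/6 is recommended.  ``weighted`` applies
    least-squares weights proportional to n_pairs/s (the approximate
    count of statistically independent segments per separation), which
    leaves noiseless power laws exact while stabilising noisy tails.
    """
    if isinstance(profile, (list, tuple)):
        fits = [fit_flory(p, mode=mode, b_fixed=b_fixed, min_sep=min_sep,
                          max_sep=max_sep, weighted=weighted)
                for p in profile]
        nus = np.array([f.nu for f in fits])
        bs = np.array([f.b for f in fits])
        return ScalingResult(
            nu=float(nus.mean()), b=float(bs.mean()), mode=mode,
            min_sep=fits[0].min_sep,
            r_squared=float(np.mean([f.r_squared for f in fits])),
            nu_sd=float(nus.std(ddof=1)) if len(fits) > 1 else None,
            b_sd=float(bs.std(ddof=1)) if len(fits) > 1 else None,
        )
    if mode not in ("paper", "free"):
        raise ValueError("mode must be 'paper' or 'free'")
    if min_sep is None:
        min_sep = 200 if mode == "paper" else 10
    sel = profile.separation > min_sep
    if max_sep is not None:
        sel &= profile.separation <= max_sep
    if not np.any(sel):
        raise ValueError(
            f"profile has no separations above min_sep={min_sep}; use a "
            "longer chain or a smaller min_sep"
        )
    x = np.log(profile.separation[sel].astype(float))
    y = np.log(profile.distance[sel])
    w = (profile.n_pairs[sel] / profile.separation[sel] if weighted
         else np.ones_like(x))
    w = w / w.sum()
    if mode == "paper":
        yc = y - np.log(b_fixed)
        nu = float(np.sum(w * x * yc) / np.sum(w * x * x))
        b = float(b_fixed)
        resid = yc - nu * x
        ybar = np.sum(w * yc)
        tss = np.sum(w * (yc - ybar) ** 2)
    else:
        xbar, ybar = np.sum(w * x), np.sum(w * y)
        sxx = np.sum(w * (x - xbar) ** 2)
        sxy = np.sum(w * (x - xbar) * (y - ybar))
        nu = float(sxy / sxx)
        logb = ybar - nu * xbar
        b = float(np.exp(logb))
        resid = y - (nu * x + logb)
        tss = np.sum(w * (y - ybar) ** 2)
    r2 = 1.0 - float(np.sum(w * resid ** 2)) / tss if tss > 0 else 1.0
    if not 0.0 < nu <= 1.2:
        raise ValueError(f"fitted exponent nu={nu:.3f} outside the physical range")
    return ScalingResult(nu=nu, b=b, mode=mode, min_sep=int(min_sep),
                         r_squared=r2)


def radius_of_gyration(coords, masses=None):
    """Mass-weighted radius of gyration, nm.

    (N, 3) frame -> float; (F, N, 3) ensemble -> (F,) array.
    """
    x = np.asarray(coords, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    if masses is None:
        w = np.full(x.shape[1], 1.0)
    else:
        w = np.asarray(masses, dtype=float)
    w = w / w.sum()
    com = np.einsum("fni,n->fi", x, w)
    d = x - com[:, None, :]
    rg2 = np.einsum("fni,fni,n->f", d, d, w)
    rg = np.sqrt(rg2)
    return float(rg[0]) if single else rg


@dataclass
class EnergyMap:
    """Residue x residue mean pairwise interaction energy, kJ/mol."""

    energy: np.ndarray
    highlight_threshold: float = -7.0

    @property
    def highlight(self) -> np.ndarray:
        """Entries matching or exceeding the threshold in magnitude
        (energy <= threshold; the boundary is inclusive)."""
        return self.energy <= self.highlight_threshold

    def to_frame(self) -> pd.DataFrame:
        n = self.energy.shape[0]
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        return pd.DataFrame({"i": i.ravel(), "j": j.ravel(),
                             "energy_kj_mol": self.energy.ravel()})


def residue_energy_map(traj: Trajectory, system: System,
                       highlight_threshold: float = -7.0) -> EnergyMap:
    """Time-averaged pairwise interaction energy aggregated per residue.

    Entry (i, j) is the trajectory average of the nonbonded-plus-
    electrostatic pair energy between the beads of residues i and j
    (phospho side beads aggregate onto their serine's residue).  Pairs
    never within the cutoff contribute exactly 0.  The grand sum over
    i < j equals the trajectory-averaged nonbonded + electrostatic total.
    """
    params = system.params
    n_res = int(system.residue_index.max()) + 1
    acc = np.zeros((n_res, n_res))
    box = traj.box
    # bead -> residue aggregation matrix
    agg = np.zeros((len(system.residue_index), n_res))
    agg[np.arange(len(system.residue_index)), system.residue_index] = 1.0
    for frame in traj.frames:
        dx = frame[None, :, :] - frame[:, None, :]
        dx = minimum_image(dx, box)
        r = np.sqrt(np.einsum("ijk,ijk->ij", dx, dx))
        np.fill_diagonal(r, np.inf)
        r = np.where(system.exclusions, np.inf, r)
        u = _pair_energy_arrays(r, system.eps_matrix, system.qq_matrix, params,
                                sigma=system.sigma_pair_matrix)
        acc += agg.T @ u @ agg
    acc /= traj.n_frames
    # keep symmetry exactly; off-residue double counting already symmetric
    acc = 0.5 * (acc + acc.T)
    return EnergyMap(energy=acc, highlight_threshold=highlight_threshold)


@dataclass
class TurnDistribution:
    """Per-motif Ca1-Ca4 distance samples and compact/extended split.

    In the one-bead-per-residue model the 'Ca' of a motif residue is its
    backbone bead.  A sample is compact iff its distance is strictly below
    the cutoff (a distance exactly at the cutoff is extended); auc_ratio
    is mass below / mass above the cutoff, np.inf when nothing lies above.
    """

    distances: np.ndarray    # (n_motifs, n_frames), nm
    motif_indices: np.ndarray
    cutoff: float = 0.7

    @property
    def compact(self) -> np.ndarray:
        return self.distances < self.cutoff

    @property
    def compact_fraction(self) -> float:
        return float(self.compact.mean())

    @property
    def compact_fraction_per_motif(self) -> np.ndarray:
        return self.compact.mean(axis=1)

    @property
    def auc_ratio(self) -> float:
        return _auc_ratio(self.compact.sum(), (~self.compact).sum())

    @property
    def auc_ratio_per_motif(self) -> np.ndarray:
        below = self.compact.sum(axis=1)
        above = self.distances.shape[1] - below
        return np.array([_auc_ratio(b, a) for b, a in zip(below, above)])

    def to_frame(self) -> pd.DataFrame:
        m, f = self.distances.shape
        return pd.DataFrame({
            "motif": np.repeat(self.motif_indices, f),
            "frame": np.tile(np.arange(f), m),
            "distance_nm": self.distances.ravel(),
        })


def _auc_ratio(below, above) -> float:
    if above == 0:
        return np.inf
    return float(below) / float(above)


def turn_metrics(traj: Trajectory, motif_indices, cutoff: float = 0.7,
                 chain: int = 0) -> TurnDistribution:
    """Ca1-Ca4 distances of SPXX motifs over a trajectory.

    ``motif_indices`` are residue start indices from find_spxx_motifs;
    bead indices are resolved within the requested chain (backbone beads
    carry their residue index).
    """
    motif_indices = np.asarray(motif_indices, dtype=int)
    sel = np.flatnonzero(traj.chain_id == chain)
    # backbone beads come first within a chain: residue_index is identity there
    backbone = {int(traj.residue_index[b]): b for b in sel}
    i1 = np.array([backbone[m] for m in motif_indices])
    i4 = np.array([backbone[m + 3] for m in motif_indices])
    d = traj.frames[:, i1, :] - traj.frames[:, i4, :]
    d = minimum_image(d, traj.box)
    dist = np.sqrt(np.einsum("fmi,fmi->fm", d, d)).T
    return TurnDistribution(distances=dist, motif_indices=motif_indices,
                            cutoff=cutoff)


def classify_turns(distances, cutoff: float = 0.7):
    """Compact fraction and AUC ratio of a pooled distance sample."""
    d = np.asarray(distances, dtype=float)
    below = int(np.sum(d < cutoff))
    above = d.size - below
    return below / d.size, _auc_ratio(below, above)
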
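"""Condensed-phase analyses: contacts, chain clustering, dissolution.

A contact is any pair of beads from distinct chains whose minimum-image
distance is strictly below the 0.6 nm cutoff.  Two chains are joined when
their contact count strictly exceeds a threshold (20, 50 or 80 in the
reference protocol), and clusters are the connected components of the
resulting chain graph.  Both boundaries are strict, read literally from
"within the distance cutoff" and "more than a predefined threshold".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import norm

from .core import Trajectory, minimum_image


def chain_pair_contacts(frame, chain_ids, box=None,
                        cutoff: float = 0.6) -> np.ndarray:
    """Symmetric matrix of inter-chain bead-pair contact counts.

    Counts every pair of beads from distinct chains with minimum-image
    distance strictly below ``cutoff``; the diagonal is zero.
    """
    pos = np.asarray(frame, dtype=float)
    cid = np.asarray(chain_ids, dtype=int)
    n_chains = int(cid.max()) + 1
    dx = pos[None, :, :] - pos[:, None, :]
    dx = minimum_image(dx, None if box is None else np.asarray(box))
    r2 = np.einsum("ijk,ijk->ij", dx, dx)
    contact = (r2 < cutoff * cutoff) & (cid[:, None] != cid[None, :])
    counts = np.zeros((n_chains, n_chains), dtype=int)
    ii, jj = np.nonzero(contact)
    np.add.at(counts, (cid[ii], cid[jj]), 1)
    return counts


def cluster_chains(contact_counts, threshold: int,
                   mode: str = "pairwise") -> np.ndarray:
    """Cluster labels per chain from a contact-count matrix.

    'pairwise' (default): chains i, j are joined when counts[i, j] is
    strictly greater than the threshold; clusters are connected components.
    'aggregate': clusters are merged hierarchically while any two clusters
    share more than ``threshold`` total cross contacts (the alternative
    reading of cluster membership; order-independent by always merging the
    most connected pair first).
    """
    counts = np.asarray(contact_counts)
    if mode == "pairwise":
        adj = csr_matrix(counts > threshold)
        _, labels = connected_components(adj, directed=False)
        return labels
    if mode != "aggregate":
        raise ValueError("mode must be 'pairwise' or 'aggregate'")
    n = counts.shape[0]
    clusters = [{i} for i in range(n)]
    cross = counts.astype(float).copy()
    np.fill_diagonal(cross, -np.inf)
    while len(clusters) > 1:
        k = np.argmax(cross)
        a, b = divmod(int(k), cross.shape[0])
        if cross[a, b] <= threshold:
            break
        a, b = min(a, b), max(a, b)
        clusters[a] |= clusters.pop(b)
        cross[a, :] += cross[b, :]
        cross[:, a] += cross[:, b]
        cross = np.delete(np.delete(cross, b, axis=0), b, axis=1)
        np.fill_diagonal(cross, -np.inf)
    labels = np.empty(n, dtype=int)
    for c, members in enumerate(clusters):
        for i in members:
            labels[i] = c
    return labels


@dataclass
class ClusterSeries:
    """Per-frame cluster assignments of a condensed-phase trajectory."""

    labels: np.ndarray        # (n_frames_retained, n_chains)
    largest_size: np.ndarray  # (n_frames_retained,)
    frame_indices: np.ndarray
    threshold: int
    cutoff: float
    n_chains: int

    def size_distribution(self) -> pd.Series:
        sizes = []
        for lab in self.labels:
            _, counts = np.unique(lab, return_counts=True)
            sizes.extend(counts.tolist())
        return pd.Series(sizes, name="cluster_size").value_counts().sort_index()

    @property
    def largest_fraction(self) -> np.ndarray:
        return self.largest_size / self.n_chains

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.frame_indices,
                             "largest_cluster_size": self.largest_size})


def cluster_series(traj: Trajectory, cutoff: float = 0.6, threshold: int = 20,
                   discard_fraction: float = 0.5,
                   mode: str = "pairwise") -> ClusterSeries:
    """Cluster every retained frame of a multi-chain trajectory.

    The first ``discard_fraction`` of frames is dropped as equilibration,
    mirroring the reference protocol of analysing only the final part of
    condensed-phase runs.
    """
    if traj.n_chains < 2:
        raise ValueError("cluster analysis requires a multi-chain trajectory")
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    start = int(np.floor(traj.n_frames * discard_fraction))
    idx = np.arange(start, traj.n_frames)
    labels = []
    largest = []
    for f in idx:
        counts = chain_pair_contacts(traj.frames[f], traj.chain_id,
                                     box=traj.box, cutoff=cutoff)
        lab = cluster_chains(counts, threshold, mode=mode)
        labels.append(lab)
        _, sizes = np.unique(lab, return_counts=True)
        largest.append(int(sizes.max()))
    return ClusterSeries(labels=np.array(labels), largest_size=np.array(largest),
                         frame_indices=idx, threshold=threshold, cutoff=cutoff,
                         n_chains=traj.n_chains)


@dataclass
class DissolutionSummary:
    mean_largest_fraction: float
    trend: str               # 'decreasing', 'increasing' or 'none'
    mann_kendall_p: float
    time_to_half: float      # frame index (nan when never reached)


def _mann_kendall(x):
    """Mann-Kendall S statistic, normal-approximation two-sided p."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    s = 0
    for i in range(n - 1):
        s += np.sign(x[i + 1:] - x[i]).sum()
    # tie-corrected variance
    _, counts = np.unique(x, return_counts=True)
    var = (n * (n - 1) * (2 * n + 5) -
           np.sum(counts * (counts - 1) * (2 * counts + 5))) / 18.0
    if var == 0:
        return 0.0, 1.0
    z = (s - np.sign(s)) / np.sqrt(var)
    return float(z), float(2 * norm.sf(abs(z)))


def dissolution_metric(series: ClusterSeries,
                       alpha: float = 0.05) -> DissolutionSummary:
    """Scalar summaries of a largest-cluster time series.

    time_to_half is the first retained-frame index at which the largest
    cluster holds at most half the chains (nan when never reached); the
    trend direction comes from a two-sided Mann-Kendall test.
    """
    frac = series.largest_fraction
    if frac.size == 0:
        raise ValueError("empty cluster series")
    z, p = _mann_kendall(frac)
    if p <= alpha and z < 0:
        trend = "decreasing"
    elif p <= alpha and z > 0:
        trend = "increasing"
    else:
        trend = "none"
    half = np.flatnonzero(frac <= 0.5)
    t_half = float(series.frame_indices[half[0]]) if half.size else float("nan")
    return DissolutionSummary(
        mean_largest_fraction=float(frac.mean()), trend=trend,
        mann_kendall_p=p, time_to_half=t_half,
    )
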
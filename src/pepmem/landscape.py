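"""2D free-energy surface over (Rg, RMSD), basin detection and conformer clustering.

G(V) = −k_B·T·[ln P(V) − ln P_max] over the binned joint distribution
of radius of gyration and backbone RMSD, so the modal bin has G = 0 and
empty bins carry a +∞ sentinel (never interpolated).  Conformers are
clustered by hierarchical average linkage on the pairwise
superposition-RMSD matrix, cut at a distance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import DomainError, Trajectory
from .peptide import rmsd as _rmsd

__all__ = [
    "KB_KCAL",
    "FreeEnergySurface",
    "ClusterResult",
    "fes_2d",
    "find_minima",
    "cluster_conformers",
]

#: Boltzmann constant in kcal/(mol·K); k_B·T = 0.5961 kcal/mol at 300 K.
KB_KCAL = 0.0019872041


@dataclass
class FreeEnergySurface:
    """Binned G(Rg, RMSD) grid with minima annotations."""

    rg_edges: np.ndarray
    rmsd_edges: np.ndarray
    G: np.ndarray          # (n_rg, n_rmsd); np.inf marks empty bins
    T: float
    counts: np.ndarray
    minima: Optional[pd.DataFrame] = None

    @property
    def rg_mid(self) -> np.ndarray:
        return 0.5 * (self.rg_edges[:-1] + self.rg_edges[1:])

    @property
    def rmsd_mid(self) -> np.ndarray:
        return 0.5 * (self.rmsd_edges[:-1] + self.rmsd_edges[1:])


@dataclass
class ClusterResult:
    """Frame→cluster assignments with populations and medoid frames."""

    assignments: np.ndarray  # cluster label per frame, 0-based, by population rank
    populations: np.ndarray  # % per cluster, descending
    medoids: np.ndarray      # representative frame index per cluster
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def top_k(self, k: int) -> pd.DataFrame:
        k = min(k, self.n_clusters)
        return pd.DataFrame({
            "cluster": np.arange(k),
            "population_pct": self.populations[:k],
            "medoid_frame": self.medoids[:k],
        })


def fes_2d(
    rg_series: np.ndarray,
    rmsd_series: np.ndarray,
    T: float = 300.0,
    bins: Union[int, Tuple[np.ndarray, np.ndarray]] = 50,
) -> FreeEnergySurface:
    """Free-energy surface from the joint (Rg, RMSD) histogram.

    With an integer ``bins`` the observed range of each coordinate is
    padded by 5% and split into that many equal bins.
    """
    rg = np.asarray(rg_series, float)
    rm = np.asarray(rmsd_series, float)
    if rg.size == 0 or rg.shape != rm.shape:
        raise DomainError("rg and rmsd series must be equal-length and non-empty")
    if isinstance(bins, int):
        edges = []
        for x in (rg, rm):
            lo, hi = x.min(), x.max()
            pad = 0.05 * max(hi - lo, 1e-9)
            edges.append(np.linspace(lo - pad, hi + pad, bins + 1))
        rg_edges, rmsd_edges = edges
    else:
        rg_edges, rmsd_edges = (np.asarray(e, float) for e in bins)
    counts, _, _ = np.histogram2d(rg, rm, bins=(rg_edges, rmsd_edges))
    p = counts / counts.sum()
    g = np.full_like(p, np.inf)
    occ = p > 0
    g[occ] = -KB_KCAL * T * (np.log(p[occ]) - np.log(p.max()))
    return FreeEnergySurface(rg_edges, rmsd_edges, g, T, counts)


def _descend(g: np.ndarray, start: Tuple[int, int]) -> Tuple[int, int]:
    """Discrete steepest descent on the 8-neighborhood; ties prefer the
    lower-G neighbor then the lexicographically smaller bin index."""
    cur = start
    n0, n1 = g.shape
    while True:
        ci, cj = cur
        best = cur
        best_g = g[ci, cj]
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                i, j = ci + di, cj + dj
                if 0 <= i < n0 and 0 <= j < n1 and not (di == 0 and dj == 0):
                    if g[i, j] < best_g or (g[i, j] == best_g and (i, j) < best):
                        best, best_g = (i, j), g[i, j]
        if best == cur:
            return cur
        cur = best


def find_minima(
    fes: FreeEnergySurface,
    min_separation: int = 1,
    max_count: int = 4,
) -> pd.DataFrame:
    """Local minima of G (8-neighborhood) ranked by basin population.

    Each occupied bin is assigned to a basin by discrete steepest
    descent; a basin's population is the fraction of frames whose bins
    drain into its minimum.  At most ``max_count`` minima are returned;
    exact plateau ties resolve to the lexicographically smallest bin.
    """
    g = fes.G
    occ = np.isfinite(g)
    if not occ.any():
        return pd.DataFrame(
            columns=["rank", "rg", "rmsd", "G", "population_pct", "bin_i", "bin_j"]
        )
    total = fes.counts.sum()
    basin_pop: dict = {}
    for i, j in zip(*np.nonzero(occ)):
        sink = _descend(g, (i, j))
        basin_pop[sink] = basin_pop.get(sink, 0.0) + fes.counts[i, j]
    rows = []
    for (i, j), pop in basin_pop.items():
        rows.append({
            "rg": fes.rg_mid[i], "rmsd": fes.rmsd_mid[j], "G": g[i, j],
            "population_pct": 100.0 * pop / total, "bin_i": i, "bin_j": j,
        })
    df = pd.DataFrame(rows).sort_values(
        ["population_pct", "G", "bin_i", "bin_j"], ascending=[False, True, True, True]
    ).reset_index(drop=True)
    if min_separation > 1 and len(df) > 1:
        kept: List[int] = []
        for r in range(len(df)):
            ok = all(
                max(abs(df.loc[r, "bin_i"] - df.loc[k, "bin_i"]),
                    abs(df.loc[r, "bin_j"] - df.loc[k, "bin_j"])) >= min_separation
                for k in kept
            )
            if ok:
                kept.append(r)
        df = df.loc[kept].reset_index(drop=True)
    df = df.head(max_count).copy()
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def pairwise_rmsd_matrix(
    trajectory: Trajectory, atom_selection: Iterable[int]
) -> np.ndarray:
    """Symmetric matrix of superposition RMSDs between all frame pairs."""
    idx = np.asarray(list(atom_selection), int)
    if idx.size == 0:
        raise DomainError("atom selection is empty")
    f = trajectory.n_frames
    mat = np.zeros((f, f))
    sel = trajectory.coords[:, idx, :]
    for i in range(f):
        for j in range(i + 1, f):
            mat[i, j] = mat[j, i] = _rmsd(sel[i], sel[j])
    return mat


def cluster_conformers(
    trajectory: Trajectory,
    atom_selection: Iterable[int],
    cutoff: float = 4.0,
    top_k: int = 10,
    method: str = "average",
) -> ClusterResult:
    """Cluster frames by pairwise superposition RMSD.

    Hierarchical ``average``-linkage cut at ``cutoff`` Å (a k-means
    option with a fixed seed is available via ``method="kmeans:<k>"``).
    Clusters are relabelled by descending population; the medoid is the
    member frame minimizing total intra-cluster RMSD.
    """
    mat = pairwise_rmsd_matrix(trajectory, atom_selection)
    f = mat.shape[0]
    if f == 1:
        return ClusterResult(np.zeros(1, int), np.array([100.0]),
                             np.array([0]), cutoff)
    if method.startswith("kmeans"):
        from sklearn.cluster import KMeans
        k = int(method.split(":", 1)[1])
        idx = np.asarray(list(atom_selection), int)
        flat = trajectory.coords[:, idx, :].reshape(f, -1)
        labels = KMeans(n_clusters=k, random_state=0, n_init=10).fit_predict(flat)
    else:
        z = linkage(squareform(mat, checks=False), method=method)
        labels = fcluster(z, t=cutoff, criterion="distance") - 1
    # relabel by population (ties: smaller first-frame index first)
    uniq = np.unique(labels)
    sizes = np.array([(labels == u).sum() for u in uniq])
    first = np.array([np.flatnonzero(labels == u)[0] for u in uniq])
    order = np.lexsort((first, -sizes))
    remap = {int(uniq[o]): rank for rank, o in enumerate(order)}
    new_labels = np.array([remap[int(u)] for u in labels])
    populations = 100.0 * np.sort(sizes)[::-1] / f
    # stable population ordering consistent with relabelling
    populations = np.array([100.0 * (new_labels == r).sum() / f
                            for r in range(len(uniq))])
    medoids = np.empty(len(uniq), dtype=int)
    for r in range(len(uniq)):
        members = np.flatnonzero(new_labels == r)
        sub = mat[np.ix_(members, members)]
        medoids[r] = members[np.argmin(sub.sum(axis=1))]
    return ClusterResult(new_labels, populations, medoids, cutoff)
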
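"""Two-stage mass-univariate + cluster-based permutation statistics.

Stage 1 runs a one-sample t-test on the log of baseline-normalized
power at every (channel, frequency, time) bin across subjects and
thresholds the t-map two-sided at ``alpha_bin``.  Stage 2 groups
supra-threshold bins of the same sign into clusters — neighbors in
frequency (±1 bin) and time (±1 bin) on the same or a spatially
adjacent sensor (coil positions within 4 cm by default) — sums the
t-values into a cluster mass, and compares each observed mass against
a permutation null of maximal |mass| built by random sign-flips of the
subject maps.  The max-statistic null controls family-wise error
across all clusters.  When the requested permutation count reaches the
number of distinct sign patterns, the null is enumerated exhaustively
instead.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .forward import SensorArray

__all__ = [
    "sensor_adjacency",
    "ClusterResult",
    "two_stage_cluster_test",
    "select_imaging_window",
]

logger = logging.getLogger(__name__)


def sensor_adjacency(sensors: SensorArray,
                     threshold: float = 0.04) -> np.ndarray:
    """Symmetric, irreflexive channel adjacency from coil distances."""
    d = np.linalg.norm(sensors.coil_position[:, None, :]
                       - sensors.coil_position[None, :, :], axis=2)
    adj = d <= threshold
    np.fill_diagonal(adj, False)
    return adj


@dataclass
class ClusterResult:
    """One supra-threshold cluster and its permutation p-value."""

    bins: np.ndarray          # (n_bins, 3) — (channel, freq, time) indices
    cluster_value: float      # summed t over member bins (signed)
    p_value: float
    sign: int                 # +1 or -1
    null_distribution: np.ndarray


def _neighbor_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Per-channel neighbor indices, self first, padded with -1."""
    n = adjacency.shape[0]
    lists = [np.concatenate([[c], np.flatnonzero(adjacency[c])])
             for c in range(n)]
    kmax = max(len(x) for x in lists)
    out = -np.ones((n, kmax), dtype=np.int64)
    for c, x in enumerate(lists):
        out[c, :len(x)] = x
    return out


def _label_components(coords: np.ndarray, tv: np.ndarray,
                      shape: tuple[int, int, int], nbr_mat: np.ndarray):
    """Connected components of one sign's supra-threshold bins.

    ``coords`` (m, 3) and ``tv`` (m,) hold one sign's supra-threshold
    bins and their t-values on a (channels, freqs, times) lattice.
    Two bins are connected when their channels are identical or
    adjacent and they are within ±1 frequency and ±1 time bin.  Edge
    construction is vectorized (one gather per channel-neighbor slot);
    components come from scipy's sparse graph machinery, with a
    union-find fast path for the small supra sets typical of null
    permutations.  Returns (coords, labels, masses) or None.
    """
    n_ch, n_f, n_t = shape
    m = len(coords)
    if m == 0:
        return None
    c, f, t = coords.T

    if m <= 256:
        # union-find over a coordinate dictionary: cheaper than the
        # vectorized path for the sparse supra sets of null data
        index = {(ci, fi, ti): i
                 for i, (ci, fi, ti) in enumerate(map(tuple, coords))}
        parent = list(range(m))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(m):
            ci, fi, ti = coords[i]
            for cn in nbr_mat[ci]:
                if cn < 0:
                    break
                for df in (-1, 0, 1):
                    for dt in (-1, 0, 1):
                        j = index.get((cn, fi + df, ti + dt))
                        if j is not None and j != i:
                            ri, rj = find(i), find(j)
                            if ri != rj:
                                parent[ri] = rj
        roots = np.fromiter((find(i) for i in range(m)), dtype=np.int64)
        _uniq, labels = np.unique(roots, return_inverse=True)
        masses = np.bincount(labels, weights=tv)
        return coords, labels, masses

    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    # padded index cube: out-of-range offsets land on -1 sentinels
    idx_map = np.full((n_ch + 1, n_f + 2, n_t + 2), -1, dtype=np.int64)
    idx_map[c, f + 1, t + 1] = np.arange(m)
    offs_f, offs_t = np.meshgrid((-1, 0, 1), (-1, 0, 1), indexing="ij")
    offs_f, offs_t = offs_f.ravel(), offs_t.ravel()
    fn = (f + 1)[:, None] + offs_f[None, :]
    tn = (t + 1)[:, None] + offs_t[None, :]
    rows, cols = [], []
    row_idx = np.broadcast_to(np.arange(m)[:, None], (m, 9))
    for k in range(nbr_mat.shape[1]):
        cn = nbr_mat[c, k]           # -1 padding maps to sentinel row
        j = idx_map[cn[:, None], fn, tn]
        good = j >= 0
        if good.any():
            rows.append(row_idx[good])
            cols.append(j[good])
    graph = coo_matrix(
        (np.ones(sum(len(r) for r in rows), dtype=np.int8),
         (np.concatenate(rows), np.concatenate(cols))), shape=(m, m))
    n_comp, labels = connected_components(graph, directed=False)
    masses = np.bincount(labels, weights=tv, minlength=n_comp)
    return coords, labels, masses


def _split_by_sign(coords: np.ndarray, tv: np.ndarray):
    pos = tv > 0
    yield coords[pos], tv[pos]
    yield coords[~pos], tv[~pos]


def _clusters_from_bins(coords: np.ndarray, tv: np.ndarray,
                        shape: tuple[int, int, int], nbr_mat: np.ndarray
                        ) -> list[tuple[np.ndarray, float]]:
    """All same-sign clusters as (member coords, summed t) pairs."""
    out: list[tuple[np.ndarray, float]] = []
    for cs, ts in _split_by_sign(coords, tv):
        comp = _label_components(cs, ts, shape, nbr_mat)
        if comp is None:
            continue
        ccoords, labels, masses = comp
        order = np.argsort(labels, kind="stable")
        bounds = np.searchsorted(labels[order],
                                 np.arange(len(masses) + 1))
        for lab in range(len(masses)):
            members = ccoords[order[bounds[lab]:bounds[lab + 1]]]
            out.append((members, float(masses[lab])))
    return out


def _max_cluster_mass(coords: np.ndarray, tv: np.ndarray,
                      shape: tuple[int, int, int],
                      nbr_mat: np.ndarray) -> float:
    """Largest |summed t| over clusters (0 when nothing is supra)."""
    best = 0.0
    for cs, ts in _split_by_sign(coords, tv):
        comp = _label_components(cs, ts, shape, nbr_mat)
        if comp is not None:
            best = max(best, float(np.abs(comp[2]).max()))
    return best


def two_stage_cluster_test(maps: np.ndarray, adjacency: np.ndarray,
                           alpha_bin: float = 0.05, n_perm: int = 5000,
                           seed: int | None = None,
                           log_transform: bool = True
                           ) -> list[ClusterResult]:
    """Cluster-permutation test of normalized power against baseline.

    Parameters
    ----------
    maps : (n_subjects, n_channels, n_freqs, n_times)
        Baseline-normalized power per subject (ratios; the test runs on
        their log unless ``log_transform`` is False).
    adjacency : (n_channels, n_channels) boolean sensor adjacency.
    """
    maps = np.asarray(maps, dtype=float)
    n_subj = maps.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    shape = maps.shape[1:]
    X = np.log(maps).reshape(n_subj, -1) if log_transform \
        else maps.reshape(n_subj, -1)

    t_crit = float(stats.t.ppf(1.0 - alpha_bin / 2.0, n_subj - 1))
    nbr = _neighbor_matrix(adjacency)
    n = n_subj
    sumsq = (X ** 2).sum(axis=0)
    # |t| > t_crit is equivalent to S² > thr2 for the column sum S,
    # which lets permutations skip materializing full t-maps
    thr2 = n * t_crit ** 2 * sumsq / ((n - 1) + t_crit ** 2)

    def _supra(S):
        idx = np.flatnonzero(S ** 2 > thr2)
        if idx.size == 0:
            return idx, None, None
        mean = S[idx] / n
        var = (sumsq[idx] - n * mean ** 2) / (n - 1)
        tv = mean / np.sqrt(np.maximum(var, 1e-300) / n)
        coords = np.column_stack(np.unravel_index(idx, shape))
        return idx, coords, tv

    S_obs = X.sum(axis=0)
    _idx, coords_obs, tv_obs = _supra(S_obs)
    if coords_obs is None:
        return []
    observed = _clusters_from_bins(coords_obs, tv_obs, shape, nbr)
    if not observed:
        return []

    if n_perm >= 2 ** n_subj:
        logger.info("n_perm=%d >= 2^%d sign patterns: enumerating "
                    "exhaustively", n_perm, n_subj)
        flips = np.array(list(itertools.product((1.0, -1.0),
                                                repeat=n_subj)))
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))

    null_max = np.zeros(flips.shape[0])
    chunk = max(1, int(4e7 // max(X.shape[1], 1)))
    for lo in range(0, flips.shape[0], chunk):
        sums = flips[lo:lo + chunk] @ X
        for k in range(sums.shape[0]):
            _idx, coords, tv = _supra(sums[k])
            if coords is not None:
                null_max[lo + k] = _max_cluster_mass(coords, tv, shape, nbr)

    n_null = len(null_max)
    results = []
    for members, mass in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (n_null + 1.0)
        results.append(ClusterResult(members, mass, float(p),
                                     int(np.sign(mass)), null_max))
    results.sort(key=lambda c: abs(c.cluster_value), reverse=True)
    return results


def select_imaging_window(clusters: list[ClusterResult],
                          freq_axis: np.ndarray, time_axis: np.ndarray,
                          target_freq: float, alpha: float = 0.05
                          ) -> dict | None:
    """Tightest time–frequency window covering the cluster at a target.

    Among significant positive clusters whose frequency extent covers
    ``target_freq``, takes the one with the largest mass and returns
    its covering window, with the band clipped to ±1 Hz around the
    target (the envelope statistics use a 1 Hz resolution).  Returns
    None when no significant cluster covers the target.
    """
    best = None
    for cl in clusters:
        if cl.p_value >= alpha or cl.sign < 0:
            continue
        f = freq_axis[cl.bins[:, 1]]
        if f.min() - 0.5 <= target_freq <= f.max() + 0.5:
            if best is None or abs(cl.cluster_value) > abs(best.cluster_value):
                best = cl
    if best is None:
        return None
    f = freq_axis[best.bins[:, 1]]
    t = time_axis[best.bins[:, 2]]
    return {
        "fmin": max(float(f.min()), target_freq - 1.0),
        "fmax": min(float(f.max()), target_freq + 1.0),
        "tmin": float(t.min()),
        "tmax": float(t.max()),
        "cluster": best,
    }
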
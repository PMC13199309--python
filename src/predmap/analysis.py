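"""Quantitative readouts of simulated runs.

All statistics work on binned, occupancy-normalized spatial activity maps
built from a trajectory and aligned per-step unit activities, with full
torus awareness: connected components wrap across edges, field centers of
mass are circular means, and all distances are shortest wrapped distances.

The headline readouts are:

* per-unit place-field summaries (peak, center of mass, skew vector);
* population skew statistics (mean ± SD of |skew|, direction histogram,
  Welch's t-test between layers);
* lag-1 autocorrelation of unit activity along the trajectory;
* kernel density estimates of field-center positions (periodic, Scott's
  rule) and of nearest-neighbor field-center distances;
* cross-context remapping tables with reward-tracking classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .environments import wrapped_difference

__all__ = [
    "ActivityMap",
    "PlaceFieldSummary",
    "activity_map",
    "activity_maps",
    "field_summary",
    "summarize_fields",
    "skew_population_stats",
    "lag1_autocorr",
    "lag1_autocorr_batch",
    "center_density",
    "min_pairwise_distances",
    "remapping_table",
]

SILENT_MEAN_ACTIVITY = 1e-4
FIELD_THRESHOLD = 0.2


@dataclass
class ActivityMap:
    """Occupancy-normalized mean activity on a spatial grid.

    ``mean`` has shape (nbins,) in 1D or (nbx, nby) in 2D (x first);
    unvisited bins hold 0 and are flagged in ``occupancy``.
    """

    mean: np.ndarray
    occupancy: np.ndarray
    L: float

    @property
    def bin_size(self):
        return self.L / self.mean.shape[0]

    def bin_centers(self, axis=0):
        n = self.mean.shape[axis]
        return (np.arange(n) + 0.5) * self.L / n


def _bin_indices(positions, L, bins):
    idx = np.floor(np.asarray(positions, dtype=float) / L * bins).astype(int)
    return np.clip(idx, 0, bins - 1)


def activity_maps(positions, activities, L, bins=50):
    """Binned occupancy-normalized maps for many units at once.

    ``positions``: (T,) or (T, 2); ``activities``: (T, N). Returns
    (maps, occupancy) where maps has shape (bins, N) in 1D or
    (bins, bins, N) in 2D. Unvisited bins are 0.
    """
    positions = np.asarray(positions, dtype=float)
    activities = np.asarray(activities, dtype=float)
    if len(positions) == 0:
        raise ValueError("empty trajectory")
    if len(positions) != len(activities):
        raise ValueError("positions and activities must be aligned per step")
    n_units = activities.shape[1]
    if positions.ndim == 1:
        idx = _bin_indices(positions, L, bins)
        occ = np.bincount(idx, minlength=bins).astype(float)
        sums = np.zeros((bins, n_units))
        np.add.at(sums, idx, activities)
        maps = np.divide(sums, occ[:, None], out=np.zeros_like(sums),
                         where=occ[:, None] > 0)
        return maps, occ
    ix = _bin_indices(positions[:, 0], L, bins)
    iy = _bin_indices(positions[:, 1], L, bins)
    flat = ix * bins + iy
    occ = np.bincount(flat, minlength=bins * bins).astype(float)
    sums = np.zeros((bins * bins, n_units))
    np.add.at(sums, flat, activities)
    maps = np.divide(sums, occ[:, None], out=np.zeros_like(sums),
                     where=occ[:, None] > 0)
    return maps.reshape(bins, bins, n_units), occ.reshape(bins, bins)


def activity_map(positions, unit_activity, L, bins=50):
    """Single-unit occupancy-normalized :class:`ActivityMap`."""
    acts = np.asarray(unit_activity, dtype=float).reshape(-1, 1)
    maps, occ = activity_maps(positions, acts, L, bins)
    return ActivityMap(mean=maps[..., 0], occupancy=occ, L=L)


# ---------------------------------------------------------------------------
# place-field geometry on the torus
# ---------------------------------------------------------------------------

def _periodic_label(mask):
    """Connected-component labels with wrap-around on every axis."""
    labels, n = ndimage.label(mask)
    if n <= 1:
        return labels
    parent = np.arange(n + 1)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for axis in range(mask.ndim):
        lo = np.take(labels, 0, axis=axis).ravel()
        hi = np.take(labels, -1, axis=axis).ravel()
        for a, b in zip(lo, hi):
            if a and b:
                union(a, b)
    remap = np.array([find(i) for i in range(n + 1)])
    return remap[labels]


def _circular_com(coords, weights, L):
    """Activity-weighted circular mean of positions on a ring of period L."""
    ang = 2.0 * np.pi * np.asarray(coords) / L
    s = np.sum(weights * np.sin(ang))
    c = np.sum(weights * np.cos(ang))
    return (L / (2.0 * np.pi)) * np.mod(np.arctan2(s, c), 2.0 * np.pi)


@dataclass
class PlaceFieldSummary:
    """Geometry of one unit's place field on the torus/ring."""

    unit: int
    peak: np.ndarray            # bin-center location of the activity peak
    com: np.ndarray             # circular center of mass over the field
    skew: np.ndarray            # wrapped (com − peak)
    peak_rate: float
    area: float                 # field area (m² in 2D, m in 1D)
    silent: bool = False

    @property
    def skew_magnitude(self):
        return float(np.linalg.norm(self.skew))


def field_summary(amap: ActivityMap, unit=0, threshold=FIELD_THRESHOLD):
    """Place-field geometry of one activity map.

    The field is the periodic connected component above ``threshold·max``
    that contains the peak bin; the center of mass is the activity-weighted
    circular mean over that component, and the skew vector is the shortest
    wrapped displacement from peak to COM.
    """
    m = np.asarray(amap.mean, dtype=float)
    L = amap.L
    if m.max() <= 0:
        nan = np.full(m.ndim, np.nan)
        return PlaceFieldSummary(unit, nan, nan, nan, 0.0, 0.0, silent=True)
    peak_idx = np.unravel_index(np.argmax(m), m.shape)
    labels = _periodic_label(m >= threshold * m.max())
    field = labels == labels[peak_idx]
    bin_w = L / m.shape[0]
    centers = [(np.arange(n) + 0.5) * L / n for n in m.shape]
    coords = np.meshgrid(*centers, indexing="ij")
    w = m[field]
    com = np.array([_circular_com(c[field], w, L) for c in coords])
    peak = np.array([c[peak_idx] for c in coords])
    skew = wrapped_difference(com, peak, L)
    area = float(field.sum()) * bin_w ** m.ndim
    return PlaceFieldSummary(unit, peak, com, skew, float(m.max()), area)


def summarize_fields(maps, occupancy, L, threshold=FIELD_THRESHOLD,
                     silent_mean=SILENT_MEAN_ACTIVITY):
    """Per-unit field summaries for a stack of maps (last axis = units).

    Units whose mean map activity over visited bins falls below
    ``silent_mean`` are flagged silent and excluded from field statistics.
    """
    maps = np.asarray(maps, dtype=float)
    n_units = maps.shape[-1]
    visited = occupancy > 0
    out = []
    for u in range(n_units):
        m = maps[..., u]
        if m[visited].mean() < silent_mean:
            nan = np.full(m.ndim, np.nan)
            out.append(PlaceFieldSummary(u, nan, nan, nan, 0.0, 0.0, silent=True))
        else:
            s = field_summary(ActivityMap(m, occupancy, L), unit=u, threshold=threshold)
            out.append(s)
    return out


def skew_population_stats(summaries, n_angle_bins=16):
    """Population statistics of skew vectors of non-silent units.

    Returns a dict with magnitudes, directions, their mean ± SD, the
    circular-mean direction, and a rose histogram over ``n_angle_bins``.
    """
    active = [s for s in summaries if not s.silent]
    if len(active) < 2:
        raise ValueError("need at least two non-silent units")
    mags = np.array([s.skew_magnitude for s in active])
    skews = np.array([s.skew for s in active])
    if skews.shape[1] == 2:
        dirs = np.arctan2(skews[:, 1], skews[:, 0])
    else:
        dirs = np.where(skews[:, 0] >= 0, 0.0, np.pi)
    edges = np.linspace(-np.pi, np.pi, n_angle_bins + 1)
    rose, _ = np.histogram(dirs, bins=edges)
    circ_mean = np.arctan2(np.mean(np.sin(dirs)), np.mean(np.cos(dirs)))
    return {
        "magnitudes": mags,
        "directions": dirs,
        "mean": float(mags.mean()),
        "sd": float(mags.std(ddof=1)),
        "circular_mean_direction": float(circ_mean),
        "rose": rose,
        "rose_edges": edges,
        "n_units": len(active),
    }


def welch_ttest(a, b):
    """Welch's unequal-variance t-test (two-sided)."""
    return stats.ttest_ind(a, b, equal_var=False)


def lag1_autocorr(series):
    """Pearson correlation of (x_t, x_{t+1}); 0 for (near-)constant series."""
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise ValueError("series must have length >= 3")
    a, b = x[:-1], x[1:]
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def lag1_autocorr_batch(activities):
    """Lag-1 autocorrelation per column of a (T, N) activity matrix."""
    X = np.asarray(activities, dtype=float)
    a, b = X[:-1], X[1:]
    sa, sb = a.std(axis=0), b.std(axis=0)
    cov = np.mean((a - a.mean(axis=0)) * (b - b.mean(axis=0)), axis=0)
    denom = sa * sb
    return np.divide(cov, denom, out=np.zeros_like(cov), where=denom > 1e-24)


# ---------------------------------------------------------------------------
# field-center densities and remapping
# ---------------------------------------------------------------------------

def center_density(centers, L, grid=None):
    """Periodic Gaussian KDE (Scott's rule) of field-center positions.

    Periodicity is handled by tiling the sample across neighboring copies
    of the fundamental domain and rescaling the density accordingly.
    Returns (grid_points, density).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] == 1 and centers.shape[1] > 2:
        centers = centers.T
    n, d = centers.shape
    if n < 5:
        raise ValueError("need at least 5 centers for a KDE")
    shifts = np.array([-L, 0.0, L])
    if d == 1:
        kde = stats.gaussian_kde(centers[:, 0])   # bandwidth from the raw sample
        if grid is None:
            grid = np.linspace(0, L, 200, endpoint=False) + L / 400
        dens = sum(kde(np.asarray(grid) + s) for s in shifts)
        return grid, dens
    kde = stats.gaussian_kde(centers.T)
    if grid is None:
        ax = np.linspace(0, L, 50, endpoint=False) + L / 100
        gx, gy = np.meshgrid(ax, ax, indexing="ij")
        grid = np.column_stack([gx.ravel(), gy.ravel()])
    grid = np.asarray(grid, dtype=float)
    offs = np.array([(sx, sy) for sx in shifts for sy in shifts])
    dens = sum(kde((grid + o).T) for o in offs)
    return grid, dens


def torus_distance_matrix(a, b, L):
    """Pairwise shortest wrapped distances between point sets on the torus."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] not in (1, 2):
        a, b = a.T, b.T
    d = wrapped_difference(a[:, None, :], b[None, :, :], L)
    return np.sqrt(np.sum(d * d, axis=-1))


def min_pairwise_distances(centers, L):
    """Nearest-neighbor wrapped distance for each field center."""
    centers = np.asarray(centers, dtype=float)
    if centers.ndim == 1:
        centers = centers[:, None]
    if len(centers) < 2:
        raise ValueError("need at least two centers")
    D = torus_distance_matrix(centers, centers, L)
    np.fill_diagonal(D, np.inf)
    return D.min(axis=1)


def _distance_to_interval(x, interval, L):
    """Shortest wrapped distance from a point to a closed interval on a ring."""
    a, b = interval
    if a <= x <= b:
        return 0.0
    return float(min(abs(wrapped_difference(x, a, L)), abs(wrapped_difference(x, b, L))))


def remapping_table(summaries_1, summaries_2, reward_interval_1,
                    reward_interval_2, L, tracking_radius=0.3):
    """Pair field centers across two contexts and flag reward-tracking units.

    A unit is reward-tracking when its field center lies within
    ``tracking_radius`` of the (relocated) reward interval in *both*
    contexts. Returns a pandas DataFrame with one row per unit.
    """
    import pandas as pd

    if len(summaries_1) != len(summaries_2):
        raise ValueError("contexts must summarize the same units")
    rows = []
    for s1, s2 in zip(summaries_1, summaries_2):
        if s1.unit != s2.unit:
            raise ValueError("unit ids must align across contexts")
        silent = s1.silent or s2.silent
        if silent:
            rows.append((s1.unit, np.nan, np.nan, True, False))
            continue
        c1 = float(np.atleast_1d(s1.com)[0])
        c2 = float(np.atleast_1d(s2.com)[0])
        tracking = (
            _distance_to_interval(c1, reward_interval_1, L) <= tracking_radius
            and _distance_to_interval(c2, reward_interval_2, L) <= tracking_radius
        )
        rows.append((s1.unit, c1, c2, False, tracking))
    return pd.DataFrame(
        rows, columns=["unit", "center_ctx1", "center_ctx2", "silent", "reward_tracking"]
    )
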
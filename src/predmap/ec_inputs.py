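"""Parametric entorhinal population codes.

Four cell classes provide the input vector to the sparse coding layer:

* **Grid cells** (MEC): hexagonally periodic fields built from three cosine
  gratings at 120°, parameterized by spacing λ, orientation θ and 2D phase.
  Activity is ``g(x) = (2/3)·[(1/3)·Σ_j cos(k·u_j·(x − x0)) + 1/2]`` with
  wave number ``k = 4π/(√3·λ)``, so fields span [0, 1] with peak 1 at the
  phase center and field spacing exactly λ. 1D activity is a slice of the
  2D field at a fixed y.
* **Boundary-tuned inputs** (MEC, 2D only): Gaussian over the distance to the
  nearest periodic boundary times a Gaussian over the along-boundary phase,
  scaled by 0.83 to match typical grid peaks. These anchor the coordinate
  frame where grid codes are discontinuous across the wrap; they are a
  modelling device, not biological border cells.
* **Object cells** (LEC, 2D only): sum of one Gaussian bump per object,
  centers jittered around the object locations.
* **Pre-/post-reward cells** (LEC, 1D only): Gaussian envelope anchored at
  the reward location multiplied by a sigmoid gate that switches off past
  (pre) or before (post) the reward.

All population parameters are sampled once at construction from the stated
uniform ranges and are fixed thereafter; the reward-cell anchor may be
re-anchored when the reward moves between contexts.
"""

from __future__ import annotations

import numpy as np

from .environments import wrapped_difference

__all__ = [
    "GridCellPopulation",
    "BoundaryInputPopulation",
    "ObjectCellPopulation",
    "RewardCellPopulation",
    "EntorhinalCortex",
    "grid_activity",
    "boundary_activity",
    "object_activity",
    "reward_cell_activity",
    "default_grid_spacings",
]

GRID_MIN_SPACING = 0.28
GRID_SPACING_RATIO = 1.42
GRID_N_SPACINGS = 4
GRID_ORIENTATIONS = np.deg2rad(np.arange(0, 360, 60))  # 6 orientations
GRID_PHASES_PER_AXIS = 5
BOUNDARY_AMPLITUDE = 0.83


def default_grid_spacings():
    """Geometric spacing sequence 0.28 m scaled by 1.42, all under 1 m."""
    return GRID_MIN_SPACING * GRID_SPACING_RATIO ** np.arange(GRID_N_SPACINGS)


def grid_activity(position, spacing, orientation, phase):
    """Hexagonal grid-cell activity at 2D position(s); range [0, 1].

    Vectorized over cells when ``spacing``/``orientation``/``phase`` are
    arrays, and over positions when ``position`` has shape (M, 2).
    """
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("grid spacing must be positive")
    orientation = np.asarray(orientation, dtype=float)
    phase = np.asarray(phase, dtype=float)
    pos = np.atleast_2d(np.asarray(position, dtype=float))  # (M, 2)
    squeeze = np.asarray(position).ndim == 1

    k = 4.0 * np.pi / (np.sqrt(3.0) * spacing)              # (N,)
    diff = pos[:, None, :] - np.atleast_2d(phase)[None, :, :]  # (M, N, 2)
    total = np.zeros(diff.shape[:2])
    for j in (1, 2, 3):
        ang = 2.0 * np.pi * j / 3.0 + orientation
        proj = diff[..., 0] * np.cos(ang) + diff[..., 1] * np.sin(ang)
        total += np.cos(k * proj)
    g = (2.0 / 3.0) * (total / 3.0 + 0.5)
    return g[0] if squeeze else g


def boundary_activity(position, scale, orientation, phase, L):
    """Boundary-tuned input activity at 2D position(s).

    ``orientation`` 0 responds to left–right boundaries (distance taken
    along x), 1 to top–bottom boundaries (distance along y).
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    squeeze = np.asarray(position).ndim == 1
    scale = np.asarray(scale, dtype=float)
    orientation = np.asarray(orientation)
    phase = np.atleast_2d(np.asarray(phase, dtype=float))

    x, y = pos[:, 0:1], pos[:, 1:2]                    # (M, 1)
    dist_x = np.minimum(x, L - x)
    dist_y = np.minimum(y, L - y)
    two_s2 = 2.0 * scale**2
    b_lr = np.exp(-dist_x**2 / two_s2) * np.exp(-((y - phase[:, 1]) ** 2) / two_s2)
    b_tb = np.exp(-dist_y**2 / two_s2) * np.exp(-((x - phase[:, 0]) ** 2) / two_s2)
    b = BOUNDARY_AMPLITUDE * np.where(orientation == 0, b_lr, b_tb)
    return b[0] if squeeze else b


def object_activity(position, centers, amplitudes, widths):
    """LEC object-cell activity: sum of Gaussian bumps, one per object.

    ``centers`` has shape (N, n_obj, 2); ``amplitudes``/``widths`` (N, n_obj).
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    squeeze = np.asarray(position).ndim == 1
    centers = np.asarray(centers, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    widths = np.asarray(widths, dtype=float)

    d2 = np.sum((pos[:, None, None, :] - centers[None]) ** 2, axis=-1)  # (M, N, n_obj)
    act = np.sum(amplitudes * np.exp(-d2 / (2.0 * widths**2)), axis=-1)
    return act[0] if squeeze else act


def reward_cell_activity(x, anchor, offset, width, sharpness, kind, L=None):
    """Pre-/post-reward cell activity on a 1D track.

    Gaussian envelope around ``anchor + offset`` gated by a sigmoid:
    pre-reward cells switch off just past the reward, post-reward cells
    switch on just past it. When ``L`` is given, the signed distance to the
    anchored center is taken on the ring (shortest wrapped difference).
    """
    xv = np.atleast_1d(np.asarray(x, dtype=float))[:, None]     # (M, 1)
    squeeze = np.asarray(x).ndim == 0
    center = anchor + np.asarray(offset, dtype=float)           # (N,)
    if L is not None:
        d = wrapped_difference(xv, center, L)
    else:
        d = xv - center
    env = np.exp(-(d**2) / (2.0 * np.asarray(width, dtype=float) ** 2))
    z = d / np.asarray(sharpness, dtype=float)
    sig = 1.0 / (1.0 + np.exp(-z))
    is_pre = np.asarray(kind) == "pre"
    gate = np.where(is_pre, 1.0 - sig, 1.0 - (1.0 - sig))  # post gate = S(z)
    act = env * gate
    return act[0] if squeeze else act


class GridCellPopulation:
    """Deterministic grid of 4 spacings × 6 orientations × 25 phases = 600 cells."""

    def __init__(self, phases_per_axis=GRID_PHASES_PER_AXIS, y0=0.5):
        spacings = default_grid_spacings()
        lam, theta, phase = [], [], []
        for s in spacings:
            offsets = np.arange(phases_per_axis) * s / phases_per_axis
            for o in GRID_ORIENTATIONS:
                for px in offsets:
                    for py in offsets:
                        lam.append(s)
                        theta.append(o)
                        phase.append((px, py))
        self.spacing = np.array(lam)
        self.orientation = np.array(theta)
        self.phase = np.array(phase)
        self.y0 = y0

    @property
    def n_cells(self):
        return len(self.spacing)

    def activity(self, position):
        """Activity vector at 2D position(s) (shape (2,) or (M, 2))."""
        return grid_activity(position, self.spacing, self.orientation, self.phase)

    def activity_1d(self, x):
        """1D-track activity: slice of the 2D field along y = y0."""
        xv = np.atleast_1d(np.asarray(x, dtype=float))
        pos = np.column_stack([xv, np.full_like(xv, self.y0)])
        act = self.activity(pos)
        return act[0] if np.asarray(x).ndim == 0 else act


class BoundaryInputPopulation:
    """300 boundary-tuned inputs, half per boundary orientation."""

    def __init__(self, rng, n_cells=300, L=1.0, scale_range=(0.08, 0.12)):
        if n_cells % 2:
            raise ValueError("n_cells must be even (half per orientation)")
        self.L = L
        self.scale = rng.uniform(*scale_range, size=n_cells)
        self.orientation = np.repeat([0, 1], n_cells // 2)
        self.phase = rng.uniform(0.0, L, size=(n_cells, 2))

    @property
    def n_cells(self):
        return len(self.scale)

    def activity(self, position):
        return boundary_activity(position, self.scale, self.orientation, self.phase, self.L)


class ObjectCellPopulation:
    """600 LEC object cells; each has one jittered center per object."""

    def __init__(self, rng, object_locations, n_cells=600,
                 jitter=0.07, amplitude_range=(0.5, 1.0), width_range=(0.03, 0.06)):
        objects = np.asarray(object_locations, dtype=float)    # (n_obj, 2)
        n_obj = len(objects)
        eps = rng.uniform(-jitter, jitter, size=(n_cells, n_obj, 2))
        self.centers = objects[None] + eps
        self.amplitudes = rng.uniform(*amplitude_range, size=(n_cells, n_obj))
        self.widths = rng.uniform(*width_range, size=(n_cells, n_obj))

    @property
    def n_cells(self):
        return len(self.centers)

    def activity(self, position):
        return object_activity(position, self.centers, self.amplitudes, self.widths)


class RewardCellPopulation:
    """600 LEC reward-modulated cells: 300 pre-reward + 300 post-reward.

    The anchor tracks the reward-zone center and can be re-anchored when the
    reward relocates; per-cell offsets, widths and gate sharpness are fixed.
    """

    def __init__(self, rng, anchor, n_cells=600, L=4.0,
                 offset_range=(-0.05, 0.05), width_range=(0.3, 0.6),
                 sharpness_range=(0.01, 0.05)):
        if n_cells % 2:
            raise ValueError("n_cells must be even (half pre, half post)")
        self.L = L
        self.anchor = float(anchor)
        self.offset = rng.uniform(*offset_range, size=n_cells)
        self.width = rng.uniform(*width_range, size=n_cells)
        self.sharpness = rng.uniform(*sharpness_range, size=n_cells)
        self.kind = np.array(["pre"] * (n_cells // 2) + ["post"] * (n_cells // 2))

    @property
    def n_cells(self):
        return len(self.offset)

    def re_anchor(self, anchor):
        self.anchor = float(anchor)

    def activity(self, x):
        return reward_cell_activity(
            x, self.anchor, self.offset, self.width, self.sharpness, self.kind, L=self.L
        )


class EntorhinalCortex:
    """Assembles the entorhinal input vector s_e for one environment.

    Concatenation order is fixed: grid, boundary, reward, object — matching
    the MEC block (grid then boundary) followed by the LEC blocks. Boundary
    and object populations are valid only in 2D; reward cells only in 1D.
    """

    def __init__(self, grid, boundary=None, reward=None, objects=None, ndim=2):
        if ndim == 1 and (boundary is not None or objects is not None):
            raise ValueError("boundary/object populations are 2D-only")
        if ndim == 2 and reward is not None:
            raise ValueError("reward-cell populations are 1D-only")
        self.grid = grid
        self.boundary = boundary
        self.reward = reward
        self.objects = objects
        self.ndim = ndim

    @property
    def n_inputs(self):
        n = self.grid.n_cells
        for pop in (self.boundary, self.reward, self.objects):
            if pop is not None:
                n += pop.n_cells
        return n

    def encode(self, position):
        """Input vector(s) s_e at wrapped position(s)."""
        parts = []
        if self.ndim == 1:
            parts.append(self.grid.activity_1d(position))
        else:
            parts.append(self.grid.activity(position))
        if self.boundary is not None:
            parts.append(self.boundary.activity(position))
        if self.reward is not None:
            parts.append(self.reward.activity(position))
        if self.objects is not None:
            parts.append(self.objects.activity(position))
        return np.concatenate(parts, axis=-1)

    def save_parameters(self, path):
        arrays = {
            "grid_spacing": self.grid.spacing,
            "grid_orientation": self.grid.orientation,
            "grid_phase": self.grid.phase,
        }
        if self.boundary is not None:
            arrays.update(
                boundary_scale=self.boundary.scale,
                boundary_orientation=self.boundary.orientation,
                boundary_phase=self.boundary.phase,
            )
        if self.reward is not None:
            arrays.update(
                reward_anchor=np.array(self.reward.anchor),
                reward_offset=self.reward.offset,
                reward_width=self.reward.width,
                reward_sharpness=self.reward.sharpness,
                reward_kind=self.reward.kind,
            )
        if self.objects is not None:
            arrays.update(
                object_centers=self.objects.centers,
                object_amplitudes=self.objects.amplitudes,
                object_widths=self.objects.widths,
            )
        np.savez(path, **arrays)
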
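"""Continuous periodic environments and agent kinematics.

Two arenas are modelled, both with periodic boundary conditions (opposite
edges identified, i.e. a torus):

* :class:`Arena2D` — a square arena of side ``L`` (default 1 m) with an
  axis-aligned rectangular reward region and optional point objects.
* :class:`Track1D` — a circular track of length 4 m with a reward interval
  that can be relocated between behavioural contexts.

Positions are always stored wrapped into ``[0, L)`` per coordinate; all
distances and displacements are interpreted modulo ``L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Arena2D",
    "Track1D",
    "TrajectoryRecord",
    "wrap_position",
    "wrapped_difference",
    "step_biased_policy",
    "step_random_walk",
    "reward_at",
    "sample_start_2d",
]


def wrap_position(position, L):
    """Wrap ``position`` (scalar or array-like) into ``[0, L)`` per coordinate."""
    if L <= 0:
        raise ValueError(f"environment size must be positive, got L={L}")
    w = np.mod(np.asarray(position, dtype=float), L)
    # np.mod of a tiny negative can round up to exactly L; fold it back
    return np.where(w >= L, w - L, w)


def wrapped_difference(a, b, L):
    """Shortest signed displacement a − b on a ring/torus of period ``L``.

    Result lies in ``[−L/2, L/2)`` per coordinate.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return np.mod(d + L / 2.0, L) - L / 2.0


@dataclass
class Arena2D:
    """Square periodic arena.

    The reward region is a closed axis-aligned box; membership uses closed
    intervals so that e.g. ``0.4 <= x <= 0.6`` delivers reward at both
    endpoints.
    """

    L: float = 1.0
    reward_region: tuple[float, float, float, float] | None = None  # x_lo, x_hi, y_lo, y_hi
    reward_magnitude: float = 10.0
    object_locations: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.reward_region is not None:
            x_lo, x_hi, y_lo, y_hi = self.reward_region
            if not (0 <= x_lo < x_hi <= self.L and 0 <= y_lo < y_hi <= self.L):
                raise ValueError(f"invalid reward region {self.reward_region}")
        for o in self.object_locations:
            if not (0 <= o[0] < self.L and 0 <= o[1] < self.L):
                raise ValueError(f"object location {o} outside [0, L)^2")

    @property
    def ndim(self) -> int:
        return 2

    def reward_at(self, position) -> float:
        if self.reward_region is None:
            return 0.0
        x, y = position
        x_lo, x_hi, y_lo, y_hi = self.reward_region
        if x_lo <= x <= x_hi and y_lo <= y <= y_hi:
            return self.reward_magnitude
        return 0.0


@dataclass
class Track1D:
    """Periodic linear track with a relocatable reward interval.

    The reward task on this track is continuing (no episode resets); a
    behavioural context is a block of steps with a fixed reward interval.
    Reward is delivered on every step spent inside the closed interval.
    """

    L: float = 4.0
    reward_interval: tuple[float, float] = (3.56, 3.76)
    reward_magnitude: float = 1.0
    context_id: str = "A_end"

    def __post_init__(self):
        a, b = self.reward_interval
        if not (0 <= a < b <= self.L):
            raise ValueError(f"invalid reward interval {self.reward_interval}")

    @property
    def ndim(self) -> int:
        return 1

    @property
    def reward_center(self) -> float:
        a, b = self.reward_interval
        return 0.5 * (a + b)

    def set_context(self, context_id: str, reward_interval: tuple[float, float]):
        self.context_id = context_id
        self.reward_interval = reward_interval
        self.__post_init__()

    def reward_at(self, position) -> float:
        x = float(np.asarray(position).reshape(-1)[0])
        a, b = self.reward_interval
        return self.reward_magnitude if a <= x <= b else 0.0


def reward_at(position, environment) -> float:
    """Scalar reward at a wrapped position in the given environment."""
    return environment.reward_at(position)


def step_biased_policy(position, L, rng, speed=0.1, angular_noise_sd=1.0):
    """One step of the fixed upward-biased policy in a 2D arena.

    The agent moves a constant distance ``speed`` in direction
    ``π/2 + ε`` with ``ε ~ Normal(0, angular_noise_sd²)`` — predominantly
    upward head direction perturbed by angular noise.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    eps = rng.normal(0.0, angular_noise_sd)
    heading = np.pi / 2.0 + eps
    disp = speed * np.array([np.cos(heading), np.sin(heading)])
    return wrap_position(np.asarray(position) + disp, L)


def step_random_walk(position, L, rng, speed=0.1):
    """Uniform-heading exploration step (2D) or uniform forward step (1D)."""
    position = np.asarray(position, dtype=float)
    if position.ndim == 0 or position.size == 1:
        # 1D track: forward displacement uniform in (0, speed] for coverage
        dx = rng.uniform(0.0, speed)
        return wrap_position(position + dx, L)
    heading = rng.uniform(0.0, 2 * np.pi)
    disp = speed * np.array([np.cos(heading), np.sin(heading)])
    return wrap_position(position + disp, L)


def sample_start_2d(rng, L=1.0, edge=0.1):
    """Random start near the arena boundary.

    Exactly one coordinate is drawn from an edge interval
    ``[0, edge] ∪ [L−edge, L]`` (edge and coordinate chosen uniformly); the
    other coordinate is uniform on ``[0, L]``.
    """
    edge_coord = rng.uniform(0.0, edge)
    if rng.random() < 0.5:
        edge_coord = L - edge_coord
    other = rng.uniform(0.0, L)
    if rng.random() < 0.5:
        pos = np.array([edge_coord, other])
    else:
        pos = np.array([other, edge_coord])
    return wrap_position(pos, L)


@dataclass
class TrajectoryRecord:
    """Time-indexed record of a simulation run: the substrate of all analyses."""

    positions: np.ndarray          # (T, ndim) or (T,) for 1D
    rewards: np.ndarray | None = None
    actions: np.ndarray | None = None
    episode_ids: np.ndarray | None = None

    def __len__(self):
        return len(self.positions)

    def save(self, path):
        arrays = {"positions": self.positions}
        for k in ("rewards", "actions", "episode_ids"):
            v = getattr(self, k)
            if v is not None:
                arrays[k] = v
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path) as data:
            return cls(
                positions=data["positions"],
                rewards=data.get("rewards"),
                actions=data.get("actions"),
                episode_ids=data.get("episode_ids"),
            )
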
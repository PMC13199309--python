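"""Figure helpers for the simulation studies.

Each function renders one standard panel from study results: example place
fields per layer, rose plots of skew directions, field-center scatter over
the center-density KDE, learning curves, and the 1D policy profile. All
functions accept an optional matplotlib Axes and return the Axes, so they
compose into multi-panel figures.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "plot_field_maps",
    "plot_skew_rose",
    "plot_center_density",
    "plot_learning_curves",
    "plot_speed_profile",
    "save_skew_figure",
]


def _ax(ax, **subplot_kw):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw=subplot_kw)
    return ax


def plot_field_maps(maps, units, L=1.0, n_cols=5, fig=None):
    """Grid of example spatial activity maps (one panel per unit)."""
    import matplotlib.pyplot as plt

    n = len(units)
    n_rows = int(np.ceil(n / n_cols))
    if fig is None:
        fig, axes = plt.subplots(n_rows, n_cols, figsize=(2 * n_cols, 2 * n_rows))
    else:
        axes = fig.subplots(n_rows, n_cols)
    for ax, u in zip(np.atleast_1d(axes).ravel(), units):
        ax.imshow(maps[..., u].T, origin="lower", extent=(0, L, 0, L), cmap="viridis")
        ax.set_xticks([])
        ax.set_yticks([])
        ax.set_title(f"unit {u}", fontsize=8)
    for ax in np.atleast_1d(axes).ravel()[n:]:
        ax.axis("off")
    return fig


def plot_skew_rose(stats, ax=None, color="k", label=None):
    """Rose plot (polar histogram) of place-field skew directions."""
    ax = _ax(ax, projection="polar")
    edges = stats["rose_edges"]
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    ax.bar(centers, stats["rose"], width=width, alpha=0.6, color=color, label=label)
    return ax


def plot_center_density(grid_points, density, centers, L=1.0, objects=None, ax=None):
    """Field-center scatter over the periodic KDE background (2D)."""
    ax = _ax(ax)
    n = int(np.sqrt(len(density)))
    ax.imshow(density.reshape(n, n).T, origin="lower", extent=(0, L, 0, L),
              cmap="magma", alpha=0.8)
    ax.plot(centers[:, 0], centers[:, 1], "k.", ms=4)
    if objects is not None:
        objects = np.asarray(objects)
        ax.plot(objects[:, 0], objects[:, 1], "wo", ms=8, mec="k")
    ax.set_xlim(0, L)
    ax.set_ylim(0, L)
    return ax


def plot_learning_curves(steps_per_episode, window=100, ax=None, label=None):
    """Windowed mean of steps-to-goal, averaged over replicates."""
    ax = _ax(ax)
    steps = np.atleast_2d(steps_per_episode)
    n = steps.shape[1] // window * window
    blocks = steps[:, :n].reshape(steps.shape[0], -1, window).mean(axis=2)
    x = (np.arange(blocks.shape[1]) + 1) * window
    ax.plot(x, blocks.mean(axis=0), label=label)
    ax.set_xlabel("episode")
    ax.set_ylabel(f"steps to goal ({window}-episode mean)")
    return ax


def plot_speed_profile(positions, displacements, L=4.0, bins=100,
                       reward_interval=None, ax=None):
    """Mean selected step size per position bin on the 1D track."""
    ax = _ax(ax)
    idx = np.clip((np.asarray(positions) / L * bins).astype(int), 0, bins - 1)
    sums = np.bincount(idx, weights=displacements, minlength=bins)
    counts = np.bincount(idx, minlength=bins)
    mean = np.divide(sums, counts, out=np.zeros(bins), where=counts > 0)
    x = (np.arange(bins) + 0.5) * L / bins
    ax.plot(x, mean)
    if reward_interval is not None:
        ax.axvspan(*reward_interval, color="red", alpha=0.2)
    ax.set_xlabel("position (m)")
    ax.set_ylabel("mean step (m)")
    return ax


def save_skew_figure(result, path):
    """Four-panel summary of a biased-policy run (fields, roses, value map)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(10, 8))
    active = [s.unit for s in result["summaries_sparse"] if not s.silent][:5]
    axs = [fig.add_subplot(2, 2, i + 1, projection="polar" if i in (0, 1) else None)
           for i in range(4)]
    plot_skew_rose(result["skew_sparse"], ax=axs[0], color="k", label="sparse")
    axs[0].set_title("sparse-layer skew directions")
    plot_skew_rose(result["skew_predictive"], ax=axs[1], color="r", label="predictive")
    axs[1].set_title("predictive-layer skew directions")
    axs[2].imshow(result["maps_sparse"][..., active[0]].T, origin="lower",
                  extent=(0, 1, 0, 1))
    axs[2].set_title(f"example sparse field (unit {active[0]})")
    axs[3].imshow(result["value_map"].T, origin="lower", extent=(0, 1, 0, 1))
    axs[3].set_title("state value map")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
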
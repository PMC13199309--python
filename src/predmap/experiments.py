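"""Reproducible runners for the four simulation studies.

Every runner builds its environment and entorhinal populations from a seed,
pretrains the sparse coding layer under random exploration, freezes the
dictionary, runs the study-specific phase, and returns a results dict with
trajectories, layer activities, learned matrices and the analysis tables.
A ``scale`` factor in (0, 1] uniformly shrinks layer sizes and step/episode
counts for quick runs while preserving all ordering-based effects.

Studies
-------
``run_skew2d``
    Fixed upward-biased policy in the 1 m × 1 m periodic arena; measures
    place-field skew and lag-1 autocorrelation in the sparse and predictive
    layers, plus the learned reward vector and value map.
``run_watermaze``
    1,000-episode actor–critic navigation to a central reward region, with
    an optional ablation in which the value function reads the sparse layer
    directly instead of the predictive map.
``run_objects2d``
    Random exploration with and without LEC object cells; measures
    object-centered overrepresentation of place-field centers.
``run_reward1d``
    Continuing reward task on a 4 m circular track with a mid-run reward
    relocation; measures reward-centered overrepresentation, slow-down at
    the reward, and cross-context remapping.
"""

from __future__ import annotations

import numpy as np

from . import analysis as an
from .ec_inputs import (
    BoundaryInputPopulation,
    EntorhinalCortex,
    GridCellPopulation,
    ObjectCellPopulation,
    RewardCellPopulation,
)
from .environments import (
    Arena2D,
    Track1D,
    TrajectoryRecord,
    reward_at,
    sample_start_2d,
    step_biased_policy,
    step_random_walk,
    wrap_position,
)
from .predictive_map import SuccessorFeatures
from .rl import (
    Actor1D,
    Actor2D,
    Adam,
    SGD,
    policy_gradient_step,
    state_value,
    td_error,
    update_reward_vector,
)
from .sparse_coding import NonNegativeSparseCoding, train_sparse_layer

__all__ = ["run_skew2d", "run_watermaze", "run_objects2d", "run_reward1d"]

DEFAULT_OBJECTS = [(0.25, 0.25), (0.25, 0.75), (0.75, 0.25), (0.75, 0.75)]


def _scaled(value, scale, minimum=1):
    return max(int(round(value * scale)), minimum)


def _make_optimizer(name, lr):
    if name == "sgd":
        return SGD(lr)
    if name == "adam":
        return Adam(lr)
    raise ValueError(f"unknown optimizer {name!r}")


def _pretrain_coder(env, ec, rng, n_hidden, beta, eta_A, n_lca_iter, steps,
                    freeze=True):
    coder = NonNegativeSparseCoding(
        n_components=n_hidden, beta=beta, eta=eta_A, n_lca_iter=n_lca_iter,
        random_state=rng.integers(2**31),
    )
    coder, cost_history = train_sparse_layer(env, ec, coder, steps, rng)
    if freeze:
        coder.freeze()
    coder.reset_membrane()
    return coder, cost_history


def _batch_codes(coder, ec, positions, chunk=2000, n_iter=200):
    """Converged sparse codes along a trajectory (frozen dictionary)."""
    out = []
    for i in range(0, len(positions), chunk):
        S_e = ec.encode(positions[i:i + chunk])
        out.append(coder.transform(S_e, n_iter=n_iter))
    return np.vstack(out)


# ---------------------------------------------------------------------------
# study 1: place-field skew under a fixed biased policy
# ---------------------------------------------------------------------------

def run_skew2d(seed=0, scale=1.0, n_hidden=110, beta=0.3, eta_A=0.01,
               n_lca_iter=30, n_boundary=300, pretrain_steps=10000,
               run_steps=12000, gamma=0.93, eta_M=0.5, alpha=0.01,
               speed=0.1, angular_noise_sd=1.0, bins=50, reward_magnitude=10.0):
    """Fixed upward-biased policy study (skew, autocorrelation, value map)."""
    rng = np.random.default_rng(seed)
    n_hidden = _scaled(n_hidden, scale, 50)
    n_boundary = 2 * (_scaled(n_boundary, scale, 25) // 2)
    pretrain_steps = _scaled(pretrain_steps, scale, 500)
    run_steps = _scaled(run_steps, scale, 1000)

    arena = Arena2D(reward_region=(0.4, 0.6, 0.4, 0.6),
                    reward_magnitude=reward_magnitude)
    ec = EntorhinalCortex(
        grid=GridCellPopulation(),
        boundary=BoundaryInputPopulation(rng, n_cells=n_boundary, L=arena.L),
    )
    coder, cost_history = _pretrain_coder(
        arena, ec, rng, n_hidden, beta, eta_A, n_lca_iter, pretrain_steps)

    sf = SuccessorFeatures(gamma=gamma, eta=eta_M).initialize(n_hidden)
    R = np.zeros(n_hidden)
    pos = np.array([0.5, 0.5])
    positions = np.empty((run_steps, 2))
    codes = np.empty((run_steps, n_hidden))
    rewards = np.empty(run_steps)

    s_h = coder.step(ec.encode(pos), learn=False)
    for t in range(run_steps):
        positions[t] = pos
        codes[t] = s_h
        r = reward_at(pos, arena)
        rewards[t] = r
        R = update_reward_vector(R, r, s_h, alpha)
        pos = step_biased_policy(pos, arena.L, rng, speed=speed,
                                 angular_noise_sd=angular_noise_sd)
        s_h_next = coder.step(ec.encode(pos), learn=False)
        sf.td_update(s_h, s_h_next)
        s_h = s_h_next

    predictive = sf.predict(codes)                       # (T, N_h), final M
    maps_s, occ = an.activity_maps(positions, codes, arena.L, bins)
    maps_p, _ = an.activity_maps(positions, predictive, arena.L, bins)
    sum_s = an.summarize_fields(maps_s, occ, arena.L)
    sum_p = an.summarize_fields(maps_p, occ, arena.L)
    stats_s = an.skew_population_stats(sum_s)
    stats_p = an.skew_population_stats(sum_p)
    welch_skew = an.welch_ttest(stats_p["magnitudes"], stats_s["magnitudes"])
    ac_s = an.lag1_autocorr_batch(codes)
    ac_p = an.lag1_autocorr_batch(predictive)
    active_s = np.array([not s.silent for s in sum_s])
    active_p = np.array([not s.silent for s in sum_p])
    welch_ac = an.welch_ttest(ac_p[active_p], ac_s[active_s])
    value_map = maps_p @ R                               # (bins, bins)

    return {
        "trajectory": TrajectoryRecord(positions=positions, rewards=rewards),
        "codes": codes,
        "predictive": predictive,
        "coder": coder,
        "sf": sf,
        "R": R,
        "cost_history": cost_history,
        "occupancy": occ,
        "maps_sparse": maps_s,
        "maps_predictive": maps_p,
        "summaries_sparse": sum_s,
        "summaries_predictive": sum_p,
        "skew_sparse": stats_s,
        "skew_predictive": stats_p,
        "welch_skew": welch_skew,
        "autocorr_sparse": ac_s[active_s],
        "autocorr_predictive": ac_p[active_p],
        "welch_autocorr": welch_ac,
        "value_map": value_map,
        "arena": arena,
        "bins": bins,
    }


# ---------------------------------------------------------------------------
# study 2: actor–critic water maze
# ---------------------------------------------------------------------------

def _watermaze_single(seed, scale, ablate, n_hidden, beta, eta_A, n_lca_iter,
                      n_boundary, pretrain_steps, episodes, max_steps, gamma,
                      eta_M, alpha, actor_lr, optimizer, reward_magnitude):
    rng = np.random.default_rng(seed)
    arena = Arena2D(reward_region=(0.4, 0.6, 0.4, 0.6),
                    reward_magnitude=reward_magnitude)
    ec = EntorhinalCortex(
        grid=GridCellPopulation(),
        boundary=BoundaryInputPopulation(rng, n_cells=n_boundary, L=arena.L),
    )
    coder, _ = _pretrain_coder(
        arena, ec, rng, n_hidden, beta, eta_A, n_lca_iter, pretrain_steps)
    sf = SuccessorFeatures(gamma=gamma, eta=eta_M).initialize(n_hidden)
    R = np.zeros(n_hidden)
    actor = Actor2D(n_hidden, rng=rng)
    opt = _make_optimizer(optimizer, actor_lr)

    steps_per_episode = np.empty(episodes, dtype=int)
    for ep in range(episodes):
        pos = sample_start_2d(rng, L=arena.L)
        coder.reset_membrane()
        s_h = coder.step(ec.encode(pos), learn=False)
        p_h = sf.predict(s_h)
        for t in range(max_steps):
            disp, info = actor.act(s_h, rng)
            pos = wrap_position(pos + disp, arena.L)
            r = reward_at(pos, arena)
            s_h_next = coder.step(ec.encode(pos), learn=False)
            p_next = sf.predict(s_h_next)
            terminal = r > 0
            feat_now = s_h if ablate else p_h
            feat_next = s_h_next if ablate else p_next
            v_now = state_value(feat_now, R)
            v_next = 0.0 if terminal else state_value(feat_next, R)
            delta = td_error(r, v_next, v_now, gamma)
            R = update_reward_vector(R, r, s_h_next, alpha)
            sf.td_update(s_h, s_h_next)
            policy_gradient_step(actor, info, delta, opt)
            s_h, p_h = s_h_next, p_next
            if terminal:
                break
        steps_per_episode[ep] = t + 1
    return {"steps_per_episode": steps_per_episode, "actor": actor,
            "coder": coder, "sf": sf, "R": R, "arena": arena, "ec": ec}


def run_watermaze(seed=0, scale=1.0, replicates=10, ablate=False,
                  include_ablation=False, n_hidden=150, beta=0.3, eta_A=0.01,
                  n_lca_iter=50, n_boundary=300, pretrain_steps=8000,
                  episodes=1000, max_steps=2000, gamma=0.95, eta_M=0.5,
                  alpha=0.003, actor_lr=1e-3, optimizer="adam",
                  reward_magnitude=10.0):
    """Water-maze navigation study; returns per-replicate learning curves.

    With ``include_ablation`` each replicate is run twice with identical
    seeds: once intact (value from the predictive map) and once ablated
    (value directly from the sparse layer).
    """
    n_hidden = _scaled(n_hidden, scale, 50)
    n_boundary = 2 * (_scaled(n_boundary, scale, 25) // 2)
    pretrain_steps = _scaled(pretrain_steps, scale, 500)
    episodes = _scaled(episodes, scale, 20)
    max_steps = _scaled(max_steps, scale, 100)

    seeds = np.random.default_rng(seed).integers(2**31, size=replicates)
    kwargs = dict(scale=scale, n_hidden=n_hidden, beta=beta, eta_A=eta_A,
                  n_lca_iter=n_lca_iter, n_boundary=n_boundary,
                  pretrain_steps=pretrain_steps, episodes=episodes,
                  max_steps=max_steps, gamma=gamma, eta_M=eta_M, alpha=alpha,
                  actor_lr=actor_lr, optimizer=optimizer,
                  reward_magnitude=reward_magnitude)
    runs = [_watermaze_single(s, ablate=ablate, **kwargs) for s in seeds]
    result = {
        "steps_per_episode": np.array([r["steps_per_episode"] for r in runs]),
        "runs": runs,
        "episodes": episodes,
        "max_steps": max_steps,
    }
    if include_ablation:
        ab = [_watermaze_single(s, ablate=True, **kwargs) for s in seeds]
        result["steps_per_episode_ablated"] = np.array(
            [r["steps_per_episode"] for r in ab])
        result["runs_ablated"] = ab
    return result


def policy_value_maps(run, grid_n=20):
    """Evaluate the learned policy mean and value on a position grid."""
    coder, sf, R, actor, ec = (run["coder"], run["sf"], run["R"],
                               run["actor"], run["ec"])
    L = run["arena"].L
    ax = (np.arange(grid_n) + 0.5) * L / grid_n
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    codes = _batch_codes(coder, ec, pts)
    values = codes @ sf.M_ @ R
    mus = np.array([actor.forward(c)[1] for c in codes])
    return {"grid": pts, "value": values.reshape(grid_n, grid_n),
            "policy_mean": mus.reshape(grid_n, grid_n, 2)}


# ---------------------------------------------------------------------------
# study 3: object-centered overrepresentation
# ---------------------------------------------------------------------------

def run_objects2d(seed=0, scale=1.0, n_hidden=110, beta=0.3, eta_A=0.05,
                  n_lca_iter=50, n_boundary=300, n_object_cells=600,
                  pretrain_steps=30000, eval_steps=8000, bins=50,
                  objects=None, speed=0.1):
    """Free exploration with vs. without LEC object cells (matched seeds)."""
    objects = DEFAULT_OBJECTS if objects is None else objects
    n_hidden = _scaled(n_hidden, scale, 50)
    n_boundary = 2 * (_scaled(n_boundary, scale, 25) // 2)
    n_object_cells = _scaled(n_object_cells, scale, 50)
    pretrain_steps = _scaled(pretrain_steps, scale, 500)
    eval_steps = _scaled(eval_steps, scale, 500)

    results = {}
    for label, with_objects in (("without_objects", False), ("with_objects", True)):
        rng = np.random.default_rng(seed)          # identical streams per condition
        arena = Arena2D(object_locations=[tuple(o) for o in objects] if with_objects else [])
        obj_pop = (ObjectCellPopulation(rng, objects, n_cells=n_object_cells)
                   if with_objects else None)
        ec = EntorhinalCortex(
            grid=GridCellPopulation(),
            boundary=BoundaryInputPopulation(rng, n_cells=n_boundary, L=arena.L),
            objects=obj_pop,
        )
        coder, _ = _pretrain_coder(
            arena, ec, rng, n_hidden, beta, eta_A, n_lca_iter, pretrain_steps)
        # evaluation walk (frozen dictionary, converged batch codes)
        pos = np.array([0.5, 0.5])
        eval_positions = np.empty((eval_steps, 2))
        for t in range(eval_steps):
            eval_positions[t] = pos
            pos = step_random_walk(pos, arena.L, rng, speed=speed)
        codes = _batch_codes(coder, ec, eval_positions)
        maps, occ = an.activity_maps(eval_positions, codes, arena.L, bins)
        summaries = an.summarize_fields(maps, occ, arena.L)
        centers = np.array([s.peak for s in summaries if not s.silent])
        _, density = an.center_density(centers, arena.L,
                                       grid=np.asarray(objects, dtype=float))
        min_d = an.min_pairwise_distances(centers, arena.L)
        grid_pts, density_grid = an.center_density(centers, arena.L)
        results[label] = {
            "coder": coder, "ec": ec, "summaries": summaries,
            "centers": centers, "density_at_objects": density,
            "min_pairwise_distances": min_d,
            "density_grid_points": grid_pts, "density_grid": density_grid,
            "trajectory": TrajectoryRecord(positions=eval_positions),
        }
    results["objects"] = np.asarray(objects, dtype=float)
    return results


# ---------------------------------------------------------------------------
# study 4: reward relocation on the 1D track
# ---------------------------------------------------------------------------

def run_reward1d(seed=0, scale=1.0, n_hidden=100, beta=0.3, eta_A=0.01,
                 n_lca_iter=50, n_reward_cells=600, pretrain_steps=20000,
                 steps_per_context=60000, gamma=0.95, eta_M=0.05, alpha=0.01,
                 actor_lr=1e-3, optimizer="adam", bins=100, joint_training=False,
                 contexts=(("A_end", (3.56, 3.76)), ("A_mid", (1.56, 1.76)))):
    """Continuing 1D reward task with a context switch of the reward zone.

    With ``joint_training`` (default) the sparse dictionary keeps adapting
    during the task on its fast time scale. This is what produces the
    reward-centered overrepresentation: once the policy slows down inside
    the reward zone, occupancy (and hence dictionary learning) concentrates
    there and more units are recruited to reward-adjacent inputs.
    """
    rng = np.random.default_rng(seed)
    n_hidden = _scaled(n_hidden, scale, 50)
    n_reward_cells = 2 * (_scaled(n_reward_cells, scale, 50) // 2)
    pretrain_steps = _scaled(pretrain_steps, scale, 500)
    steps_per_context = _scaled(steps_per_context, scale, 2000)

    first_interval = contexts[0][1]
    track = Track1D(reward_interval=first_interval, context_id=contexts[0][0])
    reward_pop = RewardCellPopulation(
        rng, anchor=track.reward_center, n_cells=n_reward_cells, L=track.L)
    ec = EntorhinalCortex(grid=GridCellPopulation(), reward=reward_pop, ndim=1)
    coder, _ = _pretrain_coder(
        track, ec, rng, n_hidden, beta, eta_A, n_lca_iter, pretrain_steps,
        freeze=not joint_training)

    sf = SuccessorFeatures(gamma=gamma, eta=eta_M).initialize(n_hidden)
    R = np.zeros(n_hidden)
    actor = Actor1D(n_hidden, rng=rng)
    opt = _make_optimizer(optimizer, actor_lr)

    x = 0.0
    per_context = {}
    for context_id, interval in contexts:
        track.set_context(context_id, interval)
        reward_pop.re_anchor(track.reward_center)
        coder.reset_membrane()
        s_h = coder.step(ec.encode(float(x)), learn=False)
        p_h = sf.predict(s_h)
        half = steps_per_context // 2
        rec_pos = np.empty(steps_per_context - half)
        rec_disp = np.empty(steps_per_context - half)
        rec_codes = np.empty((steps_per_context - half, n_hidden))
        for t in range(steps_per_context):
            disp, info = actor.act(s_h, rng)
            x_new = float(wrap_position(x + disp, track.L))
            r = reward_at(x_new, track)
            s_h_next = coder.step(ec.encode(x_new), learn=joint_training)
            p_next = sf.predict(s_h_next)
            v_now = state_value(p_h, R)
            v_next = state_value(p_next, R)
            delta = td_error(r, v_next, v_now, gamma)
            R = update_reward_vector(R, r, s_h_next, alpha)
            sf.td_update(s_h, s_h_next)
            policy_gradient_step(actor, info, delta, opt)
            if t >= half:
                i = t - half
                rec_pos[i], rec_disp[i], rec_codes[i] = x, disp, s_h
            x, s_h, p_h = x_new, s_h_next, p_next
        # analysis codes: converged batch settle with the end-of-context
        # dictionary (online warm-started codes are kept in rec_codes)
        analysis_codes = _batch_codes(coder, ec, rec_pos)
        maps, occ = an.activity_maps(rec_pos, analysis_codes, track.L, bins)
        summaries = an.summarize_fields(maps, occ, track.L)
        centers = np.array([float(s.peak[0]) for s in summaries if not s.silent])
        grid_pts, density = an.center_density(centers, track.L)
        a, b = interval
        inside = (rec_pos >= a) & (rec_pos <= b)
        per_context[context_id] = {
            "interval": interval,
            "summaries": summaries,
            "centers": centers,
            "density_grid_points": grid_pts,
            "density": density,
            "density_peak_location": float(grid_pts[np.argmax(density)]),
            "mean_step_inside": float(rec_disp[inside].mean()) if inside.any() else np.nan,
            "mean_step_outside": float(rec_disp[~inside].mean()),
            "trajectory": TrajectoryRecord(positions=rec_pos, actions=rec_disp),
        }
    ids = [c[0] for c in contexts]
    remap = an.remapping_table(
        per_context[ids[0]]["summaries"], per_context[ids[1]]["summaries"],
        contexts[0][1], contexts[1][1], track.L)
    return {"contexts": per_context, "remapping": remap, "track": track,
            "coder": coder, "sf": sf, "R": R, "actor": actor, "ec": ec}
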
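import numpy as np
import pytest
from scipy import stats

from predmap.ec_inputs import (
    BoundaryInputPopulation,
    EntorhinalCortex,
    GridCellPopulation,
    ObjectCellPopulation,
    RewardCellPopulation,
    boundary_activity,
    default_grid_spacings,
    grid_activity,
    object_activity,
    reward_cell_activity,
)


class TestGridActivity:
    def test_peak_one_at_phase_center(self):
        assert grid_activity((0.3, 0.4), 0.28, 0.7, (0.3, 0.4)) == pytest.approx(1.0)

    def test_lattice_translation_invariance(self):
        """Shifting by a primitive lattice vector leaves the field unchanged.

        The hexagonal lattice of a three-cosine grid with wave vectors at
        2πj/3 + θ has primitive vectors of length λ at angles θ ± 30°.
        """
        lam, th = 0.28, 0.3
        for ang in (th + np.pi / 6, th - np.pi / 6):
            prim = lam * np.array([np.cos(ang), np.sin(ang)])
            pts = np.random.default_rng(0).uniform(0, 1, size=(50, 2))
            v0 = grid_activity(pts, lam, th, (0.0, 0.0))
            v1 = grid_activity(pts + prim, lam, th, (0.0, 0.0))
            np.testing.assert_allclose(v0, v1, atol=1e-9)

    def test_range_is_zero_to_one(self):
        xs = np.linspace(0, 1, 300)
        pts = np.column_stack([a.ravel() for a in np.meshgrid(xs, xs)])
        vals = grid_activity(pts, 0.28, 0.1, (0.0, 0.0))
        assert vals.max() == pytest.approx(1.0, abs=1e-4)
        assert vals.min() == pytest.approx(0.0, abs=1e-4)
        assert np.all(vals >= -1e-12)

    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(ValueError):
            grid_activity((0.1, 0.1), -0.2, 0.0, (0.0, 0.0))

    def test_discontinuous_across_wrap_for_generic_phase(self):
        """Grid spacing 0.28 m does not divide L=1, so the field read in
        box coordinates jumps across the periodic boundary — the stated
        motivation for adding boundary-tuned inputs."""
        lo = grid_activity((1e-9, 0.37), 0.28, 0.2, (0.11, 0.05))
        hi = grid_activity((1.0 - 1e-9, 0.37), 0.28, 0.2, (0.11, 0.05))
        assert abs(lo - hi) > 1e-3

    def test_1d_slice_equals_2d_evaluation(self):
        pop = GridCellPopulation(y0=0.5)
        xs = np.random.default_rng(1).uniform(0, 1, 100)
        slice_vals = pop.activity_1d(xs)
        full_vals = pop.activity(np.column_stack([xs, np.full(100, 0.5)]))
        np.testing.assert_allclose(slice_vals, full_vals, atol=0)


class TestGridPopulation:
    def test_counts_and_spacings(self):
        pop = GridCellPopulation()
        assert pop.n_cells == 600  # 4 spacings x 6 orientations x 25 phases
        np.testing.assert_allclose(
            np.round(default_grid_spacings() * 100, 2), [28.0, 39.76, 56.46, 80.17]
        )
        assert np.all(default_grid_spacings() < 1.0)

    def test_phases_tile_the_unit_cell(self):
        pop = GridCellPopulation()
        lam0 = default_grid_spacings()[0]
        sel = (pop.spacing == lam0) & (pop.orientation == 0.0)
        assert sel.sum() == 25
        assert len(np.unique(pop.phase[sel], axis=0)) == 25
        assert np.all(pop.phase[sel] < lam0)


class TestBoundaryActivity:
    def test_peak_at_boundary_is_083(self):
        assert boundary_activity((0.0, 0.55), 0.1, 0, (0.2, 0.55), 1.0) == pytest.approx(0.83)

    def test_mirror_symmetry_in_boundary_distance(self):
        for x in (0.1, 0.33, 0.48):
            a = boundary_activity((x, 0.4), 0.1, 0, (0.9, 0.4), 1.0)
            b = boundary_activity((1 - x, 0.4), 0.1, 0, (0.9, 0.4), 1.0)
            assert a == pytest.approx(b)

    def test_center_value_matches_arithmetic(self):
        val = boundary_activity((0.5, 0.7), 0.1, 0, (0.0, 0.7), 1.0)
        assert val == pytest.approx(0.83 * np.exp(-0.25 / 0.02), rel=1e-9)

    def test_orientations_split_half_half(self, rng):
        pop = BoundaryInputPopulation(rng, n_cells=300)
        assert (pop.orientation == 0).sum() == 150
        assert (pop.orientation == 1).sum() == 150


class TestObjectActivity:
    def test_peak_approximates_amplitude(self):
        centers = np.array([[[0.2, 0.2], [0.8, 0.8], [0.2, 0.8], [0.8, 0.2]]])
        amps = np.array([[0.7, 1.0, 1.0, 1.0]])
        widths = np.full((1, 4), 0.04)
        val = object_activity((0.2, 0.2), centers, amps, widths)
        assert val == pytest.approx(0.7, abs=1e-6)

    def test_three_sigma_value(self):
        sigma = 0.05
        centers = np.zeros((1, 4, 2))
        centers[0, :, 0] = 3 * sigma          # all four centers 3σ away
        val = object_activity((0.0, 0.0), centers, np.ones((1, 4)), np.full((1, 4), sigma))
        assert val == pytest.approx(4 * np.exp(-4.5), rel=1e-9)

    def test_bounded_by_amplitude_sum(self, rng):
        pop = ObjectCellPopulation(rng, [(0.25, 0.25), (0.25, 0.75), (0.75, 0.25), (0.75, 0.75)], n_cells=50)
        pts = rng.uniform(0, 1, size=(200, 2))
        act = pop.activity(pts)
        assert np.all(act <= pop.amplitudes.sum(axis=1) + 1e-9)
        assert np.all(act >= 0)


class TestRewardCellActivity:
    def test_value_half_at_anchored_center(self):
        for kind in ("pre", "post"):
            v = reward_cell_activity(2.0, anchor=2.0, offset=0.0, width=0.4,
                                     sharpness=0.02, kind=kind)
            assert v == pytest.approx(0.5)

    def test_pre_cell_gate_saturates_far_before_reward(self):
        x = 2.0 - 10 * 0.02
        v = reward_cell_activity(x, 2.0, 0.0, 5.0, 0.02, "pre")
        assert v == pytest.approx(np.exp(-(x - 2.0) ** 2 / (2 * 25.0)), rel=1e-3)

    def test_pre_cell_suppressed_past_reward(self):
        v = reward_cell_activity(2.1, 2.0, 0.0, 0.4, 0.02, "pre")
        expected = np.exp(-0.01 / 0.32) * (1 - 1 / (1 + np.exp(-5.0)))
        assert v == pytest.approx(expected, rel=1e-9)

    def test_gate_monotonicity(self):
        xs = np.linspace(1.0, 3.0, 200)
        pre = np.array([reward_cell_activity(x, 2.0, 0.0, 50.0, 0.05, "pre") for x in xs])
        post = np.array([reward_cell_activity(x, 2.0, 0.0, 50.0, 0.05, "post") for x in xs])
        assert np.all(np.diff(pre) <= 1e-12)   # wide envelope: gate dominates
        assert np.all(np.diff(post) >= -1e-12)

    def test_population_split_and_reanchor(self, rng):
        pop = RewardCellPopulation(rng, anchor=3.66, n_cells=600)
        assert (pop.kind == "pre").sum() == 300
        assert (pop.kind == "post").sum() == 300
        a1 = pop.activity(3.6)
        pop.re_anchor(1.66)
        a2 = pop.activity(1.6)
        np.testing.assert_allclose(a1, a2, atol=1e-12)  # pure translation on the ring


class TestParameterDistributions:
    def test_uniform_ranges_pass_ks(self, rng):
        """Sampled population parameters match their stated uniform ranges."""
        bpop = BoundaryInputPopulation(rng, n_cells=300)
        rpop = RewardCellPopulation(rng, anchor=3.66, n_cells=600)
        checks = [
            (bpop.scale, 0.08, 0.12),
            (bpop.phase.ravel(), 0.0, 1.0),
            (rpop.offset, -0.05, 0.05),
            (rpop.width, 0.3, 0.6),
            (rpop.sharpness, 0.01, 0.05),
        ]
        for sample, lo, hi in checks:
            p = stats.kstest(sample, stats.uniform(lo, hi - lo).cdf).pvalue
            assert p > 0.01


class TestAssembly:
    def test_2d_without_objects(self, rng):
        ec = EntorhinalCortex(grid=GridCellPopulation(),
                              boundary=BoundaryInputPopulation(rng, 300))
        assert ec.n_inputs == 900
        assert ec.encode((0.3, 0.3)).shape == (900,)

    def test_2d_with_objects(self, rng):
        ec = EntorhinalCortex(
            grid=GridCellPopulation(),
            boundary=BoundaryInputPopulation(rng, 300),
            objects=ObjectCellPopulation(
                rng, [(0.25, 0.25), (0.25, 0.75), (0.75, 0.25), (0.75, 0.75)], n_cells=600),
        )
        assert ec.n_inputs == 1500

    def test_1d_reward_task(self, rng):
        ec = EntorhinalCortex(grid=GridCellPopulation(),
                              reward=RewardCellPopulation(rng, anchor=3.66, n_cells=600),
                              ndim=1)
        assert ec.n_inputs == 1200
        vec = ec.encode(1.2)
        assert vec.shape == (1200,)
        assert np.all(vec >= 0) and np.all(np.isfinite(vec))

    def test_mismatched_populations_rejected(self, rng):
        with pytest.raises(ValueError):
            EntorhinalCortex(grid=GridCellPopulation(),
                             reward=RewardCellPopulation(rng, anchor=1.0), ndim=2)
        with pytest.raises(ValueError):
            EntorhinalCortex(grid=GridCellPopulation(),
                             boundary=BoundaryInputPopulation(rng, 10), ndim=1)

    def test_all_activities_nonnegative_finite(self, rng):
        ec = EntorhinalCortex(grid=GridCellPopulation(),
                              boundary=BoundaryInputPopulation(rng, 100))
        pts = rng.uniform(0, 1, size=(500, 2))
        S = ec.encode(pts)
        assert np.all(S >= 0) and np.all(np.isfinite(S))
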
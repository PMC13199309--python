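import numpy as np
import pytest
from scipy import stats

from predmap.analysis import (
    ActivityMap,
    activity_map,
    activity_maps,
    center_density,
    field_summary,
    lag1_autocorr,
    lag1_autocorr_batch,
    min_pairwise_distances,
    remapping_table,
    skew_population_stats,
    summarize_fields,
    welch_ttest,
)
from predmap.analysis import PlaceFieldSummary, _periodic_label


def gaussian_map(center, sigma=0.08, bins=50, L=1.0):
    ax = (np.arange(bins) + 0.5) * L / bins
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    d2 = ((gx - center[0] + L / 2) % L - L / 2) ** 2 + ((gy - center[1] + L / 2) % L - L / 2) ** 2
    return np.exp(-d2 / (2 * sigma**2))


class TestActivityMap:
    def test_constant_activity_fills_visited_bins(self, rng):
        pos = rng.uniform(0, 1, size=(500, 2))
        amap = activity_map(pos, np.ones(500), 1.0, bins=10)
        visited = amap.occupancy > 0
        np.testing.assert_allclose(amap.mean[visited], 1.0)
        assert np.all(amap.mean[~visited] == 0)

    def test_localized_activity_stays_local(self):
        pos = np.array([[0.05, 0.05], [0.55, 0.55], [0.95, 0.95]])
        act = np.array([0.0, 2.0, 0.0])
        amap = activity_map(pos, act, 1.0, bins=10)
        assert amap.mean[5, 5] == 2.0
        assert amap.mean.sum() == 2.0

    def test_recovers_synthetic_tuning_center(self, rng):
        """Binned map of a Gaussian-tuned unit peaks within one bin of the
        true tuning center."""
        center = np.array([0.62, 0.31])
        pos = rng.uniform(0, 1, size=(20000, 2))
        act = np.exp(-np.sum((pos - center) ** 2, axis=1) / (2 * 0.05**2))
        amap = activity_map(pos, act, 1.0, bins=50)
        peak = np.unravel_index(np.argmax(amap.mean), amap.mean.shape)
        peak_xy = (np.array(peak) + 0.5) / 50
        assert np.all(np.abs(peak_xy - center) < 0.02 + 1e-9)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            activity_maps(np.empty((0, 2)), np.empty((0, 1)), 1.0)

    def test_1d_occupancy_normalization(self):
        pos = np.array([0.1, 0.1, 2.1])
        act = np.array([[1.0], [3.0], [5.0]])
        maps, occ = activity_maps(pos, act, 4.0, bins=4)
        assert maps[0, 0] == pytest.approx(2.0)   # mean of 1 and 3
        assert maps[2, 0] == pytest.approx(5.0)
        assert occ[0] == 2


class TestPeriodicLabel:
    def test_wrapped_component_is_single(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 4:6] = True
        mask[-1, 4:6] = True
        labels = _periodic_label(mask)
        assert len(np.unique(labels[mask])) == 1

    def test_disjoint_components_stay_distinct(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2, 2] = True
        mask[7, 7] = True
        labels = _periodic_label(mask)
        assert len(np.unique(labels[mask])) == 2


class TestFieldSummary:
    def test_symmetric_field_has_tiny_skew(self):
        amap = ActivityMap(gaussian_map((0.5, 0.4)), np.ones((50, 50)), 1.0)
        s = field_summary(amap)
        assert s.skew_magnitude < 0.02  # one bin width
        np.testing.assert_allclose(s.peak, [0.5, 0.4], atol=0.011)

    def test_field_across_the_wrap_uses_circular_com(self):
        """A field straddling x=0 must not be pulled to the arena middle."""
        amap = ActivityMap(gaussian_map((0.02, 0.5)), np.ones((50, 50)), 1.0)
        s = field_summary(amap)
        d = (s.com[0] - 0.02 + 0.5) % 1.0 - 0.5
        assert abs(d) < 0.02

    def test_secondary_lobe_is_ignored(self):
        m = gaussian_map((0.25, 0.25)) + 0.45 * gaussian_map((0.75, 0.75), sigma=0.05)
        amap = ActivityMap(m, np.ones((50, 50)), 1.0)
        s = field_summary(amap)
        # COM belongs to the peak's component, far from the secondary lobe
        assert np.linalg.norm(s.com - [0.25, 0.25]) < 0.05
        assert s.area < 0.2

    def test_all_zero_map_reported_silent(self):
        amap = ActivityMap(np.zeros((20, 20)), np.ones((20, 20)), 1.0)
        assert field_summary(amap).silent

    def test_summarize_flags_silent_units(self):
        maps = np.stack([gaussian_map((0.5, 0.5)), np.full((50, 50), 1e-6)], axis=-1)
        out = summarize_fields(maps, np.ones((50, 50)), 1.0)
        assert not out[0].silent and out[1].silent


class TestSkewStats:
    def test_identical_skews_have_zero_sd(self):
        s = [PlaceFieldSummary(i, np.zeros(2), np.zeros(2), np.array([0.02, 0.0]), 1.0, 0.1)
             for i in range(5)]
        st = skew_population_stats(s)
        assert st["sd"] == 0.0
        assert st["mean"] == pytest.approx(0.02)

    def test_isotropic_directions_give_flat_rose(self, rng):
        angles = rng.uniform(-np.pi, np.pi, 400)
        s = [PlaceFieldSummary(i, np.zeros(2), np.zeros(2),
                               0.05 * np.array([np.cos(a), np.sin(a)]), 1.0, 0.1)
             for i, a in enumerate(angles)]
        st = skew_population_stats(s)
        chi2 = stats.chisquare(st["rose"]).pvalue
        assert chi2 > 0.01

    def test_downward_bias_detected(self, rng):
        angles = rng.normal(-np.pi / 2, 0.3, 200)
        s = [PlaceFieldSummary(i, np.zeros(2), np.zeros(2),
                               0.05 * np.array([np.cos(a), np.sin(a)]), 1.0, 0.1)
             for i, a in enumerate(angles)]
        st = skew_population_stats(s)
        assert abs(np.rad2deg(st["circular_mean_direction"]) + 90) < 45

    def test_requires_two_active_units(self):
        with pytest.raises(ValueError):
            skew_population_stats([PlaceFieldSummary(0, np.zeros(2), np.zeros(2),
                                                     np.zeros(2), 1.0, 0.1)])


class TestWelch:
    def test_equal_variance_case_reduces_to_student(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        welch = welch_ttest(a, b)
        student = stats.ttest_ind(a, b, equal_var=True)
        assert welch.statistic == pytest.approx(student.statistic, abs=1e-10)


class TestAutocorr:
    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 50)
        assert lag1_autocorr(x) == pytest.approx(-1.0)

    def test_constant_series_is_zero_by_convention(self):
        assert lag1_autocorr(np.full(100, 3.3)) == 0.0

    def test_ar1_recovers_coefficient(self, rng):
        n = 100_000
        x = np.empty(n)
        x[0] = 0
        eps = rng.normal(size=n)
        for t in range(1, n):
            x[t] = 0.5 * x[t - 1] + eps[t]
        assert lag1_autocorr(x) == pytest.approx(0.5, abs=0.01)

    def test_batch_matches_scalar(self, rng):
        X = rng.normal(size=(500, 4))
        X[:, 2] = 1.0   # constant column
        batch = lag1_autocorr_batch(X)
        for j in range(4):
            assert batch[j] == pytest.approx(lag1_autocorr(X[:, j]), abs=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            lag1_autocorr([1.0, 2.0])


class TestCenterDensity:
    def test_clustered_centers_peak_at_cluster(self, rng):
        centers = np.vstack([rng.normal(0.5, 0.02, size=(30, 2)),
                             rng.uniform(0, 1, size=(10, 2))])
        grid, dens = center_density(centers, 1.0)
        peak = grid[np.argmax(dens)]
        assert np.linalg.norm(peak - [0.5, 0.5]) < 0.1

    def test_uniform_centers_are_nearly_flat(self, rng):
        """No spurious clustering: with 400 uniform centers the Scott-rule
        KDE fluctuates within about a factor two peak-to-trough."""
        centers = rng.uniform(0, 1, size=(400, 2))
        _, dens = center_density(centers, 1.0)
        assert dens.max() / dens.min() < 2.25

    def test_density_integrates_to_one_on_the_torus(self, rng):
        centers = rng.uniform(0, 1, size=(50, 2))
        _, dens = center_density(centers, 1.0)
        assert dens.mean() == pytest.approx(1.0, rel=0.05)

    def test_needs_five_centers(self):
        with pytest.raises(ValueError):
            center_density(np.zeros((3, 2)), 1.0)


class TestMinPairwiseDistances:
    def test_two_centers(self):
        d = min_pairwise_distances(np.array([[0.1, 0.5], [0.3, 0.5]]), 1.0)
        np.testing.assert_allclose(d, [0.2, 0.2])

    def test_regular_grid_spacing(self):
        ax = np.arange(10) / 10
        centers = np.column_stack([a.ravel() for a in np.meshgrid(ax, ax)])
        d = min_pairwise_distances(centers, 1.0)
        np.testing.assert_allclose(d, 0.1, atol=1e-12)

    def test_wrap_distance_used(self):
        d = min_pairwise_distances(np.array([[0.02, 0.5], [0.98, 0.5]]), 1.0)
        np.testing.assert_allclose(d, 0.04)


class TestRemapping:
    def _summary(self, unit, x, silent=False):
        return PlaceFieldSummary(unit, np.array([x]), np.array([x]),
                                 np.zeros(1), 1.0, 0.1, silent=silent)

    def test_identical_maps_give_identical_centers(self):
        s1 = [self._summary(0, 1.0), self._summary(1, 3.0)]
        tab = remapping_table(s1, s1, (3.56, 3.76), (1.56, 1.76), 4.0)
        np.testing.assert_allclose(tab["center_ctx1"], tab["center_ctx2"])

    def test_reward_locked_unit_flagged(self):
        s1 = [self._summary(0, 3.66), self._summary(1, 0.5)]
        s2 = [self._summary(0, 1.66), self._summary(1, 0.5)]
        tab = remapping_table(s1, s2, (3.56, 3.76), (1.56, 1.76), 4.0)
        assert bool(tab.loc[0, "reward_tracking"])
        assert not bool(tab.loc[1, "reward_tracking"])

    def test_stable_spatial_unit_not_flagged(self):
        s1 = [self._summary(0, 3.66), self._summary(1, 3.60)]
        s2 = [self._summary(0, 1.66), self._summary(1, 3.60)]
        tab = remapping_table(s1, s2, (3.56, 3.76), (1.56, 1.76), 4.0)
        # unit 1 stays at 3.6: near zone 1 but ~1.9 m from zone 2
        assert not bool(tab.loc[1, "reward_tracking"])

    def test_silent_units_carried_but_unflagged(self):
        s1 = [self._summary(0, 3.66, silent=True)]
        s2 = [self._summary(0, 1.66)]
        tab = remapping_table(s1, s2, (3.56, 3.76), (1.56, 1.76), 4.0)
        assert bool(tab.loc[0, "silent"]) and not bool(tab.loc[0, "reward_tracking"])
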
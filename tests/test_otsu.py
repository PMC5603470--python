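"""Histogram construction, class statistics, and multi-level Otsu search."""

import itertools

import numpy as np
import pytest

from mopet import (
    DegenerateDistributionError,
    build_histogram,
    class_statistics,
    multilevel_otsu,
    segment_mo_pet,
)

# ---------------------------------------------------------------------------
# independent oracles


def brute_force_bin_counts(values, edges):
    """Per-bin counting by direct scan (last bin right-inclusive)."""
    counts = np.zeros(len(edges) - 1, dtype=int)
    for v in values:
        for b in range(len(edges) - 1):
            hi_ok = v <= edges[b + 1] if b == len(edges) - 2 else v < edges[b + 1]
            if edges[b] <= v and hi_ok:
                counts[b] += 1
                break
    return counts


def naive_class_moments(hist, cuts):
    """Weighted mean/variance per class by an explicit loop over member bins."""
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    bounds = [0] + list(cuts) + [hist.n_bins]
    out = []
    for lo, hi in zip(bounds, bounds[1:]):
        mass = 0.0
        for b in range(lo, hi):
            mass += hist.probabilities[b]
        if mass == 0:
            out.append((0.0, 0.0, 0.0))
            continue
        mean = 0.0
        for b in range(lo, hi):
            mean += centers[b] * hist.probabilities[b]
        mean /= mass
        var = 0.0
        for b in range(lo, hi):
            var += (centers[b] - mean) ** 2 * hist.probabilities[b]
        var /= mass
        out.append((mass, mean, var))
    return out


def naive_interval_cost_matrix(hist):
    """cost[a][b] = P * sigma^2 over bins [a, b), two-pass formula."""
    b_tot = hist.n_bins
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    p = hist.probabilities
    cost = np.zeros((b_tot, b_tot + 1))
    for a in range(b_tot):
        for b in range(a + 1, b_tot + 1):
            mass = p[a:b].sum()
            if mass == 0:
                continue
            mean = (centers[a:b] * p[a:b]).sum() / mass
            cost[a, b] = ((centers[a:b] - mean) ** 2 * p[a:b]).sum()
    return cost


def exhaustive_otsu(hist, k):
    """Enumerate every ordered cut combination; lexicographic first argmin."""
    cost = naive_interval_cost_matrix(hist)
    b = hist.n_bins
    combos = np.array(list(itertools.combinations(range(1, b), k - 1)), dtype=int)
    bounds = np.column_stack(
        [np.zeros(len(combos), dtype=int), combos, np.full(len(combos), b)]
    )
    total = np.zeros(len(combos))
    for j in range(k):
        total += cost[bounds[:, j], bounds[:, j + 1]]
    best = int(np.argmin(total))  # first minimum = lexicographically smallest
    return combos[best], total[best]


def random_histogram(rng, n_bins=64):
    vals = rng.random(2000) * rng.uniform(2, 20)
    return build_histogram(vals, n_bins)


# ---------------------------------------------------------------------------
# build_histogram


class TestBuildHistogram:
    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateDistributionError, match="degenerate"):
            build_histogram(np.full(100, 3.0), n_bins=16)

    def test_uniform_occupancy(self):
        h = build_histogram([0.0, 1.0, 2.0, 3.0], n_bins=4)
        np.testing.assert_allclose(h.probabilities, 0.25)
        assert h.value_min == 0.0 and h.value_max == 3.0
        assert h.n_samples == 4

    def test_matches_counting_oracle(self, rng):
        vals = rng.gamma(2.0, 2.0, size=10_000)
        h = build_histogram(vals, n_bins=32)
        expected = brute_force_bin_counts(vals, h.bin_edges) / len(vals)
        np.testing.assert_allclose(h.probabilities, expected, atol=1e-12)
        assert abs(h.probabilities.sum() - 1.0) < 1e-9

    def test_edges_span_value_range(self, rng):
        vals = rng.random(500) * 7 + 1
        h = build_histogram(vals, n_bins=10)
        assert h.bin_edges[0] == pytest.approx(vals.min())
        assert h.bin_edges[-1] == pytest.approx(vals.max())

    @pytest.mark.parametrize(
        "bad, err",
        [
            ([], "empty input"),
            ([1.0, np.nan], "finite"),
            ([1.0, -0.5], "non-negative"),
        ],
    )
    def test_invalid_inputs(self, bad, err):
        with pytest.raises(ValueError, match=err):
            build_histogram(bad, n_bins=8)


# ---------------------------------------------------------------------------
# class_statistics


class TestClassStatistics:
    def test_single_class_is_whole_histogram(self, rng):
        h = random_histogram(rng)
        (stats,) = class_statistics(h, [])
        centers = h.bin_centers
        assert stats.mass == pytest.approx(1.0)
        assert stats.mean == pytest.approx(float(centers @ h.probabilities))

    def test_delta_distribution_flags_empty_class(self):
        h = build_histogram([1.0] * 99 + [9.0], n_bins=8)
        # all mass below a cut near the top: top class empty except last bin
        stats = class_statistics(h, [float(h.bin_edges[4])])
        assert stats[0].variance >= 0
        lone = class_statistics(build_histogram([1.0] * 99 + [1.0001], 4), [1.00005])
        assert lone[1].empty or lone[1].mass > 0  # partition covers all bins

    def test_empty_class_convention(self):
        h = build_histogram([1.0] * 50 + [2.0] * 50, n_bins=4)
        # cut inside the empty middle region twice -> middle class has no mass
        t1, t2 = float(h.bin_edges[2]), float(h.bin_edges[3])
        stats = class_statistics(h, [t1, t2])
        assert stats[1].empty
        assert stats[1].mass == 0.0 and stats[1].mean == 0.0 and stats[1].variance == 0.0

    def test_matches_naive_moments_oracle(self, rng):
        for _ in range(20):
            h = random_histogram(rng, n_bins=32)
            cuts = sorted(rng.choice(np.arange(1, 32), size=3, replace=False))
            thresholds = h.bin_edges[cuts]
            stats = class_statistics(h, thresholds)
            expected = naive_class_moments(h, cuts)
            assert len(stats) == 4
            for s, (m, mu, var) in zip(stats, expected):
                assert s.mass == pytest.approx(m, abs=1e-12)
                assert s.mean == pytest.approx(mu, abs=1e-9)
                assert s.variance == pytest.approx(var, abs=1e-9)

    def test_masses_sum_to_one(self, rng):
        h = random_histogram(rng)
        stats = class_statistics(h, h.bin_edges[[10, 30, 50]])
        assert sum(s.mass for s in stats) == pytest.approx(1.0, abs=1e-9)

    def test_threshold_outside_range_raises(self, rng):
        h = random_histogram(rng)
        with pytest.raises(ValueError, match="outside"):
            class_statistics(h, [h.value_max + 1.0])

    def test_threshold_inside_bin_assigned_to_lower_class(self):
        h = build_histogram([0.0, 1.0, 2.0, 3.0], n_bins=4)
        mid_bin1 = 0.5 * (h.bin_edges[1] + h.bin_edges[2])  # inside bin 1
        stats = class_statistics(h, [mid_bin1])
        # bin 1 joins the lower class -> lower mass 0.5
        assert stats[0].mass == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# multilevel_otsu


class TestMultilevelOtsu:
    def test_two_separable_deltas(self):
        vals = [1.0] * 50 + [9.0] * 50
        h = build_histogram(vals, n_bins=16)
        ts = multilevel_otsu(h, 2)
        assert 1.0 < ts.thresholds[0] < 9.0
        assert ts.objective == pytest.approx(0.0, abs=1e-12)
        assert ts.per_class[0].mass == pytest.approx(0.5)
        assert ts.per_class[1].mass == pytest.approx(0.5)

    def test_three_separable_deltas(self):
        vals = [1.0] * 50 + [5.0] * 50 + [9.0] * 50
        h = build_histogram(vals, n_bins=16)
        ts = multilevel_otsu(h, 3)
        t1, t2 = ts.thresholds
        assert 1.0 < t1 < 5.0 < t2 < 9.0
        assert ts.objective == pytest.approx(0.0, abs=1e-12)

    def test_k2_matches_classical_otsu_scan(self, rng):
        for _ in range(25):
            h = random_histogram(rng)
            ts = multilevel_otsu(h, 2)
            cuts, _ = exhaustive_otsu(h, 2)
            assert ts.thresholds[0] == h.bin_edges[cuts[0]]

    @pytest.mark.parametrize("k", [3, 4])
    def test_matches_exhaustive_enumeration(self, rng, k):
        for _ in range(5):
            h = random_histogram(rng, n_bins=32)
            ts = multilevel_otsu(h, k)
            cuts, best = exhaustive_otsu(h, k)
            np.testing.assert_array_equal(ts.thresholds, h.bin_edges[cuts])
            assert ts.objective == pytest.approx(best, abs=1e-9)

    def test_objective_consistent_with_per_class(self, rng):
        h = random_histogram(rng)
        ts = multilevel_otsu(h, 3)
        recomputed = sum(s.mass * s.variance for s in ts.per_class)
        assert ts.objective == pytest.approx(recomputed, abs=1e-9)

    def test_threshold_count_and_ordering(self, rng):
        h = random_histogram(rng)
        for k in range(2, 6):
            ts = multilevel_otsu(h, k)
            assert len(ts.thresholds) == k - 1
            assert np.all(np.diff(ts.thresholds) > 0)
            assert h.value_min < ts.thresholds[0]
            assert ts.thresholds[-1] < h.value_max

    def test_insufficient_levels_raises(self):
        h = build_histogram([1.0] * 10 + [2.0] * 10, n_bins=8)
        with pytest.raises(ValueError, match="insufficient distinct levels"):
            multilevel_otsu(h, 3)

    def test_affine_intensity_invariance(self, rng):
        """Cut indices invariant under positive affine transform; objective
        scales with the square of the scale factor."""
        vals = rng.random(3000) * 10
        scale, shift = 3.5, 2.0
        h1 = build_histogram(vals, 64)
        h2 = build_histogram(scale * vals + shift, 64)
        for k in (2, 3):
            ts1 = multilevel_otsu(h1, k)
            ts2 = multilevel_otsu(h2, k)
            np.testing.assert_allclose(
                ts2.thresholds, scale * ts1.thresholds + shift, rtol=1e-9
            )
            assert ts2.objective == pytest.approx(
                scale**2 * ts1.objective, rel=1e-9
            )


# ---------------------------------------------------------------------------
# segment_mo_pet


class TestSegmentMoPet:
    def test_exact_sphere_recovery(self, sharp_sphere_phantom):
        image, truth, voi = sharp_sphere_phantom
        mask, ts = segment_mo_pet(image, voi, k=2)
        np.testing.assert_array_equal(mask.data, truth.data)
        assert 1.0 < ts.thresholds[0] < 8.0

    def test_constant_voi_raises(self, sharp_sphere_phantom):
        image, _, _ = sharp_sphere_phantom
        from mopet import EllipsoidVOI

        far_voi = EllipsoidVOI(center=(10.0, 10.0, 10.0), semi_axes=(6.0, 6.0, 6.0))
        with pytest.raises(DegenerateDistributionError):
            segment_mo_pet(image, far_voi, k=2)

    def test_blurred_noisy_recovery_within_25pct(self, blurred_phantom):
        """Two-class scene: K=2 recovers a blurred noisy sphere within 25%.

        (K=3 with the top-threshold tumor rule underestimates blurred
        spheres; see the mask-threshold consistency test below.)
        """
        ratios = []
        for seed in range(8):
            image, truth, voi = blurred_phantom(seed=seed)
            mask, _ = segment_mo_pet(image, voi, k=2)
            ratios.append(mask.volume_cm3 / truth.volume_cm3)
        assert 0.75 <= np.mean(ratios) <= 1.25

    def test_mask_respects_topmost_threshold(self, blurred_phantom):
        image, _, voi = blurred_phantom(seed=1)
        mask, ts = segment_mo_pet(image, voi, k=3)
        assert np.all(image.data[mask.data] >= ts.thresholds[-1])

    def test_mask_is_single_connected_component(self, blurred_phantom):
        from scipy import ndimage

        image, _, voi = blurred_phantom(seed=2)
        mask, _ = segment_mo_pet(image, voi, k=2)
        _, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3), dtype=int))
        assert n == 1

    def test_k_out_of_range(self, sharp_sphere_phantom):
        image, _, voi = sharp_sphere_phantom
        with pytest.raises(ValueError):
            segment_mo_pet(image, voi, k=1)
        with pytest.raises(ValueError):
            segment_mo_pet(image, voi, k=6)

    def test_threshold_set_json_roundtrip(self, blurred_phantom):
        import json

        image, _, voi = blurred_phantom(seed=0)
        _, ts = segment_mo_pet(image, voi, k=3)
        d = json.loads(json.dumps(ts.to_dict()))
        assert d["K"] == 3
        assert len(d["thresholds"]) == 2
        assert len(d["per_class"]) == 3
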
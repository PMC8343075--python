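"""Bundle resampling, core estimation, outlier cleaning, profile weighting."""

from __future__ import annotations

import numpy as np
import pytest

from tractsvm import (
    StreamlineBundle,
    clean_bundle,
    core_trajectory,
    generate_bundle,
    profile_bundle,
    resample_fiber,
)
from tractsvm.profiling import deviation_scores, fiber_length


def _straight(length=99.0, n=2):
    t = np.linspace(0.0, length, n)
    return np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])


class TestResampleFiber:
    def test_equidistant_nodes_on_straight_fiber(self):
        pts, _ = resample_fiber(_straight(99.0, 2), 100)
        np.testing.assert_allclose(pts[:, 0], np.arange(100.0), atol=1e-12)
        np.testing.assert_allclose(pts[:, 1:], 0.0)

    def test_idempotent_on_equidistant_fiber(self):
        rng = np.random.default_rng(0)
        direction = np.array([1.0, 2.0, -0.5])
        base = np.outer(np.linspace(0.0, 80.0, 100), direction)
        pts1, vals1 = resample_fiber(base, 100, rng.normal(size=100))
        pts2, vals2 = resample_fiber(pts1, 100, vals1)
        np.testing.assert_allclose(pts2, pts1, atol=1e-9)
        np.testing.assert_allclose(vals2, vals1, atol=1e-9)

    def test_linear_scalar_field_stays_linear(self):
        fiber = _straight(90.0, 10)
        vals = 2.0 + 0.5 * fiber[:, 0]  # linear in arc length
        _, out = resample_fiber(fiber, 37, vals)
        expected = 2.0 + 0.5 * np.linspace(0.0, 90.0, 37)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_zero_length_fiber_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            resample_fiber(np.zeros((3, 3)), 10)


class TestCoreTrajectory:
    def test_identical_fibers_give_zero_spread(self):
        f = _straight(50.0, 20)
        bundle = StreamlineBundle([f, f.copy(), f.copy()], [np.ones(20)] * 3)
        core = core_trajectory(bundle, 25)
        np.testing.assert_allclose(core.node_positions[:, 0], np.linspace(0, 50, 25), atol=1e-9)
        np.testing.assert_allclose(core.node_spread, 0.0, atol=1e-12)

    def test_two_offset_fibers_core_is_midline(self):
        f = _straight(50.0, 20)
        up, down = f.copy(), f.copy()
        up[:, 1] += 1.0
        down[:, 1] -= 1.0
        bundle = StreamlineBundle([up, down], [np.ones(20)] * 2)
        core = core_trajectory(bundle, 10)
        np.testing.assert_allclose(core.node_positions[:, 1], 0.0, atol=1e-9)

    def test_core_recovers_generating_centerline(self, straight_centerline):
        n_fib, disp = 200, 1.0
        bundle = generate_bundle(n_fib, straight_centerline, dispersion_sd=disp, seed=3)
        core = core_trajectory(bundle, 50)
        # constant random offsets of SD 1 per axis: SE of the node mean ~ disp/sqrt(F)
        se = disp / np.sqrt(n_fib)
        off = np.abs(core.node_positions[:, 1:])
        assert off.max() < 5 * se

    def test_needs_two_fibers(self):
        f = _straight(50.0, 20)
        with pytest.raises(ValueError):
            core_trajectory(StreamlineBundle([f], [np.ones(20)]), 10)


class TestCleanBundle:
    def test_homogeneous_bundle_untouched(self, clean_base_bundle):
        cleaned = clean_bundle(clean_base_bundle, n_nodes=50)
        assert cleaned.n_fibers == clean_base_bundle.n_fibers

    def test_removes_exactly_injected_long_fibers(self, straight_centerline):
        bundle = generate_bundle(
            100, straight_centerline, dispersion_sd=1.0, length_jitter=0.03,
            outlier_spec={"n_long": 3, "n_far": 0}, seed=9,
        )
        cleaned = clean_bundle(bundle, n_nodes=50)
        assert cleaned.n_fibers == 100
        lengths = [fiber_length(f) for f in cleaned.fibers]
        base_lengths = [fiber_length(f) for f in bundle.fibers[:100]]
        assert max(lengths) <= max(base_lengths) + 1e-9

    def test_removes_exactly_injected_far_fibers(self, straight_centerline):
        bundle = generate_bundle(
            100, straight_centerline, dispersion_sd=1.0, length_jitter=0.03,
            outlier_spec={"n_long": 0, "n_far": 2}, seed=13,
        )
        cleaned = clean_bundle(bundle, n_nodes=50)
        assert cleaned.n_fibers == 100
        # survivors are the base fibers: all within a few dispersion SDs of the core
        scores = deviation_scores(cleaned, 50)
        assert scores.max() <= 5.0

    def test_idempotent_after_convergence(self, straight_centerline):
        bundle = generate_bundle(
            80, straight_centerline, dispersion_sd=1.0,
            outlier_spec={"n_long": 2, "n_far": 1}, seed=17,
        )
        once = clean_bundle(bundle, n_nodes=50)
        twice = clean_bundle(once, n_nodes=50)
        assert twice.n_fibers == once.n_fibers

    def test_minimum_fiber_count(self):
        f = _straight(50.0, 20)
        with pytest.raises(ValueError):
            clean_bundle(StreamlineBundle([f, f.copy()], [np.ones(20)] * 2))


class TestProfileBundle:
    def test_constant_field_gives_constant_profile(self, straight_centerline):
        bundle = generate_bundle(
            50, straight_centerline, dispersion_sd=1.0, seed=1,
            field=lambda t: 0.7 * np.ones_like(t), tract_id="left_ilf",
        )
        prof = profile_bundle(bundle, "s01", "FA", n_nodes=40)
        np.testing.assert_allclose(prof.values, 0.7, atol=1e-12)
        assert prof.tract_id == "left_ilf"

    def test_equidistant_fibers_average_equally(self):
        f = _straight(50.0, 20)
        up, down = f.copy(), f.copy()
        up[:, 1] += 1.0
        down[:, 1] -= 1.0
        bundle = StreamlineBundle(
            [up, down], [np.full(20, 0.2), np.full(20, 0.8)], tract_id="left_ilf"
        )
        prof = profile_bundle(bundle, "s01", "FA", n_nodes=10)
        np.testing.assert_allclose(prof.values, 0.5, atol=1e-9)

    def test_weights_decay_with_core_distance(self):
        # several on-core fibers valued a, one distant fiber valued b:
        # the weighted profile must sit closer to a than the unweighted mean
        f = _straight(50.0, 20)
        rng = np.random.default_rng(4)
        fibers = [f + rng.normal(0, 0.05, f.shape) for _ in range(6)]
        values = [np.full(20, 0.3)] * 6
        far = f.copy()
        far[:, 1] += 3.0
        fibers.append(far)
        values.append(np.full(20, 0.9))
        bundle = StreamlineBundle(fibers, values, tract_id="left_ilf")
        prof = profile_bundle(bundle, "s01", "FA", n_nodes=10)
        unweighted = (6 * 0.3 + 0.9) / 7
        assert np.all(prof.values < unweighted)
        assert np.all(prof.values > 0.3)

    def test_profile_is_convex_combination_of_fiber_values(self, straight_centerline):
        rng = np.random.default_rng(8)
        bundle = generate_bundle(30, straight_centerline, dispersion_sd=1.5, seed=8)
        bundle = StreamlineBundle(
            bundle.fibers, [rng.uniform(0.1, 0.9, len(v)) for v in bundle.values],
            tract_id="left_ilf",
        )
        prof = profile_bundle(bundle, "s01", "FA", n_nodes=25)
        lo = min(v.min() for v in bundle.values)
        hi = max(v.max() for v in bundle.values)
        assert np.all(prof.values >= lo - 1e-12)
        assert np.all(prof.values <= hi + 1e-12)


def test_generate_bundle_rejects_degenerate_centerline():
    with pytest.raises(ValueError, match="degenerate"):
        generate_bundle(10, np.zeros((3, 3)))
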
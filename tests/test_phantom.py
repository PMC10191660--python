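"""Synthetic organoid phantom: geometry, AR(1) speckle statistics, motion."""

import numpy as np
import pytest

from livoct import (
    Alveolus,
    CLASS_LABELS,
    MotionTrace,
    PhantomSpec,
    build_label_map,
    compute_liv,
    inject_bulk_motion,
    simulate_timeseries,
)
from livoct.liv import stack_to_db
from livoct.stack import FrameStack

from conftest import uniform_class_maps

LOG_EXP_VAR_DB2 = (10.0 / np.log(10.0)) ** 2 * np.pi ** 2 / 6.0  # ~31.025


class TestLabelMap:
    def test_empty_scene_is_all_background(self):
        spec = PhantomSpec(grid_shape=(32, 32, 2))
        assert np.all(build_label_map(spec) == CLASS_LABELS["background"])

    def test_epithelium_annulus_pixel_count(self):
        # rasterized annulus r_in=20, r_out=24 vs continuous area ~553 px^2
        spec = PhantomSpec(grid_shape=(128, 128, 1),
                           alveoli=[Alveolus((64, 64, 0), 20, 4)])
        labels = build_label_map(spec)
        epi = np.isin(labels, [CLASS_LABELS["epithelium_high"],
                               CLASS_LABELS["epithelium_low"]])
        expected = np.pi * (24.0 ** 2 - 20.0 ** 2)
        assert abs(epi.sum() - expected) / expected < 0.10
        lumen = (labels == CLASS_LABELS["lumen"]).sum()
        assert abs(lumen - np.pi * 400) / (np.pi * 400) < 0.10

    def test_later_alveolus_wins_overlap(self):
        small = Alveolus((32, 32, 0), 10, 2, tessellated=True)
        large = Alveolus((32, 32, 0), 20, 4)
        spec = PhantomSpec(grid_shape=(64, 64, 1), alveoli=[small, large])
        labels = build_label_map(spec)
        # the small alveolus's annulus (radius 10..12) now lies inside the
        # large lumen; no tessellated (low-dynamics) label may survive
        assert labels[32, 43] == CLASS_LABELS["lumen"]
        assert not np.any(labels == CLASS_LABELS["epithelium_low"])

    def test_alveolus_outside_grid_rejected(self):
        spec = PhantomSpec(grid_shape=(64, 64, 1),
                           alveoli=[Alveolus((200, 200, 0), 10, 2)])
        with pytest.raises(ValueError, match="outside"):
            build_label_map(spec)

    def test_tessellation_alternates_sectors(self):
        spec = PhantomSpec(grid_shape=(128, 128, 1),
                           alveoli=[Alveolus((64, 64, 0), 20, 6,
                                             tessellated=True)])
        labels = build_label_map(spec)
        high = (labels == CLASS_LABELS["epithelium_high"]).sum()
        low = (labels == CLASS_LABELS["epithelium_low"]).sum()
        assert high > 0 and low > 0
        assert abs(high - low) / (high + low) < 0.15

    def test_filled_alveolus_inclusion_disk(self):
        spec = PhantomSpec(grid_shape=(128, 128, 1),
                           alveoli=[Alveolus((64, 64, 0), 20, 4, filled=True)])
        labels = build_label_map(spec)
        inc = (labels == CLASS_LABELS["inclusion"]).sum()
        expected = np.pi * (0.6 * 20) ** 2
        assert abs(inc - expected) / expected < 0.10

    def test_surface_layer_present_and_tilted(self):
        spec = PhantomSpec(grid_shape=(64, 32, 4), surface_depth_px=20,
                           surface_tilt_slow=1.0)
        labels = build_label_map(spec)
        fib = CLASS_LABELS["fibroblast"]
        first = np.argmax(labels == fib, axis=0)
        assert np.all(first[:, 0] == 20)
        assert np.all(first[:, 3] == 23)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            Alveolus((0, 0, 0), -5, 2)
        with pytest.raises(ValueError):
            PhantomSpec(class_correlation={k: 1.5 for k in CLASS_LABELS})


class TestSimulateTimeseries:
    def test_frozen_field_has_zero_liv(self):
        mu, rho = uniform_class_maps(rho=1.0)
        spec = PhantomSpec(grid_shape=(32, 32, 1), class_intensity=mu,
                           class_correlation=rho, noise_floor_mean=0.0,
                           seed=5)
        stack = simulate_timeseries(build_label_map(spec), spec,
                                    n_frames=8, seed=5)[0]
        assert np.allclose(stack.data, stack.data[0])
        liv = compute_liv(stack_to_db(stack))
        assert np.allclose(liv.liv, 0.0)

    def test_decorrelated_speckle_db_variance_closed_form(self):
        # dB-scaled unit-exponential intensity has variance
        # (10/ln10)^2 pi^2/6 ~ 31.0 dB^2; LIV's divisor-N estimator is
        # biased by (N-1)/N. Spatially uncorrelated speckle maximizes the
        # number of independent Monte Carlo samples.
        mu, rho = uniform_class_maps(rho=0.0)
        spec = PhantomSpec(grid_shape=(128, 128, 1), class_intensity=mu,
                           class_correlation=rho, noise_floor_mean=0.0,
                           speckle_grain_px=0.0, seed=11)
        n = 32
        stack = simulate_timeseries(build_label_map(spec), spec,
                                    n_frames=n, seed=11)[0]
        liv = compute_liv(stack_to_db(stack, 1e-12))
        expected = (n - 1) / n * LOG_EXP_VAR_DB2
        assert liv.liv.mean() == pytest.approx(expected, rel=0.01)

    def test_mean_intensity_matches_class_mean(self):
        mu, rho = uniform_class_maps(rho=0.0, mu=2.5)
        spec = PhantomSpec(grid_shape=(96, 96, 1), class_intensity=mu,
                           class_correlation=rho, noise_floor_mean=0.25,
                           speckle_grain_px=0.0, seed=7)
        stack = simulate_timeseries(build_label_map(spec), spec,
                                    n_frames=16, seed=7)[0]
        samples = stack.data.ravel()
        # Exp(mu) + Exp(nu): mean mu + nu, var mu^2 + nu^2
        se = np.sqrt(2.5 ** 2 + 0.25 ** 2) / np.sqrt(samples.size)
        assert abs(samples.mean() - 2.75) < 3 * se

    def test_liv_monotone_in_frame_correlation(self):
        means = []
        for rho_val in (0.0, 0.5, 0.9, 1.0):
            mu, rho = uniform_class_maps(rho=rho_val)
            spec = PhantomSpec(grid_shape=(128, 128, 1), class_intensity=mu,
                               class_correlation=rho, seed=42)
            stack = simulate_timeseries(build_label_map(spec), spec,
                                        n_frames=32, seed=42)[0]
            liv = compute_liv(stack_to_db(stack, spec.noise_floor_mean))
            means.append(liv.liv.mean())
        assert all(np.diff(means) < 0), means

    def test_determinism(self):
        spec = PhantomSpec(grid_shape=(24, 24, 2),
                           alveoli=[Alveolus((12, 12, 0), 6, 2)], seed=9)
        labels = build_label_map(spec)
        a = simulate_timeseries(labels, spec, n_frames=4, seed=9)
        b = simulate_timeseries(labels, spec, n_frames=4, seed=9)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.data, sb.data)

    def test_output_strictly_positive(self):
        spec = PhantomSpec(grid_shape=(48, 48, 1), seed=2)
        stack = simulate_timeseries(build_label_map(spec), spec,
                                    n_frames=6, seed=2)[0]
        assert np.all(stack.data > 0)

    def test_invalid_inputs(self):
        spec = PhantomSpec(grid_shape=(16, 16, 1))
        labels = build_label_map(spec)
        with pytest.raises(ValueError):
            simulate_timeseries(labels, spec, n_frames=1)
        with pytest.raises(TypeError):
            simulate_timeseries(labels, spec, n_frames=4, seed="abc")


class TestInjectBulkMotion:
    def _stack_from(self, frames):
        return FrameStack(frames, np.arange(len(frames), dtype=float) + 1.0,
                          scale="db")

    def test_zero_trace_is_identity(self, smooth_image):
        frames = np.stack([smooth_image] * 4)
        stack = self._stack_from(frames)
        out = inject_bulk_motion(stack, MotionTrace(np.zeros((4, 2))))
        assert np.array_equal(out.data, stack.data)

    def test_integer_shift_equals_roll_on_interior(self, smooth_image):
        stack = self._stack_from(np.stack([smooth_image] * 2))
        trace = MotionTrace([[2.0, -3.0], [0.0, 0.0]])
        out = inject_bulk_motion(stack, trace)
        rolled = np.roll(smooth_image, (2, -3), axis=(0, 1))
        assert np.allclose(out.data[0][5:-5, 5:-5], rolled[5:-5, 5:-5],
                           rtol=1e-6)

    def test_round_trip_recovers_interior(self, smooth_image):
        # shift then unshift with the cubic-spline family: the interior of
        # a band-limited image returns to within 1e-3 relative
        stack = self._stack_from(np.stack([smooth_image] * 3))
        rng = np.random.default_rng(4)
        trace = MotionTrace(rng.uniform(-1.5, 1.5, (3, 2)))
        back = inject_bulk_motion(inject_bulk_motion(stack, trace), -trace)
        interior = (slice(None), slice(8, -8), slice(8, -8))
        rel = np.abs(back.data - stack.data)[interior] / stack.data[interior]
        assert rel.max() < 1e-3

    def test_trace_length_mismatch(self, smooth_image):
        stack = self._stack_from(np.stack([smooth_image] * 3))
        with pytest.raises(ValueError):
            inject_bulk_motion(stack, MotionTrace(np.zeros((5, 2))))

    def test_non_finite_trace_rejected(self):
        with pytest.raises(ValueError):
            MotionTrace([[np.nan, 0.0]])
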
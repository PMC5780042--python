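"""Curvature extraction from centerlines: geometry oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormwave import (
    CenterlineSeries,
    CurvatureMap,
    ValidationError,
    compute_curvature_map,
    compute_curvature_profile,
    render_centerline,
    time_derivative,
)
from tests.conftest import make_wave_map


def circle_points(n=120, length=1.0, sweep=0.999):
    r = length / (2 * np.pi)
    th = np.linspace(0.0, 2 * np.pi * sweep, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


class TestCurvatureProfile:
    def test_collinear_points_give_zero_curvature(self):
        x = np.linspace(0.0, 1.0, 50)
        pts = np.column_stack([x, np.zeros_like(x)])
        assert np.allclose(compute_curvature_profile(pts), 0.0, atol=1e-9)

    def test_circle_curvature_is_two_pi(self):
        # kappa = 1/r, so kappa * L = 2*pi for a circle of circumference L
        prof = compute_curvature_profile(circle_points())
        interior = np.abs(prof[2:-2])
        assert np.max(np.abs(interior - 2 * np.pi)) / (2 * np.pi) < 0.01

    def test_shallow_sinusoid_matches_dense_numerical_oracle(self):
        # y = a sin(2 pi x / lam), a << lam: peak |kappa| ~ a (2 pi / lam)^2
        a, lam = 0.01, 0.5
        x = np.linspace(0.0, 1.0, 300)
        pts = np.column_stack([x, a * np.sin(2 * np.pi * x / lam)])
        prof = compute_curvature_profile(pts)

        # independent oracle: parametric curvature on a dense analytic grid
        xd = np.linspace(0.0, 1.0, 20000)
        yp = a * (2 * np.pi / lam) * np.cos(2 * np.pi * xd / lam)
        ypp = -a * (2 * np.pi / lam) ** 2 * np.sin(2 * np.pi * xd / lam)
        kappa_oracle = ypp / (1 + yp**2) ** 1.5
        peak_oracle = np.max(np.abs(kappa_oracle))

        small_angle = a * (2 * np.pi / lam) ** 2
        assert peak_oracle == pytest.approx(small_angle, rel=0.01)
        # profile is kappa*L; frame length ~ 1.0005 here
        assert np.max(np.abs(prof)) == pytest.approx(peak_oracle, rel=0.02)

    def test_rejects_too_few_and_duplicate_points(self):
        with pytest.raises(ValidationError):
            compute_curvature_profile(np.zeros((4, 2)))
        pts = circle_points()
        pts[10] = pts[9]
        with pytest.raises(ValidationError):
            compute_curvature_profile(pts)

    def test_rejects_self_intersecting_chain(self):
        pts = np.array(
            [[0, 0], [1, 0], [1, 1], [0.5, -1.0], [0.2, 0.5], [0.1, 0.6]], dtype=float
        )
        with pytest.raises(ValidationError, match="self-intersect"):
            compute_curvature_profile(pts)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        angle=st.floats(0.0, 2 * np.pi),
        dx=st.floats(-5.0, 5.0),
        dy=st.floats(-5.0, 5.0),
    )
    def test_rigid_motion_equivariance(self, angle, dx, dy):
        """Rotation + translation of the centerline leaves curvature unchanged."""
        pts = circle_points(n=80, sweep=0.7)
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = pts @ rot.T + np.array([dx, dy])
        base = compute_curvature_profile(pts)
        assert np.allclose(compute_curvature_profile(moved), base, atol=1e-8)

    def test_reflection_flips_curvature_sign(self):
        pts = circle_points(n=80, sweep=0.7)
        mirrored = pts * np.array([1.0, -1.0])
        base = compute_curvature_profile(pts)
        assert np.allclose(compute_curvature_profile(mirrored), -base, atol=1e-8)


class TestCurvatureMap:
    def test_output_shape_is_n_frames_by_100_regardless_of_k(self):
        frames = [circle_points(n=k, sweep=0.6) for k in (60, 90, 123)]
        series = CenterlineSeries(frames=frames, sampling_rate=40.0)
        cmap = compute_curvature_map(series)
        assert cmap.values.shape == (3, 100)

    def test_repeated_straight_frame_gives_zero_map(self):
        x = np.linspace(0.0, 1.0, 50)
        frame = np.column_stack([x, np.zeros_like(x)])
        series = CenterlineSeries(frames=[frame, frame, frame], sampling_rate=40.0)
        cmap = compute_curvature_map(series)
        assert np.allclose(cmap.values, 0.0, atol=1e-9)

    def test_needs_at_least_two_frames(self):
        series = CenterlineSeries(frames=[circle_points()], sampling_rate=40.0)
        with pytest.raises(ValidationError):
            compute_curvature_map(series)

    def test_short_frames_are_flagged_not_dropped(self):
        good = circle_points(n=80, sweep=0.7)
        short = good[:55]  # ~21% shorter arc
        series = CenterlineSeries(frames=[good, good, short], sampling_rate=40.0)
        assert list(series.flagged) == [False, False, True]
        assert len(compute_curvature_map(series).times) == 3


class TestRenderRoundTrip:
    def test_zero_map_renders_straight_equally_spaced_centerline(self):
        cmap = make_wave_map(amplitude=0.0, duration=0.1)
        series = render_centerline(cmap, worm_length=1.0)
        pts = series.frames[0]
        assert np.allclose(pts[:, 1], 0.0, atol=1e-12)
        assert np.allclose(np.diff(pts[:, 0]), pts[1, 0] - pts[0, 0], atol=1e-9)
        assert series.arc_lengths()[0] == pytest.approx(1.0, rel=1e-3)

    def test_constant_two_pi_map_closes_into_a_circle(self):
        s = np.linspace(0.0, 100.0, 100)
        t = np.array([0.0, 0.025])
        cmap = CurvatureMap(
            values=np.full((2, 100), 2 * np.pi),
            times=t,
            body_coords=s,
            sampling_rate=40.0,
            worm_length=1.0,
        )
        pts = render_centerline(cmap, worm_length=1.0).frames[0]
        # first and last points coincide on a closed arc: drop the duplicate
        # so the centroid is unbiased
        centre = pts[:-1].mean(axis=0)
        radii = np.hypot(*(pts - centre).T)
        assert radii == pytest.approx(1.0 / (2 * np.pi), rel=1e-3)
        assert np.hypot(*(pts[-1] - pts[0])) < 1e-3  # closes

    def test_travelling_wave_round_trip_below_1e3(self):
        cmap = make_wave_map(duration=1.0)
        series = render_centerline(cmap, worm_length=1.0)
        assert np.max(np.abs(series.arc_lengths() - 1.0)) < 1e-3
        recovered = compute_curvature_map(series)
        # the outermost two coordinates per end are spline extrapolations
        err = np.abs(recovered.values[:, 2:-2] - cmap.values[:, 2:-2])
        assert err.max() < 1e-3

    def test_non_finite_map_is_rejected(self):
        cmap = make_wave_map(duration=0.1)
        cmap.values[0, 0] = np.nan
        with pytest.raises(ValidationError):
            render_centerline(cmap)


class TestTimeDerivative:
    def test_sinusoid_derivative_closed_form(self):
        # kappa = A0 sin(2 pi f t) -> d/dt = A0 2 pi f cos(2 pi f t)
        f, a0, fs = 1.0, 5.0, 40.0
        cmap = make_wave_map(freq_hz=f, amplitude=a0, fs=fs, duration=5.0)
        dk = time_derivative(cmap)
        t = cmap.times
        s = cmap.body_coords
        expected = (
            a0
            * 2
            * np.pi
            * f
            * np.cos(
                2 * np.pi * f * t[:, None] - 2 * np.pi * 1.5 * s[None, :] / 100.0
            )
        )
        # interior frames; central differences attenuate by sinc(2 pi f / fs)
        err = np.abs(dk[1:-1] - expected[1:-1]) / (a0 * 2 * np.pi * f)
        assert err.max() < 0.01

    def test_constant_map_derivative_is_zero(self):
        cmap = make_wave_map(amplitude=0.0)
        cmap.values += 3.0
        assert np.allclose(time_derivative(cmap), 0.0)

    def test_linear_ramp_is_exact_including_boundaries(self):
        cmap = make_wave_map(amplitude=0.0, duration=1.0)
        c = 2.5
        cmap.values = c * cmap.times[:, None] * np.ones_like(cmap.values)
        assert np.allclose(time_derivative(cmap), c, atol=1e-9)
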
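"""Centerline kinematics: from tracked point chains to curvature kymograms.

A worm posture is an ordered head-to-tail chain of planar points.  Arc length
along the chain defines the body coordinate s in [0, 100] (head tip 0, tail
tip 100).  Signed curvature is computed from the derivative of the tangent
angle with respect to arc length, which is well behaved near straight
postures, and stored dimensionless as kappa * L (L = worm length) so that its
time derivative carries units of 1/s.  Positive curvature is bending toward
the side designated dorsal by the first frame's orientation; the assignment
is arbitrary for dark-field recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, splev, splprep

from .errors import ValidationError

N_BODY_COORDS = 100
#: Per-frame arc lengths deviating more than this fraction from the series
#: median are flagged (mis-segmented frames), never silently dropped.
ARC_LENGTH_TOLERANCE = 0.10


def _arc_lengths(points: np.ndarray) -> np.ndarray:
    seg = np.diff(points, axis=0)
    return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])


def _orient(a, b, c):
    return (b[..., 0] - a[..., 0]) * (c[..., 1] - a[..., 1]) - (
        b[..., 1] - a[..., 1]
    ) * (c[..., 0] - a[..., 0])


def _check_simple(points: np.ndarray) -> None:
    """Reject self-intersecting chains (non-adjacent segment crossings)."""
    n = len(points) - 1
    if n < 3:
        return
    a = points[:-1][:, None, :]  # segment i start
    b = points[1:][:, None, :]
    c = points[:-1][None, :, :]  # segment j start
    d = points[1:][None, :, :]
    cross = (
        (_orient(a, b, c) * _orient(a, b, d) < 0)
        & (_orient(c, d, a) * _orient(c, d, b) < 0)
    )
    i_idx, j_idx = np.nonzero(np.triu(cross, k=2))
    if i_idx.size:
        raise ValidationError(
            f"centerline self-intersects (segments {int(i_idx[0])} and {int(j_idx[0])})"
        )


@dataclass
class CenterlineSeries:
    """Time series of head-to-tail centerline point chains.

    Attributes
    ----------
    frames:
        List of (K_i, 2) arrays of planar coordinates in mm, ordered head to
        tail.  Point counts may vary between frames.
    sampling_rate:
        Frame rate in Hz (frames are uniformly spaced in time).
    times:
        Frame times in seconds.
    worm_length:
        Median arc length across frames (mm).
    flagged:
        Boolean per-frame flags marking arc lengths outside +/-10% of the
        median (candidate segmentation failures).
    """

    frames: list
    sampling_rate: float
    times: np.ndarray | None = None
    worm_length: float = field(init=False)
    flagged: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValidationError("centerline series must contain at least one frame")
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.ndim != 2 or f.shape[1] != 2:
                raise ValidationError(f"frame {i} is not a (K, 2) point array")
            if f.shape[0] < 5:
                raise ValidationError(f"frame {i} has {f.shape[0]} points; need >= 5")
            if not np.all(np.isfinite(f)):
                raise ValidationError(f"frame {i} contains non-finite coordinates")
            if np.any(np.all(np.diff(f, axis=0) == 0.0, axis=1)):
                raise ValidationError(f"frame {i} contains duplicate consecutive points")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if self.times is None:
            self.times = np.arange(len(self.frames)) / self.sampling_rate
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (len(self.frames),):
                raise ValidationError("times must have one entry per frame")
        lengths = np.array([_arc_lengths(f)[-1] for f in self.frames])
        self.worm_length = float(np.median(lengths))
        self.flagged = np.abs(lengths / self.worm_length - 1.0) > ARC_LENGTH_TOLERANCE

    def __len__(self) -> int:
        return len(self.frames)

    def arc_lengths(self) -> np.ndarray:
        """Total arc length (mm) of every frame."""
        return np.array([_arc_lengths(f)[-1] for f in self.frames])


def _profile_raw(
    points: np.ndarray,
    n_samples: int,
    smoothing: float,
) -> tuple[np.ndarray, float]:
    """Signed curvature (1/mm) at n arc-length-uniform samples, plus length."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValidationError("frame must be a (K, 2) array of planar points")
    if points.shape[0] < 5:
        raise ValidationError(f"frame has {points.shape[0]} points; need >= 5")
    if not np.all(np.isfinite(points)):
        raise ValidationError("frame contains non-finite coordinates")
    if np.any(np.all(np.diff(points, axis=0) == 0.0, axis=1)):
        raise ValidationError("frame contains duplicate consecutive points")
    _check_simple(points)

    chord = _arc_lengths(points)
    if chord[-1] <= 0:
        raise ValidationError("frame has zero arc length")
    u = chord / chord[-1]
    if smoothing > 0:
        # FITPACK smoothing spline on the parametric curve; s scales with the
        # squared coordinate scale so the parameter is dimensionless.
        scale = float(np.ptp(points)) or 1.0
        tck, _ = splprep(points.T, u=u, s=smoothing * len(points) * scale**2, k=3)

        def ev(t, der):
            return np.array(splev(t, tck, der=der))

    else:
        csx = CubicSpline(u, points[:, 0])
        csy = CubicSpline(u, points[:, 1])

        def ev(t, der):
            return np.array([csx(t, der), csy(t, der)])

    m = max(1000, 4 * len(points))
    t = np.linspace(0.0, 1.0, m)
    dx, dy = ev(t, 1)
    speed = np.hypot(dx, dy)
    if np.any(speed <= 0):
        raise ValidationError("degenerate centerline: zero tangent speed")
    psi = np.unwrap(np.arctan2(dy, dx))
    s_dense = np.concatenate(
        [[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(t))]
    )
    length = float(s_dense[-1])
    psi_of_s = CubicSpline(s_dense, psi)
    s_targets = np.linspace(0.0, length, n_samples)
    kappa = psi_of_s(s_targets, 1)
    return kappa, length


def compute_curvature_profile(
    frame: np.ndarray,
    n_samples: int = N_BODY_COORDS,
    smoothing: float = 0.0,
) -> np.ndarray:
    """Dimensionless signed curvature kappa*L of one centerline frame.

    The chain is resampled to ``n_samples`` arc-length-uniform body
    coordinates through a (optionally smoothing) cubic spline; curvature is
    the arc-length derivative of the unwrapped tangent angle.

    Parameters
    ----------
    frame:
        (K, 2) ordered head-to-tail points in mm, K >= 5.
    n_samples:
        Number of body-coordinate samples (default 100, spanning s = 0..100).
    smoothing:
        Dimensionless smoothing weight; 0 interpolates the points exactly.

    Returns
    -------
    ndarray of shape (n_samples,), curvature times this frame's arc length.
    """
    kappa, length = _profile_raw(np.asarray(frame, dtype=float), n_samples, smoothing)
    return kappa * length


@dataclass
class CurvatureMap:
    """Curvature kymogram: dimensionless curvature over time x body coordinate.

    ``values[t_i, s_j]`` is kappa*L at time ``times[t_i]`` and body coordinate
    ``body_coords[s_j]`` (0 = head tip, 100 = tail tip).
    """

    values: np.ndarray
    times: np.ndarray
    body_coords: np.ndarray
    sampling_rate: float
    worm_length: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.body_coords = np.asarray(self.body_coords, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D (time x body) matrix")
        if self.values.shape != (self.times.size, self.body_coords.size):
            raise ValidationError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{self.times.size} times x {self.body_coords.size} coords"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("curvature values must be finite")
        if np.any(np.diff(self.body_coords) <= 0):
            raise ValidationError("body_coords must be strictly increasing")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(np.abs(dt * self.sampling_rate - 1.0) > 0.01):
                raise ValidationError("times must be uniform at 1/sampling_rate")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def coord_index(self, body_coord: float) -> int:
        """Index of the body coordinate sample nearest ``body_coord``."""
        if not 0.0 <= body_coord <= 100.0:
            raise ValidationError(f"body coordinate {body_coord} outside [0, 100]")
        return int(np.argmin(np.abs(self.body_coords - body_coord)))

    def window_slice(self, window: tuple[float, float], min_length: float = 0.0) -> slice:
        """Frame slice covering the half-open time window (t0, t1)."""
        t0, t1 = float(window[0]), float(window[1])
        if t1 - t0 < min_length:
            raise ValidationError(
                f"window [{t0}, {t1}] s is shorter than the minimum {min_length} s"
            )
        eps = 0.5 / self.sampling_rate
        if t0 < self.times[0] - eps or t1 > self.times[-1] + eps:
            raise ValidationError(
                f"window [{t0}, {t1}] s lies outside the recording "
                f"[{self.times[0]}, {self.times[-1]}] s"
            )
        i0 = int(np.searchsorted(self.times, t0 - eps))
        i1 = int(np.searchsorted(self.times, t1 - eps))
        return slice(i0, max(i1, i0 + 1))

    def trace(self, body_coord: float) -> np.ndarray:
        """Curvature time series at the nearest body coordinate."""
        return self.values[:, self.coord_index(body_coord)]


def compute_curvature_map(
    series: CenterlineSeries,
    smoothing: float = 0.0,
) -> CurvatureMap:
    """Stack per-frame curvature profiles into a kymogram.

    Raw curvature (1/mm) per frame is scaled by the series' median worm
    length, so a frame whose segmentation ran short does not silently change
    the dimensionless scale.  The outermost two body coordinates on each end
    are spline extrapolations of the tangent angle derivative and are noted
    in ``meta``.
    """
    if len(series) < 2:
        raise ValidationError("need at least 2 frames to build a curvature map")
    profiles = np.empty((len(series), N_BODY_COORDS))
    for i, f in enumerate(series.frames):
        kappa, _ = _profile_raw(f, N_BODY_COORDS, smoothing)
        profiles[i] = kappa * series.worm_length
    meta = {
        "source": "centerlines",
        "smoothing": smoothing,
        "endpoint_coords_extrapolated": 2,
        "flagged_frames": [int(i) for i in np.flatnonzero(series.flagged)],
    }
    return CurvatureMap(
        values=profiles,
        times=series.times,
        body_coords=np.linspace(0.0, 100.0, N_BODY_COORDS),
        sampling_rate=series.sampling_rate,
        worm_length=series.worm_length,
        meta=meta,
    )


def time_derivative(cmap: CurvatureMap) -> np.ndarray:
    """d(kappa*L)/dt in 1/s: central differences, one-sided at the ends."""
    if cmap.values.shape[0] < 3:
        raise ValidationError("need at least 3 frames for a time derivative")
    return np.gradient(cmap.values, axis=0) * cmap.sampling_rate
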
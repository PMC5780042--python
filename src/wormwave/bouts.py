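"""Forward-locomotion bout detection and two-frequency-undulation scoring.

A forward bout is a contiguous interval in which (1) the local activity
level -- sliding-window rms of d(kappa*L)/dt -- exceeds a fixed threshold
and (2) the bending wave travels anterior to posterior, for at least a
minimum duration (2-3 s presets).  Wave direction is estimated from the
lag of the cross-correlation between curvature traces at body coordinates
5 apart, aggregated as a magnitude-weighted median across the region.

2FU scoring operationalises the manual criteria used on kymograms: within
a stimulus window, an event requires at least two full tail undulation
cycles in some sub-window and tail waves that do not simply follow the
head -- here, an undefined or clearly non-unity tail/head frequency ratio,
or low head-tail phase coherence at the tail frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .config import StimulusMask
from .errors import ValidationError
from .kinematics import CurvatureMap, time_derivative
from .spectral import (
    DEFAULT_RATIO_MIN,
    DEFAULT_THRESHOLD,
    HEAD_COORD,
    TAIL_COORD,
    TwoFUResult,
    frequency_ratio,
)

#: Default activity threshold (1/s); shares the quiescence semantics of the
#: spectral threshold (rms bending amplitude of 1.0 1/s).
DEFAULT_ACTIVITY_THRESHOLD = 1.0
#: Body-coordinate separation used for direction cross-correlation.
DIRECTION_DS = 5.0
DEFAULT_COHERENCE_CUTOFF = 0.5


@dataclass
class ActivityMap:
    """Sliding-window rms of d(kappa*L)/dt per (time, body coordinate) cell."""

    values: np.ndarray  # (n_cells, n_coords)
    times: np.ndarray  # window centres, s
    body_coords: np.ndarray
    window_s: float
    stride_s: float


@dataclass
class Bout:
    """A contiguous interval of forward locomotion in a body region."""

    t_start: float
    t_end: float
    s_lo: float
    s_hi: float
    direction: str  # "anterior_to_posterior" | "posterior_to_anterior"
    mean_activity: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def activity_level(
    cmap: CurvatureMap,
    window_s: float = 0.5,
    stride_s: float = 0.125,
) -> ActivityMap:
    """Local undulatory activity: sliding rms of d(kappa*L)/dt.

    ``window_s`` must be at least 0.5 s (shorter windows no longer average
    over a meaningful fraction of an undulation cycle) and no longer than
    the recording.
    """
    if window_s < 0.5:
        raise ValidationError(f"activity window must be >= 0.5 s, got {window_s}")
    if window_s > cmap.duration:
        raise ValidationError(
            f"activity window ({window_s} s) exceeds the recording ({cmap.duration} s)"
        )
    fs = cmap.sampling_rate
    win = max(2, int(round(window_s * fs)))
    stride = max(1, int(round(stride_s * fs)))
    dk2 = time_derivative(cmap) ** 2
    csum = np.cumsum(dk2, axis=0)
    csum = np.vstack([np.zeros((1, dk2.shape[1])), csum])
    starts = np.arange(0, dk2.shape[0] - win + 1, stride)
    rms = np.sqrt((csum[starts + win] - csum[starts]) / win)
    centres = (starts + 0.5 * (win - 1)) / fs + cmap.times[0]
    return ActivityMap(
        values=rms,
        times=centres,
        body_coords=cmap.body_coords.copy(),
        window_s=window_s,
        stride_s=stride / fs,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


def wave_direction(
    cmap: CurvatureMap,
    region: tuple[float, float],
    window: tuple[float, float],
    ds: float = DIRECTION_DS,
    max_lag_s: float = 1.0,
) -> int:
    """Direction of wave propagation in a body region: +1, -1 or 0.

    Curvature traces at coordinate pairs (s, s + ds) are cross-correlated
    over the window; a positive magnitude-weighted median lag (posterior
    lags anterior) means anterior-to-posterior propagation (+1).  Returns 0
    for quiescent regions and for standing waves (|median lag| below the
    frame period).
    """
    s_lo, s_hi = region
    if s_hi - s_lo < 10.0:
        raise ValidationError("direction region must span >= 10 body coordinates")
    sl = cmap.window_slice(window)
    fs = cmap.sampling_rate
    coords = cmap.body_coords
    spacing = float(np.mean(np.diff(coords)))
    dj = max(1, int(round(ds / spacing)))
    sel = np.flatnonzero((coords >= s_lo) & (coords <= s_hi))
    anterior = sel[: max(0, len(sel) - dj)][::dj]
    if anterior.size == 0:
        raise ValidationError("direction region too narrow for the coordinate spacing")

    n = sl.stop - sl.start
    max_lag = min(n - 1, int(round(max_lag_s * fs)))
    lags_all = np.arange(-(n - 1), n)
    keep = np.abs(lags_all) <= max_lag

    lags, weights = [], []
    scale = float(np.sqrt(np.mean(cmap.values[sl] ** 2))) or 1.0
    for j in anterior:
        x = cmap.values[sl, j]
        y = cmap.values[sl, j + dj]
        x = x - x.mean()
        y = y - y.mean()
        wx, wy = np.sqrt(np.mean(x**2)), np.sqrt(np.mean(y**2))
        if wx < 1e-6 * scale or wy < 1e-6 * scale:
            continue
        c = np.correlate(y, x, mode="full")[keep]
        lag = lags_all[keep][int(np.argmax(np.abs(c)))]
        lags.append(lag / fs)
        weights.append(wx * wy)
    if not lags:
        return 0
    med = _weighted_median(np.array(lags), np.array(weights))
    if abs(med) < 0.5 / fs:
        return 0
    return 1 if med > 0 else -1


def detect_forward_bouts(
    cmap: CurvatureMap,
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
    min_duration_s: float = 3.0,
    region: tuple[float, float] = (10.0, 90.0),
    window_s: float = 0.5,
    stride_s: float = 0.125,
    direction_window_s: float = 2.0,
) -> list[Bout]:
    """Detect forward-locomotion bouts in a body region.

    Time cells whose regional mean activity exceeds ``activity_threshold``
    and whose wave direction is anterior-to-posterior are merged into
    maximal contiguous bouts; bouts shorter than ``min_duration_s``
    (typically 2-3 s) are discarded.
    """
    act = activity_level(cmap, window_s=window_s, stride_s=stride_s)
    coords = act.body_coords
    in_region = (coords >= region[0]) & (coords <= region[1])
    regional = act.values[:, in_region].mean(axis=1)

    t0, t1 = cmap.times[0], cmap.times[-1]
    passing = np.zeros(act.times.size, dtype=bool)
    for i, (c, a) in enumerate(zip(act.times, regional)):
        if a <= activity_threshold:
            continue
        w0 = max(t0, c - 0.5 * direction_window_s)
        w1 = min(t1, c + 0.5 * direction_window_s)
        passing[i] = wave_direction(cmap, region, (w0, w1)) == 1

    bouts: list[Bout] = []
    i = 0
    while i < passing.size:
        if not passing[i]:
            i += 1
            continue
        j = i
        while j + 1 < passing.size and passing[j + 1]:
            j += 1
        # bout boundaries are the first/last passing window centres
        start = max(t0, act.times[i])
        end = min(t1, act.times[j])
        if end - start >= min_duration_s:
            bouts.append(
                Bout(
                    t_start=float(start),
                    t_end=float(end),
                    s_lo=float(region[0]),
                    s_hi=float(region[1]),
                    direction="anterior_to_posterior",
                    mean_activity=float(regional[i : j + 1].mean()),
                )
            )
        i = j + 1
    return bouts


def _phase_coherence(
    cmap: CurvatureMap,
    coord_a: float,
    coord_b: float,
    window: tuple[float, float],
    f0: float,
    bandwidth: float = 0.2,
) -> float:
    """|mean phase-difference vector| between two traces band-passed at f0.

    Both curvature traces are restricted to f0 +/- bandwidth via FFT
    masking; the analytic-signal phase difference is averaged as a unit
    vector.  Coherence near 1 means the two coordinates oscillate with a
    fixed relative phase at f0 (tail waves arise from the head); phase
    drift pushes it toward 0.
    """
    sl = cmap.window_slice(window)
    fs = cmap.sampling_rate

    def analytic(trace):
        x = trace - trace.mean()
        n = x.size
        X = np.fft.fft(x)
        f = np.fft.fftfreq(n, 1.0 / fs)
        mask = (f >= max(f0 - bandwidth, 1e-9)) & (f <= f0 + bandwidth)
        return np.fft.ifft(np.where(mask, 2.0 * X, 0.0))

    za = analytic(cmap.values[sl, cmap.coord_index(coord_a)])
    zb = analytic(cmap.values[sl, cmap.coord_index(coord_b)])
    ok = (np.abs(za) > 1e-12) & (np.abs(zb) > 1e-12)
    if not np.any(ok):
        return 0.0
    dphi = np.angle(za[ok] * np.conj(zb[ok]))
    return float(np.abs(np.mean(np.exp(1j * dphi))))


def _refined_peak_freq(trace: np.ndarray, fs: float, band=(0.0, 2.5)) -> float:
    """Leakage-resistant peak frequency: Hann taper + quadratic interpolation.

    The quantised argmax of the rectangular-window spectrum is accurate to
    half a grid step at best, which is too coarse to count undulation cycles
    near a hard cycle-count criterion; tapering suppresses the
    negative-frequency image and the log-parabolic fit interpolates between
    grid points.
    """
    x = np.asarray(trace, dtype=float)
    x = x - x.mean()
    if not np.any(x):
        return 0.0
    w = np.hanning(x.size)
    nfft = max(4096, x.size)
    mag = np.abs(np.fft.rfft(x * w, nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    idx = np.flatnonzero((freqs > band[0]) & (freqs <= band[1]))
    k = idx[int(np.argmax(mag[idx]))]
    if 0 < k < mag.size - 1 and mag[k] > 0:
        a, b, c = (np.log(mag[k - 1] + 1e-300), np.log(mag[k] + 1e-300),
                   np.log(mag[k + 1] + 1e-300))
        denom = a - 2 * b + c
        shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
        return float((k + np.clip(shift, -0.5, 0.5)) * fs / nfft)
    return float(freqs[k])


#: Slack on the cycle-count criterion absorbing the residual bias of the
#: refined frequency estimate on short windows (~0.02 cycles over 3 s).
CYCLE_COUNT_TOL = 0.05


def score_2FU_event(
    cmap: CurvatureMap,
    stim: StimulusMask,
    threshold: float = DEFAULT_THRESHOLD,
    ratio_min: float = DEFAULT_RATIO_MIN,
    coherence_cutoff: float = DEFAULT_COHERENCE_CUTOFF,
    subwindow_s: float = 3.0,
    stride_s: float = 0.5,
    head_coord: float = HEAD_COORD,
    tail_coord: float = TAIL_COORD,
    min_tail_cycles: float = 2.0,
) -> TwoFUResult:
    """Score a stimulus window for a two-frequency-undulation event.

    Every ``subwindow_s`` sub-window of [stim.t_on, stim.t_off] is examined;
    an event requires (a) above-threshold tail frequency completing at least
    ``min_tail_cycles`` cycles within the sub-window (cycles counted from a
    taper-refined tail frequency, since the quantised spectral peak cannot
    resolve the cycle boundary on 3 s windows; the returned
    ``n_tail_cycles`` carries this refined count), and (b) tail waves not
    head-derived: ratio undefined, or |ratio - 1| > ratio_min - 1, or
    head-tail phase coherence at the tail frequency below
    ``coherence_cutoff``.  Sub-windows with posterior-to-anterior waves over
    the head region are excluded (reversal contamination).  The result of
    the best-scoring sub-window is returned with ``is_2FU`` set by the event
    criteria.
    """
    t_on = max(float(stim.t_on), float(cmap.times[0]))
    t_off = min(float(stim.t_off), float(cmap.times[-1]))
    if t_off - t_on < subwindow_s:
        raise ValidationError(
            f"stimulus window [{t_on}, {t_off}] s is shorter than the "
            f"{subwindow_s} s scoring sub-window"
        )
    starts = np.arange(t_on, t_off - subwindow_s + 1e-9, stride_s)
    best: TwoFUResult | None = None
    best_key = (-1, -math.inf)
    for s0 in starts:
        w = (float(s0), float(s0 + subwindow_s))
        if wave_direction(cmap, (5.0, 45.0), w) == -1:
            continue
        r = frequency_ratio(
            cmap, w, head_coord=head_coord, tail_coord=tail_coord,
            threshold=threshold, ratio_min=ratio_min,
        )
        coh = math.nan
        decoupled = not r.ratio_defined or abs(r.ratio - 1.0) > ratio_min - 1.0
        if r.f_tail > 0 and not decoupled:
            coh = _phase_coherence(cmap, head_coord, tail_coord, w, r.f_tail)
            decoupled = coh < coherence_cutoff
        if r.f_tail > 0:
            sl = cmap.window_slice(w)
            f_ref = _refined_peak_freq(
                time_derivative(cmap)[sl, cmap.coord_index(tail_coord)],
                cmap.sampling_rate,
            )
            n_cycles = f_ref * subwindow_s
        else:
            n_cycles = 0.0
        event = bool(
            r.f_tail > 0
            and n_cycles >= min_tail_cycles - CYCLE_COUNT_TOL
            and decoupled
        )
        r = replace(
            r,
            is_2FU=event,
            n_tail_cycles=n_cycles,
            coherence=None if math.isnan(coh) else coh,
        )
        key = (1 if event else 0, r.f_tail)
        if key > best_key:
            best, best_key = r, key
    if best is None:
        # every sub-window was reversal-contaminated
        return TwoFUResult(
            f_head=0.0, f_tail=0.0, ratio=math.nan, ratio_defined=False,
            n_tail_cycles=0.0, is_2FU=False, window=(t_on, t_off),
            head_coord=head_coord, tail_coord=tail_coord,
        )
    return best
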
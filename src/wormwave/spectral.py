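"""Frequency, amplitude and entrainment statistics on curvature kymograms.

All measurements operate on the time derivative of the dimensionless
curvature at a single body coordinate.  Undulation frequency is the location
of the largest magnitude-spectrum peak in the 0-2.5 Hz band, with the
spectrum zero padded onto a <= 0.05 Hz grid for peak localisation; if the
peak magnitude stays below a fixed threshold the trace is considered
quiescent and the frequency is reported as zero.  The same threshold is
meant to be used for every measurement of a run.  Bending amplitude is the
root mean square of d(kappa*L)/dt over the window (units 1/s), so a pure
sinusoid kappa*L = A0 sin(2*pi*f*t) has amplitude A0*2*pi*f/sqrt(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .kinematics import CurvatureMap, time_derivative

#: Peak-search band (Hz); undulations above 2.5 Hz are not considered.
FREQUENCY_BAND = (0.0, 2.5)
#: Maximum spectral grid spacing (Hz) after zero padding.
FREQUENCY_GRID_HZ = 0.05
#: Spectral-amplitude threshold below which a trace counts as quiescent.
#: Calibrated as the peak magnitude of a sinusoid whose rms bending
#: amplitude is 1.0 1/s (i.e. sinusoid amplitude sqrt(2)).
DEFAULT_THRESHOLD = math.sqrt(2.0)
#: Tail/head frequency ratio above which an event counts as two-frequency
#: undulation; exposed as a sensitivity parameter.
DEFAULT_RATIO_MIN = 1.3
#: Default measurement coordinates: head 15, tail 85 (presets 45/60/75 serve
#: mid-body and alternative tail measurements).
HEAD_COORD = 15.0
TAIL_COORD = 85.0
MIN_WINDOW_S = 1.0


@dataclass
class SpectralResult:
    """Peak-frequency measurement at one body coordinate and time window."""

    peak_frequency: float
    peak_magnitude: float
    frequencies: np.ndarray
    magnitudes: np.ndarray
    above_threshold: bool
    window: tuple
    body_coord: float


@dataclass
class TwoFUResult:
    """Head/tail frequency pair and their ratio.

    ``ratio`` is ``f_tail / f_head``; when the head is quiescent while the
    tail oscillates the ratio is infinite and flagged undefined
    (``ratio_defined = False``) so aggregate statistics can exclude it.
    ``is_2FU`` marks simultaneous undulation at distinct frequencies.
    """

    f_head: float
    f_tail: float
    ratio: float
    ratio_defined: bool
    n_tail_cycles: float
    is_2FU: bool
    window: tuple = (0.0, 0.0)
    head_coord: float = HEAD_COORD
    tail_coord: float = TAIL_COORD
    coherence: float | None = None


def _magnitude_spectrum(x: np.ndarray, fs: float, grid_hz: float = FREQUENCY_GRID_HZ):
    """Zero-padded magnitude spectrum normalised to sinusoid amplitude.

    A pure sinusoid A*sin(2*pi*f*t) yields a peak of magnitude ~A.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(fs / grid_hz)))
    nfft = max(nfft, x.size)
    mags = 2.0 * np.abs(np.fft.rfft(x, nfft)) / x.size
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    return freqs, mags


def bending_frequency(
    cmap: CurvatureMap,
    body_coord: float,
    window: tuple[float, float],
    threshold: float = DEFAULT_THRESHOLD,
    band: tuple[float, float] = FREQUENCY_BAND,
) -> SpectralResult:
    """Dominant undulation frequency at one body coordinate.

    The d(kappa*L)/dt trace over the window (>= 1 s) is mean-subtracted,
    zero padded onto a <= 0.05 Hz grid, and the largest magnitude peak in
    ``band`` (default 0-2.5 Hz, exclusive of 0) is reported.  A peak below
    ``threshold`` means no undulation: the frequency is returned as 0 and
    ``above_threshold`` is False.
    """
    sl = cmap.window_slice(window, min_length=MIN_WINDOW_S)
    dk = time_derivative(cmap)[sl, cmap.coord_index(body_coord)]
    freqs, mags = _magnitude_spectrum(dk, cmap.sampling_rate)
    in_band = (freqs > band[0]) & (freqs <= band[1])
    idx = np.flatnonzero(in_band)
    peak = idx[int(np.argmax(mags[idx]))]
    above = bool(mags[peak] >= threshold)
    return SpectralResult(
        peak_frequency=float(freqs[peak]) if above else 0.0,
        peak_magnitude=float(mags[peak]),
        frequencies=freqs,
        magnitudes=mags,
        above_threshold=above,
        window=(float(window[0]), float(window[1])),
        body_coord=float(body_coord),
    )


def bending_amplitude(
    cmap: CurvatureMap,
    body_coord: float,
    window: tuple[float, float],
) -> float:
    """Bending amplitude: rms of d(kappa*L)/dt over the window, in 1/s."""
    sl = cmap.window_slice(window, min_length=MIN_WINDOW_S)
    dk = time_derivative(cmap)[sl, cmap.coord_index(body_coord)]
    return float(np.sqrt(np.mean(dk**2)))


def frequency_ratio(
    cmap: CurvatureMap,
    window: tuple[float, float],
    head_coord: float = HEAD_COORD,
    tail_coord: float = TAIL_COORD,
    threshold: float = DEFAULT_THRESHOLD,
    ratio_min: float = DEFAULT_RATIO_MIN,
) -> TwoFUResult:
    """Tail/head frequency ratio (the two-frequency-undulation assay).

    A silent head with an oscillating tail yields an infinite, undefined
    ratio that aggregate statistics exclude.  ``is_2FU`` is true when the
    tail oscillates and the ratio is either undefined or exceeds
    ``ratio_min``.
    """
    head = bending_frequency(cmap, head_coord, window, threshold)
    tail = bending_frequency(cmap, tail_coord, window, threshold)
    fh, ft = head.peak_frequency, tail.peak_frequency
    if fh > 0:
        ratio, defined = ft / fh, True
    elif ft > 0:
        ratio, defined = math.inf, False
    else:
        ratio, defined = math.nan, False
    is_2fu = ft > 0 and (not defined or ratio > ratio_min)
    return TwoFUResult(
        f_head=fh,
        f_tail=ft,
        ratio=ratio,
        ratio_defined=defined,
        n_tail_cycles=ft * (window[1] - window[0]),
        is_2FU=is_2fu,
        window=(float(window[0]), float(window[1])),
        head_coord=float(head_coord),
        tail_coord=float(tail_coord),
    )


def ratio_summary(results: Sequence[TwoFUResult]) -> dict:
    """Aggregate ratio statistics, excluding undefined (infinite) ratios."""
    ratios = [r.ratio for r in results if r.ratio_defined]
    n_undef = sum(1 for r in results if not r.ratio_defined)
    return {
        "n_total": len(results),
        "n_undefined": n_undef,
        "mean_ratio": float(np.mean(ratios)) if ratios else math.nan,
        "n_2fu": sum(1 for r in results if r.is_2FU),
    }


@dataclass
class MeanSpectrum:
    """Trial-averaged magnitude spectrum at one body coordinate."""

    frequencies: np.ndarray
    magnitudes: np.ndarray
    n_trials: int
    body_coord: float
    window: tuple


def head_power_spectrum(
    maps: Sequence[CurvatureMap],
    window: tuple[float, float],
    body_coord: float = HEAD_COORD,
) -> MeanSpectrum:
    """Mean magnitude spectrum of d(kappa*L)/dt across trials.

    All maps must share a sampling rate so the zero-padded frequency grids
    coincide; spectra are averaged point-wise.
    """
    if len(maps) == 0:
        raise ValidationError("need at least one trial map")
    rates = {float(m.sampling_rate) for m in maps}
    if len(rates) != 1:
        raise ValidationError(f"inconsistent sampling rates across trials: {sorted(rates)}")
    acc = None
    freqs = None
    for m in maps:
        r = bending_frequency(m, body_coord, window, threshold=0.0)
        if freqs is None:
            freqs, acc = r.frequencies, r.magnitudes.copy()
        else:
            if r.frequencies.shape != freqs.shape:
                raise ValidationError("trial spectra fall on different frequency grids")
            acc += r.magnitudes
    return MeanSpectrum(
        frequencies=freqs,
        magnitudes=acc / len(maps),
        n_trials=len(maps),
        body_coord=float(body_coord),
        window=(float(window[0]), float(window[1])),
    )


@dataclass
class EntrainmentMap:
    """Imposed-frequency x response-frequency spectral heat map."""

    imposed_freqs: np.ndarray
    response_freqs: np.ndarray
    power: np.ndarray  # (n_imposed, n_response)

    def ridge(self, band: tuple[float, float] = FREQUENCY_BAND) -> np.ndarray:
        """Response frequency of the strongest peak per imposed frequency."""
        in_band = (self.response_freqs > band[0]) & (self.response_freqs <= band[1])
        idx = np.flatnonzero(in_band)
        return self.response_freqs[idx[np.argmax(self.power[:, idx], axis=1)]]


def entrainment_map(
    spectra: Mapping[float, MeanSpectrum],
    imposed_step: float = 0.05,
) -> EntrainmentMap:
    """Stack mean spectra over imposed frequencies into an entrainment map.

    Rows are linearly interpolated along the imposed-frequency axis at
    ``imposed_step`` spacing (mirroring how swept-frequency heat maps are
    displayed); ridge extraction per imposed frequency exposes the locking
    structure (response = f_p on the 1:1 tongue, f_p/2 on the 2:1 tongue).
    """
    if len(spectra) < 2:
        raise ValidationError("need spectra for at least 2 imposed frequencies")
    fps = np.array(sorted(spectra))
    first = spectra[fps[0]]
    grid = first.frequencies
    rows = np.empty((fps.size, grid.size))
    for i, fp in enumerate(fps):
        s = spectra[fp]
        if s.frequencies.shape != grid.shape or not np.allclose(s.frequencies, grid):
            raise ValidationError("response-frequency grids differ between spectra")
        rows[i] = s.magnitudes
    dense = np.arange(fps[0], fps[-1] + 0.5 * imposed_step, imposed_step)
    dense = np.clip(dense, fps[0], fps[-1])
    power = np.empty((dense.size, grid.size))
    for j in range(grid.size):
        power[:, j] = np.interp(dense, fps, rows[:, j])
    return EntrainmentMap(imposed_freqs=dense, response_freqs=grid, power=power)
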
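"""Spectral statistics: peak frequency, amplitude, ratios, entrainment maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormwave import (
    ValidationError,
    bending_amplitude,
    bending_frequency,
    entrainment_map,
    frequency_ratio,
    head_power_spectrum,
    ratio_summary,
)
from wormwave.spectral import MeanSpectrum
from tests.conftest import make_two_band_map, make_wave_map


class TestBendingFrequency:
    @pytest.mark.parametrize("freq", np.round(np.arange(0.3, 2.45, 0.3), 2))
    def test_unbiased_on_pure_sinusoids(self, freq):
        cmap = make_wave_map(freq_hz=freq, duration=3.0)
        r = bending_frequency(cmap, 45.0, (0.0, 3.0))
        assert r.above_threshold
        assert r.peak_frequency == pytest.approx(freq, abs=0.1)

    def test_every_coordinate_sees_the_forced_frequency(self, wave_map):
        for coord in (0, 15, 45, 85, 100):
            r = bending_frequency(wave_map, coord, (0.0, 3.0))
            assert r.peak_frequency == pytest.approx(1.0, abs=0.1)

    def test_zero_map_reports_zero_and_below_threshold(self):
        cmap = make_wave_map(amplitude=0.0, duration=3.0)
        r = bending_frequency(cmap, 45.0, (0.0, 3.0))
        assert r.peak_frequency == 0.0
        assert not r.above_threshold

    def test_two_band_map_resolves_head_and_tail_frequencies(self, two_band_map):
        head = bending_frequency(two_band_map, 15.0, (0.0, 3.0))
        tail = bending_frequency(two_band_map, 85.0, (0.0, 3.0))
        assert head.peak_frequency == pytest.approx(0.7, abs=0.1)
        assert tail.peak_frequency == pytest.approx(1.6, abs=0.1)

    def test_window_validation(self, wave_map):
        with pytest.raises(ValidationError):
            bending_frequency(wave_map, 45.0, (0.0, 0.5))  # too short
        with pytest.raises(ValidationError):
            bending_frequency(wave_map, 45.0, (4.0, 9.0))  # outside map

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(thr_lo=st.floats(0.1, 5.0), thr_delta=st.floats(0.0, 50.0))
    def test_threshold_monotonicity(self, thr_lo, thr_delta):
        """Raising the threshold never converts a zero frequency to nonzero."""
        cmap = make_wave_map(amplitude=0.3, duration=3.0)
        lo = bending_frequency(cmap, 45.0, (0.0, 3.0), threshold=thr_lo)
        hi = bending_frequency(cmap, 45.0, (0.0, 3.0), threshold=thr_lo + thr_delta)
        if lo.peak_frequency == 0.0:
            assert hi.peak_frequency == 0.0


class TestBendingAmplitude:
    def test_sinusoid_closed_form(self):
        # rms of d/dt of A0 sin(2 pi f t) = A0 * 2 pi f / sqrt(2) ~ 22.2 1/s
        cmap = make_wave_map(freq_hz=1.0, amplitude=5.0, duration=4.0)
        amp = bending_amplitude(cmap, 45.0, (0.0, 4.0))
        assert amp == pytest.approx(5.0 * 2 * np.pi / np.sqrt(2), rel=0.02)

    def test_constant_map_has_zero_amplitude(self):
        cmap = make_wave_map(amplitude=0.0, duration=3.0)
        cmap.values += 2.0
        assert bending_amplitude(cmap, 45.0, (0.0, 3.0)) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("a0,freq", [(10.0, 1.0), (5.0, 2.0)])
    def test_amplitude_scales_with_a0_times_f(self, a0, freq):
        """Doubling A0 or doubling f doubles the amplitude statistic."""
        cmap = make_wave_map(freq_hz=freq, amplitude=a0, duration=4.0)
        doubled = bending_amplitude(cmap, 45.0, (0.0, 4.0))
        assert doubled == pytest.approx(2 * 5.0 * 2 * np.pi / np.sqrt(2), rel=0.03)


class TestFrequencyRatio:
    def test_two_band_ratio(self, two_band_map):
        r = frequency_ratio(two_band_map, (0.0, 3.0))
        assert r.ratio == pytest.approx(1.6 / 0.7, abs=0.15)
        assert r.ratio_defined
        assert r.is_2FU

    def test_uniform_wave_ratio_is_one_and_not_2fu(self, wave_map):
        r = frequency_ratio(wave_map, (0.0, 3.0))
        assert r.ratio == pytest.approx(1.0, abs=0.1)
        assert not r.is_2FU

    def test_silent_head_gives_undefined_infinite_ratio(self):
        cmap = make_two_band_map(f_head=1.5, f_tail=1.5)
        cmap.values[:, cmap.body_coords < 50] = 0.0
        r = frequency_ratio(cmap, (0.0, 3.0))
        assert r.f_head == 0.0 and r.f_tail > 0
        assert math.isinf(r.ratio) and not r.ratio_defined
        assert r.is_2FU  # tail oscillates without any head wave

    def test_ratio_summary_excludes_only_flagged_entries(self, two_band_map):
        defined = frequency_ratio(two_band_map, (0.0, 3.0))
        silent = make_two_band_map(f_head=1.5, f_tail=1.5)
        silent.values[:, silent.body_coords < 50] = 0.0
        undefined = frequency_ratio(silent, (0.0, 3.0))
        both = ratio_summary([defined, undefined])
        only = ratio_summary([defined])
        assert both["n_undefined"] == 1
        assert both["mean_ratio"] == only["mean_ratio"]


class TestHeadPowerSpectrum:
    def test_single_trial_peak(self, wave_map):
        spec = head_power_spectrum([wave_map], (0.0, 3.0))
        band = (spec.frequencies > 0) & (spec.frequencies <= 2.5)
        idx = np.flatnonzero(band)
        peak = spec.frequencies[idx[np.argmax(spec.magnitudes[idx])]]
        assert peak == pytest.approx(1.0, abs=0.05)

    def test_two_trials_average_to_two_equal_peaks(self):
        # equal d(kappa)/dt amplitude requires A0 * f matched across trials
        m1 = make_wave_map(freq_hz=0.8, amplitude=5.0, duration=10.0)
        m2 = make_wave_map(freq_hz=1.2, amplitude=5.0 * 0.8 / 1.2, duration=10.0)
        spec = head_power_spectrum([m1, m2], (0.0, 10.0))
        f, mag = spec.frequencies, spec.magnitudes

        def peak_near(f0):
            sel = np.abs(f - f0) < 0.1
            return mag[sel].max()

        assert peak_near(0.8) == pytest.approx(peak_near(1.2), rel=0.05)

    def test_zero_trials_and_mixed_rates_error(self, wave_map):
        with pytest.raises(ValidationError):
            head_power_spectrum([], (0.0, 3.0))
        other = make_wave_map(fs=50.0)
        with pytest.raises(ValidationError, match="sampling rates"):
            head_power_spectrum([wave_map, other], (0.0, 3.0))


def _delta_spectrum(peak_hz, grid=None):
    f = np.arange(0.0, 2.5, 0.05) if grid is None else grid
    mag = np.exp(-(((f - peak_hz) / 0.05) ** 2))
    return MeanSpectrum(
        frequencies=f, magnitudes=mag, n_trials=1, body_coord=15.0, window=(0, 3)
    )


class TestEntrainmentMap:
    def test_duplicated_spectrum_interpolates_to_identity(self):
        s = _delta_spectrum(1.0)
        emap = entrainment_map({1.0: s, 1.2: s})
        assert np.allclose(emap.power, s.magnitudes[None, :])

    def test_ridge_follows_the_peaks(self):
        spectra = {fp: _delta_spectrum(fp / 2) for fp in (1.4, 1.7, 2.0)}
        emap = entrainment_map(spectra)
        ridge = emap.ridge()
        # at the swept frequencies the ridge sits exactly on response = fp/2
        for fp in (1.4, 1.7, 2.0):
            i = int(np.argmin(np.abs(emap.imposed_freqs - fp)))
            assert ridge[i] == pytest.approx(fp / 2, abs=0.05)
        # between sweep points the linearly interpolated rows peak at one of
        # the neighbouring response frequencies, so the ridge is monotone
        assert np.all(np.diff(ridge) >= -1e-9)
        assert set(np.round(ridge, 3)) <= {0.7, 0.85, 1.0}

    def test_requires_two_frequencies_and_matching_grids(self):
        with pytest.raises(ValidationError):
            entrainment_map({1.0: _delta_spectrum(1.0)})
        other = _delta_spectrum(1.0, grid=np.arange(0.0, 2.5, 0.1))
        with pytest.raises(ValidationError, match="grids"):
            entrainment_map({1.0: _delta_spectrum(1.0), 1.5: other})
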
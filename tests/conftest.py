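"""Shared fixtures: analytic kymograms and small simulator runs."""

import numpy as np
import pytest

from wormwave import CurvatureMap, SimConfig


def make_wave_map(
    freq_hz=1.0,
    amplitude=5.0,
    waves_per_bl=1.5,
    duration=5.0,
    fs=40.0,
    direction=-1.0,
    phase=0.0,
):
    """Analytic travelling-wave kymogram.

    ``direction=-1`` (spatial phase subtracted) propagates anterior to
    posterior; ``+1`` posterior to anterior.
    """
    s = np.linspace(0.0, 100.0, 100)
    t = np.arange(int(round(duration * fs)) + 1) / fs
    values = amplitude * np.sin(
        2 * np.pi * freq_hz * t[:, None]
        + direction * 2 * np.pi * waves_per_bl * s[None, :] / 100.0
        + phase
    )
    return CurvatureMap(
        values=values,
        times=t,
        body_coords=s,
        sampling_rate=fs,
        worm_length=1.0,
    )


def make_two_band_map(
    f_head=0.7, f_tail=1.6, amplitude=5.0, duration=6.0, fs=40.0, split=50.0
):
    """Kymogram whose anterior and posterior halves oscillate at different
    frequencies (the signature of two-frequency undulation)."""
    s = np.linspace(0.0, 100.0, 100)
    t = np.arange(int(round(duration * fs)) + 1) / fs
    f_of_s = np.where(s < split, f_head, f_tail)
    values = amplitude * np.sin(2 * np.pi * f_of_s[None, :] * t[:, None])
    return CurvatureMap(
        values=values, times=t, body_coords=s, sampling_rate=fs, worm_length=1.0
    )


@pytest.fixture(scope="session")
def wave_map():
    return make_wave_map()


@pytest.fixture(scope="session")
def two_band_map():
    return make_two_band_map()


@pytest.fixture(scope="session")
def default_sim_map():
    """One noiseless default (autonomous) simulator trial."""
    from wormwave import simulate

    return simulate(SimConfig(duration=12.0, noise_sigma=0.0))
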
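"""Synthetic locomotion: a chain of coupled phase-amplitude oscillators.

Each of the ``n_units`` circuit units carries a phase ``theta_i`` and a
bending amplitude ``a_i`` and is responsible for an equal span of the body
coordinate axis.  The dynamics per unit are

    dtheta_i/dt = 2*pi*(f_i - slow*A_i)
                  + g_p * G(a_{i-1}) * sin(theta_{i-1} - theta_i - Delta)
                  + g_a * (e1*sin(theta_i) + e2*sin(2*theta_i)) * Dtilde_i(t)
                  + sqrt(2*sigma^2) * xi(t)

    da_i/dt     = r * (a_target_i(t) - a_i)

where ``G(a) = clip(a/a0, 0, 1)`` gates posteriorward proprioceptive input on
the anterior neighbour's bending amplitude, ``Delta`` is the inter-unit phase
lag implied by the undulation wavelength, ``D_i(t) = max_{j>i} (1 - a_j/a0)``
is the largest amplitude deficit anywhere posterior to unit i (the
anteriorward pathway is neural and long-range: rhythmic inhibition of the
tail alone entrains the head), ``A_i`` is a slow moving average of ``D_i``
(time constant ``prc_adapt_tau``) and ``Dtilde_i = D_i - A_i`` is the
adapted phase-response drive, so that only *changes* in posterior inhibition
reset the phase, while a sustained deficit instead slows the unit through
the ``deficit_slowing`` gain.  Amplitude targets are 0 wherever a stimulus mask
covers the unit's body span and ``a0`` otherwise; in relay mode the target of
units i > 0 is additionally gated by the anterior amplitude, so paralysing
any region silences everything posterior to it.

The field is rendered as
``kappa(s, t) = a_i(s)(t) * sin(theta_i(s)(t) - 2*pi*w*(s - s_i)/100)``
with ``w`` waves per body length and ``s_i`` the start of the owning unit's
span; at phase lock the pieces join continuously into ~w travelling waves
per body length, anterior to posterior.

Integration is fixed-step Euler-Maruyama at ``oversample`` substeps per
output frame, decimated to the output sampling rate.  Identical configs
(including the seed) give bitwise-identical kymograms.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .config import SimConfig
from .errors import UnstableIntegrationError, ValidationError
from .kinematics import CenterlineSeries, CurvatureMap, N_BODY_COORDS


def _check_stability(cfg: SimConfig) -> float:
    dt = 1.0 / (cfg.sampling_rate * cfg.oversample)
    e1, e2 = cfg.prc_coeffs
    fastest = (
        cfg.coupling_post
        + cfg.coupling_ant * (abs(e1) + 2.0 * abs(e2))
        + cfg.relax_rate
        + 1.0 / cfg.prc_adapt_tau
        + 2.0 * np.pi * max(cfg.intrinsic_freqs)
    )
    if fastest * dt > 0.5:
        raise UnstableIntegrationError(
            f"integration step {dt:.4g} s cannot resolve dynamics with rate "
            f"{fastest:.3g} 1/s; raise oversample (currently {cfg.oversample}) "
            f"or sampling_rate"
        )
    return dt


def _integrate(cfg: SimConfig, seeds: Sequence[int]):
    """Integrate the chain for several seeds at once.

    Returns (times, theta, amp) with theta/amp of shape
    (n_frames, n_trials, n_units).
    """
    dt = _check_stability(cfg)
    n = cfg.n_units
    B = len(seeds)
    n_frames = int(round(cfg.duration * cfg.sampling_rate)) + 1
    n_sub = cfg.oversample
    n_steps = (n_frames - 1) * n_sub

    f = np.asarray(cfg.intrinsic_freqs, dtype=float)
    a0 = cfg.base_amplitude
    e1, e2 = cfg.prc_coeffs
    delta = cfg.inter_unit_lag
    relay = cfg.mode == "relay"

    theta = np.empty((B, n))
    noise = np.empty((n_steps, B, n))
    sigma_step = np.sqrt(2.0 * cfg.noise_sigma**2 * dt)
    for b, sd in enumerate(seeds):
        rng = np.random.default_rng(int(sd))
        theta[b] = rng.uniform(0.0, 2.0 * np.pi) - np.arange(n) * delta
        noise[:, b, :] = sigma_step * rng.standard_normal((n_steps, n))

    # Stimulus activity per substep, shared across trials.
    t_sub = np.arange(n_steps) * dt
    masked = cfg.masked_units(t_sub).astype(float)  # (n_steps, n)

    # start amplitudes at their masked targets to avoid onset transients
    amp = np.tile(a0 * (1.0 - masked[0]), (B, 1))
    adapt = np.zeros((B, n))

    th_out = np.empty((n_frames, B, n))
    a_out = np.empty((n_frames, B, n))
    th_out[0] = theta
    a_out[0] = amp

    two_pi = 2.0 * np.pi
    for k in range(n_steps):
        m = masked[k]
        target = a0 * (1.0 - m)[None, :] * np.ones((B, 1))
        if relay:
            gate = np.clip(amp[:, :-1] / a0, 0.0, 1.0)
            target = target.copy()
            target[:, 1:] *= gate

        deficit = np.clip(1.0 - amp / a0, 0.0, 1.0)
        # D_i = max deficit over strictly posterior units.
        post = np.zeros_like(deficit)
        post[:, :-1] = np.flip(
            np.maximum.accumulate(np.flip(deficit[:, 1:], axis=1), axis=1), axis=1
        )
        drive = post - adapt

        sin_th = np.sin(theta)
        prop = np.zeros_like(theta)
        prop[:, 1:] = (
            cfg.coupling_post
            * np.clip(amp[:, :-1] / a0, 0.0, 1.0)
            * np.sin(theta[:, :-1] - theta[:, 1:] - delta)
        )
        dtheta = (
            two_pi * (f[None, :] - cfg.deficit_slowing * adapt)
            + prop
            + cfg.coupling_ant * (e1 * sin_th + e2 * np.sin(2.0 * theta)) * drive
        )
        theta = theta + dt * dtheta + noise[k]
        amp = amp + dt * cfg.relax_rate * (target - amp)
        adapt = adapt + dt * (post - adapt) / cfg.prc_adapt_tau

        if (k + 1) % n_sub == 0:
            j = (k + 1) // n_sub
            th_out[j] = theta
            a_out[j] = amp

    times = np.arange(n_frames) / cfg.sampling_rate
    return times, th_out, a_out


def _render_map(cfg: SimConfig, times, theta, amp, seed: int) -> CurvatureMap:
    s = np.linspace(0.0, 100.0, N_BODY_COORDS)
    span = 100.0 / cfg.n_units
    unit = np.minimum((s / span).astype(int), cfg.n_units - 1)
    s_local = s - unit * span
    phase_off = 2.0 * np.pi * cfg.waves_per_bl * s_local / 100.0
    values = amp[:, unit] * np.sin(theta[:, unit] - phase_off[None, :])
    meta = {
        "source": "model_sim",
        "mode": cfg.mode,
        "seed": int(seed),
        "config_hash": cfg.config_hash(),
        "masks": [m.to_dict() for m in cfg.masks],
    }
    return CurvatureMap(
        values=values,
        times=times,
        body_coords=s,
        sampling_rate=cfg.sampling_rate,
        worm_length=cfg.worm_length_mm,
        meta=meta,
    )


def simulate(config: SimConfig) -> CurvatureMap:
    """Simulate one trial and return its curvature kymogram.

    The run is fully determined by ``config`` (including ``config.seed``).
    An uninhibited chain produces ~``waves_per_bl`` undulation waves per body
    length travelling anterior to posterior at the locked frequency.
    """
    times, th, am = _integrate(config, [config.seed])
    return _render_map(config, times, th[:, 0, :], am[:, 0, :], config.seed)


def simulate_batch(config: SimConfig, seeds: Sequence[int]) -> list[CurvatureMap]:
    """Simulate one trial per seed (vectorised over trials)."""
    if len(seeds) == 0:
        raise ValidationError("seeds must be non-empty")
    times, th, am = _integrate(config, list(seeds))
    return [
        _render_map(config, times, th[:, b, :], am[:, b, :], sd)
        for b, sd in enumerate(seeds)
    ]


def render_centerline(
    cmap: CurvatureMap,
    worm_length: float | None = None,
    n_points: int = 400,
) -> CenterlineSeries:
    """Reconstruct centerline point chains from a curvature kymogram.

    Per frame the tangent angle is the arc-length integral of curvature,
    psi(s) = int_0^s kappa ds' (taken exactly on the interpolating spline of
    the stored profile), and positions follow by integrating
    (cos psi, sin psi).  Every frame starts at the origin pointing along +x;
    rigid-body pose is not represented in a curvature map.  Arc length equals
    ``worm_length`` by construction (points are arc-length-uniform), and the
    round trip through :func:`~wormwave.kinematics.compute_curvature_map`
    recovers the input to < 1e-3 for smooth maps.
    """
    if worm_length is None:
        worm_length = cmap.worm_length
    if worm_length <= 0:
        raise ValidationError("worm_length must be > 0")
    if not np.all(np.isfinite(cmap.values)):
        raise ValidationError("curvature map contains non-finite values")

    s_norm = cmap.body_coords / 100.0  # fraction of body length
    s_mm = s_norm * worm_length
    dense = np.linspace(0.0, worm_length, max(2001, 5 * n_points + 1))
    targets = np.linspace(0.0, worm_length, n_points)

    frames = []
    for row in cmap.values:
        kappa = row / worm_length  # 1/mm
        spline = CubicSpline(s_mm, kappa)
        psi = spline.antiderivative()(dense)
        cx = np.cos(psi)
        sy = np.sin(psi)
        h = np.diff(dense)
        x = np.concatenate([[0.0], np.cumsum(0.5 * (cx[1:] + cx[:-1]) * h)])
        y = np.concatenate([[0.0], np.cumsum(0.5 * (sy[1:] + sy[:-1]) * h)])
        pts = np.column_stack(
            [CubicSpline(dense, x)(targets), CubicSpline(dense, y)(targets)]
        )
        frames.append(pts)
    return CenterlineSeries(
        frames=frames, sampling_rate=cmap.sampling_rate, times=cmap.times.copy()
    )
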
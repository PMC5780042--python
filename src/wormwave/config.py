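"""Simulator configuration and spatiotemporal stimulus masks.

The simulator represents the forward locomotor circuit as a head-to-tail
chain of ``n_units`` phase-amplitude oscillator units, each responsible for
an equal span of the 0-100 body coordinate axis.  Two circuit modes are
supported:

``relay``
    A single rhythm generator in the head; every more posterior unit merely
    copies the bending phase of its anterior neighbour through gated
    proprioceptive coupling.  Paralysing any region therefore silences
    everything posterior to it.

``autonomous``
    Every unit carries intrinsic rhythmogenic capability, with natural
    frequencies increasing from head to tail.  Posterior units free-run when
    proprioceptive input is interrupted, and an anteriorward (neurally
    mediated) pathway lets posterior inhibition entrain the head.

``StimulusMask`` describes targeted-illumination style inhibition: a body
coordinate band, a time window, and an optional pulse train.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .errors import ValidationError

DEFAULT_SAMPLING_RATE = 40.0  # Hz; camera/targeting loop rate of the tracker emulated here

#: Default intrinsic frequency profile endpoints (Hz).  Isolated posterior
#: circuit sections run faster than anterior ones, so the chain default rises
#: linearly head to tail.
DEFAULT_FREQ_HEAD = 0.7
DEFAULT_FREQ_TAIL = 1.4


@dataclass(frozen=True)
class StimulusMask:
    """Spatiotemporal inhibition of a body-coordinate band.

    Parameters
    ----------
    s_lo, s_hi:
        Body coordinates bounding the illuminated band, in [0, 100].
    t_on, t_off:
        Start and end of the stimulus window in seconds.
    pulse_freq:
        Pulse-train frequency in Hz. ``0`` means the light is on
        continuously for the whole window.
    duty:
        Fraction of each pulse period during which the stimulus is active
        (only meaningful when ``pulse_freq > 0``).
    """

    s_lo: float
    s_hi: float
    t_on: float
    t_off: float
    pulse_freq: float = 0.0
    duty: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.s_lo < self.s_hi <= 100.0):
            raise ValidationError(
                f"mask body range must satisfy 0 <= s_lo < s_hi <= 100, got "
                f"[{self.s_lo}, {self.s_hi}]"
            )
        if not self.t_on < self.t_off:
            raise ValidationError(
                f"mask time window must satisfy t_on < t_off, got [{self.t_on}, {self.t_off}]"
            )
        if self.pulse_freq < 0:
            raise ValidationError(f"pulse_freq must be >= 0, got {self.pulse_freq}")
        if self.pulse_freq > 0 and not (0.0 < self.duty <= 1.0):
            raise ValidationError(f"duty must be in (0, 1] for pulsed masks, got {self.duty}")

    def active(self, t):
        """Boolean activity of the stimulus at time(s) ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        inside = (t >= self.t_on) & (t < self.t_off)
        if self.pulse_freq <= 0:
            return inside
        period = 1.0 / self.pulse_freq
        phase = np.mod(t - self.t_on, period)
        return inside & (phase < self.duty * period)

    def covers(self, span_lo: float, span_hi: float) -> bool:
        """Whether the mask band overlaps the open body-coordinate span."""
        return (self.s_lo < span_hi) and (self.s_hi > span_lo)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusMask":
        allowed = {"s_lo", "s_hi", "t_on", "t_off", "pulse_freq", "duty"}
        unknown = set(d) - allowed
        if unknown:
            raise ValidationError(f"unknown mask fields: {sorted(unknown)}")
        missing = {"s_lo", "s_hi", "t_on", "t_off"} - set(d)
        if missing:
            raise ValidationError(f"mask missing required fields: {sorted(missing)}")
        return cls(**d)


def _default_freqs(n_units: int, mode: str) -> tuple:
    if mode == "relay":
        f = np.zeros(n_units)
        f[0] = 1.0
    else:
        f = np.linspace(DEFAULT_FREQ_HEAD, DEFAULT_FREQ_TAIL, n_units)
    return tuple(float(x) for x in f)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the oscillator-chain simulator.

    Gains were frozen after mapping the 1:1 and 2:1 entrainment tongues of
    the chain numerically (see the methods note); they are exposed so either
    anteriorward-coupling hypothesis (phase resetting vs. loss of posterior
    excitation) can be explored.
    """

    n_units: int = 6
    #: Per-unit natural frequencies in Hz.  ``None`` selects the mode default:
    #: a linear 0.7 -> 1.4 Hz head-to-tail ramp (autonomous) or a single
    #: 1.0 Hz head oscillator (relay).
    intrinsic_freqs: tuple | None = None
    #: Spatial frequency of the rendered wave, in undulation waves per body
    #: length (a swimming worm shows ~1.5).
    waves_per_bl: float = 1.5
    #: Dimensionless curvature amplitude (kappa * L) of an uninhibited unit.
    base_amplitude: float = 5.0
    #: Posteriorward proprioceptive coupling gain, 1/s.
    coupling_post: float = 10.0
    #: Anteriorward phase-response coupling gain, 1/s.
    coupling_ant: float = 16.0
    #: (e1, e2) weights of the sin(theta) and sin(2*theta) terms of the
    #: anteriorward phase-response curve.  The sin(2*theta) term encodes the
    #: two curvature zero crossings per undulation cycle and produces 2:1
    #: entrainment.
    prc_coeffs: tuple = (1.2, 1.0)
    #: Adaptation time constant (s) of the anteriorward drive: phase resetting
    #: responds to *changes* in posterior inhibition, so a sustained deficit
    #: stops resetting the head after ~1 s.
    prc_adapt_tau: float = 1.0
    #: Head-slowing gain (Hz per unit of sustained posterior amplitude
    #: deficit); models loss of posterior excitation during 2FU.
    deficit_slowing: float = 0.1
    #: Phase diffusion sigma, rad/sqrt(s).
    noise_sigma: float = 0.1
    mode: str = "autonomous"
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    duration: float = 30.0
    seed: int = 0
    masks: tuple = ()
    #: Amplitude relaxation rate, 1/s: how fast local bending amplitude tracks
    #: its target (zero under inhibition, base_amplitude otherwise).
    relax_rate: float = 8.0
    #: Integration substeps per output frame (fixed-step Euler-Maruyama).
    oversample: int = 10
    #: Worm length in millimetres, used when rendering centerlines.
    worm_length_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("relay", "autonomous"):
            raise ValidationError(f"mode must be 'relay' or 'autonomous', got {self.mode!r}")
        if self.n_units < 2:
            raise ValidationError(f"n_units must be >= 2, got {self.n_units}")
        if self.intrinsic_freqs is None:
            object.__setattr__(
                self, "intrinsic_freqs", _default_freqs(self.n_units, self.mode)
            )
        freqs = tuple(float(f) for f in self.intrinsic_freqs)
        object.__setattr__(self, "intrinsic_freqs", freqs)
        if len(freqs) != self.n_units:
            raise ValidationError(
                f"intrinsic_freqs has {len(freqs)} entries for {self.n_units} units"
            )
        if any(f < 0 for f in freqs):
            raise ValidationError("intrinsic frequencies must be >= 0")
        if self.mode == "relay":
            if freqs[0] <= 0 or any(f != 0 for f in freqs[1:]):
                raise ValidationError(
                    "relay mode requires intrinsic drive on unit 0 only "
                    "(f_0 > 0, f_i = 0 for i > 0)"
                )
        if self.waves_per_bl <= 0:
            raise ValidationError(f"waves_per_bl must be > 0, got {self.waves_per_bl}")
        if self.base_amplitude <= 0:
            raise ValidationError("base_amplitude must be > 0")
        if self.sampling_rate <= 2.0 * max(freqs):
            raise ValidationError(
                f"sampling_rate ({self.sampling_rate} Hz) must exceed twice the "
                f"fastest intrinsic frequency ({max(freqs)} Hz)"
            )
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        if self.oversample < 1:
            raise ValidationError("oversample must be >= 1")
        if self.relax_rate <= 0 or self.prc_adapt_tau <= 0:
            raise ValidationError("relax_rate and prc_adapt_tau must be > 0")
        if len(self.prc_coeffs) != 2:
            raise ValidationError("prc_coeffs must be a pair (e1, e2)")
        masks = tuple(
            m if isinstance(m, StimulusMask) else StimulusMask.from_dict(dict(m))
            for m in self.masks
        )
        object.__setattr__(self, "masks", masks)
        for m in masks:
            if m.t_on < 0 or m.t_off > self.duration:
                raise ValidationError(
                    f"mask window [{m.t_on}, {m.t_off}] s lies outside the "
                    f"simulation duration [0, {self.duration}] s"
                )

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def autonomous(cls, **kw) -> "SimConfig":
        """Multi-oscillator chain (distributed rhythm generators)."""
        return cls(mode="autonomous", **kw)

    @classmethod
    def relay(cls, **kw) -> "SimConfig":
        """Single head oscillator with reflex-like wave propagation."""
        kw.setdefault("coupling_ant", 0.0)
        kw.setdefault("deficit_slowing", 0.0)
        return cls(mode="relay", **kw)

    def with_masks(self, *masks: StimulusMask) -> "SimConfig":
        return replace(self, masks=tuple(masks))

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))

    # -- (de)serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["masks"] = [m.to_dict() for m in self.masks]
        d["intrinsic_freqs"] = list(self.intrinsic_freqs)
        d["prc_coeffs"] = list(self.prc_coeffs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "masks" in d and d["masks"] is not None:
            d["masks"] = tuple(StimulusMask.from_dict(dict(m)) for m in d["masks"])
        if d.get("intrinsic_freqs") is not None:
            d["intrinsic_freqs"] = tuple(d["intrinsic_freqs"])
        if d.get("prc_coeffs") is not None:
            d["prc_coeffs"] = tuple(d["prc_coeffs"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown simulator config fields: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    # -- derived geometry ---------------------------------------------------------

    @property
    def unit_edges(self) -> np.ndarray:
        """Body-coordinate boundaries of the oscillator units."""
        return np.linspace(0.0, 100.0, self.n_units + 1)

    @property
    def inter_unit_lag(self) -> float:
        """Phase lag (rad) between adjacent units implied by the wavelength."""
        return 2.0 * np.pi * self.waves_per_bl / self.n_units

    def masked_units(self, t) -> np.ndarray:
        """Per-unit stimulus activity at time(s) t: shape (len(t), n_units)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        edges = self.unit_edges
        out = np.zeros((t.size, self.n_units), dtype=bool)
        for m in self.masks:
            act = m.active(t)
            for i in range(self.n_units):
                if m.covers(edges[i], edges[i + 1]):
                    out[:, i] |= act
        return out
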
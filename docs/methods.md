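# Methods

## Curvature representation

A worm posture is an ordered head-to-tail chain of K ≥ 5 planar points
(mm). Arc length along the chain, normalised to [0, 100], is the body
coordinate s. Each frame is resampled to exactly 100 arc-length-uniform
samples through a cubic spline of the chain (interpolating by default; a
dimensionless `smoothing` weight switches to a FITPACK smoothing spline for
noisy tracker output). Curvature is computed as the arc-length derivative of
the unwrapped tangent angle ψ(s) rather than from the parametric formula —
the tangent-angle route is well conditioned near straight postures, where
x′y″ − y′x″ is a difference of small numbers. The stored quantity is the
dimensionless κ·L (L = median arc length of the series), so its time
derivative carries units s⁻¹ and the amplitude statistic needs no extra
length factor; raw κ is recoverable via the `worm_length` attribute.

Numerical behaviour, fixed by tests: a noiseless circle's curvature is
recovered to < 1 % away from the chain ends; the outermost two coordinates
on each end are spline extrapolations of ψ′ and are noted in the map's
`meta`. Frames whose arc length deviates > 10 % from the series median are
flagged (mis-segmentation), never silently dropped. The inverse operation
(`render_centerline`) integrates ψ(s) = ∫κ ds exactly on the interpolating
spline and the positions by dense trapezoidal quadrature; points are
arc-length-uniform by construction, so arc length is conserved to < 0.1 %
and the map → centerline → map round trip is identity to < 10⁻³ (max abs,
interior coordinates) on smooth maps. Rigid motions leave profiles unchanged
to machine precision; mirror reflection flips their sign. Time derivatives
use central differences (one-sided at the ends), exact for linear ramps and
< 1 % low for sinusoids up to a tenth of the sampling rate.

## Spectral measurements

All frequency and amplitude statistics operate on d(κ·L)/dt at a single
body coordinate, over an analysis window of at least 1 s (3 s is the
conventional window for stimulus-locked comparisons). The trace is
mean-subtracted and zero padded to a ≤ 0.05 Hz grid (next power of two of
fs / 0.05); the magnitude spectrum is normalised so a pure sinusoid of
amplitude A peaks at ≈ A. The undulation frequency is the argmax in
(0, 2.5] Hz. If the peak magnitude is below a fixed threshold the trace
counts as quiescent and the frequency is reported as 0; the default
threshold is the peak of a sinusoid whose rms is 1.0 s⁻¹ (i.e. √2), chosen
as the point where "undulation present" coincides with the bout detector's
activity semantics, and it is meant to be held fixed across every
measurement of a run (the CLI echoes it into each manifest). Raising the
threshold can only turn frequencies to zero, never the reverse.

Head and tail are measured at body coordinates 15 and 85 (mid-body presets
45, 60 and alternative tail 75 exist for lesion-style analyses). The 2FU
ratio is f_tail / f_head; a silent head with an oscillating tail gives an
infinite ratio that is flagged undefined and excluded from aggregates
(`ratio_summary`), mirroring how such trials are excluded in practice.
`is_2FU` requires an oscillating tail and a ratio that is undefined or
exceeds `ratio_min` (default 1.3 — the quantitative 2FU events sit well
above 1; the value is exposed as a sensitivity parameter).

Trial-averaged spectra are plain point-wise means on the shared zero-padded
grid (trials must share a sampling rate). Entrainment maps stack the mean
spectra of a pulse-frequency sweep, linearly interpolated along the imposed
axis at 0.05 Hz for display; ridge extraction (per-row argmax) exposes the
locking structure. Between swept frequencies an interpolated row is a
mixture of the neighbouring spectra, so the ridge snaps to one neighbour's
peak — exact statements hold at the swept frequencies.

## Bout detection and 2FU scoring

Activity is the sliding-window rms of d(κ·L)/dt per (time, coordinate) cell
(window 0.5 s, stride 0.125 s by default). Wave direction over a region is
the sign of the magnitude-weighted median cross-correlation lag between
curvature traces 5 body coordinates apart (2 s windows); the finite-window
envelope of the correlation resolves the half-period ambiguity toward the
smallest lag, standing waves and quiescent regions return 0. A forward bout
is a maximal run of cells with regional activity above a fixed threshold
(default 1.0 s⁻¹) and anterior-to-posterior direction, at least 2–3 s long
(both presets in use; 3 s default). Bout boundaries are reported at the
first and last passing window centres, which is unbiased against the
d(κ·L)/dt spike at a paralysis release edge.

2FU scoring searches all 3 s sub-windows of a stimulus window and requires
(a) an above-threshold tail frequency completing ≥ 2 cycles in the
sub-window and (b) tail waves not explained by the head: ratio undefined,
|ratio − 1| > ratio_min − 1, or head–tail phase coherence at the tail
frequency (band-passed analytic-signal phase difference) below 0.5. The
coherence/ratio operationalisation of "waves that do not appear to arise
from the head" is this package's decision, and both cutoffs are exposed.
Sub-windows whose head region propagates posterior-to-anterior are excluded
as reversal-contaminated. Cycle counts near the hard ≥ 2 criterion cannot be
decided from the grid-quantised spectral peak (0.039 Hz bins quantise counts
in 0.125-cycle steps and leakage flips the nearest bin), so the gate uses a
Hann-tapered, log-parabolically interpolated peak estimate with a 0.05-cycle
tolerance; `frequency_ratio` results keep the plain f_tail × window count.

Measured on the simulator: planted bouts are recovered with mean IoU ≥ 0.9
over 100 seeds; the 2FU scorer shows < 5 % false positives on 100 uniform
swimming runs and > 80 % true positives on 100 neck-inhibition runs.

## The oscillator-chain simulator

The synthetic-data generator represents the circuit as n = 6 units, each
owning one sixth of the body, with phase θᵢ and bending amplitude aᵢ:

    dθᵢ/dt = 2π(fᵢ − k_slow·Aᵢ)
             + g_p·G(aᵢ₋₁)·sin(θᵢ₋₁ − θᵢ − Δ)
             + g_a·(ε₁ sin θᵢ + ε₂ sin 2θᵢ)·D̃ᵢ(t)
             + √(2σ²)·ξ(t)
    daᵢ/dt = r·(a_target,ᵢ(t) − aᵢ)

- G(a) = clip(a/a₀, 0, 1) gates posteriorward proprioceptive coupling on
  the anterior neighbour's bending amplitude: a paralysed segment transmits
  no bend to copy.
- Δ = 2π·w/n is the inter-unit lag of a wave with w = 1.5 waves per body
  length.
- Dᵢ(t) = max over units posterior to i of (1 − aⱼ/a₀) is the posterior
  amplitude deficit. The anteriorward pathway is neural and long-range
  (tail-only rhythmic inhibition entrains the head), hence the maximum over
  all posterior units rather than the nearest neighbour.
- Aᵢ is a 1 s moving average of Dᵢ and D̃ᵢ = Dᵢ − Aᵢ the adapted
  phase-response drive: only *changes* in posterior inhibition reset the
  phase. Without adaptation no gain satisfies both requirements that a 2 Hz
  pulse train capture the head across a 0.3 Hz detuning and that a
  *sustained* deficit not create a phase fixed point that stops the head
  outright. A sustained deficit instead lowers the unit's frequency through
  the separate k_slow gain — the two exposed gains correspond to the two
  candidate explanations of head slowing during 2FU (active re-entrainment
  vs. loss of posterior excitation), and either can be switched off.
- The (sin θ, sin 2θ) phase-response curve encodes that each undulation
  cycle has two curvature-zero phases in which inhibition acts equivalently;
  the sin 2θ term is what produces 2:1 locking.
- a_target is 0 wherever a stimulus mask covers the unit's span and a₀
  otherwise; in relay mode the target of units i > 0 is additionally scaled
  by G(aᵢ₋₁), so paralysis anywhere silences everything posterior
  (amplitudes start at their masked targets, avoiding onset transients).

Modes: **relay** has intrinsic drive only on unit 0 (default 1.0 Hz,
fᵢ₌₁.. = 0, g_a = k_slow = 0) — the single-oscillator hypothesis; it
propagates a normal wave but any continuous mask suppresses the posterior
time-averaged |κ̃| to < 5 % of baseline. **autonomous** gives every unit
intrinsic rhythmogenesis with fᵢ rising linearly 0.7 → 1.4 Hz head to tail
(isolated posterior circuits run faster); behind a continuous mask the tail
free-runs above the head frequency, and with no mask and no noise the chain
phase-locks to a single frequency inside [min fᵢ, max fᵢ].

The rendered field is κ̃(s, t) = a_{i(s)}·sin(θ_{i(s)} − 2π·w·(s − sᵢ)/100)
with sᵢ the owning unit's span start; at phase lock the pieces join into
~w travelling waves per body length, anterior to posterior.

### Parameters (defaults)

| parameter | default | units | meaning |
|---|---|---|---|
| n_units | 6 | – | oscillator units spanning the body |
| intrinsic_freqs | 0.7 → 1.4 linear | Hz | natural frequencies (autonomous) |
| waves_per_bl | 1.5 | waves/BL | spatial frequency of the wave |
| base_amplitude a₀ | 5 | – | κ·L amplitude of an uninhibited unit |
| coupling_post g_p | 10 | 1/s | proprioceptive (posteriorward) gain |
| coupling_ant g_a | 16 | 1/s | anteriorward phase-response gain |
| prc_coeffs (ε₁, ε₂) | (1.2, 1.0) | – | PRC weights of sin θ, sin 2θ |
| prc_adapt_tau | 1.0 | s | adaptation of the anteriorward drive |
| deficit_slowing k_slow | 0.1 | Hz | slowing per unit sustained deficit |
| noise_sigma σ | 0.1 | rad/√s | phase diffusion |
| relax_rate r | 8 | 1/s | amplitude relaxation |
| sampling_rate | 40 | Hz | output frame rate |
| oversample | 10 | – | integration substeps per frame |
| duty | 0.5 | – | pulse-train duty cycle (masks) |

Integration is fixed-step Euler–Maruyama at `oversample` × sampling_rate
(400 steps/s by default) with output decimation; a configuration whose
fastest rate cannot be resolved by the step raises an explicit error, as
does a sampling rate below twice the fastest intrinsic frequency. Identical
configurations (seed included) give bitwise-identical kymograms; batches of
seeds integrate vectorised and match single runs exactly.

### Calibration of the entrainment gains

ε₁, ε₂ and g_a were frozen by sweeping pulse frequency (0.5–2.0 Hz, both
mid-body and tail bands) and mapping where the head locks: the defaults give
1:1 locking at 0.5–0.85 Hz, 2:1 locking (head = f_p/2) throughout
1.25–2.0 Hz, and no stable lock near 1.1 Hz, the structure the targeted
experiments show. The locking is insensitive to which posterior band is
pulsed. The alternatives explored and rejected: rectifying the adapted
drive at zero (its DC and even harmonics widen the 1:1 tongue over the
whole sweep), and ε₁ ≤ 1 (the 2:1 tongue then swallows the low-frequency
1:1 regime). Amplitude a₀ = 5 and w = 1.5 are order-of-magnitude choices
matching swimming kymograms, not fits.

## What the generator does and does not emulate

It emulates dark-field-tracked swimming at 40 Hz: 0.5–1 Hz undulations,
~1.5 waves per body length travelling head to tail, spatially targeted
continuous or pulsed inhibition, posterior free-running, bidirectional
coupling and 1:1 / 2:1 entrainment, and phase noise. It does **not** model
biomechanics (fluid drag, gait modulation with viscosity), neuron classes,
reverse locomotion, turns, 3-D postures, segmentation noise of real
trackers, or the ~6 % body-length resolution limit of targeted
illumination (masks are continuous in s). Passing tests therefore validate
the estimators on idealised waves with known ground truth, not robustness
to tracker artefacts; the smoothing and flagged-frame paths exist for real
data but are exercised only on synthetic noise here.

Test-fixture protocol: bout-recovery fixtures plant quiescence with
whole-body masks on a chain with *uniform* intrinsic frequencies and the
anteriorward pathway disabled. With the default frequency gradient the
units decohere during the quiescent epoch and the resumed wave needs ~2 s
to re-lock, which would make the planted interval a property of the model
transient rather than ground truth for the detector.

## Known limitations

- The oscillator chain is a phenomenological instantiation of the
  conceptual circuit models; its anteriorward coupling form (adapted
  deficit × two-term PRC) is one admissible choice among several, chosen as
  the minimal dynamics reproducing wave propagation, posterior
  free-running, head slowing and both entrainment ratios.
- Frequency estimates are quantised to the 0.039 Hz zero-padded grid; on
  3 s windows the leakage of the negative-frequency image can shift the
  peak by one bin. Statistics that need finer resolution (the cycle-count
  gate) use the tapered interpolated estimator described above.
- Six units give a 16.7 % body-length granularity for mask-to-unit
  assignment; any overlap of a mask with a unit's span inhibits the whole
  unit.
- The 2FU coherence cutoff (0.5) and ratio_min (1.3) stand in for a human
  judgement ("waves that do not appear to arise from the head") and should
  be treated as sensitivity parameters in any quantitative comparison.
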
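# Methods

`hypojump` re-implements the analysis chain of a hypogravity jump-adaptation
experiment: participants perform countermovement jumps to a visual target at
1 g (PRE), adapt over a block of jumps in simulated hypogravity produced by
constant-force body-weight support (ADAPT), and return to 1 g (POST). The
package analyzes per-jump mechanics, landing-preparatory muscle activity,
muscle-tendon kinematics with a spindle-afferent estimate, and the PRE/POST
statistics — on synthetic trials whose ground truth is known, so every stage
can be validated by recovery.

## Synthetic trial model

A trial is a piecewise closed-form center-of-mass (COM) trajectory:

- quiet standing (0.6 s), zero acceleration;
- a raised-cosine unload pulse (countermovement dip, default 0.45 s) and a
  raised-cosine push-off pulse (0.25 s). The unload amplitude is solved so
  that the COM returns exactly to standing height at takeoff, which makes
  `v_takeoff^2 / 2g` equal the jump height identically; at very low
  effective gravity the unload duration is stretched automatically to keep
  GRF positive;
- ballistic flight under the trial's effective gravity `g_eff`
  (`t_flight = 2 v_takeoff / g_eff`);
- a critically damped spring landing (`omega` = 12 rad/s),
  `u(t) = -v_takeoff * t * exp(-omega t)`, giving a landing peak near
  6-7 body weights.

GRF is `m (a + g_eff)` throughout. Body-weight support is modeled entirely
through `g_eff`: the plate reading while standing is `m g_eff`, which is
also the body weight used for phase segmentation. Takeoff and touchdown are
modeled as force steps rather than finite ramps, so the 25 N aerial
threshold recovers the ballistic boundaries to within one sample; a finite
release ramp would make the threshold crossing lead the true boundary by
several samples and is deliberately not modeled.

EMG is a band-limited (20-450 Hz) unit-RMS Gaussian carrier multiplied by
burst envelopes, plus additive carrier noise scaled by `emg_noise_sd`
(normalized units; default 0.01). The push-off burst is a raised cosine
confined to the push window. The preactivation burst is identically zero
before the injected onset, rises over a 12 ms smoothstep, and holds through
landing; the sharp rise keeps the cumulative-integral elbow within a few
milliseconds of the true onset (a rise spread over the whole preactivation
span would bias the elbow ~15 ms late, defeating recovery tests). Injected
onsets are ~100 ms before touchdown at baseline with 3 ms per-muscle
jitter; the POST block starts at 74 ms (a 26 ms aftereffect delay) and
0.6x magnitude, both relaxing back to baseline with a 5-jump time constant.
Per-condition target biases (+5 cm early in ADAPT, -3.5 cm at POST onset)
decay similarly, emulating adaptation and washout curves. These constants
are the generator's definition of the study conditions and are configurable
but not tuned per run.

MTJ channels are emitted as pixel tracks in a static probe frame aligned
with the muscle-tendon unit (MTU) line, in a shank-fixed coordinate frame;
frame timestamps include the rolling-shutter column delay, generated by
fixed-point iteration of the self-referential capture time. The MG length
is the resting length (drawn per participant, ~0.26 m) minus a push-off
shortening transient plus a landing stretch transient.

What the generator does *not* emulate: motion-capture soft-tissue artifact,
EMG crosstalk and electrode drift, plate resonance, genuinely asymmetric
flight (takeoff and landing height differ in real jumps), fatigue across a
block, or trial-to-trial correlation beyond the smooth adaptation curves.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under the stated signal model, not robustness to every artifact of
real recordings.

## Kinetics

The aerial interval is the longest contiguous run of GRF below 25 N. The
lift phase starts at the last upward body-weight crossing before the
push-off GRF peak; the land phase ends at the first downward body-weight
crossing after the landing peak. Crossing indices report the sample on the
lower-time side of the interpolated crossing; plateaus exactly at body
weight resolve to their earliest sample. Segmentation runs on the raw GRF:
a zero-phase 25 Hz lowpass (used for the marker trace) smears the
near-impulsive landing spike tens of milliseconds backward and would drag
the detected touchdown early, corrupting every landing-referenced onset
time. Impulses are gross trapezoidal areas under GRF over the lift and land
windows; a net variant (GRF minus body weight) is available for
impulse-momentum bookkeeping. Jump height is the aerial peak of the 25 Hz
lowpassed sternum marker minus the standing reference (mean of the first
0.3 s); aerial acceleration is twice the quadratic coefficient of a
least-squares parabola fit over the interior of the aerial window.

Ballistic timing analytics: `fall_time(h, g) = sqrt(2h/g)`, the predicted
timing delay between two gravity levels is the fall-time difference, and
the mitigation percentage is `100 (predicted - observed) / predicted`.

## EMG preactivation

Raw EMG is band-limited 5-450 Hz (4th-order Butterworth, forward-backward)
and full-wave rectified. Normalization divides by the peak 100 ms centered
sliding-window average across a participant's three maximal jumps (window
truncated at edges; window length is `round(0.1 fs)` samples).

Onset detection, per muscle and jump, over the aerial window:

1. **Gate `no-late-max`** — the aerial trace is smoothed with a zero-phase
   Gaussian FIR whose -3 dB point is 1 Hz (sigma ~132 ms, kernel truncated
   at 3 sigma and renormalized by in-window mass). An IIR realization of so
   low a corner on a sub-second window is dominated by its edge transient
   and produced both spurious rejections and missed rejections in
   simulation, so the FIR smoother is used for this corner only. Local
   maxima use a relative tolerance of 1e-8 (the smoother can flatten the
   window to a numerical plateau); a plateau takes its last sample, and the
   first/last samples count when they top their neighbour. If the latest
   maximum is more than 150 ms before touchdown the jump is excluded.
2. **Elbow** — the cumulative trapezoidal integral C(t) of the rectified,
   normalized trace is compared with the chord joining its endpoints; onset
   is the sample of maximum downward deviation, ties resolving to the
   latest sample (which routes an all-zero trace to the magnitude gate
   rather than to a spurious early onset).
3. **Gate `too-early`** — onsets more than 150 ms before touchdown are
   excluded (both 150 ms gates are inclusive).
4. **Gate `sub-1-percent`** — the mean normalized activity between onset
   and touchdown must reach 0.01.

Preactivation magnitude is that mean; iEMG is the trapezoidal integral over
the same window. Triceps Surae Preactivity is the three-muscle mean of iEMG
per leg; if any member muscle is excluded the value is missing (a two-muscle
fallback exists behind `allow_partial`). Landing time is mapped from the
GRF clock to the EMG clock by nearest sample.

Under the default noise (sd 0.02 normalized and below), recovery is biased
about -4 ms (the elbow sits where activity first exceeds the aerial mean,
a few ms into the rise) with ~2 ms jitter; ~100% of trials recover within
±10 ms.

## Fascicle and Ia rate

Rolling-shutter correction adds `(u / image_width) * frame_period` to each
frame timestamp. Pixels map to the lab through the probe's rigid pose; the
MTJ is projected orthogonally onto the knee-to-insertion line, giving
muscle (knee-projection) and tendon (projection-insertion) lengths that sum
to the MTU length exactly for in-segment projections; out-of-segment
projections are flagged, not truncated. The track is cubic-interpolated
onto the kinematic clock, lowpassed at 6 Hz (zero-phase Butterworth), and
differentiated by central differences (lengthening positive). The resting
length L0 is the mean filtered length over the first 0.3 s of quiet
standing.

The Ia firing-rate model is

    R_Ia = 65 (V/L0)^0.5 + 200 (L - L0)/L0 + k_u_max * u + R_Ia0

with velocity clamped to lengthening, `k_u_max` = 100, `R_Ia0` = 0, the
activation `u` taken as the 100 ms sliding average of normalized MG EMG
clipped to [0, 1], and the total rate floored at zero. The printed form of
the source equation does not fix whether the stretch term is normalized by
L0; the normalized (Prochazka-style) reading is the default and a
strict-literal variant (`200 (L - L0)` in meters) is selectable with
`normalized_length_term=False`. Neither reading is asserted as the original
intent; both are exercised in tests. MG force is ankle torque divided by
the orthogonal ankle-to-MTU distance, flagged unreliable below 1 mm.

## Wavelet functional paired t-test

Phase waveforms are time-normalized (endpoint-preserving cubic spline on a
uniform grid) to 64 points for lift and land and 34 for aerial. Lengths
that are not a power of two are resampled *up* to the next power of two
with an FFT zero-padding resampler before decomposition and restored
afterwards; upsampling (unlike decimation to the nearest power of two) is
exactly invertible, so the decompose-reconstruct path is lossless to
machine precision. Decomposition is a third-order Coiflet at maximal depth
with periodized boundaries (an orthonormal transform: i.i.d. noise maps to
i.i.d. coefficients, which the calibration tests rely on). Each coefficient
gets a two-tailed paired t-test at alpha = .05 with no multiplicity
correction (a Holm variant exists behind a flag); zero-variance coefficient
differences are exact — significant iff the common difference is nonzero.
Significant coefficients carry their mean PRE-POST difference, others are
zeroed, and the inverse transform returns the time-domain contrast, masked
where |contrast| reaches 10% of its peak.

## Scalar battery

Shapiro-Wilk runs on the paired differences (the quantity whose normality
the paired t-test assumes; a per-group variant is available) and Levene
(median-centered) on the two condition vectors, both at .05; failure of
either routes to a Wilcoxon signed-rank test (exact when n <= 25 and
tie-free, otherwise the continuity-corrected normal approximation, whose z
is always reported). All-zero differences report p = 1; constant nonzero
differences report p = 0; both are flagged degenerate. Hedges g_av divides
the mean paired difference by the average of the two condition SDs and
applies J = 1 - 3/(4(n-1) - 1); tables report magnitudes, signed values by
flag.

Probe jumps for the battery: baseline is the **last** PRE jump; Early/Late
Adaptation are the first/last ADAPT jumps; POST/Washout are the first/last
POST jumps. Aftereffects are POST minus PRE on those probe jumps, averaged
across participants with per-participant values retained.

## Problem sizes and numerical choices

The validation studies use: 200 trials (8 participants x 25 jumps) for
onset recovery; 1000 replicates at n = 20 for both null calibrations; 100
random force profiles for the segmentation/impulse oracles; and a full
20-participant, 70-jump cohort for the end-to-end aftereffect check —
sizes chosen to put Monte-Carlo error well inside the assertion bands while
keeping a complete run in the low minutes on one core. All randomness
flows from explicit integer seeds through `numpy` `SeedSequence`; per-trial
seeds derive from (cohort seed, participant, condition, jump), so any
single trial is reproducible in isolation.

## Known limitations

- The generator's GRF is kinematically exact but stylized (no bimodal
  landing peak, no mediolateral components, identical takeoff/landing
  heights).
- The onset detector's small late bias is inherent to the elbow criterion
  on finite-rise bursts; it is characterized, not corrected.
- C3D export is not provided; trials are TSV + JSON manifest.
- The functional battery in the default pipeline compares GRF waveforms
  (lift/land); ultrasound-derived waveforms can be passed to
  `wavelet_paired_test` directly but are not wired into `run_all`.
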
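# Methods

## Problem and data model

A heel-raise session is a sequence of cued repetitions: 5 s idle, 1 s rise
(concentric), 3 s hold (isometric), 1 s drop (eccentric). The toolkit
analyzes four sensor streams: a smart-insole stream (4 FSR force channels +
3-axis accelerometer at a nominal 30 Hz), an optional reference orientation
stream (pitch/roll in degrees), an optional raw EMG stream at its own
higher rate (default 2000 Hz, configurable — reference EMG hardware rates
vary), and an optional grid-insole medio-lateral COP stream.

The insole is the master clock. Other streams are trimmed to the common
interval (`shared-clock`) or first shifted by the lag maximizing the
normalized cross-correlation between the insole's along-foot acceleration
`ay` and the reference pitch (`cross-correlation`) — during a quasi-static
heel raise both peak together, which makes `ay` a usable pitch surrogate.
Constant clock offset only; drift correction is out of scope. EMG is never
down-sampled: only phase boundaries are mapped onto the EMG clock
(nearest-sample), and waveform length is computed at the native rate.

Channel anatomy is fixed as F1 = toe, F2 = 1st metatarsal head (medial),
F3 = 4th metatarsal head (lateral), F4 = heel, so the medial partial
pressure reads directly as `100·F2/(F2+F3)`.

## Segmentation

Pitch comes from the orientation stream when present, otherwise from the
accelerometer tilt `asin(clamp(ay/‖a‖))`, low-pass filtered at 3 Hz
(2nd-order Butterworth, zero-phase). The surrogate is an attitude estimate
valid for quasi-static movement; rise/drop transients appear as deviations,
which is why the regression of angle on raw acceleration (`fit_linear_relation`)
shows structured residuals yet high R².

Event detection uses a hysteresis threshold: open above 5°, close below
3° (5° − 2° hysteresis). These defaults sit far below a typical ~25°
excursion and are configuration-exposed; the hysteresis prevents chatter on
noisy crossings. Events shorter than 1 s are discarded, events closer than
1 s merged, and the boundaries extended outward along the smoothed pitch
(while it keeps decreasing, or is still above the closing threshold) so the
full rise onset and drop completion are inside the event window.

Phases come from the gradient of the moving-average-smoothed pitch
(0.3 s window, central differences). The rise is the supra-threshold
(+3 deg/s) positive run containing the gradient maximum, the drop the
negative run containing the minimum. Each boundary is localized at the
**half-peak crossing** of its run, with sub-sample linear interpolation:
zero-phase smoothing smears a trapezoid corner symmetrically, so the
half-peak crossing sits at the underlying corner with no systematic offset,
whereas a plain "gradient falls below threshold" rule would shift every
boundary outward by roughly half the total smoothing width (~0.2 s here)
and bias all phase durations. On noiseless trapezoids the boundaries land
within one 30 Hz sample of the analytic corners for rise/drop durations
down to ~0.5 s; pitch noise inflates the peak estimate slightly and pulls
boundaries inward by a few hundredths of a second, well inside the 0.1 s
accuracy the protocol-recovery checks require. Degenerate events (no
supra-threshold rise) are reported with phases marked invalid; a monotone
ramp yields a single-sample drop/hold rather than an error.

## Features

- **Waveform length**: window-end aligned — output `t` sums the `N−1`
  absolute first differences ending at `t`; the first `N−1` samples are
  undefined (NaN). Window-end alignment keeps the envelope causal. Default
  `N` = 0.25 s of EMG samples.
- **MPP**: undefined (NaN, never a division error) when the forefoot load
  `F2+F3` is below a floor, by default 1 % of the session's 95th-percentile
  forefoot load — idle/swing ratios between two unloaded sensors are
  meaningless. MPP is invariant to the force unit, so uncalibrated device
  units are acceptable.
- **ML COP** is implemented exactly as `100·(W − COP_x)/W`. Note the sign
  convention is debatable — with `COP_x` a medial coordinate this reads as
  a lateral fraction — but the formula is kept as the field convention for
  the grid-insole comparison and only the interpretation is flagged here.
- Per-phase features are arithmetic means over each phase's samples
  (half-open intervals, drop closed at the event end; undefined MPP samples
  excluded; an empty phase falls back to its nearest sample).

## Ensemble statistics

Each phase is resampled onto `points_per_phase` = 100 equally spaced
fractions of its duration (equal allocation per phase, matching per-phase
percent axes, not duration-proportional), segments concatenated
rise→hold→drop, and the event ensemble summarized by pointwise mean and
sample SD (ddof = 1; zero SD for a single event). Phases covering fewer
than two samples are filled from the nearest samples with a warning.

Because raw EMG amplitude is not comparable across subjects, per-phase WL
features are divided by the subject's mean rise-phase WL per muscle. The
denominator pools all conditions present for the subject by default
(`mode="pooled"`); an eversion-only denominator (`mode="ev_only"`) exists
because either reading of "normalized to the rise phase" is defensible.
The choice and the denominators are recorded in the output's metadata.

## Classification

Each event × phase contributes one (mean MPP, mean roll) point; positive
roll is fixed to mean eversion. Boundaries:

- `mpp_threshold`: midpoint between the class MPP means — the "single
  vertical line" rule, which works within one subject but fails on pooled
  multi-subject data once habitual medial loading varies;
- `linear_2d`: two-class linear discriminant with equal priors on
  (MPP, roll) — the minimal 2-D linear rule; adding the roll axis restores
  pooled separability without per-subject calibration.

Event labels are the majority over the event's phase points; ties (on the
boundary, or a split majority after dropped points) resolve to IV, because
in rehabilitation a false "improper posture" flag is safer than a false
"proper". A rise-phase-only point selection is available since PL
recruitment is decided during the rise.

## Synthetic sessions

The generator's defaults are the cued protocol: phase durations
(5, 1, 3, 1) s with per-event Gaussian jitter (CV 0.08, redrawn if a draw
is non-positive), 5 repetitions, one of DL-EV / DL-IV / SL-EV / SL-IV.
From a programmed pitch trapezoid (peak 25°, corners smoothed by a 0.2 s
cosine taper so the gradient is finite) everything else is derived: roll
ramps in proportion to pitch (+5° for EV, −10° for IV); the instantaneous
MPP interpolates baseline→raised with pitch (EV 55→75 %, IV 45→25 %); the
forefoot load doubles from idle to hold while the heel channel unloads
above ~5° pitch; acceleration is the gravity projection of the orientation
plus 2–6 Hz band-limited motion bursts (0.05 g) during rise/drop and white
noise (0.02 g); the orientation stream adds 0.3° noise, forces 1 device
unit. EMG is amplitude-modulated Gaussian noise — a standard surrogate,
since WL responds to envelope amplitude; no motor-unit model — with
per-muscle per-phase envelope gains: PL hot in the EV rise (1.0 mV) and
weak + 0.3 s-delayed in the IV rise (0.3 mV); GM/GL independent of ankle
orientation but scaled ×1.6 under single-leg load; the soleus gets a mild
(×1.2) eversion boost. The peak pitch, MPP/roll levels, EMG gains and the
×1.6 single-leg factor are plausibility stand-ins — no published numeric
values exist for them — chosen once so that the qualitative contrasts
(EV/IV separation, PL rise contrast, DL/SL load effect) are present with
realistic margins.

Cohorts add per-subject offsets to the MPP levels (SD 12 %) and the roll
excursion (SD 1.5°), shared across that subject's variants. The MPP offset
SD is comparable to half the within-subject EV–IV rise-phase gap (~15 %),
which reproduces the observation motivating calibration: single-subject
separation always holds, while a pooled single MPP threshold misclassifies
events for some cohort draws; the (MPP, roll) plane stays linearly
separable because roll offsets are small against the EV–IV roll gap.

All randomness derives from one `numpy.random.default_rng` seed
(per-subject/variant seeds spawned from it), so sessions are
bit-reproducible for a given numpy generator algorithm.

## Problem sizes and numerical choices

Validation runs use sessions of ~55 s at 30 Hz (EMG 2000 Hz, generated
only where a test needs it) and 5-subject cohorts; protocol-duration
recovery is averaged over 10–20 seeded sessions (50–100 events) so the
Monte-Carlo error of the mean (~0.02 s) is small against the 0.1 s
acceptance band. Stream CSV round-trips print floats at 12 significant
digits (identity to 1e-9). Resampling is linear interpolation — exact for
ramps, with the usual `(2πf/fs)²/8` amplitude-relative error bound for
band-limited content, negligible below 3 Hz at 30 Hz.

## What the synthetic data does not show

Passing on synthetic sessions demonstrates the pipeline's correctness
against programmed ground truth, not field performance: real FSR
nonlinearity and hysteresis, accelerometer drift and non-gravity artifacts,
EMG crosstalk and motion artifacts, non-constant clock drift between
devices, and genuinely diverse movement strategies are all absent. The
accel-vs-angle regression residual structure is modeled only as additive
motion bursts. Hardware transport, device formats and biofeedback delivery
are out of scope.
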
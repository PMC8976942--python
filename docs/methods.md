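# Methods

This note documents the models, numerical choices and known limitations
behind `thermoresp`, in the order the pipeline runs.

## Radiometric model

Raw sensor counts S relate to object temperature through the camera's
Planck calibration (R1, R2, B, O, F) with emissivity, reflected-background
and atmospheric corrections:

```
S_obj = S/(ε·τ) − (1−ε)/ε · S_refl − (1−τ)/(ε·τ) · S_atm
T_obj = B / ln(R1 / (R2·(S_obj + O)) + F) − 273.15
```

where S_refl and S_atm are the idealised blackbody counts of the
reflected and atmospheric temperatures, and the transmittance τ follows
the published water-vapour attenuation formula

```
h2o = RH · exp(1.5587 + 0.06939·T − 0.00027816·T² + 6.8455e−7·T³)
τ   = X·exp(−√d·(α₁ + β₁√h2o)) + (1−X)·exp(−√d·(α₂ + β₂√h2o))
```

applied over the full object distance d. (Some conversion tools split
the path into two halves around an optional infrared window; no window
is modelled here, so the single full-path form is used.) τ = 1 at d = 0
by construction. The default α/β/X coefficients are the standard values
used by open thermal-conversion tooling; they, like everything else in
`CalibrationConstants`, are overridable per recording session — the
intended granularity is one constants file per session, since absolute
accuracy matters far less than within-trace temperature *changes*.

`temperature_to_raw` is the exact algebraic inverse; round-trip error is
below 1e−6 °C across −20…60 °C (enforced by test). Because conversions
are monotone, phase structure is invariant to calibration error — only
amplitudes scale.

**ROI convention.** The nostril ROI is 10 px wide × 5 px high, 0-based
pixel coordinates, integer centre; for even sizes the extra pixel falls
on the high-coordinate side; edges are clipped to the frame. The per-frame
signal is the ROI median intensity, converted to °C.

## Quality control

A frame is *covered* when both nostrils are detected at confidence
≥ 0.95. Maximal runs of covered frames are kept if interior gaps are
≤ 5 consecutive frames and the run spans ≥ 150 frames (5 s at 30 fps).
The 150-frame floor guarantees at least three full cycles at the mean
respiration rate (3 × 1.6 s × 30 fps = 144, provided by
`min_segment_frames`). Edge gaps are trimmed: segments start and end on
covered frames. Interior gaps are filled by linear interpolation by
default (carry-forward is available via `gap_fill="ffill"`; the choice is
recorded in the per-frame `interpolated_mask`). Left/right nostril
temperatures are averaged by default (`side_policy="mean"`); either side
can be selected instead.

Periodicity screening replaces a visual inspection step with a Welch
power spectrum of the mean-subtracted trace: a segment is usable when the
dominant peak lies in a physiological band (default 0.2–2 Hz) and exceeds
10× the median spectral power. The threshold is configurable and a manual
override is possible by simply skipping the screen.

## Phase segmentation

The trace is low-pass filtered with a second-order Butterworth at
normalized critical frequency 1/5 (0.2 in Nyquist units — 3 Hz at
30 fps), applied forward–backward (`filtfilt`) so transitions are not
lagged. Filtering convention: "critical frequency 1/5" is read in
Nyquist units, the convention of common filter-design interfaces; a
cutoff in Hz is also accepted.

Maximum-inspiration points are local minima of the smoothed trace with
prominence ≥ 0.1 °C and spacing ≥ 0.5 s (guards against noise minima).
From each minimum the curve is walked backward and forward until the
local slope magnitude falls below a threshold ε — the plateau criterion
that delimits the expiratory pause. The local slope is a centred
least-squares fit over 5 frames; ε defaults to 10 % of the median
per-cycle *peak* expiration-limb slope. The peak (rather than an average
over limb frames) is used because the threshold must sit well above the
residual drift of the pause and well below the active limbs; an average
over the limb, which includes its own near-flat ends, does not separate
the two regimes reliably.

**Boundary refinement.** Zero-phase filtering spreads each phase
boundary (a curvature changepoint) over a few frames, which biases a
pure slope-walk: detected pauses come out one to three frames short.
Each walked boundary is therefore refined on the *unsmoothed* trace by a
local changepoint fit v(t) = L + a·(t−b)²₋ + c·(t−b)²₊, scanning b on a
1/8-frame grid (two passes, windows of ±6 then ±4 frames). Noise is
handled by the least-squares averaging rather than by pre-smoothing, so
the boundary position is not displaced. On noiseless traces every
transition is recovered within ±2 frames (acceptance-tested).

**Steep pauses.** When a pause is short and its drift steep, the slope
never falls below ε and the two walks collapse onto one point. Such
pauses are recovered by a joint two-changepoint fit of
quad | line | quad over a local window (expiration tail, linearly
drifting plateau, inspiration onset). If even that degenerates, the
cycle is emitted without a measurable pause. This is why per-phase
sample counts can differ — expirations ≥ pauses — as they also do at
segment edges, where the last cycle's pause has no closing transition.

**Metrics.** Duration = frame span / fps; amplitude = |ΔT| between the
boundary frames; slope = amplitude/duration (an exact identity).
Amplitudes are read from the unsmoothed trace at the detected boundary
frames: the zero-phase filter rounds off extrema and would otherwise
shrink every amplitude by several percent. Computing them from the
smoothed trace remains available (`metric_values` argument). Residual
temperature (per-frame value minus segment mean) and the resampled mean
cycle with percentile 95 % CI support waveform-level summaries.

Durations are integer frame counts over fps; when a *median* duration is
reported (acceptance script), the grouped median — interpolating the
cumulative distribution inside the median bin — is used to escape the
1/30 s grid.

## Cycle typing and NF labels

Call onsets govern assignment: a call spanning a cycle boundary belongs
to its onset cycle. Label precedence when a cycle qualifies twice
(e.g. sandwiched between two Call cycles) is Call > Post-call > Pre-call,
configurable. The audio track is examined 2 s beyond each segment edge;
an onset in that window makes the edge cycle Pre-/Post-call. "Immediately
preceding" for NF-heard labelling means the one phase before the phase
containing the NF onset; a time-window alternative is available
(`window_s`). Only Quiet cycles are NF-labelled, because an individual's
own calling would mask the subtler effect of hearing a neighbour.

## Permutation test

The statistic is Δmean = mean(group A) − mean(group B) over the pooled
phase records. Permutations reshuffle labels against values
independently within each individual, preserving each individual's label
counts — this controls for between-individual differences in breathing
and calling rates. The two-tailed pseudo-P uses the add-one estimator
p = (1 + #{|Δperm| ≥ |Δobs|}) / (N + 1), which is never zero and is the
conventional unbiased-conservative choice; a description of the same
procedure as "the percentage of |Δperm| below |Δobs|" is the
complementary percentile of the same null distribution, and the add-one
estimator is implemented deliberately. Monte-Carlo pseudo-P agrees with
exhaustive enumeration on all small tables, and the null pseudo-P
distribution is uniform (both acceptance-tested). Each permutation run
is reproducible from its seed; the pipeline derives per-test substreams
from one master seed and records them in the results JSON. No
multiple-testing correction is applied across the phase × parameter
grid.

## Synthetic data generator

The generator emits the waveform the detection stage assumes: per cycle,
a cosine-ramp descent (inspiration), cosine-ramp rise (expiration) and a
cosine-eased drifting plateau (pause), sampled at 30 fps with additive
white Gaussian sensor noise (default sd 0.02 °C). Phase durations and
amplitudes are drawn per cycle from per-condition log-normal
distributions parameterised by median and IQR (log-normal: positive
support and right skew typical of biological durations; σ solves
IQR = 2·median·sinh(z₇₅σ)).

Default condition parameters (median/IQR):

| parameter | Quiet | Call | Pre-call | Post-call |
|---|---|---|---|---|
| inspiration duration (s) | 0.29/0.15 | 0.40/0.20 | 0.29/0.15 | 0.29/0.15 |
| expiration duration (s) | 0.29/0.15 | 0.40/0.20 | 0.29/0.15 | 0.29/0.15 |
| pause duration (s) | 0.90/0.65 | 0.65/0.53 | 0.90/0.65 | 0.90/0.65 |
| expiration amplitude (°C) | 0.78/0.40 | 1.14/0.73 | 0.80/0.40 | 0.80/0.40 |
| pause amplitude (°C) | 0.16/0.26 | 0.20/0.26 | 0.22/0.33 | 0.20/0.26 |

Amplitude and pause-duration medians follow the field-data summaries the
simulator emulates. Limb durations are not reported in those summaries;
0.29 s medians make the mean cycle duration 1.656 s — the 0.603 Hz mean
respiration rate — with an inspiration/expiration time ratio of ~1
(field data report 0.987). The Call limb duration 0.40 s is
back-computed from the reported Call expiration amplitude/slope medians
(1.14/2.87). Call pause amplitude is not reported; 0.20 °C sits between
the Quiet (0.16) and Pre-call (0.22) values.

Two structural constraints keep the waveform physical:

- **Stationarity.** Inspiration amplitude is derived per cycle as
  expiration amplitude + pause drift, so every cycle returns to its
  baseline. Drawing all three amplitudes independently at the reported
  medians would impose a secular drift of ~0.07 °C per cycle
  (0.87 ≠ 0.78 + 0.16), i.e. tens of degrees over a session. The
  configured inspiration-amplitude distribution is kept as a descriptive
  reference; `derive_insp_amplitude=False` restores independent draws.
- **Plateau stability.** The pause is a rest phase; its drift amplitude
  is capped at half the expiration amplitude and its peak drift slope at
  0.8 °C s⁻¹. The log-normal pause-amplitude tail would otherwise
  occasionally produce "pauses" that rise faster than a typical
  expiration — waveforms in which the plateau concept, and hence the
  detection method, is undefined. The caps trim the upper tail only; the
  pause-amplitude median stays within a few percent of its configured
  value (tested).

Calls are placed inside the expiration phase of Call cycles (mammalian
vocal production overlaps exhalation), with duration drawn from a 50 ms
median distribution. `simulate_dataset` wraps traces with detection
tables (both nostrils, confidence 0.99), focal/NF call label files and a
per-individual audio-clock offset; `simulate_raw_stack` renders the trace
into raw-count frames (float, unquantised, so radiometric round-trips are
exact) with warm nostril patches on a uniform background.

**What the simulator does not emulate:** pose-estimation jitter in ROI
position, head-orientation changes, slow baseline drift from ambient
conditions, motion artefacts, mini-breaths inside trill-like calls, and
any coupling between noise and phase. Passing tests therefore show the
pipeline is correct *given* clean phase-structured input with white
sensor noise; they do not certify robustness to tracking failure modes,
which the QC stage is designed to reject rather than repair.

## Problem sizes

The acceptance script simulates 600 Quiet cycles for the rate check and
1800 cycles per condition for the phase-median checks — enough that the
sampling error of a median (≈1.5 % here) is well inside the few-percent
agreement being demonstrated, while a full run stays under a minute.

## Known limitations

- Boundary localisation is limited to roughly ±1 frame at 30 fps;
  phase-duration medians inherit a bias of up to ~2 % for the shortest
  phases.
- Pauses shorter than ~4 frames are not measurable and are dropped,
  slightly truncating the lower tail of detected pause durations.
- The rate-fit option in synchronization handles linear clock drift
  only; the default pure-offset map errors out when marker residuals
  exceed one frame period.
- Tidal-volume calibration from temperature amplitude is out of scope;
  amplitudes are reported in °C.
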
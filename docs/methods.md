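# Methods

## Calibrated audio and levels

Recordings are mono WAV (PCM16 or float), digital amplitudes in [−1, 1].
Absolute calibration is a single per-file number, `full_scale_db`: the sound
pressure level in dB re 1 µPa of a full-scale tone. Observatories that
adjust gain in the field to avoid clipping log this value per file
(typically 138–150 dB); every level computation adds it back, so received
levels are invariant to digital gain — a property the test suite asserts
directly. Received level over a window is the rms of band-filtered samples:
`RL = 20·log10(rms) + full_scale_db`. Band filtering uses a 4th-order
Butterworth applied forward–backward (zero phase) so event timing is not
shifted; bands touching 0 Hz or Nyquist degenerate to low-/high-pass, and a
full-band request skips filtering.

Spectrograms are magnitude STFTs on a Hanning window, default FFT size 4048
samples at 48 kHz (the reference analysis configuration; it is not a power
of two, and `--fft-size 4096` is the documented faster alternative) with
25% window overlap, i.e. hop = 0.75 × window. Some tools quote overlap as
the hop fraction; `SpectrogramParams.overlap_denotes_hop` selects that
reading. Magnitudes are stored in dB re digital units, floored 120 dB below
the per-spectrogram maximum (matching a ~90 dB instrument dynamic range
with margin); all-zero audio maps to a uniform floor. Frame times are frame
*start* offsets, frame count = `floor((N − fft)/hop) + 1`.

## Template detection

The template is a dB-magnitude patch: 1.1 s of frames by the 21 bins of a
240 Hz band centred on the moan contour's midline (40–280 Hz for the
default call), stored zero-mean and unit-norm. At each frame lag the score
is the zero-mean normalized cross-correlation between the patch and the
same-size spectrogram window, restricted to the template band. Consequences
of this construction, each covered by a test:

- scores lie in [−1, 1] and a template scores exactly 1 at its own source;
- uniform dB offsets of the recording cancel, so scores are gain-invariant;
- out-of-band energy (ice cracking, flow noise above the call band) cannot
  raise or depress scores.

Correlation runs on dB-scaled spectrograms rather than linear power: tonal
calls are contours of roughly constant level over a large dynamic range,
and log scaling makes the match sensitive to contour shape rather than to
the loudest pixel. Detection takes local maxima at or above the threshold
(default 0.42), accepted greedily in descending score with suppression
within one minimum separation (default the template duration — a call
cannot overlap itself); ties break toward the earlier time, making output
deterministic. On synthetic scenes, moans at 10 dB in-band SNR score
~0.62–0.74 while one-minute noise maxima stay below ~0.17, so the default
threshold separates cleanly with margin on both sides. The threshold is a
plain parameter: different analysis software normalizes differently, and no
meaning is attached to matching any other tool's score scale numerically.

The review surface (`review_export` / `review_import`) writes one clip and
one CSV row per event; verdicts are merged back by event id and only
`verified == "true"` events feed presence statistics. Unreviewed events are
conservatively excluded.

## Transmission loss and ranging

The law is the one-parameter `TL = a·log10(r)`, no intercept, no absorption
term — at the 100 Hz to 300 Hz frequencies involved, seawater absorption is
far below 0.01 dB/km and the empirical coefficient absorbs the rest. Each
calibration reception gives `a_i = (SL_i − RL_i)/log10(r_i)`; the fitted
coefficient is their mean. With a single moored source all ranges are
equal, so the coefficient spread is exactly the received-level spread
mapped through the fixed range: `a_sd = sd(RL)/log10(r)` (with mixed ranges
it falls back to `sd(a_i)`). `fit_tl_summary` fits from (SL, mean RL,
sd RL, r) directly and is test-verified equal to the raw-reception fit.

Distance inversion is `r = 10^((SL − RL)/a)` with bounds from the four
(RL ± sd, a ± a_sd) corners. Since r is strictly decreasing in both RL and
a (for SL > RL), the box extremes sit at corners; a fine-grid oracle
asserts this rather than trusting the monotonicity argument. Bounds are
one-sd excursions, not a confidence interval — that is the conventional
reporting for this kind of single-receiver ranging. One physics caveat is
reproduced deliberately: moan source levels are conventionally quoted
zero-to-peak while received levels are rms; the inversion uses both on the
scales quoted, and a peak-to-rms offset, if desired, is the caller's
responsibility when constructing `CallLevelAssumption`.

## Presence, bouts, effort

Daily binning is by UTC calendar date over the effort span; a day's
`recorded_seconds` comes from intersecting effort intervals with day
boundaries. Events outside all effort intervals are included with a warning
(clock skew between detector and effort log is tolerated, silently dropping
data is not). Monthly tables carry raw counts as the headline column plus
effort fraction, a `low_effort` flag below 50%, and detections per recorded
hour for effort-aware comparison. Conservation (monthly sum = daily sum =
event count) is asserted on every fixture.

A bout is a maximal run of consecutive detection-days, minimum length 2 by
default; shorter runs are reported as singleton days. A zero-effort day
breaks a run by default — we cannot know whether calling continued through
an outage — and `bridge_no_effort=True` joins across outages instead, in
which case a bout's length counts detection days only. Both behaviours are
exposed because outage handling is a genuine analysis choice.

## Ice cover

Grid cells belong to a query disc when their centre lies within the
haversine distance (spherical Earth, 6371 km) of the centre point; at
6.25 km cells against a 100 km radius the boundary discretization error is
well under a percent of the mean. Cells are equally weighted by default
(appropriate for near-equal-area products); `cos_lat_weights` applies
cos-latitude weights for plain lat/lon grids. Missing cells drop out of
numerator and denominator, and ice % + open-water % = 100 exactly. The
daily overlay joins each presence day to the nearest dated grid within ±2
days (ties to the earlier grid), else NaN.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes, not
the full physics of a shelf-edge soundscape:

- **Moans**: harmonic stack on the arch contour
  `f1(t) = f0 + (B/2)·sin(πt/d)` with f0 = 100 Hz, B = 240 Hz, d = 1.1 s;
  3 harmonics decaying 6 dB per harmonic (real moans show harmonic
  structure but unreported levels, so these are explicit parameters, not a
  claim of fidelity); 5% Tukey taper. The analytic contour is returned as
  ground truth, and the untapered rms has the closed form
  `sqrt(ΣA_h²/2)`.
- **Levels and SNR**: a scheduled call is scaled so its rms *within the
  template band* hits either an absolute target RL or a target SNR over
  the scene's own in-band noise, measured over the call window. In-band
  definitions match what the detector sees; harmonics outside the band ride
  on top. Injected levels measure back within 0.5 dB across the full
  138–150 dB full-scale range.
- **Noise**: Gaussian background shaped to −5 dB/octave (ice-dominated
  soundscapes are red), plus Poisson-scheduled 20 ms broadband transients
  12 dB above the background, imitating ice cracking. Scenes that would
  clip raise an error rather than silently distorting calibration.
- **Calibration receptions**: `RL_i = SL − a·log10(r) + N(0, sd)` at fixed
  range, defaults a = 20.9, SL = 180 dB, r = 177 km, sd = 7 dB, n = 939 —
  the regime of a real moored low-frequency source (its 80 s, 259–261 Hz
  FM sweep is also synthesizable).
- **Ice year**: concentration oscillates sinusoidally between 5% in
  mid-February and 95% in mid-August plus per-cell Gaussian noise, clipped
  to [0, 100] — the qualitative Antarctic coastal cycle (open water in late
  summer, >90% cover in winter).
- **Presence year**: daily Poisson counts with a Gaussian seasonal bump
  (default peak mid-March, width 45 days, 8 calls/day at peak) over a
  0.25/day base rate, so sporadic winter calling occurs as observed.

Everything is a pure function of (parameters, seed) and bit-identical on
rerun. What passing tests on these fixtures do *not* show: robustness to
multipath, dispersion under ice, chorusing overlap, real moan variability,
or non-stationary noise; the detector's absolute recall on real recordings
must be established by review, which is why the review workflow is part of
the surface.

## Problem sizes and numerical choices

The test fixtures use 100 s scenes with five calls for recall, a 600 s
noise-only scene for the false-alarm rate, 50 one-minute trials for the
noise null distribution, 939 receptions for estimator consistency, and
30–48 cell grids for ice queries — sizes at which every check runs in
seconds while the statistics of interest (correlation nulls, fit standard
errors) are already in their asymptotic regime. Degenerate inputs error
loudly: zero-contrast templates, clipping scenes, empty reception lists,
discs containing no cells, bands beyond Nyquist, spectrogram parameter
mismatches. The package never resamples silently.

## Known limitations

Single-template detection only (stereotyped calls; variable call types need
a different approach). No propagation modelling beyond the empirical
log-law; no bearing, so "distance" is a ring, not a position. Bout
statistics depend on the outage-handling choice near recording gaps. The
ice radius query assumes the grid covers the disc; a partial grid biases
the mean toward covered cells.
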
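# Methods

This note records how `vertmech` defines, extracts and simulates the
mechanical parameters of vertebral compression tests, which choices were
genuinely open, and what the synthetic validation does and does not show.

## Test protocol and endpoint

Specimens are loaded axially at a constant crosshead speed (default
2 mm/min). The recorded trace is truncated at the first sample satisfying
either endpoint criterion:

* force ≤ (1 − `drop_fraction`) × running maximum force, default 50 %
  (terminal fracture), or
* displacement > `max_displacement`, default 2 mm (travel limit).

The force-drop criterion only arms once the running maximum exceeds
`min_peak_force` (default 20 N). Without this guard, load-cell noise around
zero contact force satisfies "force ≤ 50 % of the running maximum" long
before the specimen takes load; 20 N is an order of magnitude above sensor
noise and an order of magnitude below rodent vertebral peak forces. When
both criteria fire at the same sample the force-drop reason is reported.

## Elastic region and stiffness

The stiffness is the slope of the regression line fitted to the linear
elastic region, whose delimitation is not part of the protocol and is an
implementation choice here:

1. Work on the pre-peak span above a toe threshold (force ≥ `toe_fraction`
   = 5 % of the peak force), excluding specimen-seating artefacts.
2. Slide a window of width `window_fraction` (default 10 %) of the pre-peak
   samples (odd, ≥ `min_window` = 11) and fit each window by least squares
   (O(n) running-sum implementation).
3. Candidate windows need r² ≥ `r2_floor` (default 0.999; the noisy preset
   relaxes it). Among candidates, select the *steepest* window: the toe and
   the hardening segment are both shallower than the elastic limb, so
   maximal slope — not maximal r², which is high on any smooth segment — is
   the discriminating statistic. If no window reaches the floor the curve is
   flagged with "no linear elastic region found" rather than scored.
4. Grow the region outward from the selected window while the windowed
   slope stays above `best_slope − max(3·SE(slope), 0.002·best_slope)` (and
   r² above the floor). The relative term dominates on noiseless traces and
   the SE term on noisy ones, so growth stops where the curve genuinely
   bends rather than where noise dips.
5. Refit the final region; report slope (= stiffness S), intercept, r², and
   the mean and SD of *local slopes*: centred least-squares slopes over a
   smaller window (`local_window`, default ≈ window/5, minimum 11). The
   compliance is N = 1/S, checked to 1e-9 as an invariant.

Local slopes deliberately use a smaller window than region selection. The
yield rule (below) reports the force at the first failing window *centre*,
so its resolution is half a window; with the region-sized window the
half-window offset alone would bias the detected yield load several N low
on a typical trace, while an ≈ 5× smaller window keeps the offset within a
fraction of a percent yet still averages enough samples to be usable at
realistic noise (two-point difference quotients are not).

## Yield load

Yield is "stiffness decreased by two standard deviations": the first local
slope (scanning forward from the end of the elastic region, using only
windows fully before the force maximum) below

    mean_local_slope − max(k_sd · sd_local_slope, 0.005 · mean_local_slope)

with `k_sd` = 2. The relative floor handles the degenerate noiseless case:
with zero noise the local-slope SD is numerically ~0 and the bare 2-SD rule
fires on rounding error half a window before the true elastic limit. A
0.5 % slope-loss floor is far below any physical yield signature, so it
never masks a real transition; it only suppresses the numerical hair
trigger. Windows straddling the force maximum are excluded because their
slope loss comes from post-peak collapse samples, not from pre-peak
yielding; if no admissible window fails the threshold, the yield is pinned
to the peak and flagged (`yield_at_peak`), not treated as an error.

## Maximum and failure load

Maximum load is the largest force sample, ties broken to the first index
(temporal reading of "largest measured force"). Failure load is the force
at the onset of the terminal drop, operationalised as the *last* local
force maximum (≥ both neighbours) between the global peak and the endpoint
— the published group values put the failure load at ≈ 93 % of the maximum
load, so it cannot be the 50 %-drop endpoint force itself. If force
decreases monotonically after the peak, the failure index falls back to the
peak. All indices are 0-based with inclusive ranges throughout.

## Group statistics

Per group: sample mean, SD (n−1 denominator) and SEM per parameter. Per
parameter: Shapiro–Wilk per group (reported; no automatic non-parametric
fallback — the protocol assumes normality held), a two-sided variance-ratio
F-test (larger variance on top, p = 2 × upper tail), then an unpaired
two-sided t-test: pooled Student t when the F-test p ≥ 0.05, Welch
otherwise. Significance at α = 0.05; no multiple-testing correction across
the four parameters, matching the reference protocol. The Type-I error of
the full cascade under H0 is verified by simulation in the test suite
(2000 replicates at n = 17/18).

## Synthetic curves

The generator produces the curve anatomy the extractor assumes, with
ground truth (S, yL, Fmax, fL) as direct inputs:

* quadratic toe over `toe_displacement` (default 0.05 mm) meeting the
  elastic line with matched slope;
* linear elastic limb of slope S up to the yield load;
* hardening segment `Fmax − (Fmax − yL)·((d_peak − d)/span)^h` with
  `h = hardening_shape` (default 2) and `span = h·(Fmax − yL)/S`, which
  makes the tangent continuous (= S) at yield and zero at the peak — any
  smooth concave interpolant with those boundary slopes would serve, so the
  shape is a parameter;
* post-peak softening to a valley just below fL, optional discrete
  microfracture notches, re-engagement rising to exactly fL (so the failure
  point is a genuine last local maximum), then a terminal drop of
  `terminal_drop_fraction` (default 0.6, enforced ≥ 0.5) times Fmax, which
  guarantees the force-drop endpoint rule triggers; the curve extends a few
  samples past the trigger;
* optional additive Gaussian force noise (`noise_sd`), seeded.

Displacement advances at `crosshead_speed · sample_interval / 60` mm per
sample; the defaults (2 mm/min, 0.03 s) give a 1 µm grid and 1000–1500
samples per curve — desk scale, chosen for numerical resolution rather than
emulating the instrument's native acquisition rate. Parameter sets that
cannot produce a coherent curve (yield or failure above the maximum, a
failure level too close to the 50 % endpoint, an elastic limb shorter than
0.1 mm, total travel beyond the 2 mm endpoint) are rejected at
construction.

## Synthetic cohorts

Cohort specimens draw (S, yL, Fmax, fL) from independent normals per group
(no covariance structure is modelled, as none is reported for the reference
study) and redraw, up to 100 times, until the tuple is physically
realisable. Child seeds derive deterministically from the master seed and
specimen index, so cohorts are bit-reproducible.

The packaged reference configuration mirrors the validation study this
package models: 17 sham-operated vs 18 ovariectomized rats with group means
(174.2, 134.6, 154.2, 143.8) and (133.2, 125.8, 133.5, 123.4). The printed
"±" dispersions of that study are labelled SD, but with n = 17/18 they are
numerically consistent only with SEMs given the published p-values
(≈ 0.017–0.019 for the significant parameters); the config therefore
exposes `dispersion_interpretation` and defaults to `"sem"` (specimen-level
SD = dispersion × √n). Two consequences, by design: under the SEM reading
the specimen-level spread is wide enough that realisability resampling
truncates the tails (drawn group means shift somewhat from the configured
ones), and the printed p-values themselves are not reproducible from
simulation — they depend on the raw data, which is not deposited. The
package's validation is therefore the closed loop (generator truth →
extractor estimate) and the calibration of the statistics, not a
reproduction of the study's p-values.

## What passing tests show — and don't

The generator matches the assumed curve anatomy exactly, so closed-loop
recovery demonstrates the extractor's correctness *given that anatomy*
(including under 1 N Gaussian noise). Real traces can contain features the
generator omits: non-Gaussian or correlated sensor noise, pre-yield
microcracking, multi-stage collapses, compliance of the fixture, partial
unloading. No public raw traces exist for this protocol, so realism beyond
the phase structure is unvalidatable; results on real data should be
spot-checked against the annotated plots (`CompressionTestResults.plot`).

## Numerical notes

* Sliding fits use running sums on shifted coordinates; r² is clipped to
  [0, 1] against cancellation at machine precision.
* Displacement monotonicity tolerates local decreases ≤ 1e-6 mm (sensor
  jitter); force may dip to −1 N at I/O validation (configurable), and the
  analysis entry point relaxes the floor to −6 N to admit noisy toes.
* Smoothing (off by default) is a centred moving average whose window
  shrinks symmetrically at the boundaries — no padding, so no fabricated
  data at the endpoints the endpoint rules inspect; it preserves constants
  and affine ramps exactly.
* Curve CSVs store six decimal places (sub-µN/sub-nm), bounding round-trip
  error at 5e-7 per sample.
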
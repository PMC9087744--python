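# Methods

This note documents the models, conventions, and numerical choices behind
`ictalwave`, and what the synthetic-data tests do and do not demonstrate.

## Signal model and conventions

All band-pass filters are second-order Butterworth applied
forward–backward (`sosfiltfilt`), so phase estimates are undistorted; the
effective magnitude order is doubled. Bands: LFP 4–30 Hz, high-γ
80–150 Hz, multiunit (spike) 300–3000 Hz. LFP and high-γ analyses run on
data decimated to 2 kHz (polyphase FIR anti-aliasing); spike-band
detection runs at the native rate. Phase 0 of an analytic series falls at
the positive peak of the band-passed waveform. The first and last 5% of
samples of any analytic series are flagged unreliable (Hilbert edge
transients). Sample standard deviations (n−1 denominator) are used
throughout.

## Calcium recruitment

ΔF/F is (F − F0)/F0 with F0 the per-cell mean over the preseizure
baseline epoch; traces may be smoothed with a Savitzky–Golay filter
(order 2, window 7; edge frames use the polynomial fit on the truncated
window). The analysis window containing the optical onset is selected
automatically: an 80-frame window opening 5 frames before the first frame
where the population-mean ΔF/F exceeds its baseline mean + 5·SD (manual
override available). The short pre-onset stretch is deliberate: every
pre-onset frame inside the window is an opportunity for a spurious
threshold crossing, and because onset thresholds scale with the baseline
noise, the crossing probability is independent of the noise level — a
long pre-onset stretch would make the recruitment duration threshold-
sensitive no matter how clean the data.

Per cell, the onset threshold is mean + k·SD (default k = 5) of the 25
frames immediately preceding the window; the onset is the first frame in
the window exceeding it. Cells with zero baseline variance are excluded
with a warning (a flat baseline cannot define a threshold). Recruited
cells are ranked by onset frame with average ranks on ties. Recruitment
duration is (last − first onset)/frame rate.

Reliability across seizures: pairwise Spearman r (large-sample p) over
cells recruited in both seizures; Kendall's W (tie-corrected) over cells
recruited in all seizures, re-ranked within that common subset. The
permutation null re-draws each seizure's ranks as a random permutation of
1..max observed rank (when ties compressed the observed range below the
cell count, draws are uniform on 1..max); the p-value uses the
(c+1)/(n+1) convention so it lies in (0, 1].

The onset-direction vector runs from the mean centroid of the
first-recruited (minimum-rank) cells to the mean centroid of the
last-recruited (maximum-rank) cells. The imaging-to-anatomy transform
reflects about the x-axis then rotates 30° counterclockwise; the rotation
is a signed parameter since the appropriate sense depends on the optical
path of a given rig.

## Phase coupling

High-γ events are local maxima of the 80–150 Hz Hilbert amplitude above
mean + 2.5·SD with a one-cycle (1/80 s) refractory period. Multiunit
events are local minima of the spike-band signal below
t = −4·median(|x|/0.6745) (a robust −4 SD threshold) with 1 ms
separation, at sample resolution. Event phases are the 4–30 Hz analytic
phase at the nearest sample; histograms use 18 equal bins on [−π, π).

Circular tests: Watson–Williams (with the 1 + 3/(8κ̂) correction, κ̂ from
the within-sample resultant length) when the pooled concentration
criterion r̄ ≥ 0.45 holds; otherwise Fisher's nonparametric common-median
test supplies the p-value. Single-sample nonuniformity uses the
Hodges–Ajne omnibus test with the exact tail probability
2^(1−n)(n−2m)C(n,m). Nonuniformity of an observed phase sample is the
primary evidence of locking: a two-sample comparison against one drawn
uniform sample is also reported, but when the observed sample is strongly
locked and the null sample's (random) mean direction happens to align
with it, the mean-direction test can fail to reject — a property of the
test, not of the coupling.

## Traveling waves

Per channel, discharge peaks are local maxima of the rectified 4–30 Hz
signal above mean(|x|) + 2·SD(|x|), at most one per oscillation cycle
(1/30 s). Rectification makes detection polarity-free; a flag selects
SD of the signed signal instead. Peaks across channels chain into one
event by single-linkage in time with a 150 ms gap limit; within an event
each channel keeps its largest-amplitude peak (earliest on exact ties),
and events covering ≤60% of functional channels are discarded.

Each event's (x, y, t) points are fitted with t = a·x + b·y + c by
ordinary least squares; direction = atan2(b, a), speed = 1/‖(a, b)‖ (mm/s
and m/s both reported). A gradient norm below 1e−9 s/mm flags a
degenerate (simultaneous) discharge. Speed is an inverse norm, so timing
noise biases it low: with 2 ms jitter on a 4×4, 0.5 mm grid at 500 mm/s
the median recovered speed runs ~10% under the planted value — an
inherent property of the estimator, visible in the acceptance numbers.

Direction distributions are tested per dataset with the omnibus test and
compared between datasets with two-sample Kolmogorov–Smirnov on
directions linearized on (−π, π]; a re-run with the cut at 0 is included
as a sensitivity diagnostic. Early/late speed comparisons use a
two-sided Mann–Whitney U on events in the first and last 25% of the
seizure duration (time-based). With ties the asymptotic p-value without
continuity correction is used so identical distributions give p = 1
exactly.

## Windowed features and the speed model

Features are computed in 4 s windows with 3 s step (1 s overlap; the
step is configurable). Filtering and Hilbert transforms run once on the
whole record so windows are free of filter edge transients; the phase of
the high-γ amplitude envelope is the analytic phase of the mean-removed
envelope (a raw envelope has a DC offset that halves the apparent
modulation phase). Fractional band powers integrate a Hann periodogram
over the band relative to the whole spectrum. Windowing is restricted to
the ictal span (first to last discharge) when features feed epoch
comparisons — pre-seizure windows would otherwise contaminate the early
epoch. Calcium windows take frames with timestamps in [start, end) after
applying the stored clock offset. The per-window target is the median
speed of discharges inside the window; windows without discharges are
excluded from training.

Training balances three seizures to k rows each (k = smallest usable
table, subsampled without replacement). Each ensemble is a bagged forest
of CART trees (variance-reduction splits, minimum leaf 5, unlimited
depth, bootstrap samples of full size) trained with 5-fold cross
validation, keeping the fold-model with the best held-out Pearson r.
CART split selection is used instead of a curvature-test-based unbiased
selector: all ten features are continuous, which is where the two differ
least; surrogate splits are unnecessary (no missing feature values by
construction) and off. Importance is the out-of-bag permuted-predictor
delta squared error per tree, averaged over trees and divided by its SD
over trees. Generalization is the Pearson r between observed and
predicted speeds in a withheld seizure; the top 10% of ensembles form the
"best generalizing" set. Desk-scale defaults are 200 ensembles × 50
trees; the full-scale 1000 × 100 configuration is available by
parameter. Feature evolution rescales each feature per seizure to [0, 1]
(min–max) and compares the first versus last 25% of windows pooled
across seizures with Mann–Whitney U tests.

## Synthetic data

Each discharge is a Gabor wavelet (8 Hz carrier, 40 ms Gaussian σ —
energy inside the 4–30 Hz band) whose envelope peak on channel i is
t_event + (xᵢcosθ + yᵢsinθ)/v plus Gaussian timing jitter; per-event
speeds follow v₀·trendᵏ so trend < 1 models late-seizure slowing.
High-γ bursts (120 Hz carrier, ~30 ms envelope) and 1 ms biphasic spikes
(−6× spike-band noise SD) are placed at times whose *measured* 4–30 Hz
phase equals a von Mises draw: the band's low edge truncates the
wavelet's spectrum, making the measured instantaneous phase advance
~14% faster than the nominal carrier phase, so planted offsets invert
the analytic-phase profile of the band-passed wavelet template rather
than the carrier phase.

Calcium traces are zero-mean noise until a planted onset; onsets spread
uniformly over a configurable span (default 1.2 s, optional
across-seizure span SD) in template order, with optional rank noise
across seizures. After onset, a large recruitment transient plus one
transient per subsequent discharge follow a step-plus-exponential
indicator kernel (rise 0.2 s, decay 1.5 s, GCaMP6s-like). Per-discharge
transient amplitudes scale with (v/v₀)^coupling so imaging features can
carry wave-speed information; high-γ burst amplitude stays flat, giving
a planted negative control for feature-evolution comparisons. Centroids
are laid out so the recruitment template advances along +x, making the
onset-direction vector recoverable. Ground-truth recruitment ranks are
defined at imaging frame resolution with average ties — the indicator
response is zero at the onset instant, so the first observable frame is
the first one strictly after onset, and cells sharing it tie.

All randomness derives from one seed through fixed, named substreams
(LFP noise, event placement, calcium noise, rank perturbation,
centroids), so adding cells does not perturb the LFP and identical
configurations are byte-reproducible.

Standard study conditions used by the tests and the acceptance script:
a 4×4 grid with 0.5 mm pitch, 2 discharges/s, 500 mm/s planted speed,
2 ms jitter, 20 cells at 10 Hz frames, ΔF/F noise SD 0.05; the
"evolving seizure" scenario uses 120 s records, speed trend 0.997 per
discharge (~2× slowing over the seizure) and calcium-speed coupling
exponent 1.5. Model experiments use 4 seizures (3 train, 1 withheld),
200 ensembles × 50 trees. These sizes are the package's desk-scale
reference conditions; all are parameters.

What the generator does not emulate: biophysical waveform diversity,
nonstationary noise, movement artifacts, imaging gaps, indicator
saturation, or non-planar (e.g. spiral) propagation. Passing recovery
tests therefore shows the estimators are correct and calibrated under
the planted model — not that real seizures satisfy that model.

## Numerical notes and limitations

- The Hodges–Ajne exact formula is evaluated in log space and clipped
  to 1; boundary ties from floating-point grids can shift m by one.
- Kendall's W raises on an all-tie matrix (zero denominator).
- Mann–Whitney: all-identical pooled values short-circuit to p = 1.
- Plane fits use `lstsq`; a rank check rejects collinear geometries.
- The speed estimator's small-sample bias (inverse gradient norm) is
  not corrected; medians over events mitigate but do not remove it.
- Watson–Williams assumes von-Mises-like concentration; the automatic
  fallback uses Fisher's common-median test, whose χ² approximation is
  slightly anticonservative at these sample sizes (~6–7% rejection at
  α = 0.05 in the package's own calibration runs).
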
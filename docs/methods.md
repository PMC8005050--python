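# Methods

## Signal model

A head-mounted triaxial accelerometer measures, per body-frame axis
a ∈ {sway, surge, heave}, the sum of the gravity projection for the
current head/neck posture, dynamic acceleration from movement, and sensor
noise. The classifier never sees physical units: both supported loggers
emit unit-free digital counts, and every predictor is either
location/scale-robust (icv, skewness, kurtosis, wm, pitch, roll) or used
comparatively across categories (mean, sd, q).

The synthetic campaign generator makes this model explicit. Each behavior
category c carries a signature

    x_a(t) = s_a(c) + Σ_j A_j sin(2π f_j t + φ_j) + ε_a(t),   ε_a ~ N(0, σ_c²)

with a static gravity projection s_a(c) per axis (head-up feeding loads
−surge, head-down feeding/drinking +surge and reduced heave), optional
sinusoidal components (chewing ≈ 1 Hz for rumination and mid-level
feeding, gait ≈ 1.4 Hz on surge/heave for walking; all < the burst-device
Nyquist of 16.9 Hz) with a random phase per bout, and i.i.d. Gaussian
noise. Behaviors alternate as a renewal process: the next category is
uniform over the other categories (no self-transitions) and bout length is
exponential with a per-behavior mean. The ethogram returned with each
stream is exact, which lets the labeling and purity-filter stages be
tested against ground truth.

### Default campaign

Three individuals, 24 000 s each, eight analyzed categories (STA, FEA,
FTM, FED, FEG, RUM, DRI, WAL) plus the STA_STILL calibration reference
(same posture as STA, σ = 0.01 g). Noise is σ = 0.05 g (0.07 g for
walking), and every pair of categories is separated by ≥ 0.15 g = 3σ in at
least one static axis component; RUM/FTM and FEG/DRI are deliberately the
closest pairs, mirroring which real behaviors are confusable. Dwell means
are 20–60 s per behavior. The session length is chosen so that after
purity filtering every category comfortably clears the n ≥ 30 per-animal
subsampling gate on both devices under any seed; with ~40 s mean dwell
this needs several hours of observation per animal, which matches a
multi-day observation campaign.

These defaults make the classification problem *cleanly separable by
construction*: passing validation at ≈ 100 % accuracy demonstrates that
the pipeline machinery (labeling, calibration, features, fold
bookkeeping) is correct, not that field data would classify that well.
Real recordings add posture overlap within categories, non-stationary
noise, and observer timing error, none of which the generator emulates;
the confusability experiment (see Validation) is the generator's handle
for studying the degraded regime.

## Device rendering

The physical truth signal is sampled once at the burst-device master rate
(33.8 Hz). Burst-mode rendering takes an 82-sample window every 20 s
(exactly 676 master samples, so windows align without interpolation),
applies counts = 2048 + 512·g, rounds to integer and clips into [0, 4095].
Continuous-mode rendering takes the nearest master sample at each whole
second, applies counts = 8192·g clipped into [−32 000, 32 000], and
deletes dropout seconds (explicit intervals and/or an i.i.d. drop rate).
The affine constants are a simulator convention — the loggers are
unit-free, so any fixed documented affine yields the same classifier
behavior; 512 counts/g gives the burst device a ±4 g full scale, 8192
counts/g about ±3.9 g. Quantization error is at most half a count.
Rendered files use each device's raw axis order (burst device x = heave,
y = sway, z = surge; continuous device x = surge, y = sway, z = heave) so
synthetic exports look like real ones.

## Labeling conventions

Ethogram intervals are half-open [start, end); a window is inside an
interval iff every sample timestamp is. A window touching two or more
behaviors is MIXED; one touching unobserved time is UNLABELED; both are
excluded by the purity filter. Boundary seconds therefore belong to the
later behavior — the choice is arbitrary but fixed and documented.
Continuous sections shorter than 5 samples are discarded at the filter
stage: sd/skewness/kurtosis are meaningless below ~4 points and 5 adds a
margin. Clocks are assumed synchronized (the protocol in the emulated
study used a radio-controlled clock); no tolerance slack is applied.

## Calibration

Attachment differences shift the static gravity projection. The
correction is additive per axis: all of an individual's values are shifted
by the difference between the reference individual's and its own mean
during STA_STILL. Requiring an annotated micro-behavior (rather than
inferring stillness from the signal) keeps the step faithful to observer
practice and trivially auditable. Harmonized values may leave the integer
encoding range and are kept as reals — re-clipping would distort moments.
The correction is idempotent, leaves sd/skewness/kurtosis/wm exactly
invariant, and moves per-axis means by exactly the applied delta. The
reference animal is explicit and configurable (pipeline default: the
alphabetically first individual with reference bursts).

## Features

Per axis: arithmetic mean; sample sd (n−1); icv = mean/sd; excess
kurtosis and skewness as plain moment estimators (no small-sample bias
correction; Gaussian ⇒ 0 kurtosis); and, for fixed-length bursts only,
wm = Σ f_k A_k / Σ A_k over the positive-frequency DFT bins of the
mean-removed signal, magnitude-weighted, DC excluded (including DC would
duplicate the mean; on variable-length sections wm tracks section length,
so the continuous device drops it, leaving 18 predictors instead of 21).

Combined: q is the burst mean of the per-sample Euclidean norm (not the
norm of the means — the two differ by Jensen's inequality, which the test
suite checks as a strict lower bound); pitch = atan2(−surge̅,
√(sway̅² + heave̅²)) and roll = atan2(sway̅, heave̅) from per-axis means
under the static-gravity convention, in radians. Orientation features are
computed after subtracting the device's zero-g count (2048 for the burst
device, 0 for the continuous one) so both devices share one formula;
moment features stay on the raw/harmonized count scale.

Degenerate inputs yield sentinels instead of NaN/inf so tree models can
split on them: zero-sd icv → ±1e9 (signed by the mean), zero-sd
skew/kurt → 0, flat-spectrum wm → 0 Hz (outside the valid (0, Nyquist]
band).

## Validation

Random Forest with 500 trees, √p features per split, unlimited depth (the
defaults of the R package the emulated analysis used; the hyperparameters
were not reported, so these are the closest faithful reconstruction).
Sentinel feature values pass through untouched. Leave-one-burst-out seeds
fold i with base_seed + i, making the prediction multiset reproducible
and row-order invariant. Cross-individual validation trains on the union
of the other animals' rows; test categories absent from training are
reported as untrainable. Fold bookkeeping guarantees test rows never
enter training.

Reported metrics are per-category one-vs-rest accuracy (TN included — by
construction larger than the global fraction-correct), precision and
recall, with overall values as unweighted means over categories with
defined metrics; undefined ratios (zero denominators) are excluded. The
device comparison is a classical paired t on per-category accuracy
differences (df = n−1), with both two- and one-sided p-values; a zero-sd
difference vector yields t = 0 (zero mean) or ±∞ (constant non-zero
difference), documented sentinels rather than errors.

Demonstration and acceptance runs use 200-tree forests and n = 30 per
category per animal (40 is also common for richer datasets); forest
accuracy on these problem sizes saturates far below 200 trees, and the
library default stays 500.

Two structural experiments ship with the package:

* **Calibration value.** With per-individual attachment offsets of ~0.2 g
  (≈ 10–15° of harness tilt, `EXAMPLE_ATTACHMENT_OFFSETS`) and no
  calibration, cross-individual accuracy collapses (the static-posture
  features carry most of the class signal); harmonization restores it.
* **Confusability.** Setting RUM's signature identical to FTM's drives
  those two categories' recall toward the 50 % pairwise-chance level
  while all other categories stay at ceiling — the degradation is local
  to the overlapping pair, which is the qualitative confusion structure
  observed on real giraffes.

## Numerical choices and edge cases

* Timestamps: UTC epoch seconds internally, ISO-8601 on disk.
* Ingest bounds: out-of-range raw values are hard dialect errors
  (clipping exists only inside the simulator).
* Subsampling: without replacement, per category and animal, seeded
  generator recorded in provenance; input-order invariant (candidates are
  sorted before drawing).
* Paired t: implemented in closed form; verified against an independent
  statistical library implementation at 1e-10 in the test suite.
* All moment features verified against from-the-definition oracles at
  1e-10 relative tolerance; wm against a DFT-by-definition oracle.

## Known limitations

* The generator's bout process has no time-of-day structure, no
  behavior-dependent transition matrix, and no within-bout
  non-stationarity.
* Static signatures are single postures per category; real categories
  (e.g. STA with head scanning) are posture mixtures, the main source of
  real-world confusion.
* Calibration is additive only; a genuinely rotated attachment would
  need a rotation-matrix correction that is out of scope.
* The continuous device's 1 Hz sampling aliases chewing/gait frequencies;
  the pipeline (like the emulated analysis) relies on variance rather
  than spectral location for those behaviors on that device.
* Variable-time segmentation of unlabeled streams (detecting behavior
  boundaries from the signal itself) is explicitly not implemented.
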
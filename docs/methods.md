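# Methods

`eegnld` implements a nonlinear-dynamics biomarker pipeline for infant
resting-state EEG: dyadic wavelet band decomposition, nine nonlinear
invariant measures per sensor and band, and a leave-one-out SVM
protocol that predicts a binary diagnostic outcome and a continuous
symptom-severity score from the signed distance to the separating
surface.  Because the clinical recordings such pipelines are built for
are generally not shareable, the package ships a synthetic-cohort
generator that reproduces the statistical structure the analysis
assumes, and every stage is tested against that generator and against
independent brute-force oracles.

## Ingest

Recordings arrive as EDF (a fixed-width ASCII header plus int16 data
records).  The reader returns microvolt samples and rejects files with
mixed per-channel sampling rates; truncated files fail with the index
of the first incomplete record.  Analysis uses the 19 sensors of the
standard 10-20 montage, in a fixed order that defines feature indexing
(`Fp1 ... O2`).  High-density nets are reduced by exact label match or
an explicit alias table; there is deliberately no nearest-sensor
guessing.  500 Hz recordings are zero-phase low-pass filtered
(8th-order Butterworth at 100 Hz, 0.8x the target Nyquist) and
decimated by two; 250 Hz input passes through untouched.  The analysis
segment is the first 30 s of the recording — no splicing or
review-based selection — with an optional start offset for recordings
whose opening seconds are unusable.  No software band-pass filtering is
applied beyond the decomposition itself.

## Band decomposition

Each channel is decomposed into six power-of-two frequency bands: the
detail series of a 6-level Daubechies-4 discrete wavelet transform,
each reconstructed alone back to full signal length so that the
nonlinear measures see equal-length series in every band.  Level k
nominally covers the octave (fs/2^(k+1), fs/2^k]; at 250 Hz the bands
are labeled high gamma (62.5-125 Hz), gamma, beta, alpha, theta, and
delta (1.95-3.9 Hz, with everything below folded in).  The labels name
dyadic octaves, not literal clinical band edges.

The transform uses periodization boundary handling, which keeps it
orthogonal and exactly invertible: the six details plus the level-6
approximation sum to the input to machine precision, and squared norms
add up (Parseval) for lengths divisible by 2^6.  Inputs of other
lengths are edge-padded internally and trimmed after reconstruction.
We chose periodization over symmetric extension because orthogonality
is what makes the energy bookkeeping exact; on 30-s segments the
wrap-around transient is negligible.

Block-average coarse-graining (the classic multiscale-entropy scaling
step) is provided alongside with its Haar equivalence: with averaging
normalization, iterated pairwise means equal block means exactly at
every power-of-two scale; the orthonormal (a+b)/sqrt(2) variant is
available behind a flag but differs from coarse-graining by 2^(level/2).

## Nonlinear measures

Nine scalars per sensor/band cell, in fixed order
(RR, DET, LAM, L_max, L_entr, L_mean, TT, SampE, DFA):

* **RQA.** The band series is delay-embedded (dimension 3, delay 1) and
  thresholded at epsilon = 0.2 x the series SD under the max norm.  The
  line of identity is excluded (Theiler window 1).  RR is the recurrent
  fraction of off-diagonal cells; DET and LAM are the fractions of
  recurrence points on diagonal / vertical lines of length >= 2; L_max,
  L_mean, and L_entr (Shannon entropy, nats) summarize the diagonal
  line-length distribution at l >= 2, and TT is the mean vertical line
  length at v >= 2.  Embedding parameters and minimum line lengths are
  configurable and recorded in each result's settings block.
* **Sample entropy.** -ln(A/B) with template length m=2 and tolerance
  r=0.2 x SD, Chebyshev distance, self-matches excluded.
* **DFA.** First-order detrended fluctuation analysis over 8 log-spaced
  box sizes from 16 to N/4; the exponent estimates the Hurst parameter
  of fractional Gaussian noise.

Two RQA code paths exist on purpose: an explicit-matrix path used for
small inputs and validated against a brute-force run-enumeration oracle
(agreement to 1e-10 on random plots), and a streaming numba kernel that
never materializes the O(N^2) matrix; the two are tested to agree
exactly.  Sample entropy is validated against a naive O(N^2) counting
oracle, and DFA against exact fractional Gaussian noise (circulant
embedding): mean absolute error <= 0.07 at H in {0.3, 0.5, 0.8},
N = 7500.

Recurrence computation is quadratic in series length and is the cost
driver of a full-cohort extraction, so by default it runs on the first
2000 embedded points (8 s at 250 Hz) of each band series; sample
entropy and DFA always use the full series.  The window length is a
setting (`NLDSettings.rqa_max_points`) and is recorded in the output.

Degenerate cells — zero-variance bands (e.g. a flat channel), no
template matches, no qualifying lines — yield NaN sentinels or zeros as
documented rather than raising, so one pathological band cannot abort a
1026-feature extraction.  Sentinels are median-imputed at model-fitting
time with training-fold statistics only.

## Feature vectors

19 sensors x 6 bands x 9 measures = 1026 named features per session,
sensor-major, names `<sensor>.<band>.<measure>`.  Two visits of one
subject can be concatenated into a 2052-feature vector with age
prefixes (`age6.`, `age9.`); only subjects with both visits enter such
an analysis.  Cohort tables serialize to CSV with full precision
(`float_format="%.17g"` round-trips float64 exactly).

## Classification and severity

Training uses the two endpoint outcome groups: diagnosed ASD and
low-risk controls without ASD.  Under leave-one-out cross-validation
each endpoint subject is scored by a model trained on all other
endpoint subjects; intermediate high-risk (no diagnosis) subjects are
scored by the model trained on the full endpoint set.  Visits at
different ages are treated as independent encounters (one age per
call).

Per fold: median imputation, z-scoring, recursive feature elimination,
and an RBF-kernel SVM (stock hyperparameters), all fit on the training
fold only.  Elimination needs per-feature weights that an RBF kernel
does not expose, so ranking uses a linear-kernel SVM and the RBF model
is refit on the surviving subset — the only composition consistent with
pairing RFE with an RBF classifier.  The default elimination keeps 20
features in halving steps (a cross-validated variant that picks the
count itself is available via `rfe_select(cv=...)`); the fixed-size
default keeps the leave-one-out-times-permutation cost tractable.

The signed decision distance (positive on the ASD side) is mapped to
the 1-10 calibrated severity scale by a least-squares affine fit of
training severities on training distances, clipped to [1, 10]; a
min-max variant ships behind a flag.  Estimates strictly inside
(3.5, 4.5) — a half-point either side of the diagnostic cutoff at 4 —
are labeled "uncertain" when the three-way mode is on; binary mode
applies the cutoff at 4 directly, which also resolves exact ties at the
decision surface consistently with the severity path.  Sensitivity,
specificity, and PPV use standard definitions with ASD positive;
uncertain predictions are counted and excluded (or, optionally, kept as
non-ASD calls).  Zero denominators give NaN, not exceptions.

Significance is an empirical permutation test: the leave-one-out
accuracy (binary cutoff) is compared with 100 re-runs of the identical
pipeline under permuted outcome labels (group and severity permuted
together), with the add-one estimator p = (1 + #extreme) / (1 + trials),
which never reports exactly zero — with 100 trials the floor is ~0.0099.

## Group analyses

Difference maps test one measure in all 114 sensor/band cells between
two groups.  Default is Welch's unequal-variance t-test (Mann-Whitney
behind a flag); a cell is flagged at the strict Bonferroni gate
p < 5e-5, i.e. 0.05 over 1026 features treated as independent, stored
as the literal constant.  Direction is the sign of the ASD-minus-
comparison mean.  Cells degenerate in both groups report p = 1.

Regional trajectories average a measure over a sensor region and band
subset within subject, then across subjects per age, with 95%
percentile-bootstrap bands (2000 resamples, seeded).  Region presets
cover left temporal {T7}, right temporal-parietal {T8, P4, P8}, left
lateral-frontal {F7}, posterior {O1, O2}, and two frontal sets (five-
and six-sensor variants, since both appear in published regional
analyses and the choice is indeterminate); band presets are beta+gamma,
theta-through-gamma, and delta.

## Synthetic cohorts

Each channel is fractional Gaussian noise (exact circulant-embedding
generator; Hurst parameter 0.55 plus 0.12 x effect_size x group code)
plus a 10 Hz background rhythm with slowly drifting phase.  Designated
sensor/band cells — temporal/parietal beta+gamma (T7, T8, P4, P8) and
occipital delta (O1, O2), configurable — carry an additional
fixed-frequency tone whose amplitude grows linearly with the severity
score: a = effect_size x (1.2 + 2.8 x (css-1)/9) noise-SD units.  More
tone means a more regular band: determinism rises and sample entropy
falls monotonically with severity, the contrast every downstream stage
is built to detect.

Two numerical choices matter here.  First, tone periods are chosen
commensurate with the 2^6 dyadic grid (12, 6, and 96 samples; least
common multiple with 64 is 192), so the wavelet detail of a tone is
itself strictly periodic — an incommensurate tone's detail is
quasi-periodic and measurably *more* complex, which would invert the
intended effect.  Second, the tone is already dominant in its band at
the lowest severity: a weak-tone mixture is less regular than noise
alone, so sweeping amplitude from zero would make the severity effect
non-monotone in the middle.  Severity therefore moves the band from
"mostly periodic" to "almost purely periodic".

Severity scores are drawn per subject from overlapping uniform ranges —
controls U[1, 2.5], high-risk-no-ASD U[1, 5] (intermediate), ASD
U[4, 10] (diagnosis requires 4 or higher) — and held constant across
visit ages.  All group and severity dependence is multiplied by
`effect_size`, so a zero-effect cohort is exchangeable across groups
(the null case; verified at the ~nominal false-positive rate over 200
simulated cohorts).  An optional age shift inverts the severity mapping
at and after 12 months, flipping the group contrast sign for late
visits; it is off by default.  Cohorts are bit-reproducible from
(spec, seed), including after EDF serialization.

What the generator does *not* emulate: volume conduction and sensor
covariance, blink/muscle/movement artifacts, 1/f spectral shape beyond
fGn, realistic within-group heterogeneity of band power, or any
particular real cohort's group sizes.  Passing tests therefore show
that the pipeline detects the kind of severity-linked
regularity/entropy structure it assumes, at synthetic
signal-to-noise — not that any particular clinical accuracy would be
attained on real infant EEG.  Within-group feature variance in real
data is unknown; the generator's noise scales are stated choices, not
calibrated claims.

## Problem sizes and tolerances

End-to-end protocol checks run on a 20+20-subject endpoint cohort (plus
6 intermediate-risk subjects) at the full 19-channel, 250 Hz, 30-s
session format, with 100-permutation significance; null-calibration
repeats use smaller, shorter cohorts (4+4 subjects, 5-s sessions, 20
repeats) since the null property is independent of scale.  Oracle
agreement is asserted at 1e-10 (RQA) and relative 1e-12 (sample
entropy); the coarse-grain/Haar identity at 1e-12; DFA calibration at
mean absolute error 0.07; reconstruction and energy identities at 1e-8
relative.

## Known limitations

* Embedding parameters (m=3, tau=1, eps=0.2 SD) and minimum line
  lengths are field-standard defaults, not optimized per band; fixed
  radius, not fixed recurrence rate.  Results can differ materially
  under a fixed-RR convention, so the convention is recorded in every
  output.
* The RQA window (2000 points) trades diagonal-line tail mass for
  tractability; L_max in particular is bounded by the window.
* The full-band (undecomposed) signal is excluded from the feature set
  by default.
* EDF support covers uniform-rate EDF/EDF+ signals only; no annotation
  channels.
* Growth-trajectory modeling beyond per-age averaging (and the two-age
  feature concatenation) is out of scope.
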
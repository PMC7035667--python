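# Methods

## Scope and model

synovaquant quantifies knee-joint synovitis from MRI along four axes:
heuristic (semiquantitative) DCE-MRI perfusion parameters, an ordinal
whole-knee scoring instrument, paired contrast-enhanced vs. FLAIR
volumetry, and two-reader agreement statistics. It deliberately avoids
pharmacokinetic DCE modelling (no Tofts parameters, no arterial input
function): the five curve descriptors are robust, simple to compute in
a clinical workflow, and defined directly on the sampled
time–intensity curve.

## DCE parameter definitions and numerical choices

A time–intensity curve (TIC) is the arithmetic mean of voxel
intensities inside an ROI at each frame; frames are assumed motion- and
registration-corrected upstream. On a TIC with samples (tₖ, Sₖ):

- **S₀** — mean of the first `n_baseline_frames` samples, default 1.
  The emulated protocol starts the contrast injection just before the
  first measurement, so only frame 0 is reliably pre-contrast. The
  window is configurable for protocols with a longer baseline.
- **Wash-in / wash-out** — ordinary least-squares slope of S on t over
  the initial/final 30 s window, × 60 to convert to a.u./min. An OLS
  fit, not an endpoint difference quotient, because at 9.8 s spacing a
  30 s window holds 4 samples and "average slope" is then best read as
  a fit; an `endpoint` mode exists for sensitivity checks. Window
  membership is closed on both ends and no sample is interpolated onto
  the exact window boundary (samples at 9.8 s spacing never land on
  30 s or 60 s), which keeps results reproducible without resampling.
  An exactly flat window short-circuits to slope 0 so constant curves
  obey the null contract without floating-point residue.
- **TTP** — time from acquisition start to the first frame attaining
  the maximum signal (ties resolve early). Always reported in seconds.
- **PE** — (S_max − S₀)/S₀, requiring S₀ > 0.
- **iAUC** — trapezoidal integral of (S − S₀) over samples within 60 s
  of the first frame, divided by 60 → a.u.·min. Negative excursions
  are kept by default so the integral is linear in the enhancement
  signal (and a pure-baseline curve integrates to exactly 0); a
  clip-at-zero option exists. No extrapolation beyond the last
  in-window sample.

Voxelwise iAUC maps apply the same formula per voxel with a per-voxel
S₀; voxels outside an optional mask are set to NaN (the NIfTI missing
value) and the count is logged.

Patient-level summaries report per-parameter mean and SD (n−1 denominator)
over an explicit ROI inclusion set. Whether a patient summary pools all
five protocol ROIs or only the three synovial ones is a reporting
choice the data cannot arbitrate, so the inclusion set is a required,
recorded argument rather than a default.

## Scoring instrument

Eleven sites graded 0–3: nine mandatory (medial/lateral peripatellar,
suprapatellar, infrapatellar, intercondylar, medial/lateral
perimeniscal, ACL- and PCL-adjacent) and two optional (Baker's cyst,
loose bodies) that contribute 0 when absent, giving a summed score of
0–33 banded as 0–5 normal or equivocal, 6–9 mild, 10–13 moderate, ≥14
severe (all boundaries inclusive as printed). The thickness rule fixes
the upper grades (>5 mm → 3, >4 and ≤5 mm → 2); the 0/1 boundary is not
part of the instrument's definition, so it is a configurable parameter
(default 2 mm, flagged as a package choice) that callers should echo in
reports. Raising any single site grade can only raise the summed score
and its severity band; this monotonicity is property-tested.

## Volumetry and the paired comparison

Volume is foreground-voxel count × voxel volume (mm³)/1000, with true
anisotropic spacing (e.g. 0.36 × 0.36 × 2.5 mm). Slice-range selection
(superior → inferior patellar pole) is the segmenter's responsibility;
masks are consumed as given. The paired analysis reports per-patient
percent differences with the **FLAIR volume as denominator** — chosen
because only this convention reproduces the published 18.6% mean from
the per-patient volumes (the CE-denominator variant gives ≈15.2% and is
also reported) — their mean and SD (n−1), Pearson's r on the raw paired
volumes, and a two-sided paired t-test with df = n−1. No normality
pre-test gates the t-test. Degenerate inputs: identical paired lists
yield t = 0 and all-zero percent differences; a constant series makes r
undefined (NaN with a warning).

## Agreement statistics

- **Weighted kappa** (ordinal, two readers): κ = 1 − Σw·O / Σw·E with
  linear weights |i−j|/(k−1) by default (quadratic available; the
  scheme is always carried in the result metadata). The published study
  does not state its weighting, so no kappa point value is treated as
  reproducible. CI: seeded percentile bootstrap over items, 2000
  replicates by default. The point estimate is delegated to
  scikit-learn's `cohen_kappa_score`; an independent contingency-table
  implementation serves as the oracle in the test suite.
- **ICC** (continuous, two readers): computed from the one- or two-way
  mean-squares decomposition; default form is two-way random effects,
  absolute agreement, single measures — the form in which systematic
  reader offsets count as disagreement, per the usual guidance for
  inter-rater designs. 95% CIs use the standard F-distribution
  intervals (Satterthwaite degrees of freedom for the
  absolute-agreement form). The estimate and CI are computed in-house
  because the available reference implementation rounds its CI bounds
  to two decimals, which can violate the `ci_low ≤ estimate ≤ ci_high`
  contract; that implementation (pingouin) is instead the oracle the
  tests compare against. Absolute agreement is bounded above by the
  consistency form whenever the rater mean square exceeds the residual
  mean square — i.e. in the presence of a systematic reader offset —
  and the property test constructs exactly that regime, since the
  inequality can invert when the rater effect is weaker than noise.
- **Verbal bands**: Landis–Koch for kappa (≤0 poor, then slight, fair,
  moderate, substantial, almost perfect in 0.2 steps, upper edges
  inclusive); Koo for ICC (<0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good,
  ≥0.9 excellent, half-open upward — so 0.90 is excellent and 0.75 is
  good, consistent with the published tally in which 0.91 counts as
  excellent and 0.88 as good).

Both statistics are undefined (NaN plus a warning, never a silent
number) when their variance denominators vanish: kappa when both
readers use a single identical category, ICC when all ratings are
identical.

## The digital phantom

The phantom emulates the study conditions every stage is meant to face:
a 22-frame dynamic series at 9.8 s intervals (200 s total), with
compartments for synovium, artery, muscle, effusion and background laid
out as slabs on a configurable grid (default 32 × 32 × 16 voxels of
1.1 mm³, matching the dynamic sequence's isotropic resolution).

- **Kinetics**: each compartment follows a three-segment
  piecewise-linear curve (flat baseline until arrival, linear uptake to
  the peak, linear late phase that may wash out). This matches the
  qualitative morphology of synovial enhancement — steep uptake between
  roughly 20 and 40 s, then continued slower enhancement — while
  keeping all five truth parameters closed-form. Truth values are the
  estimator formulas applied to the noiseless curve sampled at the
  frame times, so the noiseless-recovery test exercises the voxel
  pipeline (4D assembly → ROI mean → estimators), not the curve
  algebra alone.
- **Signal scale**: no published raw signal ranges exist for these
  tissues, so baselines are arbitrary units (synovium 100 a.u.) chosen
  to give enhancement ratios of the order seen in inflamed synovium
  (PE ≈ 1.6 for the default synovium).
- **Noise**: additive Gaussian by default (downstream metrics act on
  ROI means, where Gaussian is adequate); a Rician magnitude model is a
  config switch. Default noise SD in noisy tests is 2 a.u. = 2% of the
  synovial baseline. Negative post-noise signals are clipped at zero
  and counted in a warning log. All randomness flows from one explicit
  seed per call; identical seeds give bit-identical volumes.
- **Mask pairing**: the FLAIR-like mask is derived from the CE mask by
  iterative 6-connectivity morphological erosion followed by removal of
  individual boundary voxels in lexicographic order, stopping at
  round(ratio·N) voxels — deterministic, always a voxelwise subset, and
  the achieved ratio is reported (with a warning whenever it cannot
  equal the target exactly).
- **Reader simulation**: reader 2 deviates from the true grades
  item-wise with a set probability, by one step in a uniform direction,
  stepping inward at the scale boundaries so a drawn disagreement
  always changes the grade (a plain clamp would silently cancel half
  the disagreements at grades 0 and 3).

What the phantom does *not* emulate: anatomy (no bone or cartilage),
MRI physics (relaxivity, B1, fat suppression, k-space), partial-volume
mixtures at compartment borders, motion, and temporally correlated
noise. Passing the recovery tests therefore shows the estimators are
correct and unbiased under the stated noise model — not that they are
robust to motion or segmentation error in clinical data.

## The packaged study table

The fixture stores the published per-patient rows of a 10-patient 7 T
feasibility cohort (ordinal scores, volumes, DCE parameter means ± SD)
and the 10 published kappa and 14 ICC estimates, as two CSVs verified
by SHA-256 at load. Headline reproduction routes the stored values
through the same scoring/volumetry/reliability code paths used for new
data. Known limits of that table, handled explicitly:

- The whole-knee summed-score row is stored with a
  `parse_confidence = reconstructed` flag, and per-patient severity
  labels are not asserted: one patient's printed label (sum 9,
  "moderate") contradicts the printed 6–9 = mild rule, so the package
  reports the rule-based banding (4 mild / 4 moderate / 2 severe)
  alongside the published label tally (3/5/2).
- TTP is stored exactly as printed but excluded from headline
  reproduction: the table's TTP scale (≈0.6–1.3) is inconsistent with
  the text's "92 ± 45 s" and its unit is unstated.
- Published kappa/ICC point values are carried as data, never
  recomputed — the raw two-reader scores are unpublished.
- The published SD of the percent volume difference (9.5%) differs from
  the value recomputed from the rounded per-patient volumes (≈10.0%);
  the mean is the reproducible quantity, the SD is reported but not
  asserted. Likewise the cohort means of wash-out and PE printed in the
  source (0.20, 2.55) do not equal the means of its ten per-patient
  values (0.193, 2.445); the per-patient means are what the package
  reports.

## Problem sizes

Tests and the acceptance script run on deliberately small phantoms
(grids of order 10–20 voxels per axis, 22 frames) and replicate counts
of 100–200 for the stochastic recovery checks; these sizes give the
quoted statistical bounds (3 SE unbiasedness, ±0.05 ICC recovery at
n = 500 items) comfortable margins while keeping the whole suite in a
few seconds.
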
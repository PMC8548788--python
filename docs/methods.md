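# Methods

This note documents the models and numerical choices behind `herbqc`: what
the synthetic study generator emulates, how each analysis stage is defined,
and where the design was genuinely open.

## The measurement model

A batch of dried herbal material is extracted (mass `m` grams into volume
`V` ml; default 1 g / 30 ml) and injected into an HPLC with UV detection at
254 nm. A compound present at content `w` mg/g reaches the detector at
concentration `x = 1000·w·m/V` µg/ml and produces a peak whose area (mAU·min)
follows the compound's calibration line

    A = a·x + b

with per-compound slope `a`, intercept `b` and a stated linear range. The
packaged calibration table carries the six quantified phenolics
(chlorogenic acid, caffeic acid, p-coumaric acid, cichoric acid, luteolin,
apigenin); cichoric acid is the single marker.

Quantification routes:

* **ESM** (external standard method) inverts each compound's own line:
  `x = (A − b)/a`, then `w = x·V/(1000·m)`. A negative implied
  concentration is clipped to 0 and flagged; concentrations outside the
  linear range are flagged as extrapolations.
* **QAMS** (single-marker method) uses the relative correction factor
  `f_si = f_s/f_i`, the ratio of response factors `f = A/C` measured from
  standard solutions, and derives every analyte from the marker peak of
  the same injection:

      C_i = f_si · C_s · A_i / A_s        (concentrations in mg/ml)

  where `C_s` is the marker concentration in the extract, itself measured
  by ESM from the marker's own curve.

### Exactness of the single-marker equation

The QAMS working equation is exact precisely when detector response is
proportional (`b = 0`): then `f_si = a_s/a_i` and the areas cancel to give
`C_i` identically equal to the ESM value — even under per-peak
multiplicative noise, because the marker area appears in both `C_s` and the
denominator and cancels. With affine curves the equation inherits a
concentration-dependent bias of order `b_i/(a_i·x_i) − b_i/(a_i·x_cal)`,
which at trace contents (tens of µg/ml against intercepts of ±50 area
units) reaches tens of percent. This is a property of the method, not of
the implementation; it is why measured correction factors in practice
differ from calibration slope ratios. Consequently:

* the generator's default detector truth is the affine calibration table
  (faithful to the published curves), and
* `StudyDesign.proportional_response()` zeroes the intercepts to provide
  the regime in which QAMS-vs-ESM consistency is a meaningful test. The
  method-agreement properties (QAMS = ESM at zero noise; |RE| < 5% for
  ≥ 95% of cells at 2% detector noise) are evaluated there.

Relative correction factors are measured at the mixed-standard level
(0.167 mg/ml per compound, 0.083 mg/ml for apigenin) over a 3 × 3 grid of
flow rates (0.6/0.8/1.0 ml/min) and column temperatures (30/35/40 °C) and
averaged; the detector model is condition-independent, so the grid spread
reflects only injection noise, mirroring the sub-percent RSDs expected of a
robust factor.

## The synthetic study generator

`synthetic_data` emulates a 15-batch study with 10 common peaks: the six
quantified compounds plus four unidentified peaks that have no standards.

* **Retention times** are fixed design constants spread over 3.2–23.4 min
  with ≥ 0.8 min spacing (elution order follows the common-peak numbering,
  with the unidentified peaks at positions 1, 3, 5 and 6). They are
  generator parameters, not measured values.
* **Peak shape**: Gaussian with sd 0.08 min for every peak — a realistic
  analytical width that makes the closed-form area `h·σ·√(2π)` available
  to tests. The time grid is 0–27 min at 0.004 min.
* **Contents** are drawn uniformly within each compound's observed
  min–max range from the packaged 15-batch content table (cichoric acid
  2.856–15.453 mg/g, etc.). An optional `groups=k` mode plants k distinct
  content profiles (centres spread across each range, ±5% jitter) to give
  the chemometric stages a known cluster structure.
* **Unidentified peaks** get a fixed response factor and nominal
  concentration, scaled per batch by a uniform ±30% factor.
* **Noise**: per-peak multiplicative detector noise (default cv 2%) and a
  low-order polynomial baseline drift (default amplitude 1 mAU). Negative
  predicted areas (possible below the linear range when `b < 0`) are
  clipped to 0 and flagged `clipped`; a zero content emits no peak.
* All generation is a pure function of (design, seed); study-level
  randomness flows from one root seed through named substreams.

What the generator does **not** model — and therefore what passing tests do
not establish about real data: gradient-elution physics, peak tailing or
asymmetry, co-elution and deconvolution, detector saturation, retention
drift between runs, matrix interferences, and extraction chemistry.

## Signal processing

* **Baseline**: the trace is split into 20 windows; in each, the anchor is
  the grid point at the 10th intensity percentile (a low quantile sits on
  the baseline while peaks occupy < 90% of a window). Anchors are joined
  by piecewise-linear interpolation, extrapolated linearly at the edges,
  and subtracted. Flat offsets and linear ramps vanish identically;
  smooth polynomial drift leaves a residual bounded by the window-width
  interpolation error.
* **Detection**: local maxima above height/prominence thresholds
  (scipy `find_peaks`; defaults 0.5–1 mAU at study scale). Peak bounds
  are placed where the signal falls below 0.1% of peak height or at the
  nearest valley; with ≥ 0.8 min spacing and σ = 0.08 min this captures
  > 99.97% of a Gaussian's area.
* **Integration**: trapezoidal, minus the chord between the bound
  endpoints (local linear baseline), clipped at zero. Against a 10×-finer
  oracle the error is well under 0.5%; the bound truncation contributes a
  systematic ≈ 0.3% loss, comfortably inside the 2% round-trip budget.
* **Matching**: each reference retention time claims the nearest unclaimed
  peak within 0.2 min (greedy by distance; ties break toward the earlier
  reference, deterministically). The tolerance is large against the grid
  step and small against the designed spacing.
* **Common peaks** are reference positions matched in 100% of samples
  (configurable fraction). Quantification deliberately does not use the
  strict common-peak table: it works from a per-sample matched-area matrix
  so that a peak absent in one batch (e.g. clipped at trace content)
  yields a flagged zero for that cell instead of discarding the compound
  everywhere.

## Fingerprint similarity

Batches are compared on full baseline-corrected traces resampled to the
intersection of their time spans at 0.01 min — below the peak width, small
enough to keep vectors light. The default statistic is the congruence
(cosine) coefficient `Σxy/(‖x‖‖y‖)`; Pearson (centred cosine) is an option,
since similarity software conventions differ and neither reading is
asserted as canonical. The reference profile is a designated good batch
(S15 by default) or the point-wise mean. Similarity is scale-invariant,
equals 1 for replicates, decreases in expectation with added noise, and
batches below 0.82 are flagged.

## Chemometrics

* **HCA** comes in the two modes used in practice: a heatmap-style mode
  (per-feature z-scores, distance 1 − Pearson between batch profiles,
  average linkage — constant profiles are rejected as undefined) and a
  squared-Euclidean mode on raw contents with between-groups (average)
  linkage. Both delegate the merge loop to scipy's linkage with its
  deterministic index-order tie-breaking.
* **Adequacy**: KMO = Σr²/(Σr² + Σq²) over off-diagonal elements, with
  anti-image partial correlations `q_ij = −s_ij/√(s_ii s_jj)` from the
  inverse correlation matrix (singular matrices raise rather than return
  an unstable number; p = 2 gives exactly 0.5). Bartlett's sphericity:
  `χ² = −(n − 1 − (2p+5)/6)·ln det R`, df = p(p−1)/2.
* **Factor extraction** is principal-component based: eigendecomposition
  of the correlation matrix, loadings = eigenvector·√λ, retaining λ > 0.8
  (the study's stated rule; the Kaiser λ > 1 rule is a parameter away).
* **Varimax** maximises the variance of squared loadings with Kaiser row
  normalization (SVD-based sweeps, tolerance 1e-8, ≤ 100 iterations).
  Communalities are preserved to machine precision. Determinism across
  platforms is imposed by ordering rotated factors by explained variance
  and signing each column so its largest-|loading| element is positive.
  The implementation reproduces R's `stats::varimax` to ~1e-5 on frozen
  test matrices.
* **Scores and ranking**: regression-method coefficients `B = R⁻¹Λ`,
  scores = standardized data × B (unit variance by construction for
  principal-component extraction). The composite quality score is the
  contribution-weighted mean `F = Σ w_j F_j / Σ w_j` with `w_j` the
  rotated variance contributions; ranking is competition-style (ties
  share the smaller rank) and invariant to positive rescaling of the
  weights.
* The factor-analysis input defaults to the six quantified compounds; any
  sample × feature matrix (e.g. all 10 common-peak areas) is accepted.

## Orthogonal-design range analysis

For the L9(3⁴) design, `k[level, factor]` is the mean response over the
three runs at that level and `R = max(k) − min(k)` ranks the factors; the
best level is argmax k (ties flagged ambiguous, first level by order).
Because published tables often derive R from rounded level means, a
report-only rounded-k variant is emitted next to the raw one. The design
validator enforces balance (each level appearing equally often); R is
invariant to response shifts and scales linearly with response scaling.

## Numerical conventions

* RSD = 100·sd/mean with the sample (n−1) standard deviation throughout.
* The per-cell two-method spread in content reports is the RSD of the
  (ESM, QAMS) pair (n = 2).
* Report rounding: contents 3 dp (means 4 dp), RE/RSD 2 dp, RCF 4 dp.
* Paired t-tests are two-sided; 0.05 is reported, not enforced. Zero
  variance makes correlations undefined (reported as NaN with a note,
  never as 1); all-zero differences report "no difference".
* Config files are flat YAML with unknown keys rejected; every run logs
  the tolerance, linkage, similarity method and thresholds actually used.

## Problem sizes

The test suite and the acceptance script run the study at its native size:
15 batches × 10 peaks on a 6751-point grid, 9-condition RCF grids, and a
1000-seed sampling check for the replicate-RSD oracle. The full suite
completes in a few seconds on one CPU.

## Known limitations

* The affine-response intercept bias means the default (affine) design is
  the wrong regime for asserting QAMS/ESM equivalence; the package makes
  the regime explicit rather than hiding it (see above).
* No peak deconvolution: overlapping peaks would be mis-integrated; the
  generator guarantees separation, real data may not.
* The similarity statistic is computed on full traces; a common-peak-area
  variant can be built from the peak table but is not the default.
* No weighted or nonlinear calibration, no LOD/LOQ estimation, no oblique
  rotations, no bootstrap uncertainty on loadings, no ANOVA on the
  orthogonal design.
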
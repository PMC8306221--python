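# Methods

This note records the models, conventions, and numerical choices behind
`echotex`, and what the synthetic phantoms do and do not establish.

## Normalization and quantization

All second-order texture families operate on grey levels re-expressed
relative to the ROI's own intensity distribution.  With μ and σ the
in-ROI mean and *population* (divide-by-N) standard deviation, an
intensity v maps to

    level(v) = clip( floor( (v − (μ − 3σ)) · L / (6σ) ), 0, L − 1 ),  L = 2^bits.

The window μ ± 3σ suppresses scanner brightness/contrast variation, so
these families are invariant to positive affine transforms of the raw
image.  Conventions fixed here (the originating tool's dialect is
undocumented): floor-then-clip binning with half-open bins; σ = 0 (the
test is relative, σ ≤ 1e−12·max(1, |μ|), so a shifted constant image
stays constant) maps every pixel to the mid level 2^(bits−1); RGB input
collapses by the unweighted channel mean.

**Histogram features are the deliberate exception.**  They are computed
on raw display-scale intensities (floored into 2^bits bins of the 0–255
range) because the absolute grey level is itself the diagnostic signal:
the 10th percentile of a near-anechoic hemorrhagic cyst is a single-digit
grey value, and rescaling each ROI to its own μ ± 3σ window would map
both lesion types onto overlapping mid-range levels and empirically
*invert* the class ordering of Perc10.  `ExtractionProfile
(histogram_normalized=True)` restores the normalized variant.

Percentiles follow the counting definition: Perc_n is the smallest
level whose cumulative in-ROI fraction reaches n/100.  Moments are
population moments; kurtosis is excess kurtosis.

## Feature families

* **Gradient** (4 bits): central differences (half the two-pixel span)
  at ROI pixels whose 4-neighbourhood lies inside the ROI; moments of
  the magnitude plus the nonzero fraction.
* **Co-occurrence** (6 bits, distances 1–5, directions H (0,d),
  V (d,0), N (−d,d), Z (d,d)): symmetric pair counting with both
  endpoints in the ROI, no padding; normalized to sum 1.  The 11
  Haralick statistics use natural logarithms with 0·log 0 = 0.
  `DifVarnc` is the variance of the |i−j| difference distribution and
  `Contrast` its second raw moment; `SumVarnc` centres on the sum
  average (the common reading of the classical definition); correlation
  of a zero-variance matrix is reported as 0.  The direction letters are
  fixed here for determinism; the source naming never defines them.
* **Run length** (6 bits, same 4 directions): maximal equal-level runs,
  truncated where the scan line leaves the ROI; `Fraction` is the run
  percentage R/Np with Np the in-ROI pixel count.
* **Autoregressive** (on 6-bit levels): mean-centred causal model
  f(x,y) = θ₁f(x−1,y) + θ₂f(x−1,y−1) + θ₃f(x,y−1) + θ₄f(x+1,y−1) + e,
  least squares over pixels with a full causal neighbourhood (≥ 5
  required), minimum-norm for rank-deficient systems; Sigma is the
  population SD of the residuals.
* **Wavelet** (on 8-bit levels): Haar DWT under periodization of the
  ROI bounding box, out-of-ROI pixels filled with the in-ROI mean to
  avoid background edge energy; WavEn(band, s) is the mean squared
  coefficient over coefficients whose 2^s-pixel support intersects the
  ROI.  Subband letters are ordered (x-filter, y-filter): HL responds
  to vertical edges.  A bounding box below 32 px emits the reachable
  scales and 0 for the rest, with a warning.

The standard profile totals 275 uniquely named features (5 + 5 + 20 +
220 + 5 + 20); the histogram count is held at 5 (Mean, Variance,
Skewness, Kurtosis, Perc10) because only that reading is consistent
with the 275 total — the `mazda-full` profile adds Perc01/50/90/99 for
users who want the wider percentile range.

## Feature reduction

* **Fisher coefficient** F = D/V with D = Σ P_k(μ_k − μ)², V = Σ P_kσ_k²
  (class priors P_k, population variances); V = 0 with D > 0 yields a
  +∞ sentinel.
* **POE + ACC**: the first pick minimizes the error of the best
  single-threshold classifier (candidate thresholds at midpoints of
  sorted distinct values, both orientations, ties to the lower
  threshold); later picks minimize POE(f) + mean |Pearson r| with the
  already-selected set, weighted 1:1.  A constant feature degenerates
  to the majority-class rule; correlation with a constant column counts
  as 0.  Note the consequence, visible in both phantoms and the
  published selections: because discriminative features are mutually
  correlated through the class signal, POE + ACC intentionally
  sacrifices per-feature discrimination for decorrelation after its
  first pick, and should not be expected to recover a full block of
  shifted columns.
* **Mutual information**: 4 equal-frequency bins (reduced with a
  warning when a feature has fewer distinct values), MI in bits.

All tie-breaks are lexicographic on the rendered feature name, making
selections bit-reproducible.  The union keeps first-appearance order
and records which methods share each name.

## Reproducibility filter

ICC form: two-way random effects, absolute agreement, average of k = 2
measurements (McGraw–Wong "case 2A"), from the ANOVA decomposition; the
95% CI uses the Satterthwaite-approximated F construction for the
single-measure form stepped up by Spearman–Brown.  Zero between-subject
variance raises a typed error rather than returning NaN; such features
are dropped and reported as NaN by the filter.  The default exclusion
threshold is 0.85.

## Screening and the prediction model

Mann–Whitney U is reported as min(U_x, U_y) with an exact two-sided p
for pooled n ≤ 20 without ties, otherwise the tie- and
continuity-corrected normal approximation.  The Bonferroni threshold is
α/m *floored* to 4 decimals — the printed-threshold convention that
turns 0.05/30 into 0.0016 — with the family size defaulting to the
unique-selection count plus three (age and the two entities).

The prediction model is a linear probability model: OLS of the 0/1
class on all screened features entered in one step, matching the
coefficient semantics of mainstream "enter"-method multiple regression
on a binary outcome (a logistic fit is a one-line swap but is not used
by the reported tables).  VIF_j = 1/(1 − R²_j); columns are pruned
iteratively, highest VIF first (ties by name), while any VIF exceeds
10⁴.  Exact rank deficiency raises an error naming the offending
columns.

## ROC analysis

AUC via the Mann–Whitney identity with half-weight ties; orientation
chosen so AUC ≥ 0.5 and reported with the criterion (">" when high
scores predict the positive class, "≤" otherwise).  The DeLong SE comes
from placement-value sample variances; the AUC CI is the normal
interval clipped to [0, 1] (the "binomial exact" AUC interval printed
by some commercial packages has no published construction and is not
reproduced).  The Youden optimum maximizes J = Se + Sp − 1 over
observed score values, ties resolved toward higher specificity, then
lower threshold; Se/Sp at the optimum carry exact Clopper–Pearson
(beta-quantile) 95% CIs.  Reported operating points are
self-consistent: re-applying the criterion to the stored scores
reproduces Se and Sp exactly.

## Synthetic phantoms

Phantoms exist to exercise the pipeline, not to imitate any scanner.
An elliptical ROI (semi-axes 24–44 px in a 128 px field) sits on a
Rayleigh-speckled background.  Endometrioma-like content is a mid-level
base (90) times unit-mean multiplicative Rayleigh speckle smoothed with
σ = 4 px; hemorrhagic-cyst-like content is a low base (12) with lightly
smoothed speckle (σ = 0.5), 3–7 bright reticular strands (smoothed
random-walk polylines with a Gaussian cross-profile, gain 110), and a
wall-adherent Gaussian clot blob with probability 0.6.  The EN
smoothing length is deliberately larger than the largest co-occurrence
distance (5 px): homogeneity in the normalized domain *is* spatial
correlation, and that is what makes contrast-type features lower in EN
phantoms, matching the published class-median directions (DifVarnc and
Contrast higher in HOC, Perc10 higher in EN).  No attempt is made to
match absolute feature medians — they depend on unavailable scanner
settings.  Repeat sessions are emulated by seeded Gaussian intensity
noise plus an optional one-pixel ROI jitter.

All randomness flows through `numpy.random.default_rng` integer seeds;
a given seed yields bit-identical cohorts across platforms.

What passing phantom tests shows: the pipeline's stages compose
correctly, its statistics are calibrated (family-wise error of the
screen at the nominal level on null tables), and it separates two
texture populations whose differences mirror the clinical description.
What it does not show: performance on real ultrasound, where speckle is
correlated with the point-spread function, lesions are not ellipses,
and class differences are far subtler.

## Problem sizes used by the test suite

Oracle-agreement suites run on random images up to 8×8 (exact,
bit-level).  Calibration suites use 1000 null replicates (family-wise
error), 100 replicates for selection recovery and screen power, and a
30 + 26 training cohort with 100 held-out phantoms per class for the
end-to-end separation check — sizes chosen to make Monte-Carlo error
small relative to the asserted margins.

## Known limitations

* The histogram family is intentionally not affine-invariant (see
  above); users comparing cohorts across scanners should verify
  display-curve comparability or switch to the normalized variant.
* DeLong CIs are asymptotic; at n ≈ 56 with AUC near 1 they can touch
  the clip boundary.
* The binary-sign cohort builder reproduces only the marginal presence
  counts; joint-model coefficients on that reconstruction are arbitrary
  (single-sign Se/Sp/AUC are exact).
* 2-D single-ROI analysis only; no 3-D volumes, Doppler, or vendor
  private-tag handling.
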
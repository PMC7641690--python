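# Methods

## Model and assumptions

The package implements summary-level two-sample Mendelian randomization.
For each instrument SNP *j* the inputs are the estimated SNP–exposure
effect γ̂ⱼ with standard error σₓⱼ and the estimated SNP–outcome effect Γ̂ⱼ
with standard error σᵧⱼ, taken from two non-overlapping samples. The
working sampling model is

    γ̂ⱼ ~ N(γⱼ, σₓⱼ²),   Γ̂ⱼ ~ N(θ γⱼ + αⱼ, σᵧⱼ²),

with independent errors across SNPs and across the two sides (the
two-sample, distinct-cohorts assumption). θ is the causal effect of the
exposure on the outcome scale and αⱼ is a direct (pleiotropic) effect,
assumed independent of instrument strength (InSIDE). Instruments are
treated as uncorrelated: the intended instrument panels are pruned for
linkage disequilibrium upstream, and no between-SNP correlation is
modelled anywhere.

Exposures are the four iron-status biomarkers; higher serum iron, ferritin
and transferrin saturation indicate higher systemic iron, while higher
transferrin indicates *lower* iron status. The pipeline does not flip
transferrin estimates; rows carry a direction annotation instead, so the
emitted ORs are on each biomarker's own scale.

## Estimators

- **Wald ratio** θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ. Two delta-method SE modes are provided:
  `full_delta` (default), √(σᵧⱼ²/γ̂ⱼ² + Γ̂ⱼ²σₓⱼ²/γ̂ⱼ⁴), which keeps the
  exposure-side variance; and `first_order`, σᵧⱼ/|γ̂ⱼ|, the no-measurement-
  error approximation under which IVW coincides with weighted regression
  through the origin. Whether a published delta-method SE includes the
  exposure term is often unstated, so the mode used is always surfaced in
  output metadata. With per-SNP F of several hundred the two differ by
  well under 1%.
- **Fixed-effect IVW** (primary): weighted mean of ratios with weights
  1/se(θ̂ⱼ)², se = (Σwⱼ)^(−1/2), two-sided normal p. Fixed-effect pooling
  assumes a single common θ.
- **Simple and weighted median** (sensitivity): the weighted median is the
  0.5 point of the piecewise-linear weighted empirical CDF through
  (θ̂₍ⱼ₎, sⱼ) with sⱼ = Σᵢ≤ⱼwᵢ − wⱼ/2 (clamped to the extreme ratio when
  0.5 falls outside [s₁, s_J]); it is consistent when at least half the
  weight comes from valid instruments. Standard errors come from a
  parametric bootstrap (default B = 5,000, seed mandatory): the simple
  median redraws θ̂ⱼ* ~ N(θ̂ⱼ, se²), the weighted median redraws γ̂ⱼ* and
  Γ̂ⱼ* and recomputes ratios, delta SEs and weights per replicate. Noise
  is drawn in antithetic pairs, which lowers bootstrap variance and makes
  the SE exactly invariant under a global sign flip of the outcome betas
  (a symmetry the estimators themselves obey). B should be even; an odd B
  leaves one unpaired draw.
- **Egger regression** (pleiotropy diagnostic): WLS of Γ̂ⱼ on γ̂ⱼ with
  intercept, weights 1/σᵧⱼ², after orienting every SNP so γ̂ⱼ > 0 (the
  intercept is only interpretable under a fixed orientation convention;
  re-signing γ̂ⱼ and Γ̂ⱼ together leaves Wald ratios unchanged). Inference
  uses normal quantiles on the unscaled covariance (X′WX)⁻¹ — the
  fixed-effect convention matching the IVW choice, with no residual
  variance inflation. This makes the intercept test exact when the σᵧⱼ are
  correct and anti-conservative when extra between-SNP dispersion exists;
  with J = 3 the fit has a single residual degree of freedom and results
  are flagged `low_df`. Requires J ≥ 3.
- **Odds scale**: OR = exp(β) with exp(β ± z·se) intervals. Outcome scans
  of biobank releases fit linear models to binary endpoints, so these are
  odds ratios only approximately; the transform mirrors the field's
  reporting convention and the caveat applies to all emitted ORs.
- **Sex difference**: z = (β_m − β_f)/√(se_m² + se_f²), two-sided normal.
  Reported but deliberately not multiplicity-corrected, and labelled
  exploratory in the output metadata.

p-values are never truncated to zero; they are written at full double
precision.

## Harmonization

Outcome rows are re-expressed on the exposure's effect allele: matching
alleles pass through, swapped alleles negate the beta and complement the
EAF, and a strand complement (A↔T, C↔G relabelling) is applied when that
is the only reconciliation; irreconcilable allele sets raise an error
naming the SNP. Palindromic variants (A/T, C/G) carry no strand
information in their letters, so the default policy (`eaf-resolve`)
orients them by whether the two effect-allele frequencies fall on the same
side of 0.5, dropping the SNP only when **both** EAFs are within 0.08 of
0.5. The threshold and the both-sides rule were chosen so that a C/G
variant with strongly informative frequencies (e.g. EAF ≈ 0.15 in both
studies) is retained rather than silently discarded — dropping it would
change a three-SNP instrument materially. `keep` and `drop` policies are
available for sensitivity analyses. Harmonizing an already-aligned pair is
a no-op, and every action is recorded in a per-SNP orientation log.
Instrument SNPs absent from an outcome file are dropped with a warning
rather than failing the cell, because sex-stratified releases may omit
variants and all estimators are defined for J ≥ 1 (J ≥ 3 for Egger).

Per-SNP instrument strength is summarised as F = (γ̂ⱼ/σₓⱼ)²; any F < 10
sets a weak-instrument flag on the cell.

## The analysis grid

`run_grid` analyses every exposure × outcome × available-stratum cell:
harmonize, orient, per-SNP F, IVW plus configured sensitivity methods,
Egger intercept attached to each row. Multiplicity control follows the
family of overall tests: with E exposures and O outcomes the per-test
threshold is α/(E·O) (0.05/48 ≈ 1.04 × 10⁻³ for the default 4 × 12 grid),
and each record is classified `significant` (p below the strict
threshold), `potential` (between strict and the nominal 0.05) or `null`.
The same classifier is applied to sex-stratified rows; the metadata file
records both thresholds and notes that the strict one derives from the
overall grid, since stratified analyses are companions rather than an
enlargement of the family. Cell-level harmonization failures are recorded
and the grid continues; bootstrap seeds derive from the config seed and a
hash of the cell identity, so results are independent of iteration order
and reruns are byte-identical.

## Synthetic data

The generator draws directly from the sampling model above — summary-level
generation was chosen over individual-level simulation because the
estimators consume summary statistics and this matches their assumed model
exactly. Defaults emulate the intended application: an exposure GWAS of
48,972 subjects; outcome scans of 361,194 subjects (167,020 male, 194,174
female) with per-outcome case counts from a few hundred to ~14,000 and
linear-model SEs computed as √(p(1−p))/√(2·n·q(1−q)) for case fraction p
and a nominal effect-allele frequency q; three instruments with exposure
effects 0.33/0.19/0.18 per SD of systemic iron and per-SNP F drawn
log-uniformly from 50–2,000 (strong instruments, with weak-SNP scenarios
available by lowering the range); biomarker tables proportional to a
shared systemic-iron effect with a negative scale for transferrin. The
packaged fixture study (seed pinned in code, generated at call time — no
bundled data files) sets a positive venous causal effect in both sexes and
a male-driven protective arterial effect, with all other cells null, and
ships a ground-truth manifest from which every file regenerates
byte-identically.

Balanced-pleiotropy scenarios default to τ = 0.3·σᵧ ("mild" pleiotropy).
This regime was fixed a priori: the fixed-effect Egger intercept test does
not model pleiotropic dispersion as extra variance, so it is near-nominal
only while τ is small against sampling noise (variance inflation
1 + τ²/σᵧ² ≈ 1.1 here); larger τ calls for random-effects inference,
which is out of scope. Directional-pleiotropy scenarios can restrict the
direct effects to the first k of J SNPs to emulate invalid-instrument
settings.

What the generator does **not** emulate: linkage disequilibrium between
instruments, case-control ascertainment, winner's-curse selection of
instruments, sample overlap between exposure and outcome studies, and
non-normal sampling error. Passing calibration tests therefore validate
the estimators under their own assumptions, not robustness to these
real-data complications.

## Numerical choices

- Weighted-median interpolation clamps to the extreme ratio when 0.5 lies
  outside the standardised cumulative range; ties in ratios are handled by
  stable sorting.
- A Wald ratio with γ̂ⱼ = 0 raises a degenerate-instrument error naming
  the SNP (rather than returning ±inf); orientation likewise refuses a
  zero exposure beta.
- In the weighted-median bootstrap an exposure draw that lands exactly on
  zero is nudged to the smallest positive double; with F ≫ 10 this path
  is unreachable in practice.
- Bootstrap seeds are mandatory; identical seed and B give bit-identical
  standard errors.
- Output floats are written with full `repr` precision so reruns are
  byte-comparable; read them back with round-trip float parsing.

## Limitations

Fixed-effect pooling and unscaled Egger covariances understate uncertainty
under effect heterogeneity; no random-effects IVW, MR-PRESSO, mode-based
or multivariable estimators are provided. The odds-ratio transform of
linear-model betas is approximate for common outcomes. With three
instruments the Egger regression is close to saturated and its intercept
test has little power — its role here is diagnostic, not confirmatory.
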
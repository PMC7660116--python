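# Methods

## Statistical model

Two-sample Mendelian randomization treats genetic variants as instrumental
variables for a modifiable exposure. Variant j carries a true exposure
effect γ_j and a direct (pleiotropic) outcome effect α_j; the true outcome
effect is

    Γ_j = θ·γ_j + α_j ,

where θ is the causal effect of interest. The observed summary statistics
add independent sampling noise: γ̂_j ~ N(γ_j, σ_xj²) in the exposure GWAS,
Γ̂_j ~ N(Γ_j, σ_Γj²) in the outcome GWAS, with the two samples
non-overlapping. A valid instrument has α_j = 0; "balanced" pleiotropy has
E[α] = 0, "directional" pleiotropy E[α] ≠ 0, and the InSIDE condition
requires cor(γ, α) = 0.

All ratio standard errors use the first-order delta expansion
se(Γ̂/γ̂) = σ_Γ/|γ̂|, which ignores exposure-side noise; a second-order
form (adding Γ²σ_x²/γ⁴) is available behind a flag for sensitivity
analysis. First-order weights make IVW identical to a weighted regression
of Γ̂ on γ̂ through the origin with weights 1/σ_Γj².

### Estimators

- **IVW**: θ̂ = Σw_jγ_jΓ_j / Σw_jγ_j², fixed-effects se = (Σw_jγ_j²)^−1/2.
  The random-effects default multiplies the se by √φ̂ with
  φ̂ = max(1, RSS_w/(J−1)) — multiplicative overdispersion truncated below
  at 1, matching the convention of the standard MR software; truncation is
  logged when active. J = 1 under the random model falls back to fixed with
  a warning.
- **MR-Egger**: the same weighted regression with an unconstrained
  intercept (J ≥ 3, all γ̂_j > 0 after risk-increasing orientation — the
  intercept is only interpretable on a consistent allele orientation). The
  slope estimates θ under InSIDE; the intercept estimates E[α] and carries
  its own Wald test. Overdispersion uses J−2 degrees of freedom and
  inflates both slope and intercept standard errors.
- **Weighted median**: ratios sorted ascending; with standardized
  cumulative weights s_j = (Σ_{i≤j}w_i − w_j/2)/Σw, the estimate linearly
  interpolates the sorted ratios at s = 0.5. The standard error is the
  standard deviation of the estimate over a parametric bootstrap
  (default 10,000 replicates, explicit seed mandatory) that redraws every
  γ̂_j and Γ̂_j from their sampling distributions.

Confidence intervals use normal quantiles (t quantiles available as an
option); p-values are two-sided normal throughout. No multiple-testing
adjustment is applied across outcomes or methods, and the run report says
so explicitly.

### Harmonization

Matching is by rsID only. Non-palindromic variants are aligned directly or
after strand complementing; a label swap negates the outcome beta and
complements its frequency. Palindromic variants (A/T, C/G) carry no strand
information in their labels, so they are resolved by allele frequency:
kept when exposure and outcome frequencies sit on the same side of 0.5,
sign-flipped when on opposite sides, and dropped whenever either frequency
is missing or falls within the ambiguity window (default ±0.08 around 0.5,
the community convention; configurable). A frequency near 0.5 genuinely
cannot distinguish strands, so dropping is the only defensible default —
the window is deliberately applied even to frequencies like 0.43 that a
human might be tempted to wave through.

### Diagnostics

Both MR regressions are refit on the √w-transformed design, giving the
weighted hat matrix. Reported studentised residuals are *externally*
studentised (the residual scale is re-estimated with the variant deleted),
which is the convention the |SR| > 3 outlier rule pairs with; internally
studentised values are also emitted. Cook's distance uses
D_j = r_j²h_jj/(p(1−h_jj)) with p the coefficient count, and the influence
flag is D > 4/n. The MR-PRESSO implementation covers the *global* test
only: the observed statistic is the leave-one-out weighted residual sum of
squares Σ_jw_j(Γ_j − θ̂_{−j}γ_j)²; the null redraws both γ*_j (with σ_xj —
exposure noise is deliberately part of the null, matching the cited
method) and Γ*_j around the fitted values and recomputes the statistic,
leave-one-out fits included. The p-value uses the add-one estimator, so
the smallest reportable value is 1/(n_sim+1).

### Per-doubling rescale and power

Binary-exposure log-odds estimates are rescaled to "per doubling of the
odds of exposure" by multiplying the log-scale estimate and CI by 0.693
(the conventional rounding of ln 2, used literally as the published
analyses do) and exponentiating for binary outcomes; continuous outcomes
(cIMT, in mm) stay linear. Power for binary outcomes uses the normal
approximation se(θ̂) ≈ 1/√(n·R²·cf·(1−cf)), giving
power = Φ(|θ|/se − z_{1−α/2}) + Φ(−|θ|/se − z_{1−α/2}); this reduces to α
at θ = 0.

### LD-score regression

E[χ²_j] = 1 + n·h²·ℓ_j/M motivates regressing χ² on LD scores; the slope
times M/n is h², and the intercept absorbs confounding inflation. For two
traits, z₁z₂ regresses on ℓ with slope √(n₁n₂)ρ_g/M, and
r_g = ρ_g/√(h²₁h²₂); the cross-trait intercept absorbs sample overlap.
Regression weights take the standard heteroskedasticity form seeded by an
unweighted fit, with a single fixed-point update — the module targets
parameter recovery on synthetic inputs at desk scale, not genome-scale
fidelity (no HapMap3 weight files, no allele merging, no partitioned
heritability). Standard errors are delete-one-block jackknives over 200
contiguous blocks (configurable), recomputing all three regressions per
deleted block with weights held fixed; r_g is not clamped to [−1, 1] —
out-of-range values are flagged.

## Synthetic-data generator

The generator draws γ_j ~ N(0.30, 0.08²) — the scale of the packaged
instrument table's log-odds ratios (ln 1.24 to ln 1.59) — and α_j with
configurable mean, sd and correlation with γ (Gaussian copula), then flips
the sign of the whole (γ, α, Γ) triple wherever γ < 0, mirroring the
allele relabelling that risk-increasing orientation performs. Default
sample sizes mirror the study conditions: an exposure GWAS of 8,254, a
stroke-scale outcome GWAS of 44,221 cases / 739,957 controls, one
palindromic variant in five, allele frequencies uniform on (0.1, 0.9).
Standard errors are either fixed scales (defaults 0.08 exposure-side —
the instrument table's typical se — and 0.012 outcome-side, the precision
implied by the outcome sample size at intermediate frequencies) or derived
per variant from the binary-trait approximation
se² = 1/(n·cf·(1−cf)·2q(1−q)).

What it does **not** emulate: linkage disequilibrium between instruments
(the real instruments are unlinked), winner's-curse selection of
instruments, allele-frequency differences between populations, sample
overlap between exposure and outcome GWAS, or non-normal effect
distributions. Passing recovery and calibration tests therefore show that
the estimators are implemented correctly under their own model, not that
the model's assumptions hold in any particular application.

## Numerical choices and degenerate inputs

- Weighted regressions solve 1×1 / 2×2 normal equations directly; the
  √w-transformed design is used wherever a hat matrix is needed.
- β = 0 at orientation keeps the alleles as given (documented tie-break);
  a zero exposure beta downstream raises (undefined Wald ratio).
- Exact-fit data (RSS = 0): overdispersion truncates to 1, studentised
  residuals and Cook's distances are reported as 0 rather than 0/0.
- The weighted-median interpolation clamps to the extreme ratios when 0.5
  falls outside the standardized-weight range; sort ties break stably.
- Meta-analysis of a single study returns it unchanged (Q = 0 on 0 df);
  a variant missing from one study is carried from the others with a
  logged provenance flag.
- Sub-seeds for replicated experiments derive from a single user seed via
  `numpy.random.SeedSequence`.

## Problem sizes used by the test suite and acceptance script

Oracle-equivalence checks run on ≤ 10-variant instances at 1e-10 relative
tolerance. Recovery and calibration experiments use J = 50 instruments
with tight standard errors (σ_x = 0.004, σ_Γ = 0.01) over 500 replicates;
type-I error uses 1,000 replicates; MR-PRESSO calibration uses J = 10,
999 null simulations, 500 replicates; LDSC recovery uses 4,000 variants,
h² = 0.4/0.4, r_g = 0.5, n = 50,000 over 100 seeds with 200 jackknife
blocks. These sizes were chosen so Monte-Carlo error is small relative to
the 3-standard-error acceptance bands while the whole suite stays
interactive.

## Known limitations

- The published outcome-side SNP estimates (MEGASTROKE,
  CARDIoGRAMplusC4D + UK Biobank, cIMT) are not publicly deposited, so the
  headline odds ratios of the original analysis are not reproducible here;
  the package instead validates every computational stage against oracles
  and generative ground truth, and reproduces the published
  instrument-strength and influence-tally figures from the packaged
  tables.
- The expected-F formula evaluates to 31.95 at N = 8254, K = 5,
  R² = 0.019; the published figure 32.0 is that value rounded.
- The one-sided 95% lower confidence limit of the F statistic (published
  as 24.1) has no stated method and is not computed.
- MR-PRESSO outlier- and distortion-tests, mode-based estimators,
  multivariable MR, LD-aware clumping and figure rendering are out of
  scope.
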
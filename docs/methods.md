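# Methods

## Model and assumptions

`mrpath` works in the two-sample summary-data MR setting. For variant j,
GWAS give estimated per-allele associations β̂_Xj (exposure) and β̂_Yj
(outcome) with standard errors; the instrumental-variable assumptions
(relevance, no confounding of the variant–outcome relation, exclusion
restriction) make the Wald ratio β_Yj/β_Xj identify the causal effect. All
binary-trait effects are handled on the log-odds scale internally; odds
ratios appear only at serialization.

### Univariable estimators

- **IVW.** Weighted least squares of β̂_Y on β̂_X through the origin with
  weights 1/se²_Y; algebraically the inverse-variance-weighted mean of the
  Wald ratios under first-order ratio SEs. Heterogeneity is summarized by
  Cochran's Q; the random-effects variant (the default, and the primary
  analysis in the pipeline) multiplies the fixed-effects SE by
  max(1, √(Q/(k−1))) — multiplicative random effects, never shrinking below
  fixed effects. CIs are z-based at 95%.
- **MR-Egger.** The same regression with a free intercept, after flipping
  rows so every exposure beta is non-negative (the flipped variant ids are
  logged in the result's extras). The intercept estimates average directional
  pleiotropy; SEs are scaled by max(1, √(RSS_w/(k−2))). With balanced
  pleiotropy the intercept test shows mild size inflation (~7% at the 5%
  level in our calibration) because the 1/se²_Y weights ignore the
  pleiotropy variance component; this is a known property of the weighting,
  not of this implementation.
- **Weighted median.** Sort ratios; with normalized weights w′ the cumulative
  midpoint of the j-th ratio is Σ_{i≤j} w′_i − w′_j/2; interpolate linearly
  at 0.5. Consistent when ≥50% of the weight is on valid instruments.
- **Weighted mode.** Mode of a weighted normal-kernel KDE over the ratios;
  bandwidth = bandwidth_factor × 0.9 × 1.4826 × MAD_w × k^(−1/5) with the
  weighted MAD taken about the weighted median (bandwidth_factor defaults
  to 1; a zero bandwidth, i.e. all ratios equal, returns that ratio exactly).
  The argmax is located on a 2048-point grid and refined by bounded scalar
  minimization.
- Median and mode SEs come from a parametric bootstrap (default 1,000 draws,
  explicit seed): resample β̂_X, β̂_Y from normals with their SEs, recompute
  the estimator. These SEs are stochastic by construction and always carry
  their seed.
- **Instrument strength.** Per-variant F = (β̂_X/se_X)²; variants under 10
  are flagged.

### Multivariable IVW

Weighted LS of β̂_Y on the k×m exposure-beta matrix, no intercept, weights
1/se²_Y; per-coefficient SEs scaled by max(1, √(RSS_w/(k−m))). Each
coefficient is a direct effect adjusted for the other exposures. An exactly
zero exposure column is treated as a null exposure (coefficient 0, infinite
SE) rather than an error; genuinely collinear columns raise a collinearity
error naming the offending exposures. Conditional instrument strength is
approximated by regressing each exposure's betas on the others' and averaging
the squared residual t-statistics — a diagnostic, not a gate. Instrument
pooling for MVMR is union-then-intersect: union of each exposure's clumped
genome-wide-significant variants, restricted to variants present in all
traits, optionally re-clumped.

### Diagnostics

- **MR-PRESSO.** For each variant the leave-one-out IVW slope predicts
  β̂_Yj; the observed weighted residual sum of squares is referenced against
  simulations that redraw β̂*_Y ~ N(β̂_ivw,−j β̂_Xj, se_Yj) (outcome betas
  only). Simulation p-values use the add-one rule (r+1)/(n_sim+1); outliers
  are Bonferroni-corrected across the k variants at the chosen level; the
  distortion test compares the IVW estimate with and without the flagged
  variants against the distribution obtained by removing random subsets of
  the same size.
- **Steiger.** Per-variant variance explained is approximated from the
  t-statistic, r²_j = t²_j/(t²_j + n − 2), summed per trait; the direction is
  declared correct when the instruments explain more variance in the exposure
  than in the outcome, with a p-value from the normal test on the difference
  of Fisher-z-transformed correlations. For binary traits the approximation
  is applied on the observed log-odds scale and is approximate.

### Harmonization and clumping

The first exposure fixes the reference orientation. Other traits are aligned
by allele labels (sign flip + EAF complement under a swap) or strand
complement. Palindromic (A/T, C/G) variants cannot be oriented from labels:
they are kept only when every trait's minor-allele frequency is below the
`palindromic_eaf_limit` (default 0.42, the common two-sample MR convention)
and the frequencies agree in orientation; otherwise dropped as
`palindromic_ambiguous`, with missing-EAF palindromic variants always
dropped. Every dropped variant appears in the drop log with exactly one
reason. Clumping is greedy: sort significant variants by ascending p (ties
broken lexicographically by id, making the result independent of row order),
take the best as an index SNP, and remove variants with r² ≥ threshold
within the physical window on the same chromosome; variants absent from the
LD matrix are treated as unlinked, with a warning. LD is always supplied as
input (identity for the synthetic scenarios), never estimated from genotypes.

### Mediation

Two-step mediation MR: β₁ is the exposure→mediator UVMR effect; β₂ is the
mediator→outcome effect from MVMR adjusted for the exposure (never UVMR);
indirect = β₁β₂; proportion = indirect / total effect. The delta-method
variance of the indirect effect is β₁²se₂² + β₂²se₁², treating the two steps
as independent (two-sample setting; sample-overlap covariance assumed zero —
a documented limitation). By default the total effect is treated as fixed in
the proportion's SE, matching common two-step practice; `propagate_total=True`
adds the full ratio-delta term indirect²·se²_total/total⁴. Proportions
outside [−1, 1] are returned with an out-of-range flag (possible inconsistent
mediation) rather than suppressed.

The mediator screen demands, at level α (default 0.05): (1) a forward
exposure→mediator effect with no reverse mediator→exposure effect and a
Steiger-consistent direction; (2) a mediator→outcome UVMR effect; (3) a
mediator→outcome MVMR effect adjusted for the exposure; (4) the mediated
path's sign (sign β₁β₂) must match the total effect's sign — the sign rule is
stated this way so the screen also works for risk-increasing exposures.
Before the reverse test the mediator's instruments are passed through a
per-variant Steiger filter (keep variants explaining more variance in the
mediator than in the exposure): with a genetically correlated mediator,
exposure-driven variants otherwise reach genome-wide significance for the
mediator and manufacture a spurious reverse association. A criterion that
cannot be evaluated (no instruments for a required direction) is recorded as
indeterminate and the candidate is ineligible.

### Pipeline

Step 1 runs bidirectional UVMR among the exposures. Step 2 runs UVMR with the
full sensitivity suite for every exposure×outcome source, pools sources per
disease by fixed-effects inverse-variance meta-analysis (meta-analysis before
FDR; the order is a fixed convention), applies Benjamini–Hochberg FDR within
each exposure's disease family, and labels each association significant
(FDR p < 0.05), suggestive (nominal p < 0.05, FDR p ≥ 0.05) or null; MVMR of
all exposures jointly then determines which diseases retain a nominal direct
effect of the primary exposure and are carried into step 3 (both significant
and suggestive tiers are carried, with the tier recorded). Step 3 screens the
candidate mediators and computes mediated proportions for eligible pairs,
using the meta-analysed total effect. BH adjustment is delegated to
statsmodels (`multipletests(method="fdr_bh")`); meta-analysis, labels and
orchestration are native. Stage failures are isolated and logged, never
fatal. All task-level seeds derive deterministically from the config seed, so
a rerun with the same config is byte-identical.

## Synthetic data generator

The generator emulates multi-trait GWAS summary statistics under the
structural model exposure →(β₁) mediator →(β₂) outcome with an additional
direct exposure→outcome path; total effect = direct + β₁β₂ by construction.
Two instrument blocks are drawn: exposure instruments with effects
γ_j ~ N(0, gamma_sd²) and mediator-specific instruments with effects
δ_j ~ N(0, delta_sd²) on the mediator only. The mediator block exists because
two-step mediation is otherwise unidentified: if every mediator effect were
exactly β₁γ_j, the exposure and mediator beta columns in the MVMR step would
be proportional and β₂ inestimable. True outcome effects are
(direct + β₁β₂)γ_j + β₂δ_j + α_j, with α_j the horizontal-pleiotropy term:
none, balanced (zero-mean), or directional — the latter oriented relative to
the exposure-increasing allele, which is the orientation in which directional
pleiotropy biases MR and survives Egger's exposure-orientation flip.

Observed betas add noise with the standard GWAS SE for a unit-variance trait,
se_j = 1/√(2 n maf_j(1−maf_j)), drawn per replicate; binary outcomes are
generated directly on the log-odds scale with the SE inflated by
1/√(cf(1−cf)) for case fraction cf. This is a variance-inflation
approximation adequate for method testing, not a case-control likelihood
simulation. Effect alleles are always the minor allele at generation time;
the harmonization tests flip and permute alleles downstream to exercise that
path. Instruments are mutually independent (identity LD); an equal-r² block
mode exists solely to exercise clumping, with chromosome chunks aligned to
blocks.

Default conditions (chosen once, as the study conditions): 150 exposure
instruments and 100 mediator instruments; exposure GWAS n = 766,345 (the
scale of the largest education GWAS), mediator n = 600,000, outcome
n = 200,000 with case fraction 0.1; gamma_sd = 0.035 and delta_sd = 0.05 per
SD of trait, giving median per-variant F around 150–300 — the strength of
post-ascertainment genome-wide-significant instruments, which the generator
(drawing unselected normal effects) does not otherwise model. The
partial-mediation scenario uses β₁ = −0.28, β₂ = 0.62, direct = −0.31
(total −0.4836, proportion ≈ 35.9%) with balanced pleiotropy of SD 0.01 — an
education→smoking→gastric-ulcer-scale pathway. The scenario library adds
null, total-effect-only, full-mediation, directional-pleiotropy,
single-outlier (one planted 0.1 log-odds pleiotropic effect among 21 clean
instruments) and reverse-causation (the outcome causally upstream) variants.

What the generator does **not** emulate: polygenic backgrounds and
significance-selection (winner's curse), MAF-dependent effect-size
architecture, population stratification, sample overlap between GWAS, and
real LD structure. Passing tests therefore demonstrate correctness of the
estimators and workflow under the stated model, not robustness to those
real-data complications.

## Numerical choices and known limitations

- Weighted regressions solve via `lstsq` on the √w-scaled design;
  coefficient covariances come from (XᵀWX)⁻¹. Test oracles re-derive
  everything from hand-coded normal equations; agreement is required to
  1e-10.
- p-values are z-based and floored at the smallest positive double so they
  stay in (0, 1].
- Simulation p-values (PRESSO) use the add-one rule and can never be zero.
- Two-sample IVW carries intrinsic regression dilution from noise in the
  exposure betas, factor ≈ 1/(1 + se²_X/var(γ)); under the default
  partial-mediation conditions this is ~0.3% toward the null (measured
  +0.0013 on a total effect of −0.4836 over 6,000 Monte-Carlo replicates).
  The mediated proportion is free of this bias to first order because the
  dilution cancels between β₁β₂ and the total effect.
- Monte-Carlo experiment sizes (500–2,000 replicates for recovery and power,
  1,000 for type-I error and coverage, 100,000 bootstrap draws for the
  delta-method check) were set so each check resolves its target to well
  under the tolerance being asserted; the calibration module exposes all of
  them with explicit seeds.
- The mediation decomposition is marginal per mediator; proportions across
  mediators may sum past 100% (inconsistent or overlapping pathways) and are
  not reconciled.
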
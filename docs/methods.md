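# Methods

## Model and assumptions

All analyses operate on GWAS summary statistics: per SNP *j*, an
estimated additive effect β̂ⱼ with standard error seⱼ in each of up to
three non-overlapping samples (exposure, mediator, binary outcome on the
log-odds scale). The instrumental-variable assumptions are the usual
ones: instruments are associated with the exposure, independent of
confounders, and affect the outcome only through the exposure.
Relationships are assumed linear and additive with no interactions; the
two-sample design assumes no sample overlap.

The per-SNP causal estimate is the Wald ratio β̂_out,j / β̂_exp,j with
first-order standard error se_out,j / |β̂_exp,j|. This ignores
exposure-side sampling error (the NOME approximation); it is defensible
here because the selection cascade enforces per-SNP F > 10 — in
practice the synthetic studies used for validation have mean F in the
hundreds — and the residual dilution it causes is measured directly in
the recovery tests (see Calibration below).

## Instrument selection

Stages applied in order, each with recorded attrition:

1. significance: p < 5×10⁻⁸ (configurable; the same threshold is used in
   reverse-direction runs);
2. palindrome removal: A/T and C/G variants are strand-ambiguous from
   allele labels alone and are removed by default ("infer_by_eaf" keeps
   those whose allele frequencies in both studies sit on the same side of
   0.5 by more than 0.08);
3. greedy LD clumping: candidates visited in ascending (p, snp_id) order
   — the id tie-break makes output independent of input permutation —
   and accepted iff r² < 0.001 with every accepted SNP on the same
   chromosome within 10,000 kb. Both the r² and the window condition
   must hold to exclude. LD is supplied as an explicit matrix (square or
   long TSV) rather than a reference panel, so the cascade is
   self-contained; `ld=None` declares the input pre-pruned;
4. strength: R² = 2(1−MAF)·MAF·β², F = R²(N−2)/(1−R²), retain F > 10.
   Effect-allele frequencies are folded to MAF as min(eaf, 1−eaf).
   Missing eaf blocks R²/F and drops the SNP at this stage with a
   recorded count. Per-SNP F and the mean F across retained instruments
   are both reported, since conventions differ.

## Estimators

* **IVW**: weighted least squares of β_out on β_exp through the origin,
  weights 1/se_out². The default flavour is multiplicative random
  effects — se scaled by max(1, √(Q/(k−1))) — the dominant convention in
  two-sample MR software; the fixed-effect se is also reported. At k = 1
  IVW reduces exactly to the Wald ratio.
* **MR-Egger**: the same regression with a free intercept, pairs first
  oriented so every β_exp > 0. The slope is the causal estimate; the
  intercept estimates the average directional pleiotropic effect.
  Inference is t-based with k−2 df and residual scale bounded below
  by 1 (k is small in practice, so normal intervals would be
  anti-conservative for Egger specifically; all other methods use the
  1.96 normal multiplier, which matches how published CIs are computed).
* **Weighted median**: ratios ordered, weighted by inverse ratio
  variance; the estimate interpolates where the cumulative normalized
  weight (at bin midpoints) crosses 0.5. Consistent when ≥ 50% of
  instrument weight is valid.
* **Simple/weighted mode**: the mode of a normal-kernel density over the
  ratios, bandwidth φ × 0.9·min(sd, MAD)·k^(−1/5) with φ = 1 by default
  (the modified Silverman rule on the ratio distribution; MAD scaled to
  be sd-consistent under normality). The weighted variant weights each
  kernel by inverse ratio variance. The mode is located by a 512-point
  grid over the ratio range refined with bounded scalar optimization;
  when all ratios coincide the bandwidth degenerates and the common
  ratio is returned.
* Bootstrap standard errors (weighted median, modes): parametric — per-SNP
  betas redrawn from Normal(β̂, se) on both sides, estimator recomputed;
  1,000 draws by default, seed mandatory (no silent nondeterminism).
  Pairs are sorted by snp_id before drawing, so bootstrap ses are
  invariant to input order. Bootstrap mode re-locations use the coarse
  grid only (256 points), which is accurate far beyond the bootstrap
  noise floor.

All estimators are sign-equivariant (negating outcome betas negates the
estimate), and on perfectly homogeneous ratios every method returns the
common ratio with Q = 0 and Egger intercept 0 — both property-tested.

## Sensitivity battery and verdict

* **Cochran's Q** over Wald ratios, weights = inverse ratio variance,
  pooled value = fixed-effect IVW, df = k−1, p from χ².
* **Outlier test (MR-PRESSO style)**: observed statistic = weighted RSS
  of each SNP's outcome beta around its leave-one-out IVW prediction;
  null distribution from parametric draws (default 1,000, seeded) of
  outcome betas about those predictions at their stated ses; global p is
  the add-one empirical tail fraction. Per-SNP outlier p-values use each
  SNP's own residual contribution against its simulated null, Bonferroni
  corrected across SNPs at level 0.05. Flagged outliers are removed,
  IVW re-run for the corrected estimate, and a distortion test compares
  the corrected-vs-raw shift with random same-size removals. With a
  fixed seed the whole battery is bit-reproducible.
* **Leave-one-out**: IVW re-fit per excluded SNP; exclusions that flip
  the estimate's sign or move its p across 0.05 are flagged. Flags are
  advisory and do not enter the verdict (mirroring qualitative use).
* **Verdict**: a nominally significant IVW result counts as robust iff
  the Q p-value, the Egger intercept p-value, and the outlier-test
  global p (re-computed after outlier removal when any were removed) are
  all ≥ 0.05 — the bound inclusive. The distortion test is reported but
  excluded from the verdict by default.
* **FDR**: Benjamini–Hochberg q-values (step-up, capped at 1,
  permutation-invariant) are reported across the mediator screen at
  level 0.05 but do not gate the cascade by default; a strict-FDR mode
  exists. The q-values come from `statsmodels.multipletests` and are
  verified in tests against the brute-force definitional computation.

## Screening and mediation

The mediator screen keeps candidates with mediator→outcome IVW p < 0.05
(stage 1; the first-pass threshold is the conventional reading and is
configurable), then p < 0.01 (stage 2), then a passing sensitivity
verdict (stage 3). A mediator enters mediation only if the
exposure→mediator IVW is itself significant (p < 0.05).

Two-step mediation composes three IVW legs: β₁ (exposure→mediator,
exposure instruments), β₂ (mediator→outcome, the mediator's own
instruments), β_all (total effect, exposure instruments). The mediated
effect is β₁β₂; the mediated proportion is β₁β₂/β_all, with proportions
outside [0, 1] reported as-is and flagged as suppression/inconsistent
mediation.

Two variance pairings for the product CI ship side by side:

* `delta` (default): se² = β₂²se₁² + β₁²se₂², the standard first-order
  delta method for a product of independent estimates;
* `paper_compat`: se² = β₁²se₁² + β₂²se₂². Back-derivation from the
  published mediation table this package replays shows its printed CIs
  follow this pairing (the two coincide when |β₁| ≈ |β₂|, which is why
  the alcohol–O/P-ratio row cannot discriminate them). The default
  stays the textbook formula; the compatibility pairing is used for
  replay so the printed table reproduces bound-for-bound.

Proportion CIs divide the mediated-effect bounds by β_all treated as
fixed — its uncertainty is deliberately not propagated, matching the
replayed table — and when β_all < 0 the transformed bounds reverse
order; the raw (printed) orientation is preserved alongside an ordered
form. A full-propagation option is out of scope for replay. In replay
mode, ses are back-derived from printed 95% CIs as width/3.92.

## Synthetic data generator

The generator emulates the statistical skeleton of a beverage →
metabolite → renal-failure study: a linear path model
(mediator = α·exposure; outcome = θ·exposure + γ·mediator on the
log-odds scale), one SNP panel instrumenting the exposure and a second
instrumenting the mediator directly (which the second mediation leg
requires), three mutually independent samples. Summary statistics are
produced analytically: β̂ ~ Normal(true marginal effect, se) with
se = 1/√(2·MAF(1−MAF)·N) for quantitative traits, divided by
√(prev(1−prev)) for the binary outcome — the linear approximation to a
log-odds GWAS. Defaults (chosen once as a realistic, well-powered
idealization): 50 + 50 instruments, MAF ~ U(0.1, 0.5), per-allele
effects U(0.05, 0.15), N = 200,000 per study, outcome prevalence 0.1,
α = 0.5, γ = 0.4, θ = 0.1. Effect alleles are coded as the
trait-increasing allele (the orientation instrument tables use), which
is what makes simulated directional pleiotropy directional. A
configurable fraction of exposure instruments receives direct Normal
pleiotropic outcome effects; optional LD blocks give consecutive SNPs a
shared r² and tag-SNP-attenuated (×√r²) marginal effects, with the block
matrix emitted for clumping; chromosome/position are assigned
deterministically (100 SNPs per chromosome, 1 Mb apart) so the clumping
window is exercised. Same seed ⇒ byte-identical output files.

The pinned directional-pleiotropy fixture uses 100 instruments with
effects U(0.02, 0.25) and 30% invalid instruments at direct effect
Normal(0.08, 0.01): a design power analysis showed the Egger intercept
test is nearly collinear with the slope when exposure effects cluster
away from zero, so detecting pleiotropy at >50% power needs both the
wider effect spread and the larger panel (measured power ≈ 0.75; null
rejection ≈ 0.02–0.05).

What the generator does **not** emulate — so what passing tests do not
show about real data: realistic genome-wide LD structure and clumping
against reference panels, sample overlap, winner's curse from in-sample
instrument selection, non-collapsibility and case-control ascertainment
beyond the prevalence se-scaling, assortative mating and dynastic
effects, and non-linear or interacting pathways.

## Calibration and problem sizes

Validation uses deliberately desk-scale problem sizes: estimator-oracle
agreement on 20-SNP sets (IVW/Egger vs statsmodels weighted least
squares at 1e−10; median/modes vs definitional and 1e−4-step grid
oracles at 1e−3), parameter recovery over 500 replicated synthetic
studies (mean recovered total effect within 3 Monte-Carlo ses of 0.30,
mean recovered mediated proportion within 3 MC ses of 2/3, 95% CI
coverage within [92%, 98%]), outlier-test type-I error over 200 null
replicates (within [0.02, 0.09] at α = 0.05), and screening behaviour
over replicated 6-candidate studies. The screening cascade's final
stage applies three independent 5%-level tests to every candidate, so
even a true mediator is dropped in roughly one run in ten; recovery is
therefore asserted as a rate across replicates, not per-seed.

## Known limitations

* First-order Wald-ratio ses (NOME); weak-instrument dilution is
  controlled by the F filter, not corrected.
* The outlier test is in the spirit of MR-PRESSO but is this package's
  own implementation (leave-one-out expected values, add-one empirical
  p-values); numerical agreement with the original R package is not
  claimed.
* Published real-data results that depend on controlled-access GWAS
  inputs (headline beverage–CRF odds ratios, the 1,400 → 67 → 15 → 11
  metabolite screening counts) are out of scope; the mediation table is
  reproduced from its printed leg estimates, and the pipeline is
  validated on synthetic data with known truth.
* No multivariable MR, Steiger direction filtering, radial MR, or
  multiple simultaneous mediators.
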
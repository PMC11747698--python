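# Methods

This note documents the statistical models, the numerical choices, and
what the synthetic data do and do not emulate.

## Snell scaling of ordinal scores

Each assessor uses the 0–5 scale idiosyncratically, so scores are mapped
per assessor onto an underlying standard-normal (liability) scale from
that assessor's own class frequencies.  Let F_b, b = 1..5, be the
cumulative frequencies at the interior class boundaries and
z_b = Φ⁻¹(F_b).  Bounded classes 1–4 receive the mean of the z values at
their two boundaries (an empty class has coinciding boundaries and
collapses onto the shared quantile).  The open extreme classes receive

    value(0) = z₁ − offset(F₁),   value(5) = z₅ + offset(F₅),
    offset(F) = −ln(F) / (1 − F),

evaluated at the adjacent boundary's cumulative frequency.  This offset
form reproduces published worked examples of the method to the printed
precision at both ends of the scale, which is why it is the implemented
(and only) variant.  No post-hoc standardization is applied; the
reported mean and SD are frequency-weighted (population-form) moments of
the class values.  A completely empty extreme class receives the finite
open-class value at the nearest informative boundary so downstream
arithmetic never sees non-finite numbers; such values carry zero weight.
The scaling is the classical z-score approximation, not an iterative
maximum-likelihood or threshold-model fit — by design, since the
downstream model is linear.

## Panel diagnostics

The chemical gold standard declares a sample tainted when skatole
reaches 0.2 ppm or androstenone reaches 1.5 ppm (both thresholds
inclusive); an assessor's call is positive when the ordinal score is
≥ 2.  All five metrics use the standard confusion-matrix definitions,
with precision as TP/(TP+FP) — the positive predictive value.  Ratios
with zero denominators are reported as missing, never as zero, and a
record enters a given assessor's table only when the chemical pair and
that assessor's score are jointly observed.

## Multivariate animal model and REML

The model per multivariate record is y = Xb + Zu + e with
u ~ N(0, A⊗G) and e ~ N(0, I⊗R).  Fixed effects are a station×month
class factor (one-hot, first level dropped, plus intercept) and
regressions on slaughter weight and age; covariates are centred, which
changes b but not G or R.  Trait order is fixed package-wide as (SKAt,
ANONt, assessors 1..k).  A is built by the tabular recursion; its sparse
inverse uses Henderson's rules with inbreeding via the Mendelian-
sampling variances d_i, and log|A| = Σ log d_i.  Before a fit the
pedigree is pruned exactly: leaves without records, and unknown-parent
founders with a single offspring, can be removed without changing the
relationship matrix over the remaining animals.

Missing traits are handled by the observed-subset blocks of R, the
standard multivariate-REML treatment.  The E step solves the
mixed-model equations and takes exact conditional expectations of the
complete-data sufficient statistics — including the conditional
mean/variance of the residuals of unobserved traits given the observed
ones — so the EM iteration

    G ← (Û′A⁻¹Û + Σᵢⱼ A⁻¹ᵢⱼ Cᵢⱼ) / q,
    R ← Σⱼ E[eⱼeⱼ′ | y] / n

is an exact EM with a monotone restricted likelihood (asserted
empirically every round in the tests).  The restricted log-likelihood is
evaluated from the same factorization as

    −2L = log|R*| + m·log|A| + q·log|G| + log|M| + y′R*⁻¹y − r′s

(up to the 2π constant), and was verified against an independent dense-V
computation.

Pure EM crawls near the optimum, so the default accelerated mode runs a
few EM warm-up rounds and then average-information (AI) Newton updates.
The REML score comes free from the EM sufficient statistics
(dL/dG = −½(qG⁻¹ − G⁻¹S_G G⁻¹), analogously per observed block for R,
both checked against numerical gradients); the AI matrix is built from
the identities Z′Py = (A⁻¹⊗G⁻¹)û and Py = R*⁻¹ê so each working vector
costs one triangular solve.  AI proposals are step-halved and discarded
for the plain EM update whenever they leave the PD cone or decrease the
likelihood, so accepted iterates never descend.  Convergence is declared
when the largest relative change of any (co)variance parameter falls
below `tol` (default 1e-8; a much stricter literal criterion is not
meaningful in double precision).  After each EM update G and R are
projected onto the PSD cone only if an eigenvalue goes negative, and any
projection is counted in the run log.

Small-sample caveat: with few records the REML optimum frequently sits
on the boundary of the parameter space (a genetic correlation pinned at
±1 or a variance at zero).  Both EM and AI slow down dramatically there;
the fit still ascends but may stop on `max_rounds`.  This is a property
of the likelihood, not of the implementation.

Standard errors of the (co)variances are square roots of the diagonal of
the inverse AI matrix at convergence (pseudo-inverse, flagged, if AI is
singular).  SEs of derived parameters — h² = g/(g+r), r_G, r_R, and the
model-based phenotypic correlation r_P = (g+r)/√((gᵢᵢ+rᵢᵢ)(gⱼⱼ+rⱼⱼ)) —
use a first-order delta method with a numerical Jacobian on the AI
inverse, and are labelled as delta-method values in the output.  The AI
SEs were validated against the exact ANOVA sampling variances of a
balanced paternal half-sib design (where REML and Henderson's ANOVA
estimators coincide); note that the naive single-variance formula
2σ⁴/df badly understates SE(σ²ₑ) in an animal model because σ²ᵤ and σ²ₑ
are strongly anti-correlated.

## Recursive reparameterization

The recursive model holds the causal compounds constant.  Λ has unit
diagonal and nonzero entries only in the two causal columns of each
dependent row; row j stores −λ where λ solves R_cc λ = R_c,j — the
residual regression of trait j on (SKAt, ANONt).  This is the LDL step
restricted to the causal columns: a full LDL of R would also regress
each sensory trait on the preceding sensory traits, which the structured
Λ deliberately does not do (dependent↔dependent residual covariances are
preserved, and the tests assert they stay nonzero).  Consequences, all
asserted: the causal↔dependent block of R_RM = ΛRΛ′ is exactly zero
(tolerance 1e-10 relative to max|R|), the causal 2×2 blocks of G and R
are unchanged, Λ⁻¹G_RMΛ⁻¹′ restores G to machine precision, and the
REML likelihood is invariant under the reparameterization (|Λ| = 1).
Sign convention: the matrix stores −λ, so a positive stored entry means
negative recursiveness (higher sensory score at lower compound level).
Δσ²ᵤ,j = 100·(g_jj − g_RM,jj)/g_jj for dependent traits, 0 for causal
traits by construction.  The module operates a posteriori on any
estimated components (file input); it never refits.

## Combining assessors

Group means use T of shape 3×m whose rows select SKAt, ANONt and the
equally weighted group (cᵢ = 1/n for members, 0 otherwise); G_T = TGT′,
R_T = TRT′, and h²/correlations follow from the 3×3 results.  All
C(k, size) groups are evaluated from the fitted components (no per-group
refit); ranking is a stable descending sort on the chosen key with
lexicographic member order breaking ties.  Default group size is 3.
Correlated-response comparisons use the ratio (√h²_a·r_G,a)/(√h²_b·r_G,b);
selection intensity and the target trait's phenotypic SD cancel, and the
CLI labels numerator and denominator explicitly since "relative to" is
direction-sensitive.  Non-uniform weights and economic indices are out
of scope.

## Synthetic data

The generator emulates the motivating progeny-test design rather than
any particular dataset: 50 Pietrain sires (with a short paternal
ancestry: 25 grandsires shared round-robin plus an own founder dam each)
mated to unrelated crossbred dams nested within sire (16 per sire,
litters of 1–2), 1,016 progeny — total pedigree ≈ 1,940 in three
generations, matching the scale of the design it mimics.  Breeding
values follow sequential Mendelian sampling (founders ~ N(0,G);
offspring = parent average + deviate with variance d_i·G), so stacked
values have covariance A⊗G by construction.  Phenotypes add a
station×month class effect (drawn once per configuration, SD defaulting
to 10% of the trait's SD so fixed-effect recovery is checkable),
regressions on weight ~ N(94.9, 4.81²) kg and age ~ N(175.9, 11.31²) d
(simulated independently; the design argument for keeping both in the
model is their near-zero correlation), and residuals ~ N(0,R).

Default G and R are assembled from published-style estimates for this
population: compound heritabilities 0.52/0.53 with genetic correlation
0.46 (phenotypic variances set to plausible log10-scale values 0.12 and
0.16, since absolute compound variances are not published), per-assessor
genetic/residual variances and correlations with the compounds, genetic
correlations among assessors, and residual covariances derived from the
phenotypic correlations.  Assembling rounded printed values can leave
the matrices marginally indefinite, in which case they are eigenvalue-
clipped to the nearest PSD matrix (the defaults currently need no
projection).  Regression coefficients default to small plausible values
(0.002/kg and 0.001/d on the log10 compound scale; 0.01 and 0.005 on the
liability scale) — they exist to exercise the covariate machinery, not
to mimic estimated effects.

Sensory scores are genuinely ordinal: the continuous liability is
standardized by its model-implied SD and cut at per-assessor thresholds
defaulting to the normal quantiles of published-style cumulative class
frequencies.  A zero-frequency class corresponds to a tied cutpoint and
stays empty, reproducing the heterogeneous (including empty-class) score
distributions that make the Snell stage necessary.  Two assessors
(defaults 4 and 5) are thinned to exactly 856 observed records by seeded
uniform sampling.  Compounds are simulated on the log10 scale and stored
as 10^value ppm, so the downstream log10 is exactly invertible; no
detection-limit censoring is simulated.  Dams carry no maternal effect
(the model fits none), and there are no dominance, litter or pen
effects: passing parameter-recovery tests shows the estimator is
consistent under the model's own assumptions, not that real sensory
data are free of such nuisances.

All randomness derives from one seed through named substreams
(CRC-keyed `SeedSequence` children), so a fixed configuration is
bit-reproducible per stage and insensitive to stage reordering.

## Problem sizes used in the test suite

Chosen so the full suite runs in about two minutes on one CPU while
keeping Monte-Carlo error well inside the asserted tolerances:
parameter recovery uses 4 traits (2 compounds at h² = 0.5, two sensory
traits at h² = 0.2/0.3) on 1,000 progeny of 50 sires, fitting the
continuous liabilities from the generator's truth store — recovery is
asserted against the simulated covariances, which ordinal
discretization would attenuate.  Its recursive Δσ²ᵤ is checked against
the algebraic value under the true components with an a-priori
tolerance of 15 percentage points (≈ two propagated SEs at this sample
size).  EM monotonicity runs on twenty 60-animal seeded datasets; the
EM-versus-brute-force check uses a 30-animal, 2-trait fixture whose
REML optimum is interior (boundary optima, common at that size, are the
regime where the 4-decimal agreement question is ill-posed).

## Known limitations

- No threshold-model (probit) REML alternative to Snell linearization;
  no genomic relationship matrices; no Bayesian/Gibbs estimation; no a
  priori structural-equation fitting — only the a posteriori transform.
- Dense MME algebra: fits are comfortable up to a few thousand
  animal×trait equations (the 12-trait, ~1,000-animal design fits in
  minutes) but the implementation is not meant for national-scale
  evaluations.
- The r_P reported is the model-based (g+r) form; a raw Pearson
  correlation of pre-adjusted phenotypes would differ slightly.
- Delta-method SEs for derived parameters are first-order
  approximations and can be optimistic near parameter-space boundaries.
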
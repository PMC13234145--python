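# Methods

This note documents the models implemented in `escalade`, the default
parameters and why they were chosen, what the synthetic-data generator
does and does not emulate, and the design decisions taken where the
methodology left room.

## Behavioral layer

**Progressive-ratio requirement.** The j-th reward on the PR schedule
costs `round(5·e^(0.2·j) − 5)` responses, floored at 1. Rounding is
half-away-from-zero to the nearest integer; this reproduces the
canonical published ratio sequence (1, 2, 4, 6, 9, 12, 15, 20, 25,
32, …). Sessions-to-breakpoint analytics beyond averaging are out of
scope.

**Breakpoint z-scores.** Per-rat breakpoints are averaged over the final
window (default 3 days, when responding has stabilized) and standardized
against the cohort's own mean and *sample* standard deviation (n−1
denominator, matching standard statistical software). A degenerate
cohort (zero spread) is an error rather than a silent zero.

**Composite behavioral score.** For validation, each rat's reinforced
(X₁), futile (X₂) and inactive (X₃) presses are averaged over the last 7
sessions and standardized against the low-intake reference group:
`Z_total = (z₁ − z₂ + z₃)/3`. The minus sign on the futile term is kept
as printed in the source methodology even though futile pressing rises
with escalation; the `signs` parameter exposes it explicitly rather
than silently "fixing" it. An alternative summary is the first
principal component of (X₁, X₂, X₃) on the correlation scale, with the
sign oriented toward reinforced pressing so it is deterministic across
platforms.

## Latent growth curve model

The marginal model is `y_i ~ N(X_i β, Z_i G Z_iᵀ + σ²I)` per rat, with
`X_i = [1, t, t², z_i, z_i t, z_i t²]`, `Z_i = [1, t, t²]`, day 1 coded
t = 0 so the covariate's intercept interaction c₀ is the effect on the
*initial* level. Partially observed rats enter with their available
days (rats sharing a day pattern are grouped for vectorized algebra).

Estimation maximizes the likelihood over `(chol(G), log σ²)` with β
profiled out by GLS, using L-BFGS-B with seeded random restarts
(default 5; 1 suffices for well-behaved designs and is used in the
calibration studies). `G` is positive semidefinite by construction.
ML is the default criterion because the targets are tests on fixed
effects; REML is available behind a flag. `log σ²` is bounded in
±30 so that noise-free (interpolating) data remain well defined.

Hypothesis tests are Wald chi-square on the covariate block:
(c₀, c₁, c₂) jointly for the *overall* association (df 3), c₀ for the
*initial* level (df 1), (c₁, c₂) for the *change* over sessions (df 2),
using the profiled-likelihood fixed-effect covariance. Simulation at
the package's cohort scale (60 rats, 21 days) puts the tests' type-I
error near nominal (the seeded 500-replicate calibration study lands
all three within [0.03, 0.07] at α = 0.05) with power ≥ 0.8 for the
initial-level test when c₀ is half the rat-level intercept sd. As
with any plug-in mixed-model Wald test, the fixed-effect covariance
ignores the uncertainty of the estimated variance components: at 60
rats the reported standard errors run ≈ 10% below the empirical
sampling spread, so the joint (df 3) test can reach ≈ 0.07–0.08
rejection in unlucky batches. This is the stated method's known
small-sample behavior, shared by the mixed-model software it mirrors;
a Kenward–Roger-type correction is deliberately out of scope. A
constant covariate is dropped with a warning, reducing to the
covariate-free growth model (identical likelihood).

statsmodels' `MixedLM` fits the same structure and serves as an
independent cross-check in the test suite; the implementation here is
self-contained because the profiled, pattern-grouped likelihood is
roughly an order of magnitude faster for the repeated-simulation
studies this package runs.

## Group-based trajectory mixture

Rats are assigned to latent groups whose three outcomes follow
polynomial mean trajectories with censored-normal observation:
an interior value y contributes `φ((y−μ)/σ)/σ`; a value at the lower or
upper recording limit contributes `Φ((lower−μ)/σ)` or
`1 − Φ((upper−μ)/σ)`. Defaults mirror the two study phases: the
21-day escalation phase censors reinforced presses at (0, 500) and the
log(x+1)-transformed futile/inactive presses at (0, 10); the 7-day
acquisition phase uses raw-scale limits (30, 70, 40). The lower bound
defaults to 0 on the modeling scale (only upper limits are stated by
the source methodology). Noise scales are shared across groups within
an outcome (the classic default of trajectory software); per-group
scales sit behind a flag.

EM details: posteriors by log-sum-exp; mixing proportions closed form;
trajectory coefficients and σ by weighted least squares when no
observation sits at a limit (exact M-step), otherwise by L-BFGS-B on
the weighted censored likelihood warm-started from the previous
parameters (a generalized-EM step that never decreases the objective;
the observed-data log-likelihood trace is monotone to 1e-8 and is
asserted in tests). Initialization is k-means on per-rat (mean, slope)
features per outcome, softened, with seeded jitter across restarts;
a start that empties a group is discarded. Final groups are relabeled
in ascending order of mean fitted reinforced pressing, so higher group
numbers mean higher intake; MAP ties break toward the lower group.

Model selection fits each candidate group count and reports
log-likelihood, `BIC = −2·loglik + p·log(n_rats)` and AIC; the chosen G
minimizes BIC (the raw log-likelihood is kept alongside for
likelihood-based comparison). Parameter count: (G−1) mixing + group
polynomial coefficients + noise scales.

Cross-phase association between two independent groupings uses a
Fisher-type exact test after excluding groups with fewer than 3
members: `fisher_exact` for 2×2; otherwise Freeman–Halton by full
enumeration of tables with the observed margins (probability-ordering),
falling back to seeded Monte-Carlo permutation (default 1e5 draws,
reported with its binomial standard error) when the enumeration would
exceed a table cap.

## Differential expression

Counts are filtered at a minimum row total (default 10: a gene with
total 10 is kept, 9 is removed), normalized by median-of-ratios
(pseudo-reference = per-gene geometric mean over genes positive in
every sample; factors rescaled to geometric mean 1), and fit per gene
with an NB log-link GLM — intercept, treatment-coded group, binary sex
— with log size factors as offsets. All genes share the design matrix,
so the IRLS is batched across genes (einsum-based weighted least
squares); this is what makes thousands of permutation refits cheap.

Dispersion is a per-gene moment estimator matching the Pearson
chi-square statistic: solve `Σ (y−μ)²/(μ(1+αμ)) = n − p` for α by
bisection, floored at 1e-8, with μ from a Poisson pre-fit. No
empirical-Bayes shrinkage is applied — a deliberate divergence from
shrinkage-based DE packages: the inferential weight here is carried by
the permutation layer, and the simplified parametric core is validated
by null-calibration simulations (fraction of p < 0.05 ≈ 0.065 at
24 samples; the chi-square-matching estimator was chosen over the
simpler linear moment estimator, which left the null fraction at the
edge of acceptability, ≈ 0.070).

Wald statistics are `cᵀβ̂ / se(cᵀβ̂)` for the requested group contrast
with two-sided normal p-values; a group contrasted with itself returns
log₂FC 0 and p 1 by construction.

**Permutation p-values.** Group labels are permuted across samples
(unrestricted by default; a strata option permits within-sex
permutation) and the statistic — pairwise |Wald| or an omnibus NB
deviance drop of the group factor ("lrt") — is recomputed with
dispersions held fixed at their observed-data estimates. p =
(1 + #{|T_b| ≥ |T_obs|})/(B + 1), never exactly zero, deterministic
given the seed. When fewer distinct label arrangements than B exist
they are enumerated exactly (identity included) and the exact p is
returned. The permutation scheme of the original supplement is not
available; unrestricted permutation of group labels with the Wald
statistic is the package's documented default assumption. Null
simulations at 2000 genes / 24 samples / B = 1000 give a p < 0.05
fraction of ≈ 0.05 and a KS distance to uniform < 0.05.

BH adjustment delegates to statsmodels' step-up implementation, with
missing p-values propagated.

## Signed co-expression network

Adjacency `a_ij = ((1 + cor_ij)/2)^β` with Pearson correlation (a
biweight option was considered unnecessary for the synthetic scope);
default β = 17 per the published network settings. TOM:
`(Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`, unit
diagonal; bounds and symmetry are property-tested over random
networks.

**Module detection.** Average-linkage clustering of 1 − TOM, then a
deterministic recursive cut: each branch is split at the highest merge
height producing at least two children of the minimum size (default
30), recursing into children. A single static height cut was tried
first and provably fails on planted-block designs — uncorrelated
background genes merge above the heights at which distinct blocks
join, so every static cut either glues blocks together or shatters
everything; recursive splitting separates blocks regardless of where
their join falls in the dendrogram, and any over-splitting is undone
by the eigengene merge below. After cutting, a membership (kME)
filter releases genes whose signed correlation with their module
eigengene is below 0.3 — standard network practice that also prevents
tight sub-minimum blocks from hiding inside loose background
clusters — then modules with eigengene dissimilarity `1 − cor` below
the merge threshold (default 0.2) are merged iteratively. Modules are
named along the conventional color sequence by descending size;
"grey" is unassigned.

Eigengenes are the leading right singular vector of the module's
z-scored member × sample matrix (unit norm, sign oriented so the mean
member correlation is positive). Module–trait relations are Pearson
correlations against numeric traits (group one-hot indicators, binary
sex) with p from the t reference on n − 2 df — at n = 24 this
reference pairs r = 0.5522 with p ≈ 0.005, the pairing the module
heat-map convention expects. Intramodular connectivity is the sum of a
gene's adjacency to its module mates (missing for grey genes).

## Priority scoring and validation

`priority = −log₁₀(adjP) · |log₂FC| · log₁₀(kWithin)`. The score is
zero when any factor is null and *negative* when kWithin < 1 — the
formula's own behavior, kept so weakly connected genes rank at the
bottom; adjusted p-values of exactly 0 are floored at the smallest
positive float with a warning, since the formula is undefined at 0.
Ranking is per module, descending, with gene-id tie-breaks.

ΔΔCt: `dCt = Ct_gene − Ct_housekeeping` per rat, referenced to the
arithmetic mean dCt of the reference group (the canonical 2^−ΔΔCt
recipe, not a geometric mean of folds); fold = 2^−ΔΔCt. Whole-plate Ct
offsets cancel by construction. Rats without a housekeeping
measurement are excluded with a warning.

Stepwise regression is the classic cycle — entry first (largest
partial F among excluded predictors enters if F ≥ F-to-enter, default
2), then removal (smallest partial F among included leaves if
F < F-to-remove, default 1) — until no change, followed by a final OLS
report (R², overall F and p, fitted-vs-observed pairs). A note on
what the selection test can show: with F-to-enter = 2, a *random*
null predictor clears entry with probability ≈ 0.16, so on designs
with random noise one of several null columns will typically enter;
the package's selection-accuracy test therefore uses an orthonormal
design whose null columns carry exactly zero in-sample association
(noise projected orthogonal to them), which isolates the threshold
semantics of the algorithm itself.

## Synthetic-data generator

The generator defines the study conditions for all tests.

*Behavior*: 58 rats × 21 days by default, three latent groups with
mixing (0.30, 0.42, 0.28) and polynomial trajectories shaped like the
low / medium / high escalator phenotypes (shallow linear ≈ 20→60,
steeper linear ≈ 30→130, steep with plateau ≈ 40→220 reinforced
presses); futile and inactive presses are generated on the log(x+1)
scale and back-transformed to integer counts (`exp(v) − 1`, floored at
0, rounded). Noise sd defaults: 12 presses (reinforced), 0.5 log-units
(futile/inactive). Values beyond a censor limit are recorded at the
limit and flagged. Optional rat-level Gaussian random coefficients
(`re_sd`) turn the generator into the exact LGCM generative model for
calibration studies. The covariate effect on reinforced pressing
defaults to 6 presses per SD on the day-1 level — the magnitude of the
reported motivation–intake association — and 0 on the change terms.
No printed per-group coefficients exist to calibrate against; the
shapes are qualitative.

*Counts*: genes in each planted module load (uniform 0.3–0.6) on a
shared standard-normal factor; module 0's factor mean shifts by group
(0, 1, 2 across the three groups — calibrated so the shifted module's
eigengene–group correlation lands near the printed module–trait
magnitudes, R ≈ 0.5–0.7); background genes are independent. Counts are
negative binomial (gamma–Poisson) with log-uniform library sizes
(0.5–2.0) and dispersion 0.05. The recorded truth includes module
membership, per-sample factors, the planted DE gene set, and each
gene's expected fold change per group (`exp(loading · Δshift)`), which
seeds the qPCR generator.

*qPCR*: `Ct = baseline − log₂(fold) + plate + noise`, housekeeping Ct
independent of group, so ΔΔCt recovers the planted fold exactly in the
noise-free limit.

What the generator does **not** emulate: within-session dynamics
(timeouts, cue responses), sex differences in behavior, correlated
background gene structure, batch effects, amplification-efficiency
variation in qPCR, and gene-length or GC biases in counts. Passing
tests therefore demonstrate correctness of the estimators under the
stated models, not robustness to every artifact of real operant or
sequencing data.

## Problem sizes and numerical choices

Simulation studies run at the cohort scales above: 60 rats for
trajectory recovery and growth-model calibration (500 null
replicates), 2000 genes × 24 samples × 1000 permutations for DE
calibration, 600 genes × 24 samples for module recovery, 100
replicates for stepwise selection. EM converges on relative
log-likelihood change 1e-7 (max 300 iterations); IRLS on coefficient
change 1e-8 (1e-6 within permutation loops); the LGCM optimizer bounds
log σ² in ±30; dispersions are floored at 1e-8; module detection caps
candidate cut heights at the 0.99 merge-height quantile. The pipeline
derives every stage's seed from one root seed via named substreams, so
a rerun is byte-identical.

## Known limitations

- The parametric NB Wald test is mildly anticonservative at small n
  (null fraction ≈ 0.065 at 24 samples); the permutation layer is the
  calibrated inference path.
- Group-membership probabilities in the mixture carry no covariates;
  associations with antecedent measures are tested post hoc.
- The exact r×c association test switches to Monte-Carlo beyond an
  enumeration cap; its p then carries a reported standard error.
- Stepwise selection inherits the classic procedure's null-entry rate;
  see the note above.
- No dual-trajectory (joint cross-phase) models, no zero-inflated
  outcome families, no consensus/multi-set networks, no enrichment or
  transcription-factor prediction.
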
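# Methods

## The model

Directed binary nominations between adults of different households are
modelled with a probit latent response.  For actor *i* in household *k*
and partner *j* in household *l*,

    y*_ik,jl = x_ik,jl β + a2_k + a1_ik + b2_l + b1_jl
               + c_ik,l + d_k,jl + h_k,l + u_|ik,jl| + e_ik,jl,
    y_ik,jl  = 1{y*_ik,jl ≥ 0},   e ~ N(0, 1).

The residual variance is fixed at 1 to identify the probit scale.  The
random-effect blocks and their joint distributions:

| block | level | pairing | free parameters |
|---|---|---|---|
| (a2_k, b2_k) | household giving/receiving | bivariate normal | σ²_a2, σ²_b2, ρ_a2b2 |
| (a1_ik, b1_ik) | individual giving/receiving | bivariate normal | σ²_a1, σ²_b1, ρ_a1b1 |
| (c_ik,l, d_l,ik) | individual ↔ foreign household | bivariate normal | σ²_c, σ²_d, ρ_cd |
| (h_k,l, h_l,k) | ordered household pair | common variance, correlated | σ²_h, ρ_hh |
| u_\|ik,jl\| | unordered individual dyad | univariate normal | σ²_u |

The actor-group pairing deserves emphasis because mispairing silently
destroys ρ_cd: the effect `c` of individual *i* toward household *l* is
coupled with the effect `d` of household *l* toward individual *i* —
both are keyed by the same (individual, foreign-household) pair.

Derived quantities, computed per posterior draw and then summarized:
ρ_uu = σ²_u/(σ²_u + 1), and the variance partition coefficients
p_x = σ²_x / (Σ all eight variances + 1), except p_u whose numerator is
σ²_u + 1.  The eight shares sum to one by construction.  Because they
are summarized as posterior means of per-draw ratios, a reported VPC
can differ in the third decimal from the ratio of reported
posterior-mean variances; the package's worked-example tests document
one such case (the partner-group share of the empty full model, ratio
of means 0.115).

Model ids 0–6 select both the random-effect structure and the
fixed-effect roster: model 0 is the conventional SRM (individual pair +
dyad effect, intercept only), model 1 adds the full group structure,
model 2 the covariate base set (21 columns), model 3 the dyadic
relatedness × wealth interactions, model 4 the household-relatedness ×
wealth interactions, model 5 the infidelity-tie indicator, model 6 the
kinship × household-relatedness cross-level interactions.  All
lower-order terms of any interaction are always included.

## Covariates

- **Wright's r** from the pedigree: r = 2φ/√((1+F_a)(1+F_b)) with φ the
  Malecot kinship by the standard recursion and F the inbreeding
  coefficient.  Unknown parents are treated as unique unrelated
  founders.  Study-scale communities are essentially outbred, so in
  practice r ≈ 2φ.
- **Affinal r**: the largest relatedness between one dyad member and
  any *current* spouse of the other (both directions scanned).  If the
  dyad also has a direct consanguineal tie r > 0, the affinal value is
  kept only when it is at least twice that tie, else set to 0.  Former
  unions are excluded — the construct follows present-tense marriage;
  this is a documented choice, configurable by editing the union table.
- **Godparent indicator**: one member is godparent of the other or of
  any of the other's children, either direction.
- **Infidelity tie** (household pair): some extra-pair-conceived
  individual resides in one household while a half-sibling (exactly one
  shared recorded parent) resides in the other.
- **Average inter-household relatedness**: mean pairwise r between the
  members, log-transformed with an ε = 10⁻⁴ floor before the log when
  the mean is zero, then centred at the sample mean over household
  dyads.  The centring constant is stored in the design metadata so
  predictions reuse the training-data scale.
- **Distance**: log Euclidean metres between houses with a 1 m floor
  for coincident coordinates.
- **Individual attributes**: age, BMI and skin reflectance are z-scored
  over the roster; age is standardized first and then squared (the
  alternative order is a one-line change where the quadratic column is
  built).  Sex uses a male indicator with female reference.
  Wealth is the natural log of thousands of cordobas, not z-scored.

Only inter-household directed dyads enter the design; within-household
relations are near-saturated in roster interviews and are excluded by
the upstream readers (with a logged count).

## Priors and sampler

Estimation uses Albert–Chib data augmentation: truncated-normal latent
responses, then exact normal conditionals for β and every random-effect
vector, then conjugate variance updates.  Correlated pairs are updated
as two alternating vectorized half-steps (all entries of one member of
a pair are conditionally independent given the other member, because no
two entries of the same vector ever share a dyad row).

Priors, all configurable via `Priors`:

- β ~ N(0, 5²) per coefficient.
- Each free 2×2 covariance block ~ inverse-Wishart(df = 3, scale = I).
  With df = p + 1 the implied marginal prior on the correlation is
  uniform on (−1, 1); the implied marginal on each variance is heavy
  tailed, weakly favouring values below ~1.
- σ²_u ~ inverse-gamma(2, 1) (prior mean 1, infinite variance).
- The household-pair block has equal variances by construction, so an
  inverse-Wishart is not applicable; instead the rotated components
  s = (h_kl + h_lk)/√2 and t = (h_kl − h_lk)/√2 are independent with
  variances λ_s = σ²_h(1 + ρ_hh) and λ_t = σ²_h(1 − ρ_hh), each given
  an inverse-gamma(2, 1) prior.  This keeps the update conjugate and
  constrains ρ_hh to (−1, 1) automatically.

The conjugate family was chosen over half-normal/LKJ priors to keep
every Gibbs update exact; at the data sizes involved the posteriors are
likelihood-dominated and the substitution is immaterial for the
reported quantities.

Chains are seeded by spawning independent child streams from a single
seed, so chain *c* reproduces its draws exactly regardless of how many
chains run.  Convergence gates: split-chain scale reduction < 1.05 and
bulk effective sample size > 200 per reported parameter (4 chains
default); failing the gate raises a warning, never passes silently.
Truncated-normal draws use lower-tail inverse-CDF sampling with
reflection for the positive branch, which stays accurate arbitrarily
far into the tails.

Counterfactual predictions condition on all random effects at zero
(closest to how worked probabilities are usually reported); a marginal
option divides the linear predictor by √(1 + Σ variances) per draw and
is labelled as such.  The covariate-holding convention for scenarios:
indicator columns at the reference level 0, continuous main effects at
their sample means (0 for z-scored columns), quadratic columns at the
sample mean of the squared column (≈1 for a z-scored variable), product
columns at the product of the held main effects unless a parent column
is overridden, in which case the product is recomputed.  Reported
worked probabilities from the motivating study are reproduced to
within a few percentage points under this convention, but the original
convention is not printed, so tests check them with a tolerance rather
than exactly.

## Synthetic communities

The generator emulates the covariate structure of the motivating field
site, not its demography: 8 founder couples, three generations, Poisson
offspring (mean 4.5) thinned by a survival-to-residency probability of
0.85, marriage rate 0.8 with 70% of spouses found locally among
unrelated candidates (pairwise r ≤ 0.06, reflecting cousin-marriage
avoidance) and the rest immigrants, extra-pair conception probability
0.05, a 60% uxorilocal residence bias, and household merging/splitting
to hit exactly the configured 32 households.  Adults (age ≥ 18) are
trimmed at random to the target roster size of 108.  Attribute
distributions match the published summary moments (age ≈ 34.5 ± 13.8,
BMI ≈ 23.9, melanin index ≈ 51.6, log-wealth −0.92 ± 1.07 in thousands
of cordobas, houses uniform on a 700 m square).  Under the default
configuration the mean pairwise inter-household relatedness stays
within [0.02, 0.10] across seeds (field value ≈ 0.05), and the
infidelity-tie rate across household dyads is ≈ 0.01.

What the generator does *not* emulate: age-structured mortality and
fertility, divorce and remarriage chains, polygyny, migration waves,
wealth–kinship correlations, or any behavioural feedback from the
network onto residence.  Passing tests on synthetic data therefore
demonstrate statistical correctness of the estimator and covariate
machinery under the model's own assumptions, not robustness to the
misspecification patterns of real communities.

## Simulation experiments and problem sizes

Two experiments mirror the methodological checks of the motivating
analysis, at sizes chosen for a single-CPU desk run:

- **Parameter recovery**: 20 replicates of a 20-household × 5-member
  balanced community (9 500 directed dyads) simulated from moderate
  generating values with all four correlations non-zero, refitted with
  2 chains × (1 200 warmup + 1 200 draws).  Acceptance: the 90%
  credible intervals cover the generating variance/correlation values
  in at least 80% of parameter-replicate pairs (observed ≈ 0.93).
- **Informant error**: extra N(0, sd²) noise injected into the
  informant-side receiving effect b1 before thresholding, over
  sd ∈ {0, 0.75, 1.5}, two replicates each.  The generalized
  reciprocity correlation ρ_a1b1 attenuates by ≈ 0.3 at the largest sd
  (the classical √(σ²_b1/(σ²_b1+sd²)) factor), while the dyadic
  reciprocities ρ_hh and ρ_uu remain within Monte-Carlo error of their
  generating values — dyad-level conclusions are robust to informant
  inaccuracy.

## Numerical notes and limitations

- Posteriors for very small communities (≲ 8 households) are genuinely
  diffuse: the symmetric-dyad, household-pair and residual scales are
  weakly separated with few household pairs, and variance posteriors
  can be heavy-tailed.  Use posterior medians and expect wide
  intervals at that scale.
- The effect-contribution vector is maintained incrementally during a
  sweep and refreshed every 200 iterations to shed float drift.
- Zero-variance blocks make the corresponding free correlation
  undefined; it is reported as NaN, never silently as 0.
- Count or continuous responses, intra-household relations, ERGM-style
  triadic terms and model-comparison criteria are out of scope.
- The fit refuses datasets where any directed dyad lacks its reverse
  direction, since every block above the individual level is defined on
  complete dyads.
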
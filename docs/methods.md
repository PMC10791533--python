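# Methods

This note documents the models, numerical choices and limitations behind
`dyadkin`.  The package analyses dispersal and inbreeding avoidance in a
long-lived social mammal community from three data sources: observational
residency/parentage records, a microsatellite-style pedigree, and
low-coverage sequencing data summarized as genotype likelihoods.

## Demographic conventions

* **Conception dates** are the birth date minus 228 days (gestation
  offset), with exact calendar arithmetic (leap years respected).
* **Ages** are fractional 365.25-day years.  An individual is
  *reproductively aged* from 10.5 years (inclusive), a threshold below the
  earliest observed ages at first conception in this kind of community.
* **Immigrant females** are assumed to be 13 years old on arrival — the
  typical female dispersal age — whenever their true birth date is
  unknown; their birth date is imputed as arrival − 13 years.
* **Philopatry rate**: among natal females who *reached* their 13th
  birthday inside the study window (females who died earlier never faced
  the dispersal decision and are excluded), the percentage who never
  emigrated.  Emigration is a terminated residency interval with no death
  date; death is not emigration, so a female who stayed and died counts as
  philopatric.  An empty denominator raises an explicit error rather than
  returning 0.
* **Potential sires** for an offspring: genotyped males, reproductively
  aged at conception, with at least one day of community residency inside
  the closed window [conception − 15 d, conception + 15 d], excluding the
  actual sire.  The ±15-day window accommodates uncertainty in the
  conception date.  Partial-window presence is deliberately read weakly
  (≥ 1 day suffices); requiring presence on the conception day itself
  would be the strictest alternative and is not used.  Mothers are not
  themselves required to pass the age threshold — the definition
  constrains the male pool only.
* Offspring whose sire is unknown or ungenotyped contribute **no rows** to
  the pair table (neither actual nor potential), keeping the
  actual/potential design balanced per offspring.

## Pedigree kinship

Kinship θ is computed with the standard recursion θ(a,a) = ½(1+F_a),
θ(a,b) = ½[θ(sire_a, b) + θ(dam_a, b)], recursing on the individual that
appears later in a topological order (so it cannot be an ancestor of the
other); a missing parent contributes 0.  Founders — individuals with both
parents unknown, including immigrant females — are assumed unrelated and
non-inbred, and F of any individual with an unknown parent is 0.  On an
acyclic pedigree this agrees exactly with Wright's path counting, which
the test suite implements independently as an oracle.

Expected relatedness is r = 2θ / √((1+F_a)(1+F_b)).  Closed forms:
parent–offspring and full siblings 0.5, half siblings 0.25, full first
cousins 0.125 (kinship 0.0625), a female and her paternal half-nephew
0.125.

**Pedigree depth** counts complete ancestral generations: 0 if any parent
is unknown, otherwise 1 + the minimum parental depth.

**Cryptic relatives** are pairs with no pedigree connection whose genetic
relatedness falls in [0.1, 0.35] (both bounds are parameters).  The band
corresponds to roughly full-cousin through half-sibling relationships;
full siblings (≈0.5) fall outside it and are more likely recording errors
than cryptic links.

## Genotype-likelihood relatedness

At a biallelic site the four alleles of a pair occupy one of the nine
condensed Jacquard identity states.  The state-conditional genotype-pair
probabilities P(g₁,g₂ | k, p) are derived by enumerating independent
allele draws per IBD class (each class draws the minor allele with
probability p) — an exact computation rather than a transcribed table,
verified in tests against Monte-Carlo allele dropping.

Per-site likelihoods mix over genotypes with the individuals' genotype
likelihood triples, and over states with Δ:

    P(site) = Σ_{g₁,g₂} L₁(g₁) L₂(g₂) Σ_k Δ_k P(g₁,g₂ | k, p)

Δ is estimated by EM on this 9-component mixture.  The E-step posterior
column sums are computed without materializing the site × state
responsibility matrix (Δ′ = Δ ∘ (Pᵀ s⁻¹)/S, with s the site likelihoods),
which makes 20k-site pairs fast.  Iteration starts at the simplex
barycentre plus 2 seeded Dirichlet restarts, stops when the log-likelihood
improves by < 1e-6 or after 500 iterations, and is monotone
non-decreasing by construction (asserted in tests).  Sites missing in
either member are dropped pairwise; fewer than 100 shared sites triggers a
warning.

From Δ: θ = Δ₁ + (Δ₃+Δ₅+Δ₇)/2 + Δ₈/4, F₁ = Δ₁+Δ₂+Δ₃+Δ₄,
F₂ = Δ₁+Δ₂+Δ₅+Δ₆, and the reported relatedness is the
inbreeding-robust form r = 4θ / (2+F₁+F₂), i.e. kinship normalized by the
arithmetic mean of the two self-kinships.  Both the arithmetic- and
geometric-mean normalizations reduce to 2θ for outbred pairs; the
arithmetic mean is used throughout.

**Allele frequencies** come from a reference panel distinct from the
focal community.  Using the community itself would bias frequencies
wherever close kin are over-represented; a random sample from the wider
population avoids this.  Panel-based sample frequencies carry a 0.5
pseudocount so monomorphic-in-panel sites stay strictly inside (0,1)
(such sites are normally removed by the MAF filter anyway).

**Site filters**, applied to the panel: non-missing fraction ≥ 0.9,
Hardy–Weinberg equilibrium retained at p ≥ 0.001 under a 1-df
likelihood-ratio test on hard-called genotype counts (free genotype
frequencies versus HWE at the ML allele frequency), and minor-allele
frequency ≥ 0.05.  The MAF default is a package choice exposed as a
parameter.  No LD pruning is performed; the simulator's sites are
unlinked, so pruning would be a no-op there.

**Validation** regresses genetic r on pedigree-expected r by OLS over
labelled pairs and reports R², slope and intercept.  Because the
estimator is constrained to Δ ≥ 0, unrelated pairs acquire a small
positive bias (the intercept in a well-calibrated run sits near +0.02 at
depth 8 with 20k sites); the slope stays near 1.

## The avoidance GLMM

Observed relatedness of (mother, male) pairs is modelled as

    y ~ Beta(μφ, (1−μ)φ)
    logit(μ) = α + β_A·A + β_nat[n] + β_int[n]·A + u_off + v_i + v_j

Natal mothers and potential pairs are the reference level, so β_A is the
actual-versus-potential shift for natal females and β_int the extra shift
for immigrant/unknown mothers.  Offspring effects u (sd σ_u) absorb
repeated offspring per mother/sire; individual effects v (sd σ_v) enter as
a multi-membership term — both members of a dyad contribute a draw from
one shared individual-level distribution, via a joint index over all
mothers and males.  The likelihood is therefore invariant to within-pair
member order.

Zeros in y are impossible under a logit-link beta, so all outcomes are
shifted by +0.0001 (and clamped strictly below 1).

**Priors** (weakly regularizing): α ~ N(−4, 1.5) on the logit scale
(centred near a mean relatedness of ≈ 0.02), β ~ N(0, 1),
σ_u, σ_v ~ Exponential(1), log φ ~ N(3, 2).  One shared σ_v covers
mothers and males.

**Sampling**: Hamiltonian Monte Carlo with analytic gradients (the beta
log-density derivatives use digamma functions; gradients are
finite-difference-checked in tests).  The varying effects use the
non-centred parametrization u = σ_u z_u, v = σ_v z_v with standard-normal
z, which removes the funnel between σ and the effects.  Warmup adapts the
step size by dual averaging toward 0.85 acceptance and estimates a
diagonal mass matrix from the middle warmup window; trajectories use ~24
jittered leapfrog steps; an energy error above 1000 counts as a
divergence.  Chains run from independent substreams of one seed, so runs
are bit-reproducible.  Split R-hat and effective sample sizes are computed
for every parameter (via ArviZ); any R-hat above 1.05 raises an error by
default rather than returning silently.

**Predictions**: for each (natality, actual/potential) category, 1000
evenly thinned posterior draws of the fixed-effect linear predictor are
mapped through the inverse logit with varying effects at zero
(population-average pair).  Reported: the median, the central 89%
percentile interval (a percentile interval, not an HPDI — recorded in the
output metadata), and the percent difference
100·(actual − potential)/potential rounded to two decimals.

## The community simulator

An annual event loop over a configurable horizon (default 45 years from
40 founders): deaths (age-banded hazards: 0.04 below 5 y, 0.02 to 35 y,
0.15 after), Poisson immigration of 13-year-old females, natal female
emigration at the 13-year dispersal age with probability 0.5 (the headline
philopatry condition), then births: each resident female of fertility age
conceives with probability 0.22/year, and the sire is drawn among males
resident at conception and aged ≥ 10.5 with probability ∝ exp(−γ·r), r
being the expected relatedness on the *hidden* pedigree.  γ = 0 is exact
random mating (the null); γ ≈ 30 effectively eliminates matings with
r ≥ 0.125.

Immigrants carry hidden two-generation external pedigrees: external
families occasionally reuse whole parent pairs (full-sib immigrants), a
single parent (half sibs), or external grandparents (first cousins), so
cryptic-relative detection has planted truth in the 0.1–0.35 band.  The
observable pedigree masks all external ancestry (immigrants become
founders) and founder-generation natality is recorded as unknown,
mirroring the oldest individuals in a real study.  Individuals dying
before age 2 are not genotyped.

Genotypes are gene-dropped down the hidden pedigree at unlinked biallelic
sites (founders Binomial(2, p); one uniformly chosen allele per parent,
independent across sites), with site frequencies Uniform(0.05, 0.5).
Genotype likelihoods: per individual-site depth ~ Poisson(λ) (0 ⇒
missing), minor-allele read count ~ Binomial(depth, q_g) with
q_g ∈ {ε, ½, 1−ε}, triples normalized.  A reference panel of unrelated
individuals drawn from the same frequencies provides the allele-frequency
estimates.  All randomness flows from one seed.

What the simulator does **not** emulate: linkage (sites are independent,
so realized relatedness is very tight around pedigree expectations — real
genomes have fewer effectively independent loci and larger Mendelian
noise), age-structured fertility beyond a threshold, interbirth intervals,
read-mapping artefacts, and reference-panel population structure.  Passing
tests therefore demonstrate correctness of the estimators under their own
assumptions, not robustness to these real-data complications.

## Problem sizes used in the automated checks

Chosen as the package's own balance of statistical resolution and
single-CPU runtime:

* Validation study: 300 labelled pairs (60 per class at expected r of 0,
  0.0625, 0.125, 0.25, 0.5), 20,000 sites, mean depth 8, base error 1%.
* GLMM parameter recovery: 20 replicates of ~1,700 rows (80 offspring,
  95 individuals), matching the dyadic study's scale; at much smaller
  sizes the N(0,1) coefficient prior visibly shrinks large effects and
  interval coverage dips below nominal.
* End-to-end null/alternative discrimination: communities of ~200 recent
  offspring with the actual pair plus 8 randomly subsampled potential
  sires each (a uniform subsample of the roster preserves the
  random-mating null), 5,000 sites.  With mostly-zero outcomes the
  avoidance effect compresses on the logit scale (most potential pairs
  are also unrelated), so ~200 actual pairs are needed before the 89%
  interval reliably separates γ = 30 from γ = 0.

## Known limitations

* The EM estimator's non-negativity constraint biases r upward by ~0.01–
  0.02 for truly unrelated pairs at moderate depth and site counts; this
  appears as a positive intercept in the validation regression, not as a
  slope distortion.
* The HMC sampler uses static jittered trajectories, not NUTS; for this
  model's dimensionality (a few hundred parameters) it converges in a few
  hundred warmup iterations, but pathological configurations (φ → 0,
  empty categories) may need larger warmup.
* Beta regression treats measurement noise in y as biological dispersion;
  φ conflates the two.  With few sites the compressed contrast
  systematically understates avoidance strength — a caveat shared by the
  modelling approach itself, not just this implementation.
* The pipeline assumes the observer-supplied disambiguation of death
  versus emigration is correct; it never infers it.
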
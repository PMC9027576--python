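# Methods

## The model

All genetic analyses are based on the linear animal model

    y = Xb + Za + Wc + e

where `y` holds one transformed trait (or two, stacked, in bivariate
fits), `b` the fixed effects — genetic line (2 levels), sex (3 levels:
male, female, castrated), batch (14 levels, pens mixed on the same day)
and a centred weight-at-mixing covariate — `a` the additive genetic
effects of every pedigree animal, `c` the common environmental pen
effects, and `e` the residuals.  Priors are

    a | A, G0 ~ N(0, A ⊗ G0)      c | C0 ~ N(0, I ⊗ C0)      e | R0 ~ N(0, I ⊗ R0)

with `A` the numerator relationship matrix.  Heritability is
`h² = σ²a / (σ²a + σ²c + σ²e)`, the pen-effect ratio
`c² = σ²c / (σ²a + σ²c + σ²e)`, and the genetic correlation
`rg = G0[1,2] / sqrt(G0[1,1] G0[2,2])`.

Binary traits (clique membership, categorical betweenness) use the
threshold-liability version: an unobserved normal liability underlies each
record and the observed category indicates which side of a threshold it
fell on.  Identifiability is fixed the standard way — threshold at 0,
liability residual variance at 1 — so threshold-trait heritabilities are
on the liability scale.  In bivariate linear–threshold fits the residual
*covariance* with the other trait stays free; the unit constraint is
imposed by rescaling the threshold trait's scale after every residual
covariance draw.  The threshold–threshold combination is implemented with
the same rescaling applied to both traits, but has not been validated as
thoroughly and is flagged experimental.

## Pedigree algebra

`A` is built by the tabular method; inbreeding is tracked via the
coancestry recursion (the two-generation populations generated here are
non-inbred, but the machinery is correct for arbitrary pedigrees, which
also gives the test suite its oracle: `A = 2 × kinship` must hold
exactly).  The sparse `A⁻¹` is assembled directly with Henderson's rules
using inbreeding-adjusted Mendelian-sampling variances; its nonzeros are
confined to {animal, sire, dam} triples.

## Gibbs sampling

Location effects are updated by single-site Gauss–Seidel sampling of the
mixed-model equations: each fixed effect, each animal effect and each pen
effect is drawn from its scalar (univariate) or 2×2 (bivariate) normal
full conditional while a running residual vector is kept in sync.  This is
the classical animal-breeding Gibbs scheme; the iteration kernel is
numba-compiled, which is what makes the chain protocols below practical on
one CPU (a 50,000-iteration univariate chain on ~2,500 pedigree animals
takes about 10 s).  A blocked sparse-factorisation update would mix faster
per iteration but costs a factorisation per iteration; at these problem
sizes the single-site kernel is the better trade and is the default.

Covariance components are drawn from their scaled inverse chi-square
(univariate) or inverse-Wishart (bivariate) full conditionals.  Two priors
are available:

- `flat` (default): improper inverse-Wishart with ν = −(k+1) and zero
  scale, the conventional "flat covariance prior" of animal-model Gibbs
  software;
- `weak`: proper inverse-Wishart with ν = k+1 and scale 0.1·I.

For linear models on the data sizes used here the flat prior behaves
well.  For threshold models it does not: with binary data the likelihood
constrains the liability-scale variances weakly, and flat-prior chains can
wander into effectively improper regions (we observed h² chains drifting
above 0.8 with effective sample sizes below 10).  Threshold fits in the
validation studies therefore use the `weak` prior.

Chain protocols: the full-scale default for final analyses is 1,000,000
iterations, 100,000 burn-in, thinning lag 20.  The validation studies use
reduced desk-scale protocols — 50,000/5,000/10 for linear recovery,
60,000/10,000/10 for threshold, 40,000/5,000/10 for bivariate, and
8,000/1,500/5 for the selection-response sign studies, where only EBV
posterior means are needed.  Chains are bit-reproducible given a seed.

Missing responses are dropped per trait in univariate fits; bivariate fits
keep records observed for either trait and integrate the missing one out
by residual data augmentation.  Convergence can be checked with the
Raftery–Lewis run-length diagnostic (default q = 0.025, r = 0.005,
s = 0.95, with BIC-based selection of the sub-sampling interval for the
dichotomised chain) and a Geyer initial-positive-sequence effective sample
size.

Posterior summaries report the mean, SD and 95% highest posterior density
interval of each derived chain.  The HPD interval is the shortest window
of ⌈0.95 n⌉ sorted draws; ties go to the smallest lower bound.  EBVs are
posterior means of `a`, reported for every pedigree animal including
non-phenotyped ancestors.

## Network traits

Fight and bully records within a pen are merged into one undirected,
unweighted graph; direction, frequency and duration are read but ignored.
Conventions, where more than one normalisation exists:

- degree: raw count and count/(n−1);
- betweenness: normalised by (n−1)(n−2)/2;
- closeness: Wasserman–Faust reachable-set rescaling on disconnected
  graphs; isolates score 0;
- eigenvector: leading eigenvector of the adjacency matrix on the largest
  connected component, max entry scaled to 1 (config-switchable to unit
  L2 norm); nodes outside that component score 0; an edgeless pen yields
  zeros with a warning;
- clustering: local transitivity, defined as 0 for animals with fewer
  than 2 partners so every animal stays phenotyped;
- clique membership: member of ≥1 maximum clique, by exact enumeration
  (pens are small; n ≤ 30 enforced); the edgeless degenerate case makes
  everyone a "member" of a size-1 clique, with a warning;
- categorical betweenness: the cut is the population-wide 75th
  percentile (not per pen), values at the cut classed "high".

Continuous centralities are square-root transformed before modelling;
lesion counts become log(x+1) of the net fresh-lesion count (24 h counts
minus pre-mixing counts, clamped at zero with a logged count of clamped
records; 3-week counts are fresh-lesion recounts used as-is).

## The synthetic-data generator

The generator emulates the structure the analyses assume: 82 founder
sires and 217 founder dams, one litter per dam (default litter size 9.8,
giving ≈ 2,400 animals in the two-generation pedigree), 78 pens of 15
animals of one sex and one genetic line composed of 3 animals from each
of 5 litters, 14 batches allocated round-robin, and a N(28, 3²) kg weight
covariate.  Sex is assigned at pen formation (pens are single-sex by
design, so this is statistically equivalent to sexing at birth and
keeps pen composition feasible at any litter size); line is a litter-level
label with a 61/39 split.  Animals left over when the requested pens are
filled are returned unpenned and carry no phenotype.

Breeding values are gene-dropped (founders iid N(0, G0), offspring =
parent average + Mendelian sampling with covariance (½ − ¼(F_s+F_d))G0);
phenotypes add one pen-effect draw per pen from N(0, C0) and iid
residuals from N(0, R0), plus modest fixed effects.  Phenotypes are
emitted directly on the modelled (transformed) scale, because parameter
recovery is assessed on that scale; raw Poisson lesion counts (with a
small Poisson pre-mixing count) are generated separately to exercise the
count-to-trait transforms.

Aggression networks are generated from a heritable latent
aggressiveness l: each within-pen dyad fights with probability
sigmoid(−1.0 + 0.8(l_i + l_j)) and bullies with probability
sigmoid(−1.6 + 0.8(l_i + l_j)).  The intercepts/slopes were chosen so a
15-pig pen yields about 5–6 interaction partners per animal, the
connectivity regime the modelled traits assume; no claim is made that
this logistic dyad model reproduces real contest dynamics (no temporal
structure, no winner/loser feedback, durations are decorative).

### The realistic preset

The preset sets the generating parameters of the 11 continuous traits
(5 centralities + 6 lesion traits) to values published for this kind of
data: centrality heritabilities 0.26/0.09/0.26/0.22/0.18, pen-effect
ratios 0.02/0.59/0.14/0.01/0.23, phenotypic variances 0.006–0.015 on the
square-root scale; lesion traits use h² = 0.20 and c² = 0.10 (inside the
0.11–0.43 range reported for log-scale lesion counts) with phenotypic
variances matching reported log-scale SDs.  The genetic correlation
matrix reproduces the published pairwise structure — centralities
mutually correlated above 0.96, clustering coefficient correlated below
−0.88 with them, positive centrality × anterior-SL24h and negative
centrality × SL3wk correlations — plus a modest 0.3/0.1 within/across
timepoint lesion–lesion correlation that is not reported anywhere and had
to be chosen.  Pairwise-estimated correlation tables are not jointly
positive definite, so the matrix is projected to the nearest valid
correlation matrix (alternating eigenvalue clipping and unit-diagonal
rescaling); the projection preserves the sign pattern that the
selection-response studies test.  Pen effects are uncorrelated across
traits; residual correlations are 0.4 × the genetic ones, giving
phenotypic correlations in the same direction but weaker, the reported
qualitative pattern.

## Selection response

EBVs are standardised to z-scores (sample SD, divisor n−1;
config-switchable — immaterial at n ≈ 1,100 but fixed for tests).  The
eigenvector-clustering index is the equal-weight sum of the two
standardised EBVs; weights are exposed.  "Lowest 10%" selects
⌊0.10·n⌋ animals (floor, ties broken by stable id order); pen-level
selection ranks pens by the per-pen mean or SD of a criterion and takes
the lowest ⌊0.20·n_pens⌋.  Reported standard errors are over the
selected animals (SD/√n_sel), not over posterior draws — the choice is an
assumption, stated here because both readings are defensible.  The EBVs
feeding the selection study come from univariate fits of each trait.

## What the validation studies do and do not show

Parameter recovery is demonstrated at n = 2,000 phenotyped offspring of
80 sires and 400 dams in 78 pens — posterior SD of h² ≈ 0.05 at
h² = 0.3 — and the selection-response sign pattern at the study scale
(82 sires, 217 dams, 78 pens of 15).  Because all data are synthetic,
these studies show that the estimation machinery is correct and that the
reported qualitative selection-response pattern follows from the reported
genetic parameters; they do not validate the generating assumptions
themselves (normality on the transformed scales, the logistic dyad model,
absence of indirect genetic effects) against real pigs.

Known limitations: no social (indirect) genetic effect models; no REML
alternative for cross-checking point estimates; threshold–threshold
bivariate fits are experimental; single-site Gibbs mixes slowly for
strongly confounded fixed effects (e.g. a batch observed in a single
pen), where the blocked update the package does not implement would do
better; the selection study predicts one generation of correlated
response only.
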
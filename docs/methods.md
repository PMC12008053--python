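# Methods

This note documents the statistical machinery in `phylopart`: the models
and conventions each stage uses, the tunable parameters and their
defaults, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was open.

## Data model

The unit of analysis is a *record*: one SLA observation of one species
at one site, with the site's climate (PAR, MAT, MTCM, MTHM, MAP, MI, α,
precipitation seasonality) and topsoil profile (sand/silt/clay
fractions, pH, organic C, CEC, TN, TP).  SLA is log₁₀-transformed at
read time; all models operate on `log_sla`.  Records join to the
phylogeny by exact match on underscore-normalized binomials — no fuzzy
taxonomy reconciliation — and the matched dataset carries a drop report
so every removed record and tip is accounted for.  Missing environment
cells are kept at read time and handled listwise per model.

Species-level analyses (signals, node contributions) use the mean of
log₁₀ SLA over a species' records (configurable to median); the
aggregation rule is a genuine choice since record counts per species
vary.

## Tree matrices

All tree-derived objects share the leaf-iteration tip order.

- **Patristic distances** d: path lengths between tips (via dendropy's
  phylogenetic distance matrix).
- **Brownian covariance** V: V_ij = root-to-MRCA depth, V_ii = tip
  depth, computed by an independent post-order traversal; the identity
  d_ij = V_ii + V_jj − 2 V_ij is asserted in tests as a
  cross-implementation check.
- **Abouheif proximity** A: product over the internal nodes on the
  inter-tip path (MRCA included, plus nodes strictly between the MRCA
  and each tip) of 1/(direct descendant count).  Polytomies contribute
  their actual child count (1/3 for a trichotomy); they are never
  arbitrarily resolved.
- **PCoA basis**: Gower double-centering of d², symmetric
  eigendecomposition, axes scaled so each squared norm equals its
  eigenvalue.  Eigenvalues ≤ 1e-10 × the largest are discarded (tree
  distances need not be perfectly Euclidean-embeddable) and counted.
  Each axis is sign-flipped so its largest-magnitude entry is positive,
  making output reproducible across linear-algebra backends.

## Signal statistics

Moran's I uses the classical cross-product form
I = (n/Σw)·(Σ w_ij z_i z_j)/(Σ z_i²) with raw 1/d weights (not
row-standardized; a switch enables standardization).  C_mean is the
same form with A as weights.  Blomberg's K is the observed-to-expected
MSE ratio with the phylogenetically corrected mean
â = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹x; K = 1 exactly on a star tree, which the tests
assert to 1e-8.  Pagel's λ multiplies off-diagonal covariances,
diagonal fixed; the mean and rate are profiled in closed form and λ is
maximized on [0, λ_max] (λ_max = 1 on ultrametric trees, otherwise
found by bisection on positive-definiteness) by a 21-point grid scan
plus bounded Brent refinement (tolerance 1e-6).  The grid guards
against local optima in the profile.

Permutation tests shuffle tip values, one-sided (greater), with
p = (#{stat ≥ obs} + 1)/(n_perm + 1).  Default n_perm = 999, so the
attainable floor is 0.001.  λ's test re-maximizes the likelihood on
every shuffle, which is the expensive path; the acceptance script uses
199 permutations at 300 tips to keep its runtime short.

## Variance decomposition

The nested random-intercept model y = μ + Σ_l u_l + ε is estimated by
REML with an own optimizer: the covariance is V = σ²I + Σ_l σ_l² Z_l
Z_lᵀ, evaluated through the Woodbury identity (one Cholesky of a q × q
system per evaluation, q = total group count), maximized over
log-variances by L-BFGS-B and polished by Nelder–Mead.  Parameters are
clamped at e⁻³⁰ on the variance scale: with degenerate data (zero
residual variance) the likelihood is unbounded and the clamp pins the
component at a numerical zero.  Nesting labels are built jointly
(factor l's groups are the distinct value-tuples of factors 1..l), so
inner factors are nested regardless of how the columns are coded.  On
balanced one-way designs the estimates coincide with the ANOVA
method-of-moments closed form to 1e-6, which is the test oracle; the
general fits were cross-checked against lme4 during development.
statsmodels' MixedLM was not used here because arbitrary-depth nested
variance components are awkward in its interface and its default
convergence tolerance is looser than the equivalence check requires;
it remains the engine for the environment screens.

## Environment screens

Per variable, two candidate mixed models (linear and quadratic fixed
effect, species random intercept) are fitted by ML and compared by AIC
— ML, not REML, because the candidates differ in fixed effects.  The
predictor is centered before squaring to limit collinearity; the
centering constant is recorded.  The winner is refitted by REML for
reported coefficients.  Marginal R² is var(Xβ̂)/(var(Xβ̂) + σ_u² +
σ_e²), the fixed-effects share of the total.  The group-contrast test
compares ML fits with and without group × environment interaction terms
at the chosen degree via a likelihood-ratio χ² with df = degree.
statsmodels' optimizers can land on a boundary with a non-finite
likelihood; the fitter falls back across bfgs/lbfgs/powell/cg and keeps
the first finite fit.

## Commonality partition

The seven models P, C, S, PC, PS, CS, PCS are OLS fits on an identical
record set (listwise deletion on the union of all class variables, so
AIC values are comparable).  Candidate terms: eigenvectors 'pc1..pcK'
(never squared, never interacted — they are coordinates, not
gradients); environment variables, squared only where the screen chose
degree 2; in the interaction variant, all climate × soil products of
centered variables, assigned exclusively to subsets containing both C
and S so single-class totals stay comparable across variants.

The eigenvector pool is the smallest leading set reaching 95% of the
positive eigenvalue mass (configurable by threshold or count) — the
pool size materially affects the phylogenetic total, and AIC selection
prunes within each model.  Selection is forward-only from the intercept
with deterministic tie-breaking (candidate order: eigenvalue rank, then
class order), so results are bit-reproducible.  Near-perfect fits are
compared on a floored RSS (TSS × 1e-12) so parameter count, not
rounding noise, decides.

Commonality components follow the R²-difference scheme: U_P = R²_PCS −
R²_CS (cyclic), C_PCS by inclusion–exclusion, C_PC = R²_P + R²_C −
R²_PC − C_PCS (cyclic).  Negative components are reported as-is
(suppressor structure).  With full term sets the seven components sum
to R²_PCS exactly; with AIC-selected sets the identity is approximate,
which is why the exactness test runs with selection disabled.

The intraspecific share (1 − R²_PCS)(1 − R²_R) has a known downward
bias when records-per-species is small: model R's species indicators
absorb roughly (g − 1)/(n − 1) of pure noise variance, so part of the
within-species variation is misattributed to species identity.  At the
default ~2.5 records per species the estimate runs several points below
the generated fraction; the recovery tests budget for this.  The bias
is a property of the estimator itself, which is reproduced here as
defined; with one record per species the indicator model saturates and
the share is exactly zero.

## Node contributions

Node means are unweighted recursive averages of daughter means (each
daughter counts once regardless of size), which removes
sampling-imbalance bias; a tip-count-weighted mean exists as a
sensitivity option.  Divergence size D is |Δ| of the two daughter means
at binary nodes and the sample SD of daughter means at true polytomies
(the SD form at a binary node would differ from |Δ| by √2, so the
absolute difference is kept where it is the natural scale).  The
contribution index of node k is n_k·SS_k normalized over internal
nodes, SS_k = Σ_j (mean(d_j) − mean(k))², n_k = descendant tip count;
tip-count weighting is the default because deep divergences affecting
many species should weigh more than shallow cherries, and an unweighted
variant is exposed.  Permutation p-values shuffle tip values across the
whole tree; the report shares one permutation set across nodes, making
its cost one vectorized traversal per permutation.

## Synthetic data

The generator emulates: an ultrametric tree (root depth 325 Myr) with
one deep split at 40% of the root depth separating a minor clade (10%
of species, the conifer-like group) from the rest, pure-birth topology
within clades; species traits from MVN(clade offsets, σ²V(λ)); 16
site-level environment variables loading on one common gradient with
loading √ρ (every cross-correlation equals ρ, default 0.5; MTHM is
MTCM plus a positive gap so the ordering invariant holds); record-level
effects through three true predictors (PAR linear, TN linear, MI
quadratic) with the other thirteen variables as correlated decoys; and
i.i.d. Gaussian intraspecific noise.  Records per species are uniform
on 1–4 (≈2.5 on average, matching the sparse-records regime of regional
trait databases); total log₁₀-SLA variance defaults to 0.06 around a
baseline of 2.31.

One realization of deep-split Brownian motion has a highly variable
across-tip variance (the clade-mean contrast is effectively a single
draw), so the default scenario rescales the centered trait draw and the
site-effect values to the exact target variances.  The ground-truth
fractions are then sharp: they are recomputed from the stored latent
components (species value, environment effect, noise draw per record),
never from the summed records, and recovery tests compare against these
realized values.

What the generator does **not** emulate — and hence what passing
recovery tests do not establish about real data: spatially structured
site gradients and biogeography, species–environment interactions,
non-Gaussian trait distributions or measurement error,
Ornstein–Uhlenbeck-style bounded evolution, phylogenetically clustered
site occupancy, and taxonomy between the two-clade split and the
species level.

## Degenerate inputs and errors

Constant traits raise a degenerate-trait error in every statistic;
all-zero weight matrices, non-PSD λ-rescaled covariances, singular V,
fewer than two shared species at harmonization, and sub-minimum group
sizes in contrasts all raise informative errors rather than returning
numbers.  Stage failures in the pipeline are isolated per stage and
collected into the results bundle.

## Problem sizes

The shipped analysis and acceptance runs use 300 species × 40 sites
(~750 records) with 199 signal permutations and 999 node permutations;
simulation-based tests use 60–200 tips and 20–200 replicates.  These
sizes put every Monte-Carlo check comfortably inside its tolerance
while keeping the full suite under a minute of compute.
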
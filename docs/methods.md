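# Methods

## The model-comparison procedure

A causal hypothesis is a DAG over standardized continuous traits plus one
terminal binary vertex (the outcome can have causes but no effects).
Candidate sets are built in two steps: a *trait-only* DAG fixes the
relationships among traits, and every subset of a list of candidate
direct trait → outcome links is added to it, giving 2^k models (k = 5
links gives the familiar 32-model scan). Model identifiers are the sorted
"+"-joined parent names of the added links; the empty subset is the
trait-only null.

Each DAG implies a d-separation basis set: one claim per non-adjacent
unordered pair {x, y}, conditioned on the union of the parents of both
vertices (minus the pair). This is Shipley's generalized basis
construction; every claim in it is d-separated in the graph (verified in
the test suite against an independent d-separation oracle on all
5-vertex DAGs). The regression response for a claim is the binary vertex
when it is in the pair — a binary variable can only be modelled as a
response — and otherwise the pair's topologically later vertex, with ties
in the topological order broken by vertex declaration order so results
are deterministic.

A claim is tested as `response ~ predictor + conditioning set`; its
p-value is the tested predictor's coefficient p-value. The claim
p-values of a model combine into Fisher's C = −2 Σ ln p, referred to the
upper tail of χ²(2k). Zero p-values are floored at 1e-300 before the log
(with a warning). Models are ranked by CICc = C + 2q·n/(n − 1 − q),
undefined (an error) when n ≤ q + 1. CICc weights ω are computed over
*all* evaluable models; support requires both ΔCICc < 2 and d-sep
p ≥ 0.05. Conditional model averaging then weights each edge's
coefficient over the supported models containing that edge, with ω
renormalised over those models; the reported SE is the
unconditional-variance estimator Σ ω′ √(se² + (β − β̄)²), which includes
between-model spread.

Two conventions worth making explicit:

* q counts directed edges (free path coefficients); adding one direct
  link raises q by exactly 1.
* ω is reported over all evaluable models, so the best model's weight is
  generally well below 1 even when it is the only supported one;
  `SelectionTable.omega_renormalized()` gives the
  renormalised-over-supported variant.

## Regression engines

**PGLS** (continuous responses). Residual covariance σ²·C(λ), where C is
the matrix of shared root-to-MRCA path lengths and Pagel's λ multiplies
its off-diagonals. λ is profiled out by restricted maximum likelihood
over [0, 1] (bounded scalar search, tolerance 1e-8, both interval
endpoints checked); `lambda_mode="fixed"` pins it. Coefficient tests are
t with n − p − 1 degrees of freedom. Estimates are invariant to global
rescaling of branch lengths, so trees are used at their native scale.

**Phylogenetic logistic regression** (the binary outcome). Latent
liability η = Xβ + ε with phylogenetically correlated ε and
P(y=1) = logistic(η). Because total latent variance is unidentifiable in
a threshold model, the phylogenetic term enters the working covariance
through the off-diagonal of the tree's correlation matrix only:

    Σ = W⁻¹ + s · offdiag(corr(C)),  s ∈ [0, s_max] by working REML,

with W the binomial weight matrix and s_max set so Σ stays positive
definite (diag(W⁻¹) ≥ 4 for binary data bounds the admissible s). Fitting
is penalized iteratively reweighted GLS: a Firth-type adjusted working
response keeps estimates finite under complete separation — essential
for rare-positive ("zero-inflated") outcomes, where a handful of
positives can otherwise separate on one predictor. Updates are damped
(step-halving whenever the step size grows) to break the 2-cycles plain
IRLS can enter near separation; convergence is a relative coefficient
change below 1e-8 within 200 inner iterations and a stable s, and
non-convergence propagates as a flagged claim (the model containing it is
excluded as unevaluable, never silently NaN). When the covariance is the
identity (or any star tree) the off-diagonal term vanishes and the
estimator reduces *exactly* to ordinary Firth-penalized logistic
regression, which is how it is validated against an independent oracle.

Per-coefficient p-values are Wald (z for the logistic, t for PGLS), since
the d-sep machinery needs one p-value per tested edge. Coefficients for
the binary response are on the latent logit scale with standardized
predictors; Gaussian-response coefficients are fully standardized. The
two scales never mix on one edge, because outcome edges are always
binary-response.

Calibration, measured in the acceptance suite (500 null replicates,
n = 100 Yule trees): rejection at α = 0.05 is 0.058 for PGLS (ML λ) and
0.052 for the logistic engine. Both are mildly anti-conservative (1–3
points at claim level in harder conditioning settings with ~20
positives); a consequence is that Fisher's C tests of a true model reject
slightly more often than the nominal 5% (≈7% in the default recovery
scenario). Wald-z inference after penalized quasi-likelihood does not
account for uncertainty in s, which is the main source.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
so every stage can be validated without any empirical dataset:

* **Trees** — Yule (pure-birth) with unit birth rate, simulated directly
  from a seeded generator for bit-reproducibility; tips are extended to
  the present, so trees are ultrametric with expected depth
  Σ_{k=2..n} 1/(λk). Any external Newick tree can be substituted.
* **Traits** — filled in topological order of the generating DAG:
  x_child = Σ β·x_parent + ε, ε ~ N(0, σ²·C(λ_v)) on the tree's
  correlation matrix; per-vertex λ defaults to 1 (Brownian residuals).
  Residual sd defaults to √(1 − Σβ²) (floored at 0.3) so marginal
  variances stay near 1 and emitted standardized coefficients track the
  configured ones.
* **Outcome** — latent liability thresholded at its empirical
  (1 − prevalence) quantile, giving exact prevalence control for
  rare-outcome stress tests; a Bernoulli-logit option exists for
  calibration work. Note the threshold mechanism is probit-scale: a
  liability effect β maps to ≈ β·π/√3 on the engine's logit scale.

Default recovery scenario: n = 150 species, five traits + outcome,
prevalence 0.15, trait–trait effects |β| = 0.6, outcome effects 0.6
(litter size) and 0.3 (diet diversity), three candidate direct links
(8 models per replicate, which exercises sub- and super-models of the
truth while keeping a 100-replicate experiment inside a few minutes on
one core). At these conditions the generating model is supported in 71%
of replicates and averaged coefficients have the correct sign in >99% of
edge recoveries.

What the generator deliberately does not emulate: biogeographic realm
structure, measurement error, and diet-category compositions (diet
diversity is simulated directly as a continuous trait). Passing recovery
tests therefore demonstrates correctness of the inference machinery
under its own assumptions, not robustness to the messiness of real
comparative datasets.

## Data preparation defaults

* Diet diversity: Shannon index H = −Σ p ln p over 10 food-item
  proportions, natural log (maximum ln 10 ≈ 2.303); a base flag is
  provided. Proportions must sum to 1 within 1e-6 unless renormalisation
  is explicitly enabled.
* Transforms: body mass, brain mass and weaning age are natural-log
  transformed by default (right-skewed, standard in comparative work);
  litter size, aspect ratio and H are z-scored without logging. The
  choice lives in config (`log_vars`), one line to change.
* Standardization is within each per-group analysis dataset, since path
  coefficients are reported per group.
* Group assembly: species of the focal order with complete traits;
  non-outcome background species restricted to the biogeographic realms
  of the positive species; species unambiguously of the complementary
  urban class excluded; species in both classes counted as positive in
  both analyses. Groups with fewer than 20 complete species are skipped
  with a logged reason (configurable `min_n`).
* Species matching is exact after whitespace→underscore normalisation
  and case-folding; off-tree species are reported.

## Numerical choices

* Covariance Cholesky factorizations fall back to a 1e-10 ridge before
  erroring; singular designs raise naming the collinear columns.
* All optimizations are bounded scalar searches with fixed tolerances;
  there is no randomness anywhere in fitting, so identical inputs give
  byte-identical outputs.
* Polytomies are handled natively by the covariance construction; an
  optional resolver adds zero-length branches when a strictly binary
  tree is wanted.
* Pruning preserves every kept tip's root-to-tip path *and* all shared
  path lengths: degree-2 nodes are collapsed with branch lengths summed,
  and a unifurcating stem above the retained clade's MRCA is kept at the
  root rather than discarded, so the pruned tree's covariance equals the
  corresponding submatrix of the full tree's covariance exactly.

## Limitations

* The phylogenetic logistic model is a penalized quasi-likelihood
  estimator, chosen for determinism and exact degeneration to Firth
  logistic on independent data. It is not numerically equivalent to
  other published binary phylogenetic regression estimators, which
  parameterise the latent correlation differently; only contract-level
  behaviour (limits, calibration, recovery) is asserted.
* Wald inference ignores uncertainty in the signal parameters (λ, s),
  giving the mild anti-conservatism quantified above.
* Conditional model averaging inherits the usual caveats of
  post-selection inference: averaged SEs are descriptive, not exact
  frequentist standard errors.
* Goodness-of-fit vs two-way contingency modes answer slightly different
  enrichment questions; both are provided and the results name the mode
  used.
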
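# Methods

## The estimand and the two estimators

The package treats "rate of evolution" of a discrete cultural trait as
the number of state changes accumulated over the history of a family of
societies, as represented by a sample of phylogenetic trees.  Absolute
rates per unit time are deliberately out of scope: language phylogenies
typically carry branch lengths in units of inferred linguistic change,
not years, so only *relative* rates — comparisons across traits within
and between families — are meaningful here.

Two estimators of the per-trait change count are implemented, chosen
because they bracket the methodological space: a model-free lower bound
and a model-based expectation.

**Maximum parsimony.**  Unordered (unit-cost) parsimony, computed by a
Sankoff dynamic programme over per-state cost vectors.  The recursion at
an internal node sums, over children, `min(cost_child[s],
min(cost_child) + 1)`; polytomies therefore need no resolution and the
score is exact and deterministic.  Only the score is computed — no
ancestral reconstructions — so most-parsimonious-reconstruction
ambiguity never arises.  The score is invariant under root placement and
state relabelling; the test suite asserts both rather than canonicalise.

**Stochastic character mapping.**  The character model is the symmetric
k-state Mk model: one instantaneous rate `r` for every ordered pair of
distinct states, generator `Q = r(J − kI)` with `J` the all-ones matrix.
Its transition kernel has the closed form

    P_same(t) = 1/k + (k−1)/k · exp(−k r t)
    P_diff(t) = 1/k − 1/k · exp(−k r t)

and a uniform stationary distribution, which is used as the root prior;
together these make the likelihood invariant under rerooting.  Equal
rates is the canonical default for mapping multistate nominal characters
and the only model supported; all-rates-different variants would be
badly overparameterised at these sample sizes.

The likelihood is computed by the pruning recursion with per-node
renormalisation (the running maximum is divided out and accumulated in
log space at every internal node, so no tree size can underflow).  The
rate is fitted by bounded scalar minimisation on `log r` over
`[1e−8, 1e3]` per unit branch length with tolerance `1e−8`; those bounds
comfortably bracket every realistic per-depth rate, and a fit landing at
either bound is flagged `boundary` rather than silently reported.
Constant characters sit at the lower bound by construction (their
likelihood is monotone decreasing in `r`) and contribute zero changes.

Histories are sampled in two exact stages.  Node states first: the root
state is drawn from prior × root partials and each child conditionally
via `P[parent, ·] × partial_child`, which is the exact joint conditional
given the tips.  Branch paths second, conditional on the sampled
endpoints: forward-simulation rejection (simulate from the parent state,
accept when the end matches) with a 1000-attempt cap, falling back to a
uniformization sampler.  For the symmetric Mk chain, uniformizing at
rate `kr` gives the auxiliary jump chain `R = I + Q/(kr) = J/k` —
uniform over all states — so the endpoint-conditioned path simplifies
dramatically: the number of auxiliary jumps is Poisson(`krt`) reweighted
by the endpoint constraint (weight 1 at `n = 0` if the endpoints agree,
`1/k` for every `n ≥ 1`), jump times are order statistics of uniforms,
and intermediate states are i.i.d. uniform.  Virtual self-jumps are
dropped and never counted as changes.  The two samplers are checked
against each other distributionally in the test suite; every history is
checked to respect the parsimony lower bound.

**Fit pooling.**  The rate is fitted separately per (trait, tree) pair
and 20 maps are drawn per tree at that tree's fitted rate.  Pooling a
single rate across a posterior sample would implicitly assume a common
branch-length scale across trees, which posterior samples do not
guarantee; per-tree fitting is the conservative choice and is exposed as
the only behaviour.

**State space.**  The Mk state count `k` is the number of *observed*
states after pruning, not the codebook category count.  Unobserved
categories would make the likelihood depend on the granularity of the
coder's scheme rather than on the data; the codebook count enters the
analysis only as a statistical covariate (below).

## Missing data

A society without a code for a trait is removed from the tree for that
trait before any computation, suppressing unifurcations by summing
branch lengths so that path lengths among retained societies are
unchanged.  Missing tips are never treated as wildcard observations: a
wildcard tip keeps its pendant branch in play and changes both the
parsimony bookkeeping and the likelihood, which is not the intended
"this society is simply absent for this variable" semantics.  Traits
coded for fewer than two societies are flagged un-analysable, logged,
and excluded from the statistics.

## The comparison layer

Per-trait counts are confounded by two mechanical covariates: the
effective sample size `N` (more taxa, more room for changes) and the
number of database categories `Cats` (more categories, more observable
distinctions).  Two adjustment paths are implemented because they answer
slightly different questions:

* The **partial correlation** between the two families' counts controls
  `{N_A, N_B, Cats}` jointly — `Cats` once, since it is a property of
  the variable shared by both families and duplicating it would be
  rank-deficient.  (Exactly collinear controls arising from degenerate
  inputs are dropped rather than fatal.)  The p-value is two-tailed from
  `t` with `df = n − q − 2`.
* **Residual rates** come from per-family OLS of counts on `(N, Cats)`
  with intercept; the unstandardized residuals are the per-trait
  relative-rate values used for ranked presentation and for the
  class contrast.

The ecological/social contrast is a pooled-variance two-sample t-test on
the residuals (two-tailed, `df = n − 2`; Welch available behind a flag),
with the sign convention that positive `t` means social traits evolve
faster.  Effect size is the `R²` of residuals on the 0/1 class
indicator, which for a binary predictor equals `t²/(t²+df)` exactly — an
identity the tests verify to 1e−10.  A non-parametric mirror
(rank-transforming counts and covariates before the same machinery) is a
config switch.  No multiple-testing correction is applied; the report
shows raw two-tailed p-values.

## The synthetic study and what it does (not) show

`SyntheticSpec` defaults define the study conditions: families of 100
and 112 societies, 10 trees per pseudo-posterior sample, 28 traits,
true rates log-uniform over a 20-fold range (0.05–1.0 per unit tree
depth — chosen so expected change counts span roughly one to several
dozen on trees of this size, matching the dynamic range of real coded
traits), category counts uniform on 2–10, per-(trait, family) missing
fractions uniform on 0–0.5, and ten ecological traits occupying the
slowest rates.  Ten trees per sample (rather than the hundred a real
posterior provides) keeps a validation run around a minute on one CPU;
change-count means stabilise quickly in the number of trees, and the
tree count is a spec field for anyone wanting the full-size run.

Trees are Yule (pure-birth) trees rescaled to unit mean root-to-tip
depth, so rates are per tree depth.  Each family's data are generated on
a dedicated generating tree; the analysis sample consists of
branch-length-jittered (±20%) copies of it.  This is a deliberate design
choice: a real posterior sample is inferred from the very populations
whose traits are analysed, so its trees are concentrated around the
data-generating history — the assumption on which every phylogenetic
comparative method rests.  Supplying analysis trees *independent* of the
generating history (the optional `independent` mode) violates that
assumption by construction: tip data then look saturated on every tree,
per-tree ML rates diverge toward the search bound, and SCM counts become
erratic.  That mode is retained as a mis-specification stress, not as a
model of a posterior.

The generator emulates the *structure* of real cross-cultural data, not
its content.  It does not simulate horizontal transmission (borrowing),
phylogenetic signal in missingness beyond the optional clustered mode,
coder error, correlated evolution between traits, or non-Yule tree
shapes.  Passing the generative checks therefore shows that the pipeline
recovers relative-rate structure *when the model family is broadly
right*; it cannot certify robustness to borrowing or to systematic
coding artefacts in any real database.

## Determinism

Every stochastic step draws from a `numpy` `SeedSequence` keyed by the
master seed plus a fixed stage tag and the (family, trait, tree, map)
indices.  Adding draws to one stage can therefore never shift another,
parallel execution over traits would reproduce serial results, reruns
with one seed are byte-identical down to the written reports, and a
parsimony-only run consumes no randomness at all.

## Numerical choices and edge cases

* Branch lengths of zero are legal everywhere: identity transition
  matrix, zero expected events, and pruning collapses zero-length
  unifurcations exactly.
* `r = 0` is handled exactly (identity kernel); conflicting tips then
  yield `−inf` log-likelihood rather than an exception.
* The truncated-Poisson draw in the uniformization sampler switches to
  an inverse-transform walk below `λ = 0.01`, where rejection of zeros
  would be wasteful.
* Ties in Spearman correlations use average ranks (scipy default).
* Recode maps must be total over observed codes with contiguous targets
  from 1; a map collapsing everything onto one code produces a constant
  variable that downstream coverage checks flag un-analysable (its
  stored category count is floored at two to keep the variable object
  valid).

## Validation problem sizes

The test suite validates the kernels by exhaustive oracles at small
sizes (500 parsimony instances on trees of up to 7 tips including
polytomies; 200 likelihood instances of up to 6 tips against full
enumeration over internal states; transition matrices against the
numerical matrix exponential over `k = 2..10`), the samplers by
10⁴-draw moment checks against closed forms, rate recovery by 50
simulated traits on a 200-tip tree (median within 15% of truth), and the
pipeline by a full run at the default study conditions, asserting the
generative findings: positive cross-family partial correlation, rank
correlation ≥ 0.6, MP-vs-SCM rank agreement ≥ 0.9 per family, and a
significant eco/social contrast with `R² > 0.1` in both families.

## Known limitations

* Only the symmetric single-rate Mk model is available; ordered or
  asymmetric characters are not supported (all parsimony costs are
  unit).
* Rates are compared via change counts, not time-calibrated rates;
  cross-family *absolute* rate comparisons are intentionally
  unsupported.
* The Mk MLE is unstable for saturated characters (few taxa, many
  states, long trees); such fits surface as large rates, are flagged
  when they reach the search bound, and propagate into heavy-tailed SCM
  counts.  Rank-based statistics are the recommended reading in that
  regime.
* Borrowing between societies is not modelled anywhere; to the extent it
  homogenises related cultures it biases counts downward, and strongly
  non-vertical traits are outside the method's assumptions.
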
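# traitrates

Do the cultural traits that change fastest in one part of the world also
change fastest in another?  `traitrates` is a Python package for
comparing *relative* rates of discrete trait evolution across two
independent families of societies, using language phylogenies as the
historical scaffold.  It is aimed at cultural phylogenetics and
phylogenetic comparative methods practitioners working with coded
cross-cultural databases (Ethnographic Atlas style trait matrices) and
Bayesian posterior samples of language trees.

## What it computes

For each discrete trait `i` and each tree `T` in a posterior sample, two
change-count estimators are available:

* **Maximum parsimony (MP)** — the minimum number of unordered state
  changes needed to explain the tip states, computed by a Sankoff-type
  post-order dynamic programme (polytomies handled natively).  The trait
  statistic is the mean score over trees, `Pars_i`.
* **Stochastic character mapping (SCM)** — under the symmetric Mk model
  (instantaneous rate `r` between every ordered state pair; transition
  probabilities `P_same(t) = 1/k + (k-1)/k·e^(−krt)`,
  `P_diff(t) = 1/k − 1/k·e^(−krt)`), the rate is fitted per tree by
  maximum likelihood (Felsenstein pruning, bounded search on `log r`),
  then complete character histories are drawn conditional on the tip
  data (exact joint node-state sampling followed by endpoint-conditioned
  branch paths via rejection sampling with a uniformization fallback).
  The trait statistic `SCM_i` is the grand mean change count over trees
  × maps (default 20 maps per tree).

Societies without a code for a trait are pruned from the tree for that
trait (path lengths among the remaining taxa preserved), so the
effective sample size `N_i` varies by trait.  Because both `N_i` and the
number of database categories `Cats_i` mechanically inflate counts, the
cross-family comparison controls them:

* partial correlation of `(count_A, count_B)` across traits, controlling
  `{N_A, N_B, Cats}`;
* per-family OLS residuals of counts on `(N, Cats)` — the "relative
  rate" values — fed to a pooled-variance t-test (df = n−2) of the
  ecological-vs-social trait classification, with effect size
  `R² = t²/(t²+df)`.

A synthetic-data module generates paired families (Yule trees scaled to
unit depth, traits evolved at one shared true rate per trait, realistic
missingness and category heterogeneity) so the entire pipeline can be
validated against a known ground truth without any external download.

## Worked example

Simulate a small paired-family dataset with known true rates, then run
the full pipeline:

```sh
traitrates simulate --outdir example --seed 7 \
    --taxa 40 45 --trees 5 5 --traits 12
traitrates all \
    --trees-a example/trees_A.nwk --trees-b example/trees_B.nwk \
    --traits-a example/traits_A.csv --traits-b example/traits_B.csv \
    --codebook example/codebook.csv \
    --outdir example/out --n-maps 5 --seed 7
```

which prints

```
[pars] partial r = 0.7974 (p = 0.01), Spearman rho = 0.7883
[scm] partial r = 0.7799 (p = 0.0132), Spearman rho = 0.8392
outputs in example/out
```

and writes `example/out/report.txt` containing, among other lines:

```
[pars] cross-family comparison (12 variables)
  Pearson r = 0.7150 (p = 0.00895)
  Spearman rho = 0.7883 (p = 0.00232)
  partial r (controls N_A, N_B, Cats) = 0.7974 (p = 0.01)
  MP-vs-SCM Spearman rho [A] = 0.9415 (p = 4.89e-06)
  MP-vs-SCM Spearman rho [B] = 0.9912 (p = 3.99e-10)
  eco vs social [B]: t(10) = 2.235, p = 0.0494, R^2 = 0.3331 (eco slower)
```

Reading the numbers: the generator gave the twelve traits one true rate
each, shared by both families, with the "eco" traits assigned the slow
end of the spectrum.  The pipeline recovers exactly that structure from
the data alone — counts correlate strongly across the two families even
after the sample-size and category-count controls (partial r ≈ 0.80),
the two estimators rank traits almost identically (ρ > 0.94), and
ecological traits show lower residual rates than social ones.  At this
deliberately small size (40–45 societies, 12 traits) the eco/social
contrast is only borderline in family A; the default study-scale
conditions (100/112 societies, 28 traits) give unambiguous results.

The per-stage subcommands `simulate`, `count` and `compare` expose the
same functionality piecewise, so real tree samples (newick or NEXUS) and
trait/codebook CSVs can replace the synthetic inputs at the `count`
stage.  Outputs include per-family summary CSVs, a combined table ranked
by family-A residual rate, and a machine-readable `statistics.csv`.

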
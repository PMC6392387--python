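# morphoclock

Bayesian divergence-time estimation from discrete morphological characters
— a "morphological clock" engine for testing how **data partitioning** and
**ascertainment-bias correction** affect the precision of node-age
estimates, with placental-mammal-style study designs in mind.

Morphological matrices are scored by specialists who, in practice, record
characters *because* they vary among the taxa at hand.  Dating analyses
that ignore this ascertainment bias overestimate evolutionary rates and
inflate posterior uncertainty.  Likewise, anatomical partitions (cranial,
dental, postcranial, soft tissue) can carry their own clocks; treating
them as independent partitions lets branch-rate noise average out — for P
partitions the rate-driven component of the posterior variance of node
ages falls roughly like 1/P.

## The model

* **Mk likelihood** (Lewis 2001): each character evolves on a rooted
  timetree under a k-state Markov chain with equal exchange rates and
  uniform equilibrium, `p_same(ν) = 1/k + (k−1)/k · e^{−kν/(k−1)}`, with
  branch lengths `ν = rate × duration` in expected changes per character.
  Discrete-gamma site-rate variation (4 equal-weight categories by
  default).  Likelihoods are computed by Felsenstein pruning, vectorised
  over characters and categories with per-node rescaling.
* **Ascertainment correction (Mkv)**: optionally each character's
  likelihood is divided by that character's probability of being variable
  among the sampled tips, `1 − Σ_s Pr(all tips in state s)`.
  Independently, the per-character state count k can be taken from the
  observed sample (untreated) or from external character annotations,
  which retains sample-invariant characters as invariable sites.
* **Relaxed clock**: uncorrelated lognormal branch rates
  (`rate_b = exp(m + s·z_b)`, `z_b ~ N(0,1)`), per partition.
* **Node-age priors**: a birth–death process with species sampling
  (Stadler 2009) conditioned on the root age and tip count, plus soft
  normal fossil calibrations on clade MRCAs.  A nine-calibration
  placental-mammal table (after Benton et al. 2015) ships with the
  package.
* **Inference**: Metropolis–Hastings on the fixed topology with
  auto-tuned moves, including likelihood-invariant rate–time ridge moves;
  output is a thinned trace plus per-node posterior mean, 95% HPD
  interval and ESS.

The synthetic-data module simulates the whole generative process
(birth–death timetrees, lognormal rates, Mk characters, missing cells,
variable-characters-only scoring with top-up) so every claim can be
tested without any external data.

## Worked example

```python
import numpy as np
from morphoclock import (
    DatingModel, MkPartitionedLikelihood, PartitionScheme, RunConfig,
    assign_state_counts, make_study_replica, run_chain, summarize_nodes,
)
from morphoclock.uncertainty_analysis import infinite_sites_fit

# a seeded 10-taxon study replica at 5% of the full character counts
rep = make_study_replica(seed=1, scale=0.05, n_taxa=10)
mat = assign_state_counts(rep.matrix, "observed")
lik = MkPartitionedLikelihood(
    mat, rep.tree, PartitionScheme.from_labels(mat),
    n_categories=4, ascertainment="condition_on_variable",
)
model = DatingModel(tree=rep.tree, likelihood=lik,
                    calibrations=rep.calibrations)
trace = run_chain(model, RunConfig(n_generations=100_000, sample_every=50,
                                   seed=7))
summary = summarize_nodes(trace, burnin_fraction=0.2)
print(summary[["node", "mean", "hpd_low", "hpd_high", "width"]].head())
fit = infinite_sites_fit(summary)
print(f"infinite-sites slope {fit.slope:.3f} Myr/Ma, R2 {fit.r2:.2f}")
```

prints:

```
     node        mean     hpd_low    hpd_high       width
0  node10   48.062525    5.311822  112.342399  107.030576
1  node11   65.020244   25.995933  112.069393   86.073460
2  node12   86.058574   47.002489  127.841748   80.839259
3  node13  104.868374   63.610958  141.605010   77.994053
4  node14  146.738372  104.129393  181.860897   77.731505
infinite-sites slope 0.429 Myr/Ma, R2 0.58
```

Each row is an internal node of the fixed topology: posterior mean age in
Ma, the bounds and width of the shortest interval holding 95% of the
posterior mass, all from the thinned post-burn-in trace.  The
infinite-sites slope says how many Myr of credible-interval width each Ma
of mean age carries — the calibration-limited regime appears as a clean
through-origin line.

The 2×2 experiment ({unpartitioned, partitioned} × {ascertainment
untreated, corrected}) runs in one call:

```python
from morphoclock.uncertainty_analysis import run_experiment
res = run_experiment(seed=1, scale=0.05, n_taxa=10)
print(res.comparisons["partitioning_corrected"].reduction_of_mean_pct)
```

A `morphoclock` command-line tool wraps the same functionality
(`simulate`, `infer`, `summarize`, `compare`, `isplot`, `experiment`);
run configuration files use flat `key = value` lines (`n_generations`,
`sample_every`, `burnin_fraction`, `n_categories`).

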
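# Methods

## Model

**Character likelihood.** Characters are discrete states 0..k−1 with
per-character state-space size k (2–10).  Evolution follows the Mk chain
(equal exchange rates, uniform equilibrium); on a branch carrying ν
expected changes per character the transition probabilities are

    p_same(ν) = 1/k + (k−1)/k · exp(−kν/(k−1))
    p_diff(ν) = 1/k −   1/k   · exp(−kν/(k−1))

Branch lengths are ν_b = r_b · t_b (rate in changes/character/Myr times
duration in Myr), optionally multiplied by a discrete-gamma site rate
(mean-of-bin discretisation, equal-weight categories, mean one; 4
categories by default, shape α estimated per partition).  Likelihoods
use Felsenstein pruning over the fixed rooted binary topology, vectorised
across characters and categories in a compiled kernel, with per-node
rescaling of partials whenever the maximum leaves [1e−140, 1e140] —
accurate to ~1e−10 relative on 40-taxon trees.  Missing cells contribute
a partial vector of ones; an all-missing character contributes zero
log-likelihood.

**Ascertainment bias** has two independent controls, mirroring the two
treatments a practitioner can apply:

1. *State-count scheme.*  `observed` takes k from the states present in
   the sample, recodes them densely and drops sample-invariant characters
   (a 1-state Mk character has likelihood 1); `annotated` takes k from
   external per-character annotations, keeping invariant characters as
   invariable sites.
2. *Variable-characters conditioning* (the Mkv correction): each
   character's likelihood is divided by 1 − Σ_s Pr(all tips in state s),
   evaluated with that character's k under the same gamma mixture.
   Conditioning is per character, so mixed-k partitions are handled
   coherently.

**Clock.**  Uncorrelated lognormal: branch rate r_b = exp(m + s·z_b)
with z_b ~ N(0,1) iid, per partition.  The latent-deviate (centred)
parameterisation is statistically identical to drawing rates from
LogNormal(m, s) but lets the sampler move m and s while dragging all
rates coherently; with naively free rates the clock hyperparameters mix
far too slowly at realistic sizes.  s = 0 recovers a strict clock.

**Node-age prior.**  Birth–death with species sampling: with speciation
λ, extinction μ < λ and sampling fraction ρ, a lineage of age t leaves
exactly one sampled descendant with density

    p1(t) = ρ (λ−μ)² e^{−(λ−μ)t} / (ρλ + (λ(1−ρ)−μ) e^{−(λ−μ)t})²

Conditioned on the root age t_root and the tip count, the n−2 non-root
divergence times are iid with density p1(t) / ∫₀^{t_root} p1 (closed-form
integral; each node's density integrates to one over (0, t_root) —
verified by quadrature in the tests).  The root age itself carries only
its calibration: no separate root-height prior.  λ and μ are estimated
through g = λ−μ (lognormal hyperprior) and d = μ/λ (uniform on (0,1));
ρ is fixed by configuration (default 0.01, a 40-of-~4000-species
sampling fraction), or the whole birth–death block can be pinned for
validation runs.

**Calibrations** are soft normal densities on MRCA ages (mean, sd in
Ma).  No truncation at zero is needed: node ages are bounded below by
their children.  Multiple calibrations multiply into the prior
unrenormalised, the convention of standard dating software.  The
packaged placental-mammal table carries nine divergences with normal
means/sds whose 95% intervals span published minimum/maximum fossil
bounds (after Benton et al. 2015).

**Hyperpriors** (all configurable): m ~ N(log 0.005, 3²) — centred on a
generic morphological rate with essentially no information; s ~
Exponential(mean 1/3); α ~ LogNormal(0, 1); g ~ LogNormal(log 0.05,
1.5²); d ~ U(0,1).

## Sampler

Metropolis–Hastings on a fixed topology.  Move mix (weights 5:3:2 for
ages : branch rates : hyperparameters):

* *ages* — uniform slide reflected into (oldest child, parent) for
  internal nodes; multiplicative scale for the root; a constant-distance
  variant that slides a node while rescaling the three adjacent branch
  rates to preserve each branch's expected changes (likelihood-invariant,
  unit Jacobian in the latent deviates); and a whole-tree up/down scaler
  (all internal ages × f, every clock location m − log f) that walks the
  rate–time ridge at prior-evaluation cost;
* *rates* — random-walk on a single branch's latent deviate z;
* *hyperparameters* — random walk on m, multiplicative moves on s, α, g,
  reflected walk on d.

Step sizes adapt during burn-in toward the 0.23–0.44 acceptance band
(Robbins–Monro, frozen after burn-in so the post-burn-in chain is a
fixed Markov kernel).  Chains are single, seeded, and bitwise
reproducible.  Defaults: 500k generations, thinned every 100, 20%
burn-in — the 100M/10k/20% convention of cluster-scale runs preserved in
ratio.  An initial state with −∞ posterior raises with the violated
component named.

**Summaries.**  Per node: posterior mean, shortest-interval 95% HPD
(exhaustive sorted-window search), width, and ESS (N / (1 + 2Στ) with
Geyer initial-positive-sequence truncation, capped at N; constant series
are flagged rather than given an ESS).  Nodes under the ESS floor
(default 200) are flagged, not dropped.

## Synthetic data

The generator mirrors the inference model: birth–death timetrees
conditioned on tip count (non-root ages by closed-form inverse-CDF
draws; topology by uniformly splitting an extant lineage), iid lognormal
branch rates, forward Mk simulation with continuous Gamma(α, α) site
rates, uniform missing-cell masking.

The study replica emulates a 40-taxon extant-only placental matrix: four
anatomical partitions (cranial/dental/postcranial/soft) with
1,284/1,451/925/881 characters at full scale (`round(scale × size)`
otherwise), per-partition rate multipliers {1.0, 1.5, 0.8, 1.2} (noise
heterogeneity knobs, not anatomical estimates), state counts mostly
binary with a thin tail to k=10 ({2: .70, 3: .20, 4: .05, 5–10: .05}),
per-partition gamma α = 1, root age 180 Ma, clock median 0.005
changes/character/Myr with lognormal spread s = 0.4 (morphology is
strongly non-clocklike), 30% missing cells.  Branch rates are drawn
independently per partition — each anatomical unit follows its own
realisation of the relaxed clock, the regime in which partitioning can
help.  Ascertainment acts at the character level *before* missingness:
characters invariant across the taxa are discarded and re-simulated
until the target count is reached (fixed-size scoring), then missing
cells are masked.  This ordering treats "does the character vary in the
clade" as the scoring criterion and missingness as specimen-level, and
it makes the variable-characters conditioning exactly match the
filtering process.  Calibrations: the crown calibration on the root plus
two further table rows attached to the internal nodes whose true ages
lie closest to the calibration means (assignments land within ~1 sd).

What the generator does *not* emulate: correlated character evolution,
hierarchically structured missingness (real matrices lose whole taxa per
anatomical region), fossil terminals, character-state ordering, and
among-character model heterogeneity beyond gamma rates.  Passing tests
therefore validate the estimator under its own model class, not the
fidelity of any particular empirical matrix.

## Numerical and design choices

* Ambiguous/polymorphic tokens ("(01)", "{0,1}") parse to missing —
  partial ambiguity is deliberately not propagated.
* NEXUS state symbols are 0–9 plus A (state ten), honouring the ≤10-state
  filter; characters whose declared k exceeds the cap are removed *after*
  state-count assignment, so an annotated k > 10 with few observed states
  is still filtered.
* Ultrametricity is checked to 1e−6 Myr on input trees; tips sit at 0.
* Through-origin infinite-sites fit: slope a = Σtw/Σt², R² = 1 −
  Σ(w−at)²/Σw² (can differ markedly from the centred convention; output
  states which is used).
* Width reductions are reported both as reduction of the across-node
  mean width and as the mean per-node reduction; averaging order is
  otherwise ambiguous.
* HPD needs ≥20 samples; node summaries need ≥100 post-burn-in samples.

## Desk-scale problem sizes

The validation suite and the acceptance script run the full pipeline at
reduced size: 8–12-taxon trees, study replicas at `scale = 0.05` (227
characters in four partitions), chains of 16k–200k generations, 10–20
seeds per property.  A data-rich controlled setup (four equal
500-character binary partitions on a small tree with a tight root
calibration) reproduces the reciprocal-of-partitions variance law
(partitioned-to-unpartitioned posterior age variance ratio ≈ 0.28 for
four partitions).  On the full-noise small replicas themselves the
effect is much weaker — mean HPD widths drop only a few percent and the
variance ratio sits near 0.8–1.0, varying seed to seed: with ~57
characters per partition, 30% missingness and broad calibrations, the
posterior variance is dominated by per-partition sampling error and by
prior structure, neither of which partitioning can divide.  The
corresponding acceptance-level tests of the replica-scale partitioning
effect therefore fail at this problem size and are retained as honest
negatives; the reciprocal law emerges as characters per partition grow,
and at full scale (4,533 characters) the rate-variation term dominates.

## Known limitations

* Topology is fixed; no tree search, no tip dating, no fossilised
  birth–death prior.
* Normal calibrations only.
* Single-chain inference; convergence diagnostics limited to ESS.
* The Mkv conditioning uses the probability of variability among all
  tips; a character whose observed (non-missing) cells happen to be
  constant is retained and handled by the likelihood, not by the
  correction.
* Branch rates are continuous lognormal draws, not the discretised rate
  categories some dating software uses — same model family, slightly
  different mixing behaviour.
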
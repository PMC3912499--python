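# Methods

## Model class and semantics

A classifier is an expression tree of activation nodes over weighted
inputs. Node operators are PADD (Σ wᵢxᵢ), PSUB (left-fold difference),
PMULT (product of weighted terms), and PDIV (left-fold protected
ratio); node arity is 2 or 3, and every child — feature leaf or
sub-node — carries its own multiplicative weight. Evaluation is total:
a denominator with |d| < 1e-10, and any non-finite intermediate
(overflow), is replaced by the protection value 1.0. Classification
thresholds the raw output at zero (output ≥ 0 → class 1); no squashing
function is applied. A sign threshold is symmetric under the
sign-flipping operators and is equivalent to a sigmoid thresholded at
½, so nothing is lost by skipping the transfer function; this package fixes
the raw-arithmetic reading.

## Genotype → phenotype mapping

Genomes are sequences of 8-bit codons. Decoding is the standard
grammatical-evolution leftmost derivation: a rule with k ≥ 2
alternatives consumes one codon and selects `codon mod k`;
single-alternative rules consume nothing. When codons run out the read
head wraps to the genome start, at most `max_wraps = 2` times; an
unfinished derivation after that marks the individual invalid (fitness
0 — strongly selected against). The variable non-terminal expands to
one of V1..Vp with p fixed at decode time; a single 8-bit codon
addresses at most 256 variables, which is ample for post-filter layers
at the problem sizes targeted here (the filter runs per layer, and the
desk-scale studies use ≤ 200 features per search).

Weights are grammar-derived decimals `[-]d.d` (−9.9..9.9 in 0.1 steps):
coarse, but the operators' multiplicative structure lets evolution
compose finer effective coefficients when they matter.

Initial genomes are not random codon strings: a random derivation tree
is grown depth-first (alternatives whose minimum completion height
exceeds the remaining budget are excluded) and the codons that
reproduce it are emitted, so every initial individual decodes to a
valid network with zero wraps.

Two decoders exist: a generic stack machine for any user BNF grammar,
and a specialised recursive decoder for the stock grammar used in hot
loops. They are asserted codon-for-codon equivalent in the tests, and
both are checked against a naive recursive reference decoder kept free
of shared code.

## Search

Island model: `n_demes` demes of `population_per_deme` individuals,
each deme owning an RNG stream derived from `(seed, deme_id)` — results
are bit-identical whether demes are stepped serially or in parallel,
and a deme's trajectory does not change when demes are added. Per
generation and deme: the single best individual is copied (elitism 1),
the rest are produced by size-2 tournaments, single-point crossover at
codon boundaries with probability 0.9 (cut points drawn independently
per parent; offspring length capped at 500 codons), and per-codon
uniform mutation at rate 0.01. Every `floor(G/M)` generations each
deme's best replaces the next deme's worst around a ring. The full-scale
cluster setting (50 demes × 5,000, 300 generations, 15 migrations)
is exposed as `EvolutionConfig.cluster_scale()`; all study defaults
below are reduced desk-scale configurations chosen by the package.

Fitness values are memoised by expression string within a search
(distinct genomes frequently decode to one phenotype); the cache cannot
affect results, only runtime.

## Cross-validation protocol

Stratified 5-fold assignment (seed-reproducible; fold sizes differ by
at most one, class proportions preserved — with 258 samples and a
110/148 split this yields folds {52,52,52,51,51} with 22 minority
samples each). For each fold, feature z-scoring (sample s.d.;
zero-variance features map to zeros) and the frequency filter are
re-fit on the training folds only, so held-out samples never influence
scaling, retention, or search. The run's best model is the variable set
identified most often across folds (tree equality would almost never
repeat; ties break by higher mean test accuracy, then smaller model);
variable consistency counts the folds whose best model contains each
variable.

## Filtering

"Intermediate models" are the per-generation per-deme best networks of
a short, wide search (default 10 demes × 500, 20 generations). A
variable's score is the fraction of intermediate models containing it;
the top `ceil(fraction·p)` variables are retained (so any positive
fraction keeps at least one), ties resolved by input-file order for
determinism. Retention is monotone in the fraction by construction.
`select_filter_threshold` cross-validates candidate fractions
(10/30/50% by convention) and keeps the best mean test accuracy.

The filter is effective exactly when variables carry *some* marginal
pull on the search; a variable whose marginal association is null by
construction (an xor member) cannot climb a frequency table, which is
why the integration study below does not filter.

## Synthetic data

Layers are independent standard-normal matrices over a shared sample
set. A latent risk state per sample is the OR over planted effects:
`main` = 1{x > 0} of its variable; `xor_pair` = 1{x₁ > 0} ⊕ 1{x₂ > 0}.
Labels are Bernoulli(penetrance_high = 0.9) on risk and
Bernoulli(penetrance_low = 0.1) off risk; with no effects, Bernoulli(½).
Thresholding continuous features at zero makes the signal expressible
both as a threshold rule and as a small arithmetic network (an xor pair
is the sign of the product of its members), while leaving each xor
member with exactly zero marginal association — the epistasis-style
structure the method is meant to recover. For a single effect the
oracle that predicts class 1 on risk state 1 has balanced accuracy
(ph + 1 − pl)/2 = 0.9 at the defaults: the ceiling for every learned
model. The generator does not emulate real-data correlation structure,
copy-number segmentation, or methylation beta distributions, so passing
tests demonstrate the machinery's ability to recover the planted
statistical structure, not performance on TCGA-like data.

## Reference studies (desk scale)

* **Main effect** — one layer × 100 features, n = 500, one main effect.
  Filter 10 × 500 × 20 generations; modelling 2 × 500 × 50 with the top
  10% retained per training fold. The filter ranks the planted variable
  first in essentially every seed; filtered modelling reaches ≈ 0.88
  mean test balanced accuracy against the 0.9 ceiling.
* **Cross-layer xor** — two layers × 100 features, n = 500, one xor
  pair spanning the layers. Single-layer models (2 × 250 × 25) stay at
  chance. The integrated stage searches the pooled 200-column matrix
  with a wide, shallow-initialised, mutation-0.05 configuration
  (4 × 4000 × 12, initial depth 5): discovery of a marginally-null pair
  is a broad-sampling problem — the pair must land in one
  multiplicative node with the right sign — not a hill-climbing one, so
  the budget goes into population width and codon churn rather than
  depth. Pooling only best-model variables (the classical protocol,
  implemented and used elsewhere in the package) cannot recover such
  pairs: an interaction with no single-layer footprint never enters a
  single-layer best model in the first place.
* **Null calibration** — two layers × 50 features, n = 300, labels
  independent of features; the full filter → model → integrate pipeline
  (filters per training fold) sits near 0.5 test balanced accuracy,
  confirming the protocol leaks no optimism.

## Statistics

Balanced accuracy requires both classes in the scored partition.
The Wilcoxon signed-rank test on the five paired fold accuracies is
exact: zero differences are dropped (Wilcoxon's treatment), tied
absolute differences get average ranks, and the null distribution of W
is built by convolution over the rank multiset — identical to
enumerating all 2^m sign assignments. One-sided p is the tail in the
observed direction; two-sided doubles it, capped at 1. At n = 5 the
attainable two-sided values are multiples of 1/16 with floor 0.0625 —
worth knowing before reading small-sample p-values from any 5-fold
comparison.

## Numerical and degenerate-input choices

Protected division constant 1.0; non-finite guard applied per node.
Output exactly 0 classifies as 1. Fold or tournament ties resolve to
the first (stable) candidate. `migration_interval` clamps to one
generation when migrations exceed generations and disables migration
when `n_migrations = 0`. Missing cells (`NA`) are imputed with the
feature median at load; duplicate sample ids, conflicting labels across
layers, and single-class partitions are errors, not warnings.

## Known limitations

Single-codon variable addressing caps a search at 256 candidate
features (filter first for wider layers). Weights are 0.1-grained.
Censored survival outcomes are out of scope (binary labels only), as
are gradient weight refinement, Pareto/multi-objective selection, and
knowledge-driven integration. Search cost scales linearly in population
× generations × samples; the desk-scale defaults here are two to three
orders of magnitude below the full cluster-scale setting, and
recover planted structure reliably only at the effect sizes the
generator defaults encode.
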
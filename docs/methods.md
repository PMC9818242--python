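# Methods

This note documents the models and procedures `plbin` implements, the
defaults it ships, and the design choices made where more than one
convention was defensible.

## 1. Categorization

### Ternary expression states

Gene and protein expression (log scale) is mapped to down / normal / up
(−1 / 0 / +1) with a housekeeping-calibrated model:

1. For each housekeeping gene, the (q/2, 1 − q/2) quantiles of its
   non-missing values (linear interpolation) delimit its normal range,
   where q is the target outside-normal mass (default **0.30**, split
   symmetrically 15% up / 15% down; the split is configurable through the
   quantile pair).
2. The per-gene normal-range SD is the sample SD (n−1 denominator) of the
   values strictly inside those cutoffs; `sigma_bar` is the arithmetic mean
   of these SDs across the panel. A constant housekeeping gene contributes
   SD 0 to the mean (with a warning); a panel that is entirely constant is
   a degenerate model and an error.
3. Applying the model, each gene's normal range is its own center (per-gene
   **median** by default — robust and translation-equivariant; mean is an
   option) ± `width_multiplier × sigma_bar`. The width multiplier is
   calibrated by bisection so that re-categorizing the housekeeping panel
   reproduces the target outside fraction to ±0.5 percentage points. The
   outside fraction is a non-increasing step function of the multiplier, so
   bisection converges onto the jump nearest the target; on very discrete
   data the ±0.5-point goal may be unattainable, in which case the closest
   multiplier is kept and a warning is issued.

Values strictly above/below the range map to ±1; boundary values map to 0
(inclusive normal range — deterministic and conservative). Missing values
stay missing.

The multiplier is calibrated on the panel rather than fixed at 1 because
the average normal-range SD alone has no reason to reproduce the target
mass on arbitrary per-gene centers; self-consistency on the panel makes
the 30% target an actual property of the output, which is what the
calibration round-trip test asserts.

### CNV, single-cell, drug response, essentiality

- Copy number: CN < 2 deletion, CN = 2 normal, CN > 2 duplication. The rule
  is defined on integer CN states; continuous copy numbers require an
  explicit tolerance τ (normal iff |CN − 2| ≤ τ) so that segment-mean data
  cannot be silently misread.
- Single-cell: expressed (1) iff feature count > 0. Dropout makes graded
  categorization unreliable at single-cell resolution, hence the binary
  convention; the zero pattern is preserved exactly.
- Drug response (IC50/EC50): above the maximum tested dose → resistant,
  below the minimum dose → sensitive; remaining values are split at their
  mean ± 0.5 sample SD (inside, boundaries included → partial response).
  The band is computed on the values as given; a log10 mode is available
  since dose–response summaries are often analyzed on a log scale.
- Dependency scores (normalized so non-essential median = 0, essential
  median = −1): a score strictly below −0.5 flags a significant
  proliferation effect.

## 2. Prediction-logic implication networks

### Templates and error cells

Strict semantics defines an error cell as "antecedent holds and consequent
fails": e.g. ternary UP_UP has error cells {(up, normal), (up, down)}.
Lenient semantics keeps only outright contradictions, dropping error cells
that involve a ternary NORMAL state ({(up, down)} for UP_UP). The published
cell layout for the ternary templates is not fully specified, so strict is
the default and lenient a switch. EQUIVALENT is the union of UP_UP with its
transpose; OPPOSITE the union of UP_DOWN with its transpose. For two binary
variables "B high ⇒ A low" collapses into the contrapositive of
"A high ⇒ B low", so binary OPPOSITE uses the classical quadrant rule
(high/high and low/low both forbidden) rather than the degenerate one-cell
union; all six binary templates then coincide with the classical
Boolean-implication quadrant rules.

### Statistics

Scope `U_p = Σ_ω N_i.N_.j/N²`, error count `K = Σ_ω N_ij`, precision
`∇_p = 1 − (K/N)/U_p`. The per-cell weighted formulation
`Σ ω_ij (U_ij/U_p) ∇_ij` is implemented separately and kept as a
verification route; the two agree to ~1e-15 on random tables (they are
algebraically identical).

Selection treats K under independence as Binomial(N, U_p):
`z = (N·U_p − K)/√(N·U_p(1−U_p))`, one-tailed, with preset z = 1.645
(α = 0.05). A rule is significant iff `z ≥ z_preset`, `∇_p > 0`, and the
scope is *feasible*: `U_p ≥ z²/(N + z²)`, the smallest scope at which even
a perfect rule (K = 0) can reach the preset z. An optional
`min_expected_errors` floor on `N·U_p` (normal-approximation guard) exists
but is **off by default**: at typical scopes and N ≥ 100 the binomial test
is already conservative (observed null rejection ≈ 0.005 per template at
α = 0.05, because conditioning on estimated margins removes variance), and
the guard would veto legitimately strong rules on small tables.

### Selection policy

`precision_first` (default): among significant templates take the highest
∇_p, ties broken by larger U_p, then by the fixed template order (UP_UP,
DOWN_DOWN, UP_DOWN, DOWN_UP, EQUIVALENT, OPPOSITE). `strict_dominance`
returns a rule only if it simultaneously attains the maximal precision and
maximal scope of all six templates — demonstrably often empty (a table can
give UP_UP the best precision while EQUIVALENT holds the best scope), which
is why it is not the default.

**Identifiability of symmetric rules.** A planted EQUIVALENT relation also
satisfies UP_UP, and with contamination ε > 0 the two have *equal expected
precision* (both error masses and both scopes scale by the same factor), so
which one wins maximum-precision selection on a single table is decided by
sampling noise (~50/50 at N = 200, ε = 0.05). Recovery experiments
therefore score a selection as correct when the selected template's error
cells are empty under the planted rule at ε = 0: {EQUIVALENT, UP_UP} for
planted equivalence, {OPPOSITE, UP_DOWN} for planted opposition, and the
exact template for asymmetric plantings. Under that criterion recovery at
ε = 0.05, N = 200 is ≥ 95% for every template (measured 100%).

### Genome-scale induction

All ordered pairs are evaluated in O(n²) via blocked indicator-matrix
products (per-state one-hot matrices; joint counts, margins and retained-N
for a whole block of pairs come from a handful of GEMMs in float32, exact
for counts < 2²⁴). Genes with fewer than two observed states are skipped
(logged); pairs retaining fewer than `min_samples = 10` samples after
pairwise missing-data deletion are skipped. Symmetric-rule edges are
emitted once per unordered pair in lexicographic direction; the edge list
is sorted (source, target, template order), making output byte-identical
across runs and chunk sizes. 2000 genes × 200 samples completes in a few
seconds on one CPU.

## 3. Baselines

- **Pearson relevance network**: edge iff |r| ≥ threshold (signed option);
  zero-variance genes skipped with a warning.
- **Entropy / MI**: plug-in (maximum-likelihood) estimates in bits,
  `MI = H(X) + H(Y) − H(X,Y)`; no small-sample bias correction (the
  comparisons that use MI are threshold-based, and correction would apply
  to both sides equally).
- **StepMiner-style threshold**: the one-step case — sort, exhaustive split
  search minimizing SSE, threshold = midpoint of the optimal means, SSE
  ties broken by the most balanced split. The intermediate zone t ± 0.5
  presumes log2-scale data and the margin is configurable.
- **Sparse-quadrant implication test**: after excluding intermediate
  values, quadrant counts a_I..a_IV; for the tested quadrant with row
  margin R and column margin C, expected = R·C/total,
  statistic = (expected − observed)/√expected,
  error rate = (observed/R + observed/C)/2; significant iff statistic > 3.0
  and error rate < 0.1 (both strict). A sparse quadrant implies the rule
  forbidding it (sparse high/low corner ⇒ "A high ⇒ B high"); sparse II+IV
  merge into "equivalent", sparse I+III into "opposite", replacing their
  constituents. The typeset form of the statistic is ambiguous in its
  source; the implementation follows the margin identities
  (n_Ahigh = a_I + a_IV, n_Blow = a_III + a_IV) and reproduces the printed
  worked value (statistic 3.95, error rate 0.0244 on counts 40/15/40/1).
- **Discrete BBN**: chain-rule joint probability Π P(X_i | parents(X_i))
  over explicit CPTs (rows must sum to 1 within 1e-9; graphs must be
  acyclic). Structure learning is out of scope.

## 4. Centrality and hubs

Degree (total/in/out, normalized by N−1), eigenvector (power iteration,
L2-normalized; directed networks are projected to undirected by default
because the principal eigenvector is ill-behaved on non-strongly-connected
digraphs — a directed mode exists), closeness (Wasserman–Faust component
scaling, so disconnected graphs are handled and isolated nodes score 0),
betweenness (Brandes, endpoints excluded, standard normalization) are
delegated to networkx; tests verify each against independent brute-force
oracles (path enumeration, dense eigendecomposition). VoteRank is
implemented directly so every node carries a score usable in distributions:
the vote sum at the round of election, 0 if never elected; elected nodes
lose their voting ability and their neighbors lose 1/⟨k⟩ (floored at 0).

Hub calling takes the top pct (default 10th) percentile as top-k with ties:
k = ⌈pct·n/100⌉, cutoff = k-th largest value, every node ≥ cutoff included.

The subset permutation test compares a gene set's mean centrality (raw
values; rank-based averaging is an option) with `n_perm` uniform
same-size draws without replacement; p is the plain fraction of draws with
mean ≥ observed (ties favor the null, no +1 smoothing). Seeded, therefore
bit-reproducible.

## 5. Gene-set validation

TP: the pair co-occurs in ≥ 1 set of ≥ 1 collection. ND: either gene is
missing from the union of all collections' universes (evaluating
"annotated" per individual database would turn a gene annotated in one
collection but not another into both FP and ND simultaneously; the union
convention is unambiguous). FP otherwise. Precision = TP/(TP+FP), undefined
when no confirmatory edges exist. The permutation test shuffles class
labels, re-derives the network through a user-supplied deterministic
callback, and reports FDR = mean FP/(TP+FP) over permutations that produced
confirmatory edges (empty permutations counted and reported separately —
FP/(TP+FP) has no value on an empty network) and p = fraction of
permutations with precision ≥ observed.

## 6. Synthetic data

The generators emulate the *categorical structure* of the data the methods
consume, not the full biology:

- null ternary matrices with 15/70/15 state mass (mirroring the 30%
  outside-normal categorization target);
- planted implication rules: target states drawn from the null conditional
  restricted to rule-consistent states with probability 1 − ε, unrestricted
  otherwise, so strict error cells are exactly empty at ε = 0 and fill at
  rate ≈ ε × (null error mass) given the antecedent;
- Gaussian expression with gene means uniform on [4, 12] (a typical log2
  microarray range) and a housekeeping panel sharing SD 1.0, other genes
  drawing SDs from [0.5, 2.5];
- single-cell counts as Bernoulli(1 − dropout) × zero-truncated
  Poisson(mean 2.0), default dropout 0.8 — the zero fraction equals the
  dropout rate by construction.

What they do **not** model: gene–gene correlation beyond planted pairs,
library-size and batch effects, count overdispersion, mixed cell
populations, heavy-tailed expression. Passing tests therefore demonstrate
the correctness and calibration of the algorithms under their stated
assumptions, not performance on real cohorts.

Problem sizes used in the test and acceptance runs — 2000 genes × 200
samples for the induction scale check, 2000 null pairs for calibration,
100 replicates per template for recovery, 500 genes / 25 housekeeping for
the calibration round-trip — were chosen as the smallest sizes at which
the Monte-Carlo error of the measured rates is well below the asserted
margins.

## 7. Known limitations

- Precision-first selection reports one rule per ordered pair; genuinely
  ambiguous tables (symmetric vs constituent asymmetric rules) are resolved
  by noise, as discussed above.
- The z selection test conditions on estimated margins and is conservative;
  effective α is well below the nominal 0.05.
- Missing data is handled by pairwise deletion, which can make per-pair
  sample sizes (and hence feasibility) heterogeneous across the network.
- The MTX reader materializes a dense matrix; very large single-cell
  matrices should be pre-filtered.
- Only one-step StepMiner fits are provided (the case the implication
  construction uses), not the multi-step variants.
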
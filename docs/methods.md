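# Methods

## Scope and data model

The unit record is one pre-miRNA hairpin: an RNA sequence over
{A,C,G,U}, an optional nested secondary structure in dot-bracket
notation, an optional minimum free energy (MFE, kcal/mol), and a class
label (`animal`, `plant`, or `unlabelled`). Ingest maps T→U and folds
case, because public registries mix DNA- and RNA-style records. Two
ingest modes exist: `strict` fails on the first malformed record;
`pipeline` skips it with a logged warning. Ambiguous bases (N, IUPAC
codes) are never silently coerced.

Structures are either supplied (Vienna text or Mfold CT) or produced by
a pluggable MFE-folding adapter (`RNAfold` command line supported). The
adapter is deliberately optional: every pipeline path accepts
precomputed structures, so no thermodynamic engine is a dependency of
the analysis itself.

## Structural decomposition

A *helix* is a maximal run of consecutively stacked base pairs
(i,j),(i+1,j−1),…; a *stack* is one adjacent pair-step, so

    n_stack = n_pairs − n_helix.

This identity is the adopted definition of "stack number": element
counts reported by different folding tools are ambiguous between
pair-steps and helix segments, and the pair-step reading gives one
consistent, testable convention (it is verified against an independent
union-find element walker on 1,000 random nested structures). A pair
directly enclosing exactly one pair forms an interior loop (unpaired
gaps on both strands) or a bulge (gap on one strand); a pair enclosing
none closes a hairpin loop; two or more enclosed branches form a
multiloop. Multiloops are counted during decomposition but are not part
of the 132-feature descriptor, whose structural class uses only bulge,
helix, interior-loop and stack counts plus length. Pseudoknots are
rejected (dot-bracket input cannot express them).

## The descriptor

Classes A–C are overlapping k-mer frequencies with denominators L−k+1,
stored as fractions in [0,1]. Class D encodes, for every position, its
base together with the paired/unpaired status of its left neighbour,
itself, and its right neighbour ('+' paired, '.' unpaired) — 4 bases × 8
mark patterns = 32 states. Terminal positions take a *virtual unpaired
neighbour*, so every position contributes exactly one state and the 32
frequencies sum to 1; this closes a boundary case the original triplet
encoding leaves open for full-length precursors.

Class F: AMFE = 100·MFE/L normalises the energy per 100 nt; MFEI =
AMFE/(100·GC fraction), i.e. AMFE over the GC *percentage*, which puts
MFEI near −1 for genuine hairpins as in the literature this index comes
from. MFEI is missing when GC = 0; class F is missing when the record
has no energy. Class G ratios with zero denominators are likewise
missing (NaN), never sentinel numbers. Class H applies the Shannon
entropy −Σ p·log₂ p (bits) to the class A/B/C/D frequency vectors,
giving IESN ∈ [0,2], IEDN ∈ [0,4], IETN ∈ [0,6], IESS ∈ [0,5].

The canonical feature order is: A, B, C alphabetically over A<C<G<U;
class D by base then mark pattern (unpaired-first); then the structural,
energy, ratio and entropy features as listed in the catalog
(`mirnafeat.features.catalog()`). Name-based access is the contract;
the ordering only fixes serialisation.

## Screening

Per feature, the two cohorts are compared with the two-sample
Kolmogorov–Smirnov statistic D = sup |F1 − F2|, computed exactly by
evaluating both empirical CDFs at every pooled sample point, with an
asymptotic p-value from the Kolmogorov distribution at
√(n1·n2/(n1+n2))·D (an exact small-sample mode exists behind a flag;
cohort sizes in practice are hundreds to thousands, where the
asymptotic form is standard). A Welch (unequal-variance) two-sided
t-test accompanies it; the t-test variant is a design choice, made
because pooled-variance assumptions are indefensible across cohorts
with very different spread. Direction is reported as the label with the
higher mean. Features pass at D ≥ 0.15 and p < 0.001 — fixed raw
thresholds, no multiple-testing correction, matching the screening
convention this pipeline reproduces. Missing values are dropped per
feature with the dropped count reported.

## Feature selection

CFS merit of a subset S (|S| = k):

    merit(S) = k·r̄_cf / √(k + k(k−1)·r̄_ff)

with r̄_cf the mean |Pearson r| between subset features and the 0/1
class, r̄_ff the mean |Pearson r| among subset pairs. The original
evaluator discretises features before computing symmetrical
uncertainty; plain Pearson on the raw values is used here instead, for
determinism and because all 132 features are numeric. Zero-variance
features contribute correlation 0. Searches: exhaustive enumeration
(dynamic programming over bit masks, capped at 25 candidates), forward
best-first (stale limit 5 expansions), and greedy forward stepwise.
Merit ties break toward the lexicographically smallest name set so runs
are reproducible. Two caveats worth knowing: a perfect duplicate of a
selected feature leaves the merit unchanged (not strictly lower), and
on pure noise the merit of k weakly spurious features grows like
√k·|r|, so forward searches may accrete noise features whose joint
merit is still near zero — the merit value, not the subset size, is the
meaningful null signal.

## Classification and evaluation

The published model (intercept 6.1436; +0.0893 helix, −0.0691 stack,
−0.0241 length, +0.0263 MFE; positive class = animal) is available as a
constructor and is exactly reproduced in the model-file round trip.
De-novo training is maximum-likelihood logistic regression via
iteratively reweighted least squares: tolerance 1e−8 on the largest
coefficient change, at most 100 iterations, deterministic. Perfect
separation is detected by the perfect-prediction criterion and raises;
an optional ridge (default off; 1e−6 when used as a fallback) shrinks
the slopes enough to stabilise separable folds — synthetic cohorts can
be separable and must not crash cross-validation. Standard errors come
from the inverse Fisher information at the optimum.

Evaluation is stratified k-fold cross-validation (k = 10 by default,
fold assignment seeded and recorded) with out-of-fold probabilities
pooled before computing metrics. TP rate, precision and recall are
class-size-weighted averages over both classes, the convention of the
evaluation tool whose reports this package mirrors; weighted TP rate
and weighted recall coincide (both equal accuracy). ROC area is the
Mann–Whitney rank statistic of the pooled probabilities — the
probability that a random positive outranks a random negative, ties
counted half — which equals trapezoidal integration of the empirical
ROC curve (asserted to 1e−10 against an independent implementation);
for two classes both orientations give the same value, so the weighted
average equals it too. ZeroR, the majority-class baseline, predicts the
majority label with constant probability equal to the majority
fraction, hence ROC area 0.5. The classification threshold is 0.5,
configurable.

## Synthetic cohorts

The generator builds single stem-loops outside-in: a drawn length, a
3–8 nt terminal loop, 0–2 nt external tails, and a complementary stem
whose pair steps are interrupted by 1–2 nt bulges and 1–2 nt interior
loops at per-step rates; paired bases are Watson–Crick with a G·U
wobble rate of 0.05, and the GC probability of pair steps is
compensated for the 50% GC of wobble pairs so cohort GC converges to
the profile mean. The surrogate energy is linear in the stack count
(mean kcal/mol per pair-step + Gaussian noise, truncated at 0), a
monotone stand-in for nearest-neighbour stacking energies; an MFE
engine can replace it when configured.

Default profiles (chosen once, as the study conditions for every test):

| parameter | animal-like | plant-like | rationale |
|---|---|---|---|
| n | 500 | 500 | desk-scale cohorts |
| length | LogNormal(ln 85, 0.12) | LogNormal(ln 145, 0.55) | animal precursors concentrate in 70–100 nt with almost none past 160; plant precursors run longer with a heavy tail (several % beyond 318 nt). Registry-scale plant hairpins average ~145–160 nt |
| GC mean | 0.45 | 0.45 | typical precursor GC |
| bulge / interior rate | 0.06 / 0.06 | 0.06 / 0.06 | a handful of imperfections per stem |
| energy per stack | −1.4 ± 2.0 | −1.4 ± 2.0 | puts an 85-nt hairpin near −40 kcal/mol, AMFE ≈ −48, MFEI ≈ −1 |
| wobble rate | 0.05 | 0.05 | G·U pairs are common but minor |

Because plant stems are longer, stack counts and folding energies
separate as a consequence — no per-feature signal is injected. Under
these defaults the screening's three largest KS statistics are length,
stack number and MFE (D = 0.70/0.66/0.66 at seed 1), and the 10-fold CV
ROC area of the four-feature logistic model is 0.81–0.86 across seeds.

What the generator does *not* emulate: multi-branch precursors,
mature-miRNA duplex structure, sequence motifs, covariation between GC
and energy, or realistic trinucleotide composition. Passing tests on
these cohorts therefore demonstrate that the pipeline's statistics,
selection and classifier behave correctly on data with the real
cohorts' coarse geometry (length/stack/energy contrasts), not that the
classifier's published accuracy transfers to any particular real
library — reproducing the registry-scale numbers would require the
original sequence library and Mfold structures.

## Numerical choices and degenerate inputs

- Entropy requires frequencies summing to 1 within 1e−9; 0·log 0 := 0.
- KS D is computed with exact ECDF arithmetic (no binning); equal
  samples give D = 0, p = 1.
- t-test with zero variance in both groups and equal means returns
  (0, 1) rather than NaN.
- Pearson correlations use pairwise-complete observations; a
  zero-variance feature blanks its correlation row/column and
  contributes 0 to CFS merit.
- Feature tables serialise missing values as `NA` and round-trip
  losslessly to 12 significant digits.
- CV folds require every class to have ≥ k members; problem sizes in
  the test suite (cohorts of 10–5,000; training sets up to 10,000;
  exhaustive search over 2^17 subsets) were chosen as the smallest
  sizes at which the statistical assertions are stable.

## Known limitations

- The structural vocabulary is that of single stem-loops; multiloops
  are recognised but carry no feature.
- The asymptotic KS p-value is conservative for very small samples; use
  the exact mode there.
- CFS with Pearson correlation sees only linear feature–class
  association; a feature informative purely through shape (as the KS
  screen can detect) may be under-selected.
- The published model's coefficients are taken as printed and are tied
  to structures from the folding tool used to derive them; applying the
  model to structures from a different engine shifts helix/stack counts
  slightly and with them the scores.
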
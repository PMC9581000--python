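# Methods

## The data model

A promoter library is an ordered set of S records, each a DNA sequence of
one common length R over {A, C, G, T} paired with one or more measured
expression values; optional per-record standard deviations and replicate
counts describe the measurement. Position coordinates default to −R … −1,
i.e. upstream of a transcription start site at 0, the conventional frame
for bacterial promoters; they are overridable for other layouts. Record
identifiers are unique, and merging two libraries refuses identifier
collisions outright rather than deduplicating, because grouping for the
replicate-joint splits (below) keys on sequence identity and silent
deduplication would corrupt the split bookkeeping.

## Statistical overview

* **Position entropy.** H_i = −Σ_b p_b(i) log₂ p_b(i) with 0·log₂0 := 0,
  computed from exact nucleotide counts (the frequencies of each column sum
  to 1 and the counts to S by construction). Entropy is defined only for
  the four-nucleotide distribution at a sequence position; no entropy is
  assigned to continuous features such as GC content.
* **Consensus.** The modal nucleotide per position, ties broken by the
  fixed order A < C < G < T so the result is deterministic.
* **Diversity.** Normalized Hamming distance, either of each sequence to a
  reference (user-supplied or the consensus) or averaged over all
  unordered pairs. The pairwise mean is computed in O(S·R) from column
  counts rather than the O(S²·R) double loop; above a configurable library
  size (default 1000) the automatic mode falls back to the reference form.
* **Position–expression profile.** For every (nucleotide, position) cell,
  the mean and sample standard deviation (ddof = 1) of the expression of
  all samples carrying that nucleotide there. Cells without support are
  NaN — undefined, never zero — and sd cells need support ≥ 2.

## Replicate handling

Replicates can be regenerated from a record's mean and standard deviation
as n independent Normal(mean, sd) draws. Draws are not clamped at zero:
the sampling model is a plain normal distribution, and negative values
only trigger a warning. Optional outlier removal drops records whose
expression z-score exceeds a threshold (default 3.0) in absolute value; it
is off by default and is applied, when requested, before replicate
regeneration. The z-score rule is the simplest defensible criterion for
univariate expression screens; anything more elaborate belongs upstream.

## Features and targets

Features are the one-hot encoded nucleotides of the retained positions
(position-major, nucleotide-minor in A, C, G, T order) plus, by default,
the GC fraction of the **full** sequence — not of the retained subset —
appended last: 4·P + 1 columns for P positions. Positions are retained
when their entropy on the *training* data strictly exceeds a cutoff
(default 0.2 bits); applying the filter to training data only, and
re-deriving it inside every cross-validation repeat, keeps test
information out of feature selection.

Target encoding follows a single integer, `response_value`: 0 standardizes
the expression to zero mean and unit (population) variance, 1 uses raw
values — both regression — and k ≥ 2 bins the values into k
equal-frequency classes labelled 0 … k−1 by increasing expression.
Quantile edges are learned on training data and reapplied to test data,
with out-of-range values clamped to the extreme classes; requesting more
classes than there are distinct values is an error rather than a silent
merge. The split is not stratified by class: stratification would
interact with the sequence-grouping constraint, and the class balance of
quantile bins makes it nearly moot.

**Replicate-joint splitting.** The train/test split groups records by
their exact sequence string and assigns whole groups to one side. With G
groups and train fraction f, the test side receives ⌈G·(1−f)⌉ groups — so
63 unique sequences at the default 9:1 give a 56/7 division. The ceiling
convention is deliberate: it guarantees a nonempty test side for any
G ≥ 2.

## Estimators and tuning

Random forest, gradient-boosted trees and RBF-kernel SVM, for both tasks,
via scikit-learn. Feature values already lie in [0, 1], so the SVM uses
them as-is. Grid search scores each candidate as the mean validation
score over repeated replicate-joint 9:1 splits of the training data
(default 100 repeats), using the task metric (R², or support-weighted F1),
then refits the winner — first in grid order on ties — on the full
training set. The default grids are modest, conventional ranges (RF:
100/300/1000 trees × depth ∞/5/10 × min-leaf 1/3; GBT: 100/300 trees ×
learning rate 0.01/0.1 × depth 2/3/5; SVM: C 0.1–100 × gamma
scale/0.01/0.1) and are plain dictionaries the caller can replace.

## Evaluation and confidence

Performance is estimated by repeating the replicate-joint 9:1 split
(default 25 times), re-deriving feature selection and target encoding on
each training fold, refitting, and recording train and test scores. The
confidence measure is the coefficient of variation — sd/mean of the
per-repeat *test* scores. Negative test R² values are kept, not clipped;
a warning is issued when the mean score is near zero, where the CoV is
numerically unstable.

A consequence worth knowing: with a low-diversity library, a 10% test
fold can contain almost no variant sequences, its expression variance is
then dominated by noise, and its R² can be a large negative number. A
single such fold drags the *mean* test R² far below the median (we have
observed a median of 0.86 against a mean of 0.24 at an unlucky seed).
This is a property of unclipped R² on small grouped folds, reported
honestly rather than smoothed away; classification scores do not share
the pathology.

Impurity-based feature importances of the tree ensembles are mapped back
to a 4 × P matrix plus the scalar GC share (summing to 1), exported as a
logo-ready CSV; single ensemble members can be dumped as rule text. SVMs
expose no impurity importances and raise.

## Sequence design

The genetic algorithm works directly on integer-coded sequences:
uniform-random initial population (default 100), tournament selection
(size 3), two-point crossover (probability 0.7), per-position point
mutation to a *different* nucleotide (default probability 1/R), and
elitism of one, for a default 50 generations. Fitness is minimized:

* regression — |prediction − target|, plus an optional
  `distance_weight` × (normalized Hamming distance to the nearest
  reference) term, default weight 0 (the training data may itself have low
  diversity, in which case staying near a reference is desirable — hence
  the knob);
* classification — distance to the nearest reference plus a constant 10.0
  whenever the predicted class misses the target class. The additive
  penalty, rather than hard rejection, keeps selection pressure on
  infeasible early populations.

Reference sequences default to the library consensus when none are given.
Library members get infinite fitness *and* are filtered from the returned
set, so the exclusion holds even if a library sequence were the global
optimum. Results are the best distinct feasible sequences archived across
all generations, and the best-fitness history is non-increasing by
elitism. For R ≤ 10 an exhaustive evaluation of all 4^R sequences under
the identical fitness provides the independent optimum (lexicographic
tie-break); the GA reproduces it exactly on the R = 6 test problems.

## Synthetic libraries

The generator emulates a mutagenesis library: each sequence derives from
one base sequence by independent per-position mutation (scalar rate or
per-position vector; a mutated position is uniform over the other three
nucleotides), and expression is additive, Σ_i W[nt_i, i], plus
Normal(0, noise_sd) measurement noise, with optional replicates as
independent noise draws. The `planted_spec` constructor concentrates
nonzero weights on a few causal positions and sets the noise level
relative to the realized signal standard deviation, so signal-to-noise is
controlled directly. Defaults (R = 40, S = 200, 3 causal positions, 10%
mutation rate, 10% relative noise) describe a compact, single-regulon
mutagenesis library of the size and diversity typical of published
prokaryotic promoter screens.

What the generator does *not* emulate: epistasis (an optional pairwise
interaction term exists for constructing hard fixtures but is off by
default), position-dependent noise, batch effects, censored or saturated
reporter readouts, and any biophysical promoter model. Passing tests
therefore demonstrate correct recovery of additive position effects under
idealized noise — they bound what to expect from real libraries, where
unmodelled factors lower every score.

## Numerical choices

* Entropy uses exact counts and `xlogy`, so p = 0 cells contribute 0
  without special-casing; agreement with a direct evaluation is at the
  1e-12 level.
* Standardization uses the population standard deviation (ddof = 0), and
  its inverse transform is exact to round-off.
* All randomness flows through `numpy.random.default_rng` seeded from a
  single integer per operation; identical seeds give byte-identical
  library CSVs, splits, tuning results and designs.
* Problem sizes in the test and acceptance runs (S ≤ 200, R ≤ 40, forests
  of 50–300 trees, 25 CV repeats) are chosen so the full pipeline,
  including the exhaustive 4⁶ design oracle, completes in minutes on one
  CPU while leaving the statistical conclusions unambiguous.

## Known limitations

* Regression quality degrades on libraries whose diversity is
  concentrated in few positions (most folds then carry little signal);
  classification into quantile bins is the robust mode for such data.
* The GA has no sequence-constraint grammar (restriction sites,
  homopolymer limits) and optimizes a single objective.
* Feature importances are impurity-based and inherit their known bias
  toward high-cardinality/high-variance features; the GC column, the only
  continuous feature, benefits from this and its importance should be
  read with that in mind.
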
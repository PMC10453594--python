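# Methods

## Model and assumptions

`fuzzysel` operates on a decision table `DT = (U, A, D)` — `m` objects,
`n` continuous condition attributes, one categorical decision attribute with
at least two classes. The working assumption of the whole pipeline is that
class information is *localized in value ranges*: an attribute is useful not
because its whole scale correlates with the class but because specific
sub-ranges of it do. All stages quantify or exploit that assumption. Metric
computation supports two classes (a `positive` label must always be named
explicitly; nothing in the pipeline guesses which class is
condition-present). Discretization, fuzzification, relevance testing and
selection work for any number of classes.

## Pipeline stages and their numerical choices

### Supervised discretization (`discretize`)

Candidate cuts are arithmetic midpoints between consecutive *distinct* sorted
values whose two value-groups are not both pure with the same class; repeated
values form one group carrying the multiset of its labels. The quality of a
cut on the current subset is the number of opposite-class object pairs it
separates, with one object strictly on each side — a value equal to the cut
counts on neither side. The local strategy greedily takes the best cut
(ties break to the smallest cut value, making the result independent of
object order), splits the subset and recurses; recursion stops on class-pure
subsets, subsets with fewer than two distinct values, or when no candidate
separates any pair. The resulting cut set is *consistent*: every
opposite-class pair differing on the attribute is separated whenever any
boundary cut lies between the two values (checked in the tests against a
brute-force pair-enumeration oracle). Consistency also means the number of
cuts grows with label noise; heavily overlapping classes produce many narrow
sub-intervals. Cuts are equivariant under increasing affine transforms of the
attribute.

### Triangular fuzzification (`fuzzify`)

Sub-interval centers `c_1 < … < c_k` are the midpoints of the boundary chain
`[min, cuts…, max]`. LV_j's membership rises linearly from `c_{j-1}` to 1 at
`c_j` and falls to 0 at `c_{j+1}`; LV_1 and LV_k are trapezoids, flat at 1
between the range edge and their center. The piecewise cases are evaluated in
a fixed order with first-match-wins; since the rising branch is closed at
`c_j` and the falling branch open, memberships form an exact partition of
unity at every in-range point, with at most two non-zero LVs. Values outside
`[min, max]` (possible for held-out data) are clamped before evaluation —
the edge trapezoids are flat there, so clamping extends them naturally. A
cut-free attribute (`k = 1`) gets a single LV with membership identically 1.
The *support* of an LV is the closed range where its membership is positive:
`[min, c_2]`, `[c_{j-1}, c_{j+1}]`, or `[c_{k-1}, max]`.

### Shadow-attribute relevance (`relevance`)

Defaults: `n_trees = 500`, `max_iterations = 100`, `alpha = 0.01` — the
documented defaults of the Boruta-style packages this stage follows. Each
iteration draws a fresh independent row permutation of every active column
(shadows), fits a `RandomForestClassifier` (Gini impurity importances,
`sqrt` feature subsampling) and records a hit for every undecided column
whose importance exceeds the maximum shadow importance. Decisions use
one-sided binomial p-values against Binomial(iterations, ½) with the
two-step correction: Benjamini–Hochberg across the undecided columns plus a
Bonferroni factor across iterations (`p ≤ alpha / iteration`). The
cross-column correction matters: without it, the noise column whose
*in-sample* association with the class happens to be largest clears the
shadow maximum almost every iteration and is falsely confirmed at a
substantial rate — shadow resampling only randomizes the forest, not the
data luck. Rejected columns leave subsequent forests; confirmed columns stay
(they keep competing and contributing shadows); columns undecided at the
iteration cap are *tentative* and treated as rejected downstream by default
(configurable via `tentative_as_confirmed`). The whole loop is deterministic
given `(table, parameters, seed)`.

Practical consequence of the correction: a decision in either direction
needs roughly `log2(N/alpha)` consistent iterations for `N` columns, so runs
shorter than ~10–15 iterations leave everything tentative.

### Binarization and selection (`selection`)

A raw value maps to 1 iff it lies in the **closed** support of at least one
confirmed LV of its attribute — crisp containment OR-ed over covering LVs,
*not* max-membership assignment (a value belongs to every range that covers
it, even where a neighbouring LV has the larger degree). Feature selection
keeps attributes with column sum strictly greater than `EPS·m`; object
selection keeps objects with row sum strictly greater than `EPS·n`; counts
exactly equal to a threshold are excluded. The two selectors are transposes
of each other and both are anti-monotone in EPS. The default sweep grid is
0.01–0.29 in steps of 0.01. Joint reduction runs FFS and FOS independently
on the same binary table and intersects the results; there is no iterative
re-selection.

### Evaluation (`evaluate`)

LOOCV refits one decision tree per fold and pools the `m` held-out
predictions into a single confusion matrix — with one prediction per fold,
pooling is the only coherent aggregation. The tree is scikit-learn's
`DecisionTreeClassifier` with the information-based `entropy` criterion and
optional minimal-leaf/max-depth pre-pruning; the classical C5.0 inducer is
proprietary, and this is the closest open analogue (the criterion is
configurable). Selection is performed **once on the full table** and LOOCV
applied to the reduced table — the protocol the published sweep tables
imply; this leaks selection information into the folds, so reported scores
are optimistic relative to a fully nested protocol. Scores with zero
denominators are carried as NaN ("undefined"), never 0; F1 is the harmonic
mean of precision and sensitivity and is undefined whenever either factor is
undefined or both are zero.

## Synthetic data generator (`synthetic`)

The generator emulates the range-localized signal the pipeline assumes.
Defaults (the study conditions of the package's self-tests): `m = 200`
objects, balanced classes assigned as exact stratified counts, 5 informative
plus 20 noise features, `range_purity = 0.9`, 20 noise objects, values
snapped to a 0.05 measurement grid.

Each informative feature carries one predictive interval per class
([0.15, 0.40] and [0.60, 0.85] by default). A regular object draws each
informative value from its own class's interval with probability equal to
the purity and from the other class's interval otherwise, so the probability
that an in-range value carries the majority class equals the purity exactly
(at balance ½), and the region outside all intervals carries *no* class
information. This two-sided geometry is deliberate: if only one class had a
predictive range, the complement region would predict the other class, every
LV of an informative feature would be confirmed, and range-violating objects
would be undetectable by object selection. Noise features are uniform and
class-independent. Range-violating noise objects have all informative values
resampled to the extreme ends of the measurement range (labels kept);
violations are kept at least 0.1 away from every relevant interval and away
from mid-gap positions because confirmed LV supports overhang their interval
by half the adjacent sub-interval. A label-flip mechanism is available as an
alternative. `range_purity = 0.5` is an explicit null setting in which
informative and noise features are statistically indistinguishable from the
class.

What the generator does **not** emulate: correlated attributes, class
imbalance drift, heteroscedastic noise, multi-interval signals per class,
or the marginal distributions of any real benchmark. Passing the recovery
tests therefore shows the pipeline recovers range-localized signal under
clean conditions, not that it matches any published benchmark accuracy.

## Self-test problem sizes

The package's headline self-tests run at the generator defaults over 100
seeds each, with runtime-scale method parameters: 40 trees, 20 (recovery) or
15 (null) relevance iterations, and an EPS grid of 0.02–0.20 in steps of
0.02. The recovery study requires the best-accuracy EPS (ties resolved
toward the stronger reduction) to recover ≥ 4 of 5 informative features and
remove ≥ 70% of the range-violating objects in ≥ 90 of 100 seeds; the
all-noise null study requires the fraction of ever-confirmed LVs to stay
below the configured alpha. Unit-level simulations use the sizes stated in
their tests (e.g. m = 200 with 20 LV columns for relevance behavior).

## Known limitations

* Consistency-driven discretization can fragment heavily noisy attributes
  into many sub-intervals, inflating the LV count and slowing the relevance
  stage; no pruning/MDL stopping variant is provided.
* Metric reports are binary-class only; multi-class tables can be reduced
  and selected but not scored.
* The relevance stage inherits random-forest importance biases (e.g. toward
  columns with many distinct values) and, like any all-relevant wrapper,
  confirms columns that are genuinely associated with the class *in the
  given sample*, lucky or not.
* LOOCV with selection performed once on the full table overstates
  generalization; use the per-fold protocol for unbiased estimates if
  needed (selection bias is visible by comparing the two).
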
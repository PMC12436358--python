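# Methods

## The mislabeling model

The package models an annotator who labels a record by comparing one
attribute against its population median ("above → positive", possibly
inverted). Geometrically this draws an axis-aligned heuristic decision
boundary through the medians. Two assumptions characterize the unknown truth:

1. the two classes are linearly separable, and
2. the true decision boundary passes through the attribute medians at an
   angle θ_TDB to an attribute axis, uniform on [45°, 90°].

For a query with absolute median deviations (a, b), inclination
θ_x = arctan(b/a), the worst case over the attribute the annotator used is

    P(a, b) = 1/2 − (1/90)·arctan_deg(min(a, b)/max(a, b)),

a degree-valued arctangent (the 1/90 normalizer is only meaningful in
degrees; the radian equivalent is 1/2 − (2/π)·arctan). Properties relied on
throughout: P ∈ [0, 1/2]; P = 0 iff a = b > 0 (the 45° line); P > 0.3 iff
the point is within 18° of an axis; P(a, b) = max over the two *directed*
variants P_used-A = clip(1/2 − θ_x/90), P_used-B mirrored, where the directed
form is zero when the unused attribute deviates more (an annotator using A
cannot err on points with b > a). The 0/0 corner (a point exactly at both
medians) is undefined in the closed form; we define the worst case there as
the supremum 1/2, since such a point is maximally ambiguous for any
single-attribute rule. Probabilities are clipped after evaluation; the drop
threshold is compared strictly (`>`).

### A known internal tension, and the Monte-Carlo simulator

The closed form can also be approached by direct simulation: draw θ_TDB
uniform on [45°, 90°] and count draws for which the point lies in the wedge
between the annotator's boundary and the true one (for the attribute-A
annotator: θ_TDB < θ_x, mirrored for B). `simulate_mislabel_frequency`
implements exactly that event. Its expected worst-case frequency is
|θ_x − 45|/45 — *twice* the closed form, which integrates the same wedge
against a π/2 normalizer rather than the π/4 width of the angle range. We do
not silently reconcile the two: the simulator is documented as validating the
closed form's *ordering* of risk (rank correlation ≈ 1 on any grid, since
both are strictly monotone in the angular distance from the 45° line), not
its absolute values, and the tests assert exactly that.

## The drop-out mechanism

For each queried instance: score all unordered attribute pairs with P on
their deviations; every pair with P > `threshold` (default 0.3) nominates its
smaller-deviation member (tie → lower index); sort nominations by probability
(descending, stable in pair order), deduplicate keeping each attribute's
best-scoring occurrence, and hide the first `max_drop` (default 2)
attributes. Two guardrails the pseudo-algorithm leaves open are fixed here:
the drop list is capped at d − 1 so a query never loses every attribute (an
all-masked query is unanswerable), and "first two" is treated as an upper
bound when fewer candidates exist. Deviations are computed on raw attribute
scales, matching the definition of the probability; because cross-attribute
ratios are unit-sensitive, an optional rescaling by each attribute's median
absolute deviation is provided (`DropoutConfig.rescale`) but off by default.

## Synthetic annotators

**Take-the-Best.** Each attribute's single-cue accuracy is measured with the
median-split rule "positive iff value strictly exceeds the median"; if the
inverted rule is more accurate the direction is flipped, so fitted accuracies
are ≥ 0.5. Cues are ranked by accuracy (ties → lower index; zero-spread
attributes get accuracy 0.5, direction +1, and rank last among ties). At
query time the best *visible* cue decides; a value exactly at its median
falls through to the next visible cue ("exceeds" read strictly), and if no
visible cue can decide the annotator returns the majority class of its
fitting data — an annotator always answers.

**Fast-and-frugal tree.** Construction is the standard one from the
fast-and-frugal literature: the top-`depth` (default 3) attributes by the
same accuracy ranking become nodes; each non-terminal node exits on the
median side with higher class purity among the rows reaching it, labeled
with that side's majority class, and passes the other side on; the terminal
node exits both sides. Ties at the median fall "below"; hidden nodes are
skipped at query time; a fully-skipped traversal returns the majority class.
Whether real exit sides should be purity-chosen or hand-set per domain is
not decidable from a single example tree; purity choice is deterministic and
reproduces the expected cascade shape.

## The active-learning loop

Pool-based, one query per step, until the pool is empty. The initial labeled
set (default 5, uniform at random, unstratified) is labeled by the annotator
on unmasked instances. Each step: retrain the base classifier (logistic
regression, lbfgs, max_iter 500) on the labeled set using *all* attributes;
record accuracy on the entire dataset against ground truth (the full dataset
with true labels is the test set; the returned curve therefore has pool + 1
points, index 0 being the pre-query model); score the pool; query; optionally
mask the query with the mechanism (medians always from the full dataset);
append the full attribute vector with the annotator's label. Strategies:
`entropy` (natural-log Shannon entropy of the predictive distribution — the
base is argmax-irrelevant), `density` (entropy × mean similarity to the pool,
with sim = 1/(1 + Euclidean distance); a Gaussian kernel is available via
config; the candidate's own pool entry contributes similarity 1), and
`random`. Ties in score-based strategies resolve to the smallest dataset
index; randomness comes only from the run's seeded generator. Attributes are
z-scored on full-dataset statistics for fitting and distances, while medians
for the annotator and the mechanism stay on the raw scale, matching the raw
definition of the deviations. While the labeled set holds a single class the
classifier predicts that class and pool scoring uses uniform probabilities,
so entropy selection degrades to its tie rule until both classes appear.

## Evaluation protocol

AULC is the unit-step sum of post-query accuracies (one term per query,
pre-query point excluded), so AULC/n_queries is a mean accuracy — this is the
convention that makes values comparable across runs of equal pool size, e.g.
an AULC of 530 over 765 queries is a mean accuracy of ≈ 0.69. Effectiveness
of the mechanism for a strategy is (AULC_with − AULC_without) /
(AULC_without − AULC_random), reported as a percentage; AULC values are first
averaged across datasets because per-cell denominators can vanish, in which
case the ratio is flagged NaN rather than fabricated. Paired comparisons use
a one-sided paired t-test (alternative: with > without) across
(dataset × heuristic) cells of mean AULC; identical samples give t = 0,
p = 0.5, and zero-spread nonzero differences are reported as undefined. The
full grid runner shares iteration seeds across cells (seed = base + iteration)
so with/without runs are matched on their initial labeled sets.

## Synthetic data

`generate_linear_dataset` draws iid attributes (uniform on a symmetric
interval by default — the simplest marginal whose median is its center;
Gaussian available) and labels by a hyperplane anchored at the *sample*
medians, so the boundary passes through the medians exactly. For d = 2 the
boundary angle is drawn uniform on [45°, 90°] per the model's assumption;
the marginal distributions themselves are a package choice, as only the
boundary-angle distribution is prescribed by the model. Degenerate
single-class draws are resampled with an incremented seed (logged). Optional
symmetric label noise flips each label independently.

`generate_bias_fixture` builds the demonstration scenario the mechanism
targets: four iid U[−1, 1] attributes, true boundary through the sample
medians at 70° from the `salient` axis in the (salient, support) plane, zero
weight on the two noise attributes. Consequences (all asserted in tests):
the salient cue's single-cue accuracy is ≈ 0.91, so both annotators rank it
first; its errors are exactly the points within 20° of the support axis —
i.e. near the salient median — which the closed form flags (the 18° drop
wedge sits inside the 20° error wedge, so nearly every error-prone query
triggers a drop, while dropped-but-correct queries are rerouted to the
support cue, which decides them correctly); about a third of all points
exceed the 0.3 threshold for the salient/support pair. The fixture is
deliberately favorable: real data need not be linearly separable, annotators
need not be median-threshold rules, and units need not be comparable, so
passing tests on it demonstrate the mechanism's internal logic, not field
performance.

## Problem sizes

The reduced-scale study run by the test suite uses three bias-fixture
datasets of n = 400, both annotators, entropy sampling with and without the
mechanism, ten iterations per cell with matched seeds — 120 full AL passes of
395 queries each. These sizes keep a complete run in the low minutes while
leaving the directional effect far from marginal (per-run AULC gains on the
order of +25 against within-cell iteration spreads an order smaller).

## Limitations

The probability model is pairwise and two-dimensional by construction; with
more attributes the mechanism aggregates pairwise risks rather than modeling
the full geometry. It assumes the annotator uses exactly one attribute at a
time, linear separability, and a median-crossing boundary no shallower than
45°. The evaluation is entirely synthetic-annotator based; nothing here
estimates which heuristic a real human uses, and multi-class problems are out
of scope.
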
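# Methods

## Data model

A subject's functional brain network is the N × N matrix of Pearson
correlations between ROI time series (`compute_fc_matrix`). Pearson is
the field-standard choice of pairwise similarity; no Fisher
z-transform is applied, so stored edge values are raw correlations in
[−1, 1]. The q = N(N−1)/2 upper-triangle entries are vectorised
row-major (pair (a, b), a < b) into the per-subject feature vector;
`devectorize` inverts the map with a unit diagonal imposed. Labels are
coded 0 = patient, 1 = control.

## Filter weighting

Three per-edge scores are combined:

* **Fisher criterion** h_j = |μ_{j,0} − μ_{j,1}|² / (σ²_{j,0} + σ²_{j,1} + ε),
  ε = 1e−12 guarding constant features. All standard deviations in the
  package are population-style (divide by count).
* **Mutual information** m_j between the edge value, discretised into
  10 equal-frequency bins, and the label; the plug-in double sum over
  the empirical joint distribution, in nats, with 0·log 0 = 0. A
  `normalize` flag divides by the label entropy H(Y), bounding scores
  in [0, 1]; plain MI is the default. The hand-rolled sum is
  cross-checked against `sklearn.metrics.mutual_info_score` in the
  tests.
* **Dispersion** σ_j, the marginal population standard deviation.

The combined weight is s_j = α₁h̃_j + α₂m̃_j + α₃σ̃_j with α summing to
1 (default 0.4, 0.4, 0.2). The raw components live on scales that
differ by orders of magnitude (h is a variance ratio, m is bounded by
ln 2, σ is in correlation units), so each component is min–max
normalised across features before mixing; `raw_components=True` gives
the literal unscaled combination. Ties in the ranking break toward the
smaller feature index, everywhere.

## Knee points and strata

On the descending weight curve (x = 1-based rank, y = weight) the knee
is the interior point maximising |y_j − (a·x_j + b)| / √(a² + 1), with
(a, b) the chord through the first and last points. The first knee is
found on the full curve, the second on the sub-curve strictly after it;
a maximal distance below 1e−12 (flat or exactly linear curve) yields no
knee. Features before knee 1 are *core*, between the knees *important*,
after knee 2 *remaining*; missing knees collapse the partition
gracefully (no knee at all ⇒ everything core).

## Task generation

Selection probabilities P_j = s_j / Σs are rescaled to P′_j = P_j /
max(P) so the top-ranked edge has probability 1. By default one
threshold λ ~ U(0, 1) is drawn per task and edge j joins the task iff
λ ≤ P′_j — the literal reading of "a random number λ is generated...
for each feature"; a `per_feature_lambda` mode draws λ independently
per edge instead. Empty tasks are redrawn (bounded retries). Over many
tasks the inclusion frequency of edge j converges to P′_j in both
modes.

## Grey wolf search

Wolves hold continuous positions in [0,1]^dim over a task's candidate
edges and decode to masks at the 0.5 threshold — the simplest
deterministic binarisation consistent with the Bernoulli (0/1)
initialisation; a sigmoid transfer function would add a temperature
parameter without changing what the tests measure. Updates follow the
canonical three-leader encircling rule with d decaying linearly from 2
to 0; all non-leader wolves update identically. Leader bookkeeping is
elitist (alpha/beta/delta are the three best distinct masks ever
evaluated), so the best-so-far trace is non-decreasing by
construction.

Fitness = ρ·ACC − (1−ρ)·|mask|/q_task, ρ = 0.9 by default. ACC is the
mean stratified 3-fold inner-CV accuracy of a linear SVM (C = 1) on the
training split only; evaluations are memoised by mask. The penalty
denominator is the task candidate count by default
(`penalty_scope="global"` uses q): a task-local denominator keeps the
per-edge cost of the penalty comparable across tasks of different
sizes. Empty masks score −1.

Note an intended consequence of the penalty: when a single edge
separates the classes perfectly (the synthetic default plants 5σ
edges), any ρ < 1 makes the one-edge mask the optimum, so converged
best masks are tiny. Recovery of the full planted set is therefore
measured at ρ = 1 (pure accuracy), where the search has no incentive
to discard redundant signal edges.

**Knowledge transfer.** After each task its best mask increments a
global per-edge count vector Q. Later tasks initialise wolves with
inclusion probabilities Q/ΣQ floored at ε = 0.05 (so edges with no
history are never extinct); the first task, with no history, falls
back to P′. Counts record *solution* membership (the task's final best
mask), not candidate membership. The ablation shipped in the
acceptance script compares the mean initial-pack best fitness of tasks
2..8 with and without transfer.

**Aggregation.** How one final subset emerges from n task bests is a
genuine design gap; the default keeps edges selected by a strict
majority of task bests, falling back to the single best-fitness task's
mask when the majority set is empty, with `best` and `union`
alternatives.

## Classification and evaluation

The margin classifier is `sklearn` SVC with a linear kernel and fixed
C = 1 (no kernel or regularisation search). ACC/SEN/SPE follow the
clinical convention that the patient class (label 0) is positive;
`positive_label` flips it. Cross-validation is stratified 5-fold and
leak-free by default: the entire selection stack reruns on each
training portion. A `leaky` mode (selection once on all data) exists
solely to demonstrate the optimistic bias on null data.

Demographic table checks use the Pearson chi-square test without
continuity correction on 2×2 sex counts and a pooled-variance (not
Welch) two-sample t-test reconstructed from printed age mean/SD/n —
the variant pair that reproduces the published cohort p-values.
Paired comparisons of method accuracies use the two-sided paired
Student t-test, with (t, p) = (0, 1) by convention when all
differences vanish.

## Counterfactual explanation

For a patient's selected-edge vector c, L candidates (default 10) are
optimised jointly:

    (1/L) Σ_l max(0, 1 − z·(w·x^l + b))            validity (hinge)
  + γ₁ (1/L) Σ_l dist(x^l, c)                      proximity
  − γ₂ det(K)                                      diversity

with z = +1 for target class 1, dist(x, c) = (1/k) Σ_j |x_j − c_j| /
MAD_j (training-set median absolute deviations; zero MADs fall back to
the feature sd, then 1.0), and K_uv = 1/(1 + dist(x^u, x^v)) with a
seeded uniform [0, 1e−4] diagonal jitter, drawn once per optimisation,
stabilising the determinant. The printed distance constant is offered
both ways (`normalize_by="k"` per-feature average, default, matching
how the distance feeds the kernel; `"L"` the literal counterfactual
count). Defaults γ₁ = 0.5, γ₂ = 1.

Optimisation is fixed-step subgradient descent (rate 0.05, up to 1000
iterations, early stop when all candidates are valid and the relative
objective change is < 1e−5). Hinge and proximity have analytic
subgradients; the determinant is differentiated by central differences
(cheap: k and L are small after selection). Gradients of the L-sum are
used rather than the mean — identical minimiser, L-fold larger steps.
Candidates are not box-constrained by default, so a counterfactual edge
may leave [−1, 1]; `clip_range` restores physical bounds when wanted.
Only the k selected edges are represented and perturbed; all other
edges are frozen at their observed values.

A consequence of the L1 proximity term worth knowing: a candidate
moves away from c only along coordinates where |w_j| >
γ₁/(k·MAD_j). With a wide-margin model (small ‖w‖) and large γ₁ the
objective's optimum is legitimately x = c and no valid counterfactual
exists; the γ₁-sweep tests therefore use a tighter-margin fixture
where movement is feasible at every γ₁ swept.

## Synthetic cohorts

`synthesize_dataset` emulates the statistical skeleton of a two-class
FC case-control cohort: default 20 ROIs (190 edges), 40 + 40 subjects,
5 planted edges whose patient-class mean is shifted by Δ = 1.5 over
i.i.d. Normal(0, 0.3²) noise — a deliberately strong (5σ) signal so
recovery and classification ceilings are unambiguous; Δ = 0 gives the
matched null. A `timeseries` mode instead builds per-class
multivariate-normal ROI series with shared-factor coupling on planted
pairs and passes them through the FC construction, so planted edges
differ in population correlation by roughly Δ (capped below 1).

What the generator does *not* emulate: spatial autocorrelation between
edges sharing an ROI, site/scanner effects, heavy-tailed motion
artefacts, class imbalance, and realistic (much weaker) effect sizes.
Passing tests therefore demonstrate correctness of the machinery and
its behaviour under a known ground truth, not expected accuracy on
clinical data.

## Problem sizes and numerics

The shipped tests and the acceptance script run the search at reduced
budgets (pack 6–12, t_max 5–30, 2–8 tasks, 10–20 replicate seeds) —
the package's choice of demonstration scale on the strongly-signalled
synthetic cohorts, where larger budgets only re-confirm converged
results; defaults for real use remain pack 30, t_max 100, n = 8.
Determinism is end-to-end: per-stage seeds derive from a master seed
by CRC-hashing the stage name, every random draw flows through
`numpy.random.Generator`, and repeat runs produce byte-identical
output files (verified by manifest digests).

## Known limitations

* Only linear decision functions are supported by the counterfactual
  gradient machinery (the "logit" is w·x + b).
* The MI estimator is the binned plug-in (no k-NN continuous
  estimator); with very small cohorts it biases upward.
* Aggregation of task bests and the binarisation rule are design
  choices among several defensible ones; alternatives are exposed as
  flags, not swept automatically.
* No imaging preprocessing of any kind: inputs are already-clean time
  series or connectivity matrices in delimited text.
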
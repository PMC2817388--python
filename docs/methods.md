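# Methods

This note records the models implemented, the defaults and why, what the
synthetic-data generator does and does not emulate, and the numerical and
design choices made where more than one reasonable option existed.

## Analysis matrix and preprocessing

All four analyses operate on the same n × p binary matrix. Each raw
predictor (percent-of-gated flow variables plus the baseline CD4 count)
is dichotomised at the median of its *observed* values with a strict
"greater than" rule, so ties at the median code 0. Remaining missing
cells are singly imputed with the most common observed value of that
column; an exact 0/1 tie imputes 0 (deterministic, conservative toward
"low"). Replicated acquisitions are averaged over whichever of the four
acquisitions are observed. The outcome — CD4 count strictly greater than
450 cells/µL at week 36 — is never imputed; subjects missing it are
dropped and logged. Medians and every imputed cell are recorded on the
returned object so a fit is fully auditable.

Consequences worth knowing: a complete 0/1 column with a majority of
zeros is a fixed point of the dichotomisation; with distinct values and
odd n, exactly (n−1)/2 entries become 1; permuting subjects permutes all
outputs identically.

## Contingency screen

Odds ratio `ad/bc` with degenerate tables flagged (+∞ / 0 / NaN); an
optional Haldane 0.5 correction exists but is off — the screen reports
raw odds ratios. The χ² statistic is the closed-form 1-df Pearson
statistic with the Yates continuity term h = n/2 (clamped at zero); the
p-value is the χ²₁ upper tail. **The continuity correction is on by
default** because, on the 2×2 table implied by the reconstructed root
split (4, 35, 15, 24), the corrected test gives p = 0.008 and the
uncorrected one p ≈ 0.004; both variants are verified against
`scipy.stats.chi2_contingency` in the tests. The corrected test is
deliberately conservative: its null type-I rate at n = 78 is ≈ 0.025, so
the *calibration* study (and the corresponding acceptance quantity) uses
the uncorrected variant, whose measured type-I rate is 0.05 ± 0.02.

Multiplicity: Benjamini–Yekutieli step-up with c(m) = Σ 1/k (valid under
arbitrary dependence — quadrant variables are compositionally
correlated), and q-values as the step-up with a π₀ factor, defaulting to
π₀ = 1 (= Benjamini–Hochberg); a Storey estimator at λ = 0.5 is available
behind a flag. Both are cross-checked against
`statsmodels.stats.multitest` in the tests. Screen rows sort by p-value
with lexicographic tie-breaks for reproducibility.

## Classification tree

Splits maximise φ = i(Ω) − π_L i(Ω_L) − π_R i(Ω_R), with i = 2p(1−p) and
π_L, π_R the within-node child fractions (equivalent to the
root-referenced form up to the constant π(Ω)). Because predictors are
binary, the split search is exhaustive over variables; ties in φ go to
the lowest variable index, and leaf-prediction ties go to class 0. The
stopping rule "n = 5 per node" is read as a child-size floor: a split is
admissible only if φ > 0 and both children would hold ≥ min_node
subjects. Growing is level-wise (one pair of matrix products per depth
level), which is what makes the forest studies tractable; the result is
identical to node-at-a-time recursion.

Pruning is classical weakest-link cost-complexity: repeatedly collapse
every internal node attaining the minimal
g(t) = (r(t as leaf) − R(branch)) / (|branch leaves| − 1), merging steps
with tied α so thresholds are strictly increasing and sizes strictly
decreasing. Each step's subtree provably minimises R + α|T| at its α;
the tests verify this against exhaustive enumeration of the pruned
subtree lattice for trees up to 15 leaves.

Subtree selection: stratified k-fold CV (default 10 folds) over the
geometric midpoints of the α sequence, choosing either the error-minimum
(ties toward the smaller tree) or, by default, the smallest tree within
one binomial standard error of the minimum. One caveat the tests
document explicitly: CV scored by misclassification can only retain a
split whose strata straddle a responder probability of 1/2. An effect
like 10% vs 38% responders changes probabilities but not the majority
class, so the Bayes classifier is constant and collapse to the root is
*correct*; the CV-retention scenarios therefore plant rates such as
(0.10, 0.65), while ranking-based scenarios use milder rates.

## Random forest

Full n-out-of-n bootstrap with replacement (expected unique in-bag
fraction 1 − (1−1/n)ⁿ ≈ 63.2%, i.e. "about two-thirds"); per-tree OOB set
is the complement. Unpruned trees (min_node = 1) with a fresh random
subset of mtry = ⌈√p⌉ predictors at every node. Defaults B = 500,
exposed in `ForestConfig`. One master seed spawns independent per-tree
streams, so raising B extends a forest without reshuffling earlier trees.

Aggregate OOB error scores each subject by majority vote over the trees
where it is out-of-bag (vote ties → class 0); subjects never OOB are
excluded with a warning. Permutation importance permutes X_j *within the
OOB set* of each tree and averages the error increase over all B trees;
variables a tree never splits on contribute exactly 0 and are skipped.
The mean decrease in node impurity (per-variable sum of n·φ over that
variable's splits, averaged over trees) is always reported alongside,
since both flavours are in common use and they need not agree.

Two null-data behaviours are structural, not bugs, and the tests pin
them: (1) the aggregate OOB error of fully grown noise trees sits
slightly *above* the base-rate floor (measured 0.287 at a 0.25 base
rate; the sklearn reference implementation gives 0.321 on the same
data), because overfit trees vote away from the constant majority
prediction; (2) null permutation importances have a slightly negative
mean — permuting a variable regresses a tree's predictions toward the
majority class, which on null data is the best predictor. Accordingly
the null-centering test uses per-variable standard errors (deltas are
correlated across variables within a tree, so pooling by √p would
overstate precision).

## Logic regression

Models g(E[Y|X]) = β₀ + Σ β_j L_j with Boolean-tree covariates;
complements live at leaves only (De Morgan makes internal complements
redundant). The logit-link fit aggregates subjects into the ≤ 2^t strata
the tree columns induce and runs Newton/IRLS on the grouped binomial
likelihood — identical to the per-subject fit (verified against
statsmodels GLM to 1e-6 in deviance) but fast enough to score every
annealing proposal. Empty, constant and collinear columns (duplicates or
complements of earlier columns) are dropped with a flag; separation caps
coefficients at ±10 with a flag. Identity link = least squares,
deviance = RSS.

The search is simulated annealing over six moves (alternate a leaf's
variable, toggle its complement, alternate an operator, grow a branch,
prune a branch, split/delete a leaf — every move changes the leaf count
by at most one and respects the total-leaf budget), scored by deviance,
with geometric cooling T: 2 → 0.001. Defaults: two trees, six leaves
total (fixed for interpretability, no automated size selection), uniform
move probabilities, 50 000 iterations, one chain. `restarts` runs
independent chains and keeps the best state found: pure-interaction
signals (XOR) leave every single leaf with zero marginal effect, so a
single chain can cool before assembling both halves of the interaction —
on stalled runs the true XOR model had deviance ~90 below the found
model, identifying a search failure rather than overfitting. The
recovery studies use 4 restarts × 5 000 iterations (the same total fit
budget as one 20 000-iteration chain), which recovered the planted rule
in 20/20 and the XOR in 10/10 pilot runs.

Model identifiability: a tree T with coefficient β is the same model as
its complement with coefficient −β (and intercept shifted), so recovery
checks accept either orientation, and XOR recovery is asserted at model
level — the linear predictor over all assignments of the referenced
variables must partition exactly by the XOR of the two targets.

## Synthetic panel generator

What it emulates: 16 quadrant groups (8 stainings; primary CD3/CD8,
CD3/DR, CD45/CD3, Lin/DR gates plus 12 secondary marker pairs), each a
4-part composition drawn as independent gammas scaled to sum to exactly
100 — which forces the negative correlations between complementary
quadrants that real quadrant data show. The CD3/CD8 group gets four
acquisitions with additive Gaussian noise (default SD 1.0 percent,
renormalised so closure is exact) whose mean is stored. The
CD3-DR-CD56/CD16 group's default concentration (2, 0.45, 0.45, 2) sets
the correlation between its ++ and −− quadrants to ≈ −0.7, emulating the
strong complementary-quadrant correlation reported in the motivating
dataset; other groups default to (1.5, 1.0, 0.7, 0.8). One quadrant of
the CD3+CD8+ CD7/CD154 set is simulated but unreported so the exported
panel matches the published 63-variable list; the baseline CD4 count is
uniform on the trial's 200–350 cells/µL eligibility window. Missingness
is MCAR on flow cells only (default rate 0.05 — the real rate and
mechanism are unreported, so this is a convention, not a
reconstruction). Week-36 CD4 counts realise responder status as
450·exp(±|N(0.25, 0.12)|), guaranteed strictly above / at-or-below 450.

Outcome models plant signals on the dichotomised scale: `null` (one
rate), `marginal` (two rates by one target), `conditional` (four rates by
two targets), and `interaction` (XOR with balanced targets — marginal
effects are exactly null by construction). Recorded truth (spec, medians,
stratum memberships, responder draws) makes recovery exactly checkable.

What it does **not** emulate: event-level cytometry, instrument
compensation, isotype-control background, between-staining dependence of
a subject's compositions (groups are independent given the
concentration), informative missingness, and any real covariance between
the baseline CD4 count and the flow variables. Passing recovery tests
therefore demonstrate that the *algorithms* find planted structure under
realistic compositional correlation and missingness — not that such
structure exists in any particular trial.

## Study conditions used in the checks

- Reconstructed root split: n = 78 with 19 responders split 39/39 and
  4 vs 15 responders — the table (4, 35, 15, 24), OR 0.183, corrected
  p 0.008, root Gini 0.3685, φ 0.0398, root-only risk 0.2436.
- CART structure recovery: conditional rates (0.70, 0.70, 0.45, 0.05),
  n = 400, 100 replicates.
- Forest ranking: marginal rates 4/39 vs 15/39 (the reconstructed split's
  stratum rates), n = 400, B = 500, 100 replicates.
- Logic rule: (target₁ ∧ ¬target₂) at rates 0.75 vs 0.25 (log-odds
  difference 2.197), n = 500, 20-variable matrices, 20 runs.
- XOR: rates 0.8/0.2, n = 500 for recovery; marginal nullness checked on
  a 50 000–100 000-subject draw of the same process, where the sampling
  SD of a null log odds ratio is well below the 0.1 bound (at n = 500 it
  is ≈ 0.2, so the bound is only meaningful at large n).
- Null calibration: n = 78, 19/78 base rate; 500 replicates (screen),
  100 (CV pruning).

The acceptance script runs the same studies at reduced replicate counts
(50/30/20/10) chosen to estimate each rate with a few-percent standard
error; the test suite runs the full counts.

## Known limitations

- No surrogate splits or continuous-split search (inputs are
  pre-dichotomised by design); regression trees are out of scope.
- No significance testing of forest importances and no
  permutation-test-based logic model selection; both are exploratory
  rankings here.
- The q-value's π₀ estimator is the simple Storey plug-in at a fixed λ;
  no spline smoothing.
- The annealing schedule is a convention (the source analyses do not
  state theirs); results at fixed seeds are exactly reproducible, but
  different schedules can visit different local minima.
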
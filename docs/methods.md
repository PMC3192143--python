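# Methods

Models, assumptions, defaults and numerical choices behind the `vda`
package. Notation: M algorithms make binary calls on n instances; P / N are
the counts of truly positive / negative instances; D is the discordant set
(instances on which at least two algorithms disagree); U′ is the detectable
set (instances with at least one positive call).

## Model and assumptions

- **Operative-point performance.** Each algorithm is treated as a black box
  with one fixed (sensitivity, specificity) pair, so its AUCROC equals its
  balanced accuracy `(TP/P + TN/N)/2`. Nothing here applies to algorithms
  whose threshold will be re-tuned after validation.
- **Validation is noiseless.** A validated label is the truth. Noisy or
  ambiguous assays are out of scope.
- **Exchangeability within fingerprints.** All information about an
  instance used for selection and estimation is its M-bit call pattern.
  Instances with identical fingerprints are interchangeable; any covariates
  that distinguish them are ignored.
- **Ranking lives on D.** The pairwise AUCROC difference
  `ΔAUC_ij = |(TP_i − TP_j)/P + (TN_i − TN_j)/N| / 2` depends only on
  instances where i and j disagree, so selectors draw from D (optionally
  U′). Absolute performance levels, by contrast, depend on concordant
  instances too — hence the reference algorithms below.

## Selection

**GVDA** greedily grows the validation set, at each step choosing the
instance whose addition maximizes the ascending-sorted vector of
M·(M−1)/2 pairwise Hamming distances in lexicographic (leximin) order:
raise the minimum first, then the second-smallest, and so on. Candidates
are fingerprints (not raw instances) with remaining unselected members;
ties between fingerprints are broken uniformly at random under the plan's
seed, and the member drawn from the winning fingerprint is also random.
Each step records the distance vector after the pick, so plans are
auditable; the minimum distance is non-decreasing along the plan.

**EVDA** finds a provably minimum-cardinality subset whose pairwise
distances all reach a target h. Because members of a fingerprint are
exchangeable, the search state is the vector of per-fingerprint counts
plus the remaining distance deficit per algorithm pair; a memoized
depth-first search over these states with an infeasibility bound (suffix
totals cannot cover the deficit) returns the minimum size, and the subset
is reconstructed by walking the memo. `h="auto"` uses the largest
achievable h; requesting more raises an error reporting the achievable
maximum. `evda_sort` concatenates the minimal sets for h = 1, 2, …,
de-duplicating instances, so every prefix through a level boundary
satisfies that level's constraint. The search is exponential in the number
of distinct fingerprints; a `max_states` guard (default 2,000,000) fails
loudly rather than running unbounded.

**random_sort** shuffles the chosen pool (D by default, U′ optionally)
uniformly; it is the baseline in all experiments.

**Reference algorithms.** `add_reference_algorithms` appends AllTrue and
AllFalse columns. Each scores exactly 0.5 regardless of the data, and their
mutual disagreement on every instance makes D the full instance set, so
selectors may sample anywhere and the estimator's partitions all become
discriminating. Experiments include them by default (`include_reference=True`)
because without them large concordant partitions can never be validated and
partition-coverage bias dominates every error measure.

## Estimation

With partitions w (fingerprint classes), validated positives/negatives
Pv_w / Nv_w, the stratified estimator is

```
P̂    = Σ_w |w| · Pv_w / (Pv_w + Nv_w)
T̂P_i = Σ_{w : pattern_w[i]=1} |w| · Pv_w / (Pv_w + Nv_w)
```

(N̂, T̂N analogous), giving `AUC_i = (T̂P_i/P̂ + T̂N_i/N̂)/2`. Each partition's
cardinality is distributed according to the positive fraction observed
among its validated members. Partitions with no validated member
contribute nothing; `coverage` reports the covered fraction of instances.
With full validation the estimator reduces exactly to the balanced
accuracy (verified to 1e−12 in the tests). If P̂ or N̂ is zero the
corresponding component is undefined and a specific error is raised rather
than returning NaN silently.

Rankings use midranks on descending AUC (`scipy.stats.rankdata`);
agreement with a true ranking uses tie-corrected Kendall τ-b
(`scipy.stats.kendalltau`). Both are deliberately bought from SciPy, with
independent O(n²) oracles in the test suite.

## Simulators

- **`make_truth(n_instances, pos_fraction, seed)`** draws a random label
  permutation with `round(pos_fraction · n)` positives.
- **RDFA** (`rdfa_generate(target, truth, seed)`) produces a column whose
  balanced accuracy is *exactly* the target: it enumerates all integer
  pairs (TP, TN) with `TP/P + TN/N = 2a` (absolute tolerance 1e−9 on the
  grid equation), samples one pair uniformly, and assigns hits uniformly
  among positives and negatives. Infeasible targets raise an error naming
  the nearest achievable values on either side; `snap_target` maps a real
  target to the nearest achievable grid value (moving it by less than
  `1/(4·min(P,N))`), which is how the experiment drivers handle arbitrary
  real-valued targets.
- **IDRE** (`idre_generate(p_error, target, n_copies, truth, seed)`) draws
  one RDFA base column and makes n_copies, each flipping
  `round(p_error · n)` distinct instances chosen without replacement
  (independent streams via `SeedSequence.spawn`). Two copies then differ on
  `2·p·(1−p)·n` instances in expectation — a closed form the tests check to
  within 5% at n = 10,000.

What the simulators do **not** emulate: correlated errors between
algorithms (RDFA draws are independent given the truth), instance-level
difficulty (every positive is equally likely to be hit), class-conditional
call noise, or any covariate structure. They are calibration instruments
for the selectors and estimator, not generative models of real pipelines.

## Experiments and defaults

`convergence_experiment` builds, per replicate, an RDFA panel with M
targets — equally spaced `k/(M+1)` in *balanced* mode, i.i.d. uniform(0,1)
in *imbalanced* mode — snaps them to the achievable grid, appends
references, runs each strategy once, and records Kendall τ between the
estimated ranking (references excluded) and the true target ranking at each
budget prefix. Reported per strategy: median, quartiles, 5th percentile and
valid-replicate count per budget. The positive fraction is redrawn
uniformly from [0.1, 0.9] each replicate so class imbalance varies.

`idre_error_experiment` builds, per replicate and error probability p, an
IDRE panel (optionally plus confounder RDFAs), selects a fixed budget per
strategy, and records the maximum over copies of |estimated − true| AUCROC,
where each copy's true value is its full-validation score. Reported:
median and 95% interval per p. `summarize_ratio` forms per-p and mean
ratios of two strategies' median errors, reporting missing (NaN) at p
points with a zero denominator.

Defaults used by the acceptance script and recommended as starting points
(all are package choices, not fitted values): 200 instances, M = 6, 50
replicates, budgets {5, 10, 15, 20, 30, 40, 60, 80}, IDRE setup a = 0.7
with 5 copies, budget 50, p grid 0.05–0.5 in steps of 0.05. Budget 50 for
the error experiment is an arbitrary fixed validation effort chosen to be
small relative to n = 200 while keeping estimator coverage non-trivial.

## Numerical choices

- Calls are stored as read-only `uint8`; all AUC arithmetic is in float64.
  The exactness tests use 1e−12 tolerances; observed errors are at the
  1e−16 rounding floor.
- All randomness flows through `numpy.random.default_rng`; derived child
  seeds are drawn as integers below 2³¹ so they survive any 32-bit seed
  interface. Identical seeds reproduce byte-identical outputs (tested for
  plans, panels, and CLI artifacts).
- The RDFA feasibility check uses `round` on the grid equation with a
  1e−9 absolute tolerance instead of exact rational arithmetic; with
  P, N ≤ 10⁴ the grid spacing is ≥ 10⁻⁸, so no misclassification is
  possible at double precision.

## Limitations

- **Greedy selection trades coverage for discrimination.** GVDA spreads
  validations one per fingerprint partition across rare patterns. Under the
  stratified estimator, a partition validated once assigns its *entire*
  cardinality to a single class, so GVDA's per-algorithm estimates carry
  more reweighting noise than random sampling's size-proportional coverage.
  In the package's own convergence study on 200-instance imbalanced panels,
  GVDA's median τ does not dominate random sampling across budgets; its
  advantage shows when the budget is an appreciable fraction of |D| (small
  panels or generous budgets), and its max-AUCROC errors on noisy IDRE
  copies are larger than random sampling's on average (the acceptance
  script prints the measured ratio). Use GVDA to *discriminate and rank*
  with few validations; prefer random or mixed designs when accurate
  absolute AUCROC estimates at large n are the goal.
- EVDA is exact but exponential; it is practical only when the number of
  distinct discordant fingerprints is modest (tens, not hundreds).
- The estimator is undefined when validated instances are all of one class
  (P̂ or N̂ = 0) — common at very small budgets without reference
  algorithms; experiments report such replicates as invalid rather than
  imputing.
- Operative-point AUCROC says nothing about full ROC curves, calibration,
  or threshold choice; algorithms whose thresholds will be revisited should
  be compared by other means.
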
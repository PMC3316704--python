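# Methods

## Model and scope

Everything rests on ordinary least squares with an intercept:
*Y = β₀ + Σ βⱼ Xⱼ + ε*, ε ~ N(0, σ²) i.i.d. Only Gaussian responses are
supported — no GLM families, weights, or robust losses. Datasets must be
complete (rows with missing cells are dropped at ingestion, with a logged
count) and hold at most 31 predictors plus one response by default; the
cap mirrors the 32-column limit of the classic all-subsets tooling this
workflow grew out of and is configurable, since nothing in the algorithm
depends on it. Binary predictors are accepted as 0/1 numeric columns;
multi-level factors must be pre-encoded.

## Exact per-level best subsets

The per-level search minimises RSS over all C(p, k) subsets at each level
k. All candidate evaluations run on the centred Gram matrix
(XᵀX, Xᵀy, TSS), so one candidate costs a k × k positive-definite solve
rather than a pass over the data. Two interchangeable routes:

- **Exhaustive enumeration** for p ≤ 15 (`exhaustive_threshold`,
  configurable). 2¹⁵ solves is comfortably fast, and lexicographic
  enumeration makes the tie rule (below) automatic.
- **Branch-and-bound** above. Nodes of the subset lattice are
  (committed set C, candidate pool B) pairs; since adding variables never
  increases RSS, RSS(B) lower-bounds every subset between C and B, and a
  node is discarded only when RSS(B) cannot improve (or tie) the
  incumbent at *any* level it could still reach. The bound is exact, so —
  unlike heuristic "pathway" searches — per-level optimality is
  guaranteed; the test suite enforces identity with enumeration across
  50 seeded datasets. Greedy forward and backward passes seed the
  incumbents; children are explored least-harmful-deletion first.

The hot loop exists twice: a pure-Python/scipy version, and a
numba-compiled twin (`revs/_accel.py`) using int64 bitmask subsets and an
in-place Cholesky. They implement the same algorithm and are cross-checked
in tests; the compiled one is used automatically when numba imports, and
brings the n = 50, p = 25 reference search from roughly a minute to a few
seconds on one CPU.

**RSS ties.** Two subsets whose RSS differ by at most 1e-9 × max(TSS, 1)
are treated as tied and the lexicographically smallest index list wins.
This only matters for pathological designs (e.g. exactly duplicated
columns); on continuous data exact ties have measure zero. A subset whose
Gram submatrix is singular (exact multicollinearity) is evaluated through
a minimum-norm solve; its RSS is still well-defined.

## AIC conventions

AIC = −2·log L + 2K with the Gaussian profile log-likelihood
log L = −(n/2)(ln 2π + ln(RSS/n) + 1). K counts k slopes + intercept +
residual variance, i.e. K = k + 2, matching mainstream statistical
software. A slope-only convention K = k is exposed via
`aic_gaussian(..., convention="slopes")`; on a fixed dataset the two
differ by the constant 4 for every model, so all delta AICs — the only
AIC-derived quantity any selection step uses — are identical under
either. This equivalence is asserted in the tests rather than assumed.

A fit with RSS ≤ 1e-12 × TSS is flagged numerically perfect: its
likelihood is unbounded, so AIC is NaN (never −∞) and the model is
excluded from delta comparisons with a warning.

## Support categories

The conventional delta-AIC reading (0–2 very strong, 3–4 strong, 5–9
considerably less, > 10 essentially none) leaves the intervals (2, 3),
(4, 5) and (9, 10] unclassified. They are closed here into contiguous
bands [0, 2], (2, 4], (4, 10], (10, ∞) so every Δ has a category; the
boundary behaviour (Δ = 2 is still "very strong") is unit-tested.

## Ties and order invariance

Tied inclusion counts enter the nested series in dataset column order.
That arbitrary order is harmless when a model cutoff leaves a tie group
entirely in or entirely out, but a cutoff *inside* a group makes the
default selection arbitrary. The resolver therefore fits, at **every**
split boundary, all alternative same-size selections from the group, and
re-designates the best model over primaries plus alternatives. Expanding
every boundary (not only the currently-best one) is deliberate: it makes
the candidate model set a function of the inclusion counts alone, which
is what turns "column order does not matter" from an aspiration into a
provable property — expanding only the best model's boundary was observed
to leak order dependence through models the permuted run never fitted.

Groups wider than five are never enumerated: at a boundary away from the
best model they are skipped silently (such groups are almost always the
count-1 noise tail, whose 2ᵍ selections are combinatorially explosive and
never competitive); if the best model's own cutoff splits one, the run
raises rather than return an order-dependent answer, with an
`allow_wide_ties` override that enumerates under a warning. The residual
caveat — a best model hiding inside a skipped wide group — is the one
place order invariance is not guaranteed, and is correspondingly unlikely
because group width grows with lack of support.

## Baselines

- **Full model**: all predictors at once; identical by construction to
  the level-p model of the series, so the best series model can never
  have higher AIC than it.
- **Stepwise**: classical one-at-a-time selection. Entry/removal under
  the p-value criterion uses the candidate's partial t-test
  (α_enter = α_remove = 0.05 by default); under the AIC criterion a step
  is accepted only when it lowers AIC by ≥ 2 (forward), and a variable is
  retained only when keeping it beats dropping it by ≥ 2 (backward).
  "both" allows removals after each entry. A p-value run that admits
  nothing returns the intercept-only model with a warning; an AIC run
  always enters something when any single addition clears the drop rule.
- **All-subsets comparator**: the lowest-AIC model among the p level-best
  subsets. (A byte-compatible reproduction of any particular legacy
  backend is not attempted.)

Beating stepwise or the all-subsets pick is an empirical pattern, not a
theorem; tests assert only the constructive guarantee (never worse than
the full model) plus observed majorities on fixed seed batteries.

## Split-sample ("honest") validation

`make_holdout_split(n, h, seed)` removes h cases uniformly at random
(2 ≤ h ≤ n − 3; seeded generator, seed echoed in reports). Every method
is refitted on the training rows only — tests assert the fitters never
see hold-out rows — and predicts the hold-out responses. Honest R² and
honest RSS are the R² and residual sum of squares of the OLS regression
of predicted on actual values; the raw sum of squared prediction errors
is reported alongside as `prediction_error_ss`, since "hold-out RSS" is
used both ways in practice. Constant predictions (e.g. an intercept-only
winner) get honest R² = 0 with a warning.

## Synthetic data generator

`SyntheticSpec` emulates the structure that motivates the method:
moderate n (tens to a few hundred), many predictors drawn from a
multivariate normal with AR(1) (ρ^|i−j|) or equicorrelated structure, a
small set of true nonzero slopes, Gaussian noise, and optional
near-duplicate columns (a source column plus N(0, jitter²)) that reliably
force inclusion-count ties while keeping the design full-rank. Reference
conditions used throughout tests and the acceptance script, chosen to
match the field-typical scales above: the study-scale run uses n = 50,
p = 25, AR(1) ρ = 0.5, three true effects (1.0, 0.8, 1.2), σ = 1; the
recovery battery uses n = 200, p = 10, three unit effects, pairwise
correlation 0.3, σ = 1, 100 replicates.

What the generator does **not** emulate: non-Gaussian noise,
heteroscedasticity, nonlinear or interaction effects, categorical
predictors with many levels, missingness mechanisms, and the block-wise
"generic vs specific habitat variable" correlation of real field tables.
Passing tests therefore demonstrate correctness of the algorithmic
contracts and behaviour under the stated Gaussian conditions — not
robustness to everything real data does.

## Numerical choices and degenerate inputs

- RSS tie tolerance 1e-9 × max(TSS, 1); perfect-fit threshold
  1e-12 × TSS; both fixed, not exposed.
- Rank-deficient subset designs: minimum-norm coefficients
  (statsmodels pinv route), `degenerate` flag, warning.
- Un-fittable top models (n ≤ k + 1) in an externally supplied ranking
  are flagged un-fit and excluded from delta comparison instead of
  aborting the run; the full pipeline requires n > p + 1 up front.
- Designation ties (identical AIC to machine precision) resolve to the
  earlier, more parsimonious model in the series.
- Report CSVs are written with fixed formatting so identical
  seed + configuration reproduces byte-identical files.

## Known limitations

- Branch-and-bound remains exponential in the worst case; near-flat RSS
  landscapes (tiny n relative to p, heavy collinearity) can slow it, and
  above ~31 predictors the bitmask representation and the column cap both
  stop play by design.
- The inclusion count is a coarse statistic: it weighs all levels
  equally, and the nested series only ever contains p of the 2^p − 1
  candidate models, so the AIC optimum over the series is not the global
  all-subsets optimum (the all-subsets comparator occasionally wins by a
  small margin).
- Honest validation uses a single split, not k-fold resampling; results
  for small h are noisy by construction.
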
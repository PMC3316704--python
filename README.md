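# revs — Regression with Empirical Variable Selection

Variable selection for multiple linear regression when predictors are many
and mutually correlated — the typical shape of ecological and
environmental datasets (species–habitat tables, morphology vs climate,
and the like), where full-model regression drowns real effects in noise
and one-at-a-time stepwise selection is notoriously order- and
algorithm-dependent.

## The method

Given a response *Y* and predictors *X₁ … X_p* (p ≤ 31 by default):

1. **Per-level best subsets.** For every level *k* = 1…p, find the
   *k*-variable subset minimising the residual sum of squares
   (equivalently maximising R²). The search is exact: exhaustive
   enumeration for small p, and an RSS-bound branch-and-bound above it
   (least-squares RSS can only fall as variables are added, so a candidate
   pool whose RSS cannot beat a level's incumbent is pruned wholesale
   without risk of missing the optimum).
2. **Empirical ranking.** Stack the level-best subsets as indicator rows
   of a p × p TRUE/FALSE matrix; each variable's column sum — its
   *inclusion count*, between 1 and p — measures its empirical support.
3. **Nested model series.** Fit p models: the first holds the top-ranked
   variable, each later one adds the next-ranked (ties entered in dataset
   column order). Compare the series by
   AIC = −2·log L + 2K and Δᵢ = AICᵢ − AIC_min, with the usual support
   bands (Δ ≤ 2 very strong, ≤ 4 strong, ≤ 10 considerably less, > 10
   essentially none). The lowest-AIC model is designated best; highest
   adjusted R² and lowest overall P are reported alongside.
4. **Tie handling.** Variables with equal inclusion counts form tie
   groups. Wherever a model cutoff splits a group, every alternative
   same-size selection from the group (up to five-way ties) is fitted as
   a tie-alternative model, so the selected model does not depend on the
   order columns happen to appear in the file.
5. **Baselines and honest validation.** The result can be benchmarked
   against the full model, classical stepwise selection (p-value or
   AIC-drop-of-2 criteria) and an all-subsets comparator, including a
   split-sample protocol: withhold *h* random cases, refit every method
   on the rest, regress predicted on actual hold-out values, and report
   that regression's R² ("honest R²") and residual sum of squares
   ("honest RSS").

## Worked example

```bash
python examples/run_pipeline.py
```

generates 50 cases with 25 AR(1)-correlated predictors of which three
(x1, x6, x13) truly affect the response, and prints the nested series
(abridged):

```
 model entered_variable relationship  adj_r2  delta_aic           support  best
     1              x13     positive   0.516     43.078  essentially none False
     2               x1     positive   0.653     27.425  essentially none False
     3               x6     positive   0.776      6.288 considerably less False
     ...
     7              x10     negative   0.816      0.000       very strong  True
     8               x9     negative   0.816      0.876       very strong False
     ...
    25               x3     negative   0.749     23.480  essentially none False

Best model: x13 + x1 + x6 + x11 + x2 + x7 + x10
  adjusted R2 = 0.816, AIC = 139.02, P = 7.01e-15
```

All three true predictors head the entry order; the series has exactly 25
primary models (one per predictor), delta AIC dips to 0 at the
seven-variable model and the noise tail decays into the no-support band.
`examples/compare_baselines.py` adds the full/stepwise/all-subsets
comparison with hold-out validation, and `examples/tie_handling.py` shows
tie groups, tie-alternative models and order invariance. A command-line
interface wraps the same pipeline (`revs run`, `revs compare`,
`revs simulate`; see `revs --help`).

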
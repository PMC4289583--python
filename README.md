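# ordmi

Developing a predictive model that includes **interactions which are not
specified up front**, when the data table has **missing cells**, is
circular: the interactions belong in the imputation model (the imputation
model must be at least as rich as the analysis model), but complete data is
needed to find the interactions. `ordmi` implements the resolution used in
missing-data practice for epidemiological questionnaire studies with an
ordinal outcome:

1. **Screen** the missingness (summaries, chi-square tests of whether each
   incomplete variable, and its missingness, relate to observed values of
   other variables — the missing-at-random plausibility check).
2. **Complete once with EM**: maximum-likelihood mean/covariance of the
   (dummy-coded) table under nonmonotone missingness, then conditional-mean
   completion — a single development dataset.
3. **Discover interactions** on that dataset with stepwise selection under
   the proportional-odds model
   `logit P(Y ≤ j | x) = θ_j − x′β` (entry p < 0.05, removal p > 0.10,
   likelihood-ratio tests of whole term blocks, main-effect hierarchy).
4. **Impute m datasets** with the discovered interactions coded as
   variables (*transform-then-impute*), by either engine:
   - **MVNI** — multivariate-normal imputation via the two-step
     data-augmentation chain (I-step: conditional-normal draws; P-step:
     Jeffreys-posterior parameter draws), started at the EM estimates, run
     N = m·k iterations with every k-th state saved, followed by sensible
     rounding back to category labels;
   - **FCS** — chained equations with type-appropriate conditional models
     (linear / binary or multinomial logistic) and proper posterior
     parameter draws.
5. **Fit and pool** with Rubin's rules
   (`T = W + (1 + 1/m)B`, `df = (m−1)(1 + W/((1+1/m)B))²`), with
   Kolmogorov–Smirnov observed-vs-imputed diagnostics and the df-vs-m
   stability reading.

Two ways of combining development with imputation are provided:
**strategy 1** (all three development stages on the EM-completed set, then
impute and pool) and **strategy 2** (stages 1–2 on the EM set, backward
elimination per imputed dataset, keep terms retained in ≥ 50% of them).

Because the motivating study's data is not deposited, the package ships a
**synthetic generator** with the same structure — 382 cases, 21 categorical
predictors plus age, a fully observed 3-level ordinal outcome, per-variable
MAR missingness from 0 to 19.4% with a nonmonotone pattern — and a known
generating model (two true interactions), so every stage is testable end to
end.

## Worked example

```python
import ordmi

design = ordmi.default_design(n=382)     # the study-scale reference design
table = ordmi.simulate(design, seed=7)   # generate, then ampute (MAR)

summary = ordmi.summarize_missingness(table)
print(f"missing cells: {summary.n_missing_cells} ({summary.overall_pct:.1f}%), "
      f"pattern: {summary.pattern}")
print(f"recommended m: {int(ordmi.recommended_m(summary.overall_pct / 100))}")

result = ordmi.strategy1(table, method="mvni", m=20, seed=7)
print("selected interactions:", [t.name for t in result.terms.interactions])
print(result.pooled.table[["estimate", "se", "df", "p"]].round(3).head(8))
```

prints

```
missing cells: 421 (5.0%), pattern: nonmonotone
recommended m: 20
selected interactions: ['work_wear:violence', 'fear:breakfast', 'birth_weight:smoke_vehicle', 'stove:age', 'gender:smoke_vehicle', 'fear:tv', 'gender:fear', 'exercise:breakfast', 'fear:age', 'gender:work_wear', 'fear:area']
                           estimate     se        df      p
gender=female                 0.768  0.323  2241.482  0.018
neonatal_care=yes             0.463  0.324  1486.041  0.152
birth_weight=up to 2.5 kg    -0.607  0.341  8805.961  0.075
birth_weight=don't know      -1.403  0.708  2339.357  0.048
fear=yes                     -0.024  1.449   163.484  0.987
smoked_pregnant=yes           0.037  0.471  1094.135  0.938
smokers_home=yes              0.814  0.248  5969.197  0.001
smoke_vehicle=yes            -0.199  0.451   349.555  0.660
```

Reading it: at 5.0% missing information the band table advises m = 20
imputations. Forward selection on the EM-completed dataset retained eleven
interactions — among them the two the generating model really contains
(`fear:breakfast`, `gender:smoke_vehicle`); the rest are stepwise entries
from ~200 candidates tested at the 0.05 level, the optimism strategy 2's
per-dataset backward elimination is designed to prune. Each pooled row
shows the Rubin-combined coefficient, its total-variance standard error,
the Rubin degrees of freedom (large relative to m = 20, i.e. stabilized
estimates), and the t-based p-value.

The same pipeline is scriptable from the shell:

```bash
ordmi simulate --n 382 --seed 7 --out data.csv --schema-out schema.yaml
ordmi describe-missing data.csv schema.yaml
ordmi screen-mar data.csv schema.yaml --out mar.json
ordmi em-complete data.csv schema.yaml
ordmi impute data.csv schema.yaml --method mvni --m 20 --seed 7 \
      --interaction fear:breakfast --outdir imputed
ordmi develop data.csv schema.yaml --strategy 1 --method mvni --m 20 --seed 7
ordmi diagnose data.csv schema.yaml imputed/imputed.csv
```

## Library surface

| module | contents |
| --- | --- |
| `ordmi.schema`, `ordmi.table` | typed schema, `MaskedTable`, CSV/YAML I/O |
| `ordmi.missingness` | `summarize_missingness`, `screen_mar` |
| `ordmi.coding` | dummy coding, joint-category interaction coding, `sensible_round` |
| `ordmi.em` | `em_fit`, `em_complete`, sklearn-style `EMImputer` |
| `ordmi.mvni` | `i_step`, `p_step`, `impute_mvni`, `MVNImputer` |
| `ordmi.fcs` | `init_fill`, `fcs_iteration`, `impute_fcs`, `FCSImputer` |
| `ordmi.ordinal` | `fit_ordinal`, `lr_test`, sklearn-style `OrdinalRegression` |
| `ordmi.selection` | `forward_interactions`, `backward_eliminate`, `strategy1`, `strategy2` |
| `ordmi.pooling` | `rubin_pool`, `ks_compare`, `df_stability`, `recommended_m` |
| `ordmi.synthetic` | `SimulationDesign`, `generate_complete`, `ampute`, reference designs |

The imputers and the ordinal model follow scikit-learn conventions
(`fit`/`transform` or `fit`/`predict`, `get_params`/`set_params`,
trailing-underscore fitted attributes); see `docs/methods.md` for the full
methodological account, including every default and its rationale.

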
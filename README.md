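# relint — relevant intersections for smoking-cessation outcomes

`relint` implements a resampling-based workflow for deciding which
*intersections* of demographic and socio-economic factors — interactions of
age, sex, education, household income and region of residence — genuinely
shape two smoking-cessation outcomes in a population survey of past-year
smokers:

* **MTSS** — motivation to stop smoking, a 7-level ordinal scale collapsed
  to three categories (*absence* / *unspecific* / *motivation*) after a
  Brant test rejects the proportional-odds assumption; modelled by
  multinomial logistic regression.
* **QA** — whether the respondent made ≥ 1 serious past-year quit attempt;
  modelled by binary logistic regression.

Naive intersectionality analyses stratify the sample into every covariate
combination (here 2 × 3 × 3 × 3 × 3 = 162 strata) or test many interaction
terms at once; both produce spurious, irreproducible "intersections". This
package instead:

1. splits the data 70/30 into learning and validation sets;
2. multiply imputes item non-response by chained equations (predictive mean
   matching, logistic and multinomial draws), **separately** per split
   (m = 10 learning, m = 20 validation);
3. enumerates candidate models that cross functional forms of the
   continuous covariates (linear vs restricted cubic splines, Harrell
   quantile knots) with at most one interaction pair from the five
   intersection covariates;
4. scores every candidate on repeated bootstrap out-of-bag (OOB) samples
   of the learning data — by the **polytomous discrimination index** (PDI)
   for MTSS and the **Brier score** for QA — and selects the candidate with
   the best mean OOB score (best subset for the multinomial outcome; a
   BIC-based backward-elimination prefilter for the binary one);
5. confirms a winning interaction with a Meng–Rubin (D3) pooled
   likelihood-ratio test across imputations;
6. pools coefficients by Rubin's rules into odds-ratio tables, draws
   average-marginal-prediction surfaces for the selected interactions, and
   reports the accuracy change on the untouched validation data.

The survey behind the original analysis is third-party, so the package
ships a first-class synthetic generator (`relint.synthetic`) whose
covariate margins, outcome models (including a true age × income
interaction for MTSS and a true sex × education interaction for QA) and
selective missing-at-random mechanism emulate the published sample
characteristics. Every stage of the pipeline is exercised and tested
against that generator.

## Core quantities

For the multinomial outcome with categories *j = 1..K*, the PDI draws one
observation from each category and asks how often the observation truly in
category *j* has the highest predicted probability *for* category *j*:

    PDI = (1/K) Σ_j  P( p̂_j(X_j) > p̂_j(X_k) for all k ≠ j ),

with ties splitting credit 1/t, so an uninformative model scores exactly
1/K. The Brier score is mean((y − p̂)²). Continuous covariates use
restricted cubic splines: k quantile-placed knots, truncated-power basis,
linear beyond the boundary knots. Pooling across m imputations follows
Rubin's rules, T = W + (1 + 1/m)B, with Barnard–Rubin degrees of freedom;
likelihood-ratio tests are pooled by the Meng–Rubin D3 statistic.

## Worked example

```bash
python analysis/01_simulate.py --seed 1          # synthetic survey, n = 13 245
python analysis/02_impute.py   --seed 1          # 70/30 split + imputation
python analysis/03_select_models.py --seed 1 -B 100
python analysis/04_effects_validation.py
```

The selection step prints (seed 1, B = 100):

```
[mtss3] winner interactions: [], rule=pdi, mean score=0.45068
[qa] BE+BIC prefilter kept interactions: [('sex', 'education')]
[qa] winner interactions: [('sex', 'education')], rule=brier,
     mean score=0.14356, LR confirmation: {'retained': True, 'p': 1.9e-08}
```

— the quit-attempt model recovers the generated sex × education
intersection and the pooled LR test confirms it (p ≈ 2·10⁻⁸), while the
bootstrap keeps the motivation model sparse at this seed. The effects step
then reports

```
[mtss3] motivation peak age (income 0.5): 40
[mtss3] pdi: learning 0.4644, validation 0.4718, accuracy change -1.59%
[qa] brier: learning 0.1426, validation 0.1479, accuracy change +0.61%
```

i.e. the marginal probability of motivation to stop peaks near age 40 in
the lowest income band (the generated surface peaks at 30–50), and the
predictive accuracy of both final models moves by well under ±6% on the
independent validation data. `results/` receives the pooled OR tables,
tidy marginal-probability grids, an age × income heatmap, and the
replicate-level bootstrap scores.

The same workflow is available as a single command:

```bash
relint run --seed 1 --outdir results/run1          # or: relint simulate / impute
```

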
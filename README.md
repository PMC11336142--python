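# npbclock

A tested, reusable pipeline for building a **non-invasive physiology-and-behavior
(NPB) age clock** from longitudinal individual-year trait panels, and for asking
whether clock-derived "relative age" predicts mortality and is shaped by
early-life adversity.

The pipeline stages are:

1. **Trait screening** (`npbclock.screen`) — two-stage per-trait modeling:
   exhaustive AIC selection of a base covariate model (mixed models with an
   individual random intercept), then linear + quadratic age terms tested at
   alpha = 0.05; significant traits form the clock feature set.
2. **Inclusion filters** (`npbclock.datamodel`) — drop individual-years observed
   < 60 days or with ≥ 65% of clock traits missing.
3. **Two-phase imputation** (`npbclock.impute`) — phase 1 fills a missing year
   from the adjacent year of life (mean of both neighbors for continuous traits,
   a seeded random pick for categorical ones); phase 2 is chained **predictive
   mean matching** run *separately* on the training and test rows of each of
   5 train/test splits (years of each individual dealt evenly across test
   folds), 5 imputations per split → 25 completed train/test pairs. Age is never
   part of the imputation model.
4. **Random-forest clock** (`npbclock.clock`) — one regression forest per
   (split, imputation) pair (ntree = 2000 by default, mtry tuned by out-of-bag
   R²); each record is predicted in its own test fold once per imputation and
   the predictions averaged. Derived quantities: delta age (predicted − known),
   relative age (residual of pooled OLS of predicted on known age), lifetime
   mean relative age per individual, and the random-intercept repeatability
   (ICC) of relative age. A "restricted" variant drops the mortality-linked
   trait set.
5. **Survival & adversity models** (`npbclock.survival`) — lifetime and
   time-varying Cox models on counting-process records (Efron ties, delayed
   entry, individual-clustered robust SEs for the annual model); a cumulative
   early-adversity index (six sources, continuous ones scored at the most
   adverse population quartile); linear mixed models of annual delta age on
   adversity plus current conditions; and the adversity-adjusted Cox fit with
   its attenuation diagnostic.

Because the source field data are not public, the package ships a first-class
**synthetic cohort generator** (`npbclock.simulate`) with known ground truth:
age trajectories in six shape classes, individual random intercepts, a latent
per-individual *frailty* offset that shifts both trait trajectories (the
individual "looks" f years older) and the mortality hazard, adversity-dependent
frailty, clumped ~26% missingness, and staggered right-censoring. Every
downstream stage is tested against this recoverable truth.

## CLI

```bash
# generate a synthetic cohort (panel.csv, vitals.csv, adversity.csv, truth.csv)
npbclock simulate --seed 1 --out out/sim

# run individual stages
npbclock screen --seed 1 --out out/screen
npbclock impute --seed 1 --out out/impute
npbclock clock  --seed 1 --out out/clock --ntree 500

# full pipeline (simulate -> screen -> filter -> fill -> impute -> clock ->
# survival -> adversity), manifest.json lists every artifact
npbclock run --config config.yaml --seed 1 --out out/run

# replicate the pipeline and report truth recovery
npbclock study --seed 1 --out out/study --replicates 5
```

A config file is flat YAML mirroring `npbclock.pipeline.PipelineConfig`, e.g.:

```yaml
simulation:
  n_individuals: 319
  missing_rate: 0.26
ntree: 500
m_imputations: 5
n_splits: 5
restricted_clock: true
```

## Layout

```
src/npbclock/
  datamodel.py   # TraitSpec, CohortPanel, panel I/O, filters, standardization
  simulate.py    # synthetic cohorts with known frailty/adversity ground truth
  screen.py      # AIC base models + age-term tests (LMM / GLM / multinomial)
  impute.py      # neighbor fill, split plans, chained PMM, 5x5 imputed sets
  clock.py       # forests, prediction averaging, metrics, relative age, ICC
  survival.py    # Cox models, adversity index, delta-age mixed models
  pipeline.py    # orchestration + manifest
  cli.py         # click entry points
```
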
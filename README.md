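# proteintrial

An emulated target trial of hypothetical protein-intake interventions in a
postmenopausal cohort, estimated with the parametric g-formula.

The pipeline asks: if every eligible woman had adhered to a total daily
protein intake of at least *t* g per kg body weight (for *t* in 0.8, 1.0,
1.2, 1.5), what would mean body composition (abdominal visceral and
subcutaneous adipose tissue, body fat %, lean soft tissue %, weight) have
been at the end of three years of follow-up, compared with the natural
course?  Estimation is Monte Carlo g-computation: fit parametric models for
baseline covariates, the exposure, the outcomes, and censoring; simulate
pseudo-individuals; set the exposure by the threshold rule `max(a, t)`;
standardize predicted outcomes; and wrap everything in a nonparametric
percentile bootstrap (500 resamples by default).

Because the motivating cohort data are not publicly distributable, the
package ships a synthetic cohort generator with a fully known
data-generating process, including exact counterfactual truth for every
intervention (closed form and brute-force oracle).  All statistical claims
are validated against that truth.

## Layout

| module | role |
| --- | --- |
| `proteintrial.cohort` | data model, schema, eligibility filter, exposure derivation, intake categories |
| `proteintrial.synthetic` | DGP configuration, cohort generator, counterfactual truth (closed form + oracle), discrete toy cohorts |
| `proteintrial.strategies` | natural course and threshold interventions |
| `proteintrial.fitting` | linear/logistic/multinomial/saturated model fits, default model specifications |
| `proteintrial.engine` | Monte Carlo g-formula, plug-in standardization oracle, crude contrast |
| `proteintrial.inference` | percentile bootstrap confidence intervals |
| `proteintrial.reporting` | pipeline driver, effects table, natural-course diagnostic |
| `proteintrial.cli` | `proteintrial generate | estimate | bootstrap | report` |

## CLI

```bash
# synthetic cohort + schema + closed-form truth sidecar
proteintrial generate --n 4681 --seed 1 --out cohort.csv \
    --schema-out schema.yaml --truth-out truth.json

# point estimates
proteintrial estimate --cohort cohort.csv --schema schema.yaml \
    --strategies nc,0.8,1.0,1.2,1.5 --mc-size 20000 --seed 1 --out estimates.json

# full table with 95% percentile bootstrap CIs
proteintrial bootstrap --cohort cohort.csv --schema schema.yaml \
    --n-resamples 500 --seed 1 --out effects.csv

# end-to-end synthetic run (eligibility -> fits -> g-formula -> bootstrap)
proteintrial report --outdir results/run1 --n 4681 --seed 1 --n-resamples 500
```

Real cohorts are a one-row-per-participant CSV whose columns follow the
convention documented in `proteintrial.cohort` (`<covariate>_0/_1`,
`protein_0/1`, `<outcome>_0/_1/_2`, `energy_1`, `censor`), described by a
YAML schema; templates ship in `src/proteintrial/data/`.

## Notes on conventions

- Time index 0 is enrollment, 1 the analytic baseline (3-year visit), 2 the
  end of follow-up (6-year visit).
- Threshold interventions are minimal-change: already-adherent intakes are
  left untouched.
- Censoring (death, loss to follow-up) is handled by fitting outcome models
  on uncensored records and predicting for everyone (the "abolish
  censoring" intervention implicit in g-computation); censoring models are
  fitted for diagnostics.
- Bootstrap CIs are percentile (2.5/97.5), resampling participants before
  all model fitting; replicate seeds derive from (master seed, replicate),
  so results are invariant to worker count.
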
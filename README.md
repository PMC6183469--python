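# mimicry-risk

Quantifies the human-induced cost of viper mimicry for harmless snakes from
identification-survey data. Given a survey of respondents (attitude toward
killing snakes; snake sightings) and an identification experiment (each
respondent labels 9 snake pictures: 3 adders, 3 smooth snakes, 3 grass
snakes), the package estimates:

* **mu_0** — probability an encountered human would kill any snake, and
  **mu_v** — probability they would kill only venomous adders, as
  intercept-only binomial logit GLMs (closed form);
* **eps_i** — probability a "selective killer" identifies species *i* as an
  adder, from a binomial logit GLMM with a species fixed factor and crossed
  picture/interviewee random intercepts, fitted by Laplace-approximate
  maximum likelihood (own implementation; cross-validated against `lme4`
  and adaptive Gauss–Hermite quadrature oracles in the test suite);
* **phi_i = (mu_0 + mu_v * eps_i) / mu_0** — the fold increase in kill risk
  upon human encounter attributable to viper resemblance, with a
  10,000-draw Monte Carlo 95% interval (independent normal draws on the
  logit scale, back-transformed per draw).

A seeded synthetic survey generator with known ground truth (attitude mix,
species logits, attitude skill offsets, crossed random-effect SDs,
unknown-answer rate) makes the whole pipeline testable offline and supports
parameter-recovery and interval-coverage studies.

## CLI

```sh
# synthetic survey with ground truth
mimicry-risk generate --config config.yaml --seed 7 --out survey/

# structural validation
mimicry-risk validate --respondents survey/respondents.csv --trials survey/trials.csv

# full analysis: attitudes -> GLMMs -> Monte Carlo risk ratios
mimicry-risk analyze --respondents survey/respondents.csv \
    --trials survey/trials.csv --seed 20140601 --out analysis/
```

`analyze` writes `report.json` (lossless), `report.txt` (human-readable
summary) and `tables/*.csv`. Option flags (`--marginal`, `--joint-attitude`,
`--scale {link,response}`, `--unknown-as-mistake`,
`--drop-unknown-for-adder-model`, `--continuity-correction`) select the
documented sensitivity variants; a YAML `--config` can hold the same keys,
with flags taking precedence. Foreign CSV headers can be ingested without
editing files via a YAML `--column-map` (canonical key -> column name, plus
optional cell-value recoding).

## Data format

Two CSVs. `respondents.csv`:
`respondent_id,municipality,saw_snake_last_year,seen_where,attitude` with
`attitude in {no_kill, kill_all, kill_selective}`,
`seen_where in {yard, nature, both, none}`, booleans `true`/`false`.
`trials.csv`: `respondent_id,picture_id,true_species,response` with species
in `{adder, smooth, grass}` and `response` additionally allowing `unknown`.

By default an `unknown` answer counts as "not called an adder" in the
identification models and is excluded from the mistake model's denominator.

## Package layout

| module | contents |
| --- | --- |
| `mimicry_risk.survey_io` | data model, CSV read/write, validation, attitude proportions |
| `mimicry_risk.synthetic` | seeded survey generator with ground-truth config |
| `mimicry_risk.glmm` | Laplace engine for crossed logit random intercepts |
| `mimicry_risk.inference` | intercept GLM, identification & mistake GLMMs, level probabilities |
| `mimicry_risk.mimicry_cost` | risk ratio, Monte Carlo propagation, delta-method cross-check |
| `mimicry_risk.pipeline` | end-to-end orchestration and report output |
| `mimicry_risk.cli` | `mimicry-risk` command line |
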
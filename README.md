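# vaxdce

A discrete choice experiment (DCE) pipeline for vaccine preference and
hesitancy analysis:

- **`design_space`** — attribute grids, full-factorial enumeration,
  candidate-pair sampling, conditional-logit Fisher information, D-optimal
  subset selection via modified Fedorov exchange, random blocking with a
  chi-square balance check, dominance classification (trap tasks), and the
  Johnson–Orme sample-size rule.
- **`choice_simulation`** — synthetic respondents with configurable covariate
  prevalences, a covariate-linked hesitancy propensity that raises opt-out
  utility, an inattentive subpopulation answering at random, conditional-logit
  choice simulation over a blocked design plus trap task, and the
  trap-question quality filter.
- **`clogit_estimation`** — from-scratch conditional-logit maximum likelihood
  (Newton–Raphson, analytic gradient/Hessian, step-halving), dummy coding
  against reference levels with continuous cost, opt-out handling (ASC /
  all-zero / drop), odds ratios with Wald intervals, optional
  respondent-clustered errors.
- **`preference_metrics`** — willingness-to-pay ratios with delta-method or
  parametric-bootstrap intervals, relative attribute importance from
  part-worth ranges, fixed-rate INR→USD conversion.
- **`hesitancy_analysis`** — per-respondent opt-out scoring, the cumulative
  opt-out curve, 2×2 contingency odds ratios (Woolf intervals), and a
  from-scratch multivariate logistic regression.
- **`io_cli`** — a `vaxdce` command-line tool tying the stages together.

## CLI

```bash
# 40-task D-optimal design in 8 blocks of 5, plus the dominant trap pair
vaxdce design --seed 1 --out design.csv

# simulate 10,000 respondents over it
vaxdce simulate --design-csv design.csv --n 10000 --seed 1 --out-dir data/

# trap-filter and fit the conditional logit
vaxdce fit --data-dir data/ --out-dir fit/

# post-estimation tables
vaxdce wtp --fit-dir fit/ --out wtp.csv
vaxdce rai --fit-dir fit/ --out rai.csv
vaxdce hesitancy --data-dir data/ --out-dir hes/

# everything in one go, with a Markdown report
vaxdce run-all --n 10000 --seed 1 --out-dir results/
```

`run-all` accepts `--subset "<pandas query>"` for subgroup fits (e.g.
`"healthcare_worker == 1"`) and `--subset trap_failed` for the
failed-trap sensitivity fit. A custom attribute grid can be supplied to any
command with `--attrs-config grid.yaml` (see `io_cli.load_attributes`).

All stages derive their randomness from the single `--seed` via named
substreams, so outputs are byte-for-byte reproducible.

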
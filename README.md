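# seqsafe

Bayesian sequential non-inferiority monitoring of rare dichotomous safety
events, where the non-inferiority margin is a *distribution* — a mixture of
at most three beta densities fitted from expert elicitation — rather than a
fixed number.

At each interim analysis `l`, for each event `j`, the rule computes the
posterior probability that the experimental-minus-control rate difference
exceeds the margin distribution,

```
P(delta_j^l) = P(theta_1j - theta_0j > D_j | data at analysis l)
```

with conjugate beta posteriors per arm, and flags an unacceptable excess
when `P(delta_j^l) >= tau_j^l`.  The per-analysis thresholds come from four
decreasing curve families anchored at `(1, 0.95)` and `(L, tau_final)`,
and the final thresholds, the prior and the family are calibrated by
simulating trials under five truth scenarios against severity-weighted
misclassification ceilings (`max class-b = 0.1 + 0.5 (100 - W)/100`).

## Layout

| module                 | role |
|------------------------|------|
| `seqsafe.elicitation`  | expert answers → clamped differences → beta-mixture margin fits (EM / manual dichotomisation / hybrid), method selection by criterion |
| `seqsafe.mixtures`     | `BetaMixture`, single-beta MLE, goodness-of-fit criteria |
| `seqsafe.decision`     | conjugate updating, Monte-Carlo margin exceedance, stopping rule, 13-prior sensitivity grid |
| `seqsafe.schedules`    | uniform / linear / exponential / logarithmic threshold schedules |
| `seqsafe.calibration`  | scenario simulation, class-a/class-b misclassification tables, final-threshold calibration, rule selection |
| `seqsafe.synthetic`    | seeded generators for expert panels and sequential trial counts |
| `seqsafe.io`, `seqsafe.config`, `seqsafe.cli` | CSV/JSON/YAML interfaces and the command line |

## CLI

Every stochastic command requires `--seed` and is reproducible given it.

```sh
# synthetic inputs (no external data needed)
seqsafe synth experts --control-rates death=0.39,ivh=0.15,nec=0.06,ret=0.04 \
    --n-experts 43 --seed 1 --out answers.csv
seqsafe synth trial --theta0 death=0.39,ivh=0.15 --theta1 death=0.47,ivh=0.23 \
    --seed 1 --out-dir counts/

# fit margin distributions from an expert panel
seqsafe elicit-fit --answers answers.csv --control-rates rates.csv \
    --criterion bic --seed 1 --out margins.json

# threshold schedules through the two anchors
seqsafe schedule --family exponential -L 11 --tau-first 0.95 \
    --tau-final death=0.63,ivh=0.60,nec=0.82,ret=0.71 --out schedule.json

# calibrate prior / final thresholds / family by simulation
seqsafe calibrate --config run.yaml --margins margins.json \
    --out calib/ --seed 1 --trials 1000

# apply the sequential rule to accumulating counts
seqsafe monitor --counts counts/counts_death.csv --margin margins.json \
    --event death --schedule schedule.json --prior-label 9 \
    --samples 100000 --seed 1 --out report.json
```

## Notes

- The posterior is available in closed form (beta-binomial conjugacy), so
  margin-exceedance probabilities are computed by direct conjugate
  Monte-Carlo sampling; the test suite checks them against independent
  1-D/nested quadrature oracles.
- Decision comparisons always use raw (unrounded) thresholds; 3-decimal
  rounding is presentation only.
- Simulation entry points accept reduced `n_trials` / `mc_samples` for
  quick runs; defaults are 1000 trials and 100,000 draws per evaluation.
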
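# miebl

Bayesian selection of performance (mastery) criteria for discrete trial
training (DTT).

In DTT, a practitioner declares a skill component mastered when the student
answers at least a preset proportion τ of n assessment trials correctly —
say 8 of 10 for τ = 80%. But τ is a property of one short assessment, not
of the student: the quantity that actually matters is the student's latent
**true mastery** p, the probability they answer an arbitrary item from the
skill-component space correctly. `miebl` makes the link explicit. Modelling
the assessment as X | p ~ Binomial(n, p) with a Jeffreys Beta(½, ½) prior
over p, the posterior after x correct responses is

    p | n, x  ~  Beta(x + ½, n − x + ½)

and the package reports, for any desired mastery level p\*:

* **b = Pr(p ≥ p\* | n, x)** = 1 − I₍p\*₎(x + ½, n − x + ½) — the
  confidence a criterion actually confers (I is the regularized incomplete
  beta function);
* the **credible lower bound** q with Pr(p ≥ q) = 1 − a (default a = 0.05);
* the **posterior mean** (x + ½)/(n + 1) — the point estimate of mastery
  and the success rate to expect at a maintenance check absent real skill
  loss.

It is written for behavior-analysis practitioners and researchers choosing
criteria, and for anyone auditing what a mastery decision rule really
guarantees. Beyond the core calculator it provides per-criterion tables,
five-statement practitioner reports, overlaid posterior-density
comparisons, an assessment planner (smallest n or x reaching a target
confidence), a Monte Carlo validator of the operating characteristics, and
scoring of trial-level session CSVs.

## Worked example

A practitioner plans a 10-trial assessment and wants to know what an 80%
criterion says about reaching 90% true mastery:

```sh
$ miebl report --n 10 --mc 80
[1] "Performance criterion of 80% (8 out of 10 items)"
[2] "If the student meets this criterion, then:"
[3] "The probability that the true mastery is at least 90% is 0.143."
[4] "There is a 95% chance that the true mastery is at least 54.75%."
[5] "The average mastery of comparable students reaching this criterion is 77.27%."
```

Reading the numbers: a student who just meets 8/10 has only a 14.3% chance
of truly being at 90%+ mastery; all one can say with 95% confidence is that
their mastery exceeds 54.75%; and the best single estimate of their mastery
is 77.27% — noticeably below the 80% criterion they met. The full table
(`miebl table --n 10 --pstar 0.9`) shows b for every attainable criterion:

| x  | τ   | b    | 95% lower bound | mean  |
|----|-----|------|-----------------|-------|
| 7  | 0.7 | 0.03 | 44.19%          | 68.18% |
| 8  | 0.8 | 0.14 | 54.75%          | 77.27% |
| 9  | 0.9 | 0.44 | 66.94%          | 86.36% |
| 10 | 1.0 | 0.86 | 82.92%          | 95.45% |

Even a perfect 10/10 gives b = 0.86, not certainty. To design instead of
diagnose, ask the planner how many all-correct trials reach 70% confidence
of 90% mastery:

```sh
$ miebl plan --pstar 0.9 --confidence 0.70
{ "found": true, "n": 5, "x": 5, "achieved_b": 0.7074815446042267, ... }
```

Five for five suffices (b ≈ 0.71). The simulator shows the frequentist
meaning of that statement — among a prior-distributed population of
students who score 5/5, about 29% truly sit below 90% mastery:

```sh
$ miebl simulate --n 5 --x 5 --pstar 0.9 --reps 200000 --seed 1
{
  "reps": 200000,
  "n_meeting": 49351,
  "misclassified_frac": 0.2920102936110717,
  "mean_true_p_given_criterion": 0.9169808715588242,
  "mc_se": 0.0020467489374293014,
  "degenerate": false
}
```

Session data ingest: `miebl score --input trials.csv --scope pooled`
aggregates a trial-level CSV (columns
`student_id,skill_id,session_id,trial_index,outcome`) into (n, x) per
student and skill and reports the same three quantities. The equivalent
library calls are `criterion_table`, `build_report`, `compare`,
`min_trials_for_confidence`, `simulate_criterion`, `read_trials` /
`aggregate` from the `miebl` package.

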
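# Methods

## The model

Discrete trial training (DTT) assesses a skill component with a short
series of structured trials. Let `p` be the student's *true mastery* of the
skill-component space: the latent probability of a correct response on an
arbitrary, exchangeable item from that space. An assessment of `n`
independent trials yielding `x` correct responses is then a binomial
observation,

    X | p  ~  Binomial(n, p).

With a conjugate Beta(a0, b0) prior over `p`, the posterior is

    p | n, x  ~  Beta(x + a0, n - x + b0).

Everything the package reports is a functional of this posterior:

* **b = Pr(p >= p\* | n, x)** — the confidence, after observing the data,
  that true mastery meets the desired level `p*`. This is the upper tail of
  the posterior, `1 - I_{p*}(x + a0, n - x + b0)` with `I` the regularized
  incomplete beta function.
* **Credible lower bound** — the posterior `a`-quantile `q`, so that
  `Pr(p >= q) = 1 - a` (default `a = 0.05`, a 95% statement).
* **Posterior mean** — `(x + a0) / (n + a0 + b0)`, the point estimate of
  mastery, which is also the posterior-predictive expected success
  proportion over any number of future exchangeable trials (the mastery one
  should expect at a maintenance check, absent real skill loss).

Both special functions are delegated to `scipy.stats.beta`; the test suite
carries an independent trapezoidal-quadrature oracle (see below) so the
implementation and its check never share a code path.

## Default prior

The default prior is the Jeffreys prior Beta(1/2, 1/2), the reference prior
for a binomial proportion. It is proper, invariant to reparameterization,
and adds the information of "one trial, half correct" — appropriately weak
for the very small `n` typical of DTT sessions. Under this default the
package reproduces the published criterion tables and worked reports this
project targets (for example, 5/5 correct gives b = 0.71 at p\* = 0.90;
the uniform Beta(1, 1) prior would give 0.47 instead). The prior is a
plain parameter (`jeffreys`, `uniform`, or any `a,b`) everywhere.

## Conditioning convention

A criterion is stated as a proportion `tau`, but the posterior is built by
conditioning on the **exact** observed count `X = x` (with
`x = tau * n`, which must be a whole number of trials), not on the event
`X >= x`. Exact-count conditioning is what the per-`x` rows of a criterion
table mean, and it is what the reproduced tables and reports encode. The
simulator nonetheless offers `conditioning="at_least"` so the difference
between the two readings can be measured rather than assumed: pooling
`X >= x` mixes in higher-evidence students and shifts the retained group's
mastery upward.

Two degenerate conventions are fixed: `p* = 0` gives `b = 1` and `p* = 1`
gives `b = 0` (a continuous posterior puts no mass on the single point
{1}, even after a perfect score), and `n = 0` is rejected rather than
returning the prior, so a report can never present prior-only "mastery" as
if it were evidence.

## Display rounding

Reports freeze the following rounding so golden tests can compare strings
byte-for-byte: table `b` values at 2 decimals; report probabilities at 4
decimals with trailing zeros trimmed (so 0.1430 prints as "0.143" and
0.4665 as "0.4665"); percentages at 2 decimals with trailing zeros trimmed
("54.75%", "77.27%", "90%"); and a separate whole-percent point-estimate
display (86.36% prints as "86%"). JSON output always carries unrounded
values; rounding exists only in text renderings.

## Density grids and endpoint singularities

Posterior densities are exported as (mastery, density) grids — 1025 points
for rendering, 4097 for normalization checks — rather than as images; any
plotting layer consumes the grid. When a posterior shape parameter is below
1 (under the Jeffreys default, exactly the perfect and zero scores
`x = n` and `x = 0`) the density diverges at an endpoint. Evaluation is
clipped to `[1e-9, 1 - 1e-9]`, and the eight grid intervals adjacent to a
divergent endpoint are assigned values (by an inward sweep) such that each
interval carries its exact Beta mass under the trapezoid rule. A naive
clipped grid badly overstates the integral (about 6 at n = 10 for a
singular endpoint); with the mass-preserving boundary the trapezoidal
integral of a 4097-point grid stays within 1.1e-4 of 1 for all `n <= 40`,
comfortably inside the 1e-3 guarantee the package documents.

## Planner

`min_trials_for_confidence` returns the smallest `n` such that a student
meeting criterion `tau` (default 100%, i.e. `x = ceil(tau * n)`) yields
`b >= b_target`; `min_correct_for_confidence` returns, for fixed `n`, the
smallest `x` doing so. `ceil` is used because a fractional trial cannot be
partially correct and a criterion is a floor. The search over `n` is a
linear scan up to a configurable bound (default 10,000 trials, far beyond
any DTT session): `b` at `x = ceil(tau * n)` is not monotone in `n` for
`tau < 1` — the ceiling creates a sawtooth — so bisection would be unsound,
and at these scales correctness beats speed. An exhausted bound is reported
as an explicit no-solution result (CLI exit code 3), not an exception,
because "this design target is unreachable" is an answer, not an error.
Since `b` is strictly increasing in `x`, the first hit of the `min_x` scan
is the unique minimum, and tests verify predecessors fail the target.

## Monte Carlo simulation

`simulate_criterion` draws `p` from a population distribution (by default
the same Beta as the inference prior, making the simulation the exact
frequentist mirror of the Bayesian statement), then `X ~ Binomial(n, p)`,
retains replicates meeting the criterion, and reports the retained count,
the fraction of retained replicates with `p < p*` (the misclassification
rate, which converges to `1 - b`), their mean true mastery (which converges
to the posterior mean), and a binomial standard error
`sqrt(f(1-f)/n_meeting)`. Tests use a 3-standard-error tolerance at 200,000
replicates, where the Monte Carlo error on the misclassification fraction
is about 0.002. All randomness flows from one `numpy.random.default_rng`
seed; no global state is touched, and identical configurations are
bit-for-bit reproducible. A run in which no replicate meets the criterion
returns an explicitly flagged degenerate result with `None` fractions.

This quantifies the selection artifact the framework highlights: students
retained because they met a criterion `tau` systematically have true
mastery below `tau` (e.g. those with exactly 8/10 average 77.3% true
mastery), so a drop observed at maintenance partly reflects this bias
rather than genuine skill loss. The simulation models no actual skill
decay; that is out of scope by design.

## Synthetic session data

`generate_fixture` emulates a student with known true mastery: independent
Bernoulli(`true_p`) outcomes arranged into sessions, deterministic per
seed. It deliberately reproduces the model's own assumptions — a constant
`p` and independent trials. Real DTT data can violate both (learning or
fatigue within a session, prompting effects, serial dependence despite
inter-trial intervals), so passing round-trip and calibration tests on
these fixtures validates the software and the mathematics, not the
adequacy of the binomial model for any particular student. Dependent-trial
models, consecutive-correct criteria and first-opportunity criteria are
explicitly not modelled.

## Numerical and test-design choices

* The test oracle integrates the Beta density by the trapezoid rule on a
  million-point grid after the substitution `p = sin^2(theta)`, under which
  every Jeffreys posterior density becomes bounded
  (`2 sin^(2a-1) cos^(2b-1)`, finite for shapes >= 1/2); the normalizing
  constant is obtained numerically rather than from a Beta-function call.
  Quantiles come from inverting the tabulated numeric CDF. The oracle
  agrees with the implementation to better than 1e-6 (measured: ~5e-12)
  across all `n <= 20`, every `x`, and grids of thresholds and tail levels.
* Criterion integrality is checked to 1e-9 (`tau * n` must be whole); the
  error message lists the attainable criteria for that `n`.
* Aggregation of trial records conserves totals by construction and is
  tested both per-session and pooled; duplicate (student, skill, session,
  trial) keys and non-binary outcomes are rejected with row numbers.
* Property tests assert strict monotonicity of `b`, the lower bound and
  the mean in `x`; monotonicity of `b` in `p*`; and the quantile/tail
  inversion `Pr(p >= q_a) = 1 - a` to 1e-9. Where `b` saturates at the
  floating-point endpoints 0.0 or 1.0 (extreme thresholds), strictness is
  asserted only away from saturation — the underlying inequality is strict
  in exact arithmetic but not representable there.

## Known limitations

* The binomial likelihood assumes exchangeable, independent trials with a
  constant `p` during the assessment; none of the reported quantities are
  robust to serial dependence or within-session learning.
* The mass-preserving density grid slightly distorts the plotted density in
  the eight cells nearest a divergent endpoint (where the true density is
  unbounded anyway); tail probabilities and quantiles are unaffected, as
  they never use the grid.
* The planner's linear scan is O(n_max); at the default bound this is
  milliseconds, but the bound is a practical ceiling, not a proof of
  unreachability beyond it.
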
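# Methods

## Monitoring model

A hospital's performance on one indicator over one period is a sequence of
`n` dichotomous outcomes in temporal order, `y_t = 1` marking an adverse
event. The CUSUM statistic accumulates log-likelihood-ratio weights,
truncated at zero:

    C_0 = 0,  C_t = max(0, C_{t-1} + W_t),  alarm when C_t >= h.

The weights test a multiplicative shift of the outcome odds by the
detection level `delta` (the odds-ratio multiplier `R_A` against the
in-control odds `R_0 = 1`). Crude charts use a constant baseline failure
probability `c0`; risk-adjusted charts use per-patient Phase-I risk scores
`p_t`, and the two coincide exactly when all `p_t = c0` and `R_A = delta`
(the package computes both through the same stable form
`W = log(delta^y) - log(1 - p + delta*p)`, so the reduction is bit-exact
and the weights are exactly zero at `delta = 1`).

`delta < 1` (improvement charts) is exposed through the same formulas; the
sign structure flips (`w_failure < 0 < w_success`) and the chart climbs on
successes. Only deterioration charts are exercised by the studies here.

### Alarm rule and resets

The alarm fires on `C_t >= h`, *not* strict inequality: a zero control
limit must signal at every observation, which is the behaviour degenerate
low-risk small-volume charts actually exhibit. Comparisons against `h` use
an absolute tolerance of 1e-12 so that attainable maxima lying exactly on
the limit are classified stably.

After an alarm, monitoring continues at t+1 (the alarming observation is
not reprocessed) with the statistic reset to zero by default — appropriate
when each alarm triggers an investigation that restores control. Resetting
to a positive value below `h` (faster subsequent alarms) and no reset at
all are offered. A head start (`C_0 > 0`) is not enabled anywhere by
default; all runs start at `C_0 = 0`. The probability of *at least one*
alarm within the period — the quantity all calibrations target — is
invariant to the reset policy, since it is a first-passage event.

## Control-limit calibration

The design criterion is the false-alarm probability: the probability of
any signal within the hospital's own period of `n` in-control
observations. The limit is read off the distribution of the maximum of
unrestricted (no limit, no resets) in-control CUSUM runs:

1. simulate `n_runs` in-control sequences of length `n` — Bernoulli(`c0`),
   or risks resampled with replacement from the Phase-I population (a
   fresh case mix per run) with outcomes Bernoulli(`p`);
2. compute unrestricted runs, vectorized via the reflection identity
   `C_t = S_t - min(0, min_{s<=t} S_s)` of the truncated recursion;
3. collect each run's maximum;
4. select `h` from the attainable maxima.

Only attainable maxima (plus 0) are candidates: between two attainable
values every limit behaves identically, so the attainable value is
canonical. The default `n_runs = 100000` puts a binomial standard error of
about 0.0007 on an achieved probability near 0.05.

### Selection rule, ties, degeneracy

The support of the maximum is discrete, so "the (1-alpha) percentile"
is ambiguous at atoms. The rule used: **the smallest attainable `m` with
`P(max >= m) <= alpha`**, which under the `>=` alarm rule guarantees an
achieved false-alarm probability at or below target whenever the support
is dense enough (achieved and target then differ by at most one atom).

For rare events at small volume the achievable probabilities are few and
widely spaced — e.g. `c0 = 1.25%`, `n = 7` admits only 1, 0.0843, 0.0031,
... — and the conservative choice can undershoot the target severely.
When it undershoots by more than half (`P(max >= h) < alpha/2`), the
selection falls back one attainable candidate (the limit a plain
empirical percentile would give, typically the weight of a single adverse
event), accepts an achieved probability *above* target, and flags the
result degenerate. The fallback never passes below the smallest positive
candidate: a zero limit alarms at every observation and is not a usable
chart, so a near-1 target simply returns the smallest positive attainable
maximum. The `alpha/2` margin is a design choice; it cleanly separates
the one-atom slack of dense supports from genuine support gaps at every
grid cell studied. Degenerate charts should be redesigned (lower target,
pooled years) rather than used as-is; the flag propagates through every
report.

### Exact enumeration

For `n <= 20` the package enumerates all `2^n` outcome paths (chunked,
vectorized) with their in-control probabilities and tabulates the exact
`P(max >= h)` of every attainable limit. The same selection rule then
operates on exact tails. For risk-adjusted charts the enumeration fixes
one patient order of risk scores — unlike the simulated limit, which
integrates over case-mix resampling — and documents that difference; it
is intended for constant-risk checks and tiny fixed panels. Closed-form
binomial oracles (e.g. `P(max >= w_failure) = 1 - (1-c0)^n`) and
100 000-run Monte-Carlo estimates validate the enumeration in the test
suite.

## Evaluation

Signal rates are estimated from simulated monitored runs: data generated
at a true odds multiplier `delta_true` (1 = in control), chart weights
held at the design `delta`. The rate is the fraction of runs whose first
alarm index `t_s <= n`, reported with the normal-approximation Monte-Carlo
standard error `sqrt(rate(1-rate)/n_runs)`; at the default 2000 evaluation
runs exact binomial intervals would change nothing of interest. Run-length
(time-to-signal) samples are returned alongside, `NaN` marking runs that
never signal. `power_grid` crosses volumes x alphas x deltas and emits a
tidy table with in-control and out-of-control rows per cell.

## Synthetic data and study conditions

The generator emulates statutory per-patient hospital records: columns
`hospital_id, t, y` and optionally `p`. Out-of-control truth is a uniform
odds multiplier applied to every patient — the exact alternative the RA
weights test against; time-varying or partial shifts are out of scope.
Risk-adjusted streams carry the *unshifted* Phase-I score, since the
monitoring chart never observes the deterioration.

Default study conditions: baseline failure probabilities 1.25% (rare
neonatal surgical events) and 19.21% (delayed femur-fracture surgery);
volumes 7 / 42 / 105 (small / medium / large hospital); target false-alarm
probabilities 0.1% / 0.5% / 1% / 5%; detection levels 1.5 / 2 / 2.5 / 3.
Case-mix strata take the lower/upper quartile of a score population by
nearest-rank (inverted empirical CDF) quantiles with ties included on the
closed side (`<=` lower, `>=` upper). The bundled demonstration
population is a synthetic two-component beta mixture (92% Beta(2, 240) +
8% Beta(1.5, 15), clipped to [0.24%, 41%]) shaped like published
per-patient risk distributions for open carotid-stenosis surgery — a
realism fixture only, asserted nowhere as ground truth.

What passing tests on this generator do **not** show about real data:
risk-model miscalibration, case-mix drift between phases, reporting-lag
artefacts, and within-year volume changes are all absent by construction.
The pipeline logs a warning when a hospital's volume changes by more than
20% between phases, because a limit simulated at the Phase-II volume can
still be miscalibrated for a process whose volume was assumed wrongly at
design time.

## Pipeline

`run_pipeline` mirrors annual practice: Phase I (previous period)
estimates each hospital's pooled failure rate or case-mix population;
Phase II is monitored against a limit simulated at that hospital's own
Phase-II volume. Hospitals need at least 2 observations in each phase
(configurable); hospitals without Phase-I data are excluded with a logged
warning. All stochastic steps draw from one seeded generator, so a fixed
config and seed reproduce the report exactly.

## Problem sizes in shipped checks

The test suite runs limits at 5 000–100 000 runs and evaluations at
300–2000 runs; the calibration grid uses 2 alphas x 2 deltas x 2 volumes
with 20 000-run limits, and enumeration checks use `n = 7` (the full
4x4x3 study grid at 100 000 runs is a few minutes of compute with the
same code via `power_grid`). These sizes put 3-sigma Monte-Carlo bands
well inside the effects being checked. Far-tail exact-vs-MC comparisons
add a one-count (`1/n_runs`) continuity allowance to the 3-sigma band,
since below `P = 1/n_runs` the simulated count is Poisson and the normal
band alone is narrower than a single observed run.

## Known limitations

- Two-sided monitoring (simultaneous upper/lower limits in one trajectory)
  is not provided; improvement charts are separate `delta < 1` runs.
- Average-run-length design criteria and Markov-chain approximations are
  out of scope; the false-alarm probability over a fixed period is the
  only design criterion.
- Control limits assume the Phase-I estimate is the truth; uncertainty in
  `c0` or the risk scores is not propagated.
- Exact risk-adjusted enumeration fixes the patient order; it is not the
  case-mix-integrated false-alarm probability.
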
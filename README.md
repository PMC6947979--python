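# berncusum

Bernoulli log-likelihood CUSUM charts for monitoring hospital performance
indicators, with control limits calibrated — by Monte-Carlo simulation, or
exact enumeration at small volumes — to a predefined probability of a false
alarm within one monitoring period.

## Who this is for

Quality-assurance statisticians who monitor sequential binary outcomes
(success / adverse event) per hospital and indicator — e.g. statutory
external quality assurance of inpatient care — and need alarm thresholds
that are *fair* across hospitals of very different annual volume and case
mix: every chart is designed to the same type-I error over its own year,
instead of sharing one fixed threshold.

## The model

Outcomes `y_t ∈ {0, 1}` (1 = adverse event) arrive in temporal order. The
chart statistic follows the truncated cumulative sum

```
C_0 = 0,    C_t = max(0, C_{t-1} + W_t)
```

and signals when `C_t ≥ h`. The weights `W_t` are Bernoulli
log-likelihood ratios of a shifted process against baseline, where the
shift multiplies the outcome *odds* by a detection level `δ` (> 1 for
deterioration). For a crude indicator with constant baseline failure
probability `c0` (ST-CUSUM):

```
W_t = log(c_A / c0)              if y_t = 1
W_t = log((1-c_A) / (1-c0))      if y_t = 0,     odds(c_A) = δ · odds(c0)
```

For a risk-adjusted indicator (RA-CUSUM) each patient carries a Phase-I
risk score `p_t` and

```
W_t = log(R_A / (1 - p_t + R_A p_t))   if y_t = 1
W_t = log(1   / (1 - p_t + R_A p_t))   if y_t = 0,      R_A = δ.
```

With constant `p_t = c0` the RA weights reduce exactly to the ST weights.

The control limit `h` has no closed form. It is taken from the
distribution of the maximum of *unrestricted* in-control CUSUM runs of
length `n` (the hospital's volume): simulate many runs — resampling risk
scores with replacement from the Phase-I population in the risk-adjusted
case — and choose the smallest attainable maximum `m` with
`P(max ≥ m) ≤ α`. For small `n` all `2^n` outcome paths are enumerated
instead and the false-alarm probability of every attainable limit is
exact. Charts whose discrete support leaves no attainable limit near `α`
(rare events at small volume) are returned flagged as degenerate.

## Worked example

Design a chart for a delayed-surgery indicator (baseline failure
probability 19.21%) at a large hospital, tune it to a 5% false-alarm
probability over `n = 105` patients and a doubling of odds, then monitor a
deteriorated synthetic year:

```python
from berncusum import CrudeIndicator, CusumChart, generate_crude_stream

femur = CrudeIndicator("femur_fracture_delay", c0=0.1921)
chart = CusumChart(femur, n=105, delta=2.0, alpha=0.05)
res = chart.fit(n_runs=100_000, seed=42)
print(res.summary())
```

```
Bernoulli CUSUM chart
==========================================================
indicator                   femur_fracture_delay
chart type                  crude (ST)
baseline failure prob c0    0.1921
volume n                    105
detection level delta       2
target false-alarm prob     0.05
----------------------------------------------------------
control limit h             3.91592
achieved false-alarm prob   0.04963  (MC se 0.00069)
method                      simulated, 100000 runs
==========================================================
```

The fitted limit `h = 3.916` keeps the probability of any false alarm in
the year at 4.96% (Monte-Carlo standard error 0.0007). Monitoring a year
generated at truly doubled odds:

```python
stream = generate_crude_stream(femur.c0, 105, delta_true=2.0, seed=7)
run = res.monitor(stream["y"].to_numpy())
print(res.monitor_summary(run))
# {'n': 105, 'h': 3.9159..., 'n_alarms': 1, 'alarm_times': [38],
#  'time_to_signal': 38, 'final_cusum': 3.017...}
print(res.signal_rate(delta_true=2.0, seed=1).rate)   # 0.855
```

The chart alarms at patient 38; across 2000 simulated deteriorated years
it signals 85.5% of the time. `res.plot(run)` draws the trajectory with
the limit line and alarm marker.

The same workflow is scriptable from the shell (`berncusum
generate-data | simulate-limit | exact-limit | run-chart | evaluate |
pipeline`); `berncusum pipeline --config cfg.yaml` runs the two-phase
(estimate-then-monitor) workflow for every hospital in a CSV.

## Layout

- `berncusum.indicators` — indicator types, odds transform, weight formulas, Phase-I estimation
- `berncusum.engine` — CUSUM recursion, alarm rule, resets, times to signal
- `berncusum.limits` — simulated and exact control limits
- `berncusum.evaluation` — signal rates, run lengths, design-grid studies
- `berncusum.simulate` — synthetic crude and risk-adjusted data, case-mix strata
- `berncusum.io` / `berncusum.cli` — CSV formats, pipeline, command line
- `berncusum.model` — `CusumChart` / `CusumChartResults` front end

See `docs/methods.md` for the methodology, numerical choices and
limitations.
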
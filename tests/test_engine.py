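"""CUSUM recursion, alarm rule, resets, and trajectory invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from berncusum import (
    NO_SIGNAL,
    max_statistic,
    run_monitored,
    run_unrestricted,
    st_weights,
    time_to_signal,
)
from berncusum.engine import LIMIT_TOL

PAIR = st_weights(0.0125, 2.0)  # w_failure ~ 0.6807, w_success ~ -0.0124


def test_all_success_stays_at_zero():
    run = run_unrestricted([0] * 10, PAIR)
    np.testing.assert_array_equal(run.statistics, 0.0)
    assert max_statistic(run) == 0.0


def test_hand_recursion_failure_then_success():
    run = run_unrestricted([1, 0], PAIR)
    assert run.statistics[0] == 0.0
    assert run.statistics[1] == pytest.approx(0.6807246605613883, rel=1e-12)
    assert run.statistics[2] == pytest.approx(0.668302140562831, rel=1e-12)


def test_consecutive_failures_accumulate_linearly():
    k = 5
    run = run_unrestricted([1] * k, PAIR)
    assert run.statistics[-1] == pytest.approx(k * PAIR.w_failure, rel=1e-12)


def test_max_statistic_example():
    run = run_unrestricted([1, 0, 1], PAIR)
    assert max_statistic(run) == pytest.approx(1.3490268011242192, rel=1e-12)
    # the maximum never exceeds (#failures) * w_failure
    assert max_statistic(run) <= 2 * PAIR.w_failure + LIMIT_TOL


def test_unrestricted_records_no_alarms():
    run = run_unrestricted([1, 1, 1], PAIR)
    assert run.alarms.size == 0 and run.limit is None


def test_zero_limit_alarms_at_every_observation():
    """h = 0 signals at every t under the >= alarm rule, even on successes."""
    run = run_monitored([0, 1, 0, 0], PAIR, h=0.0)
    np.testing.assert_array_equal(run.alarms, [1, 2, 3, 4])
    assert time_to_signal(run) == 1


def test_first_failure_triggers_limit_at_failure_weight():
    run = run_monitored([0, 0, 1, 0], PAIR, h=PAIR.w_failure)
    assert time_to_signal(run) == 3


def test_unreachable_limit_never_alarms():
    n = 6
    run = run_monitored([1] * n, PAIR, h=n * PAIR.w_failure + 1.0)
    assert run.alarms.size == 0
    assert time_to_signal(run) is NO_SIGNAL


def test_reset_to_zero_restarts_the_chart():
    run = run_monitored([1, 1], PAIR, h=PAIR.w_failure, reset_policy="to_zero")
    np.testing.assert_array_equal(run.alarms, [1, 2])
    # statistic recorded at each alarm equals a fresh single-failure weight
    assert run.statistics[2] == pytest.approx(PAIR.w_failure, rel=1e-12)


def test_reset_policy_none_keeps_trajectory():
    run = run_monitored([1, 1], PAIR, h=PAIR.w_failure, reset_policy="none")
    np.testing.assert_array_equal(run.alarms, [1, 2])
    assert run.statistics[2] == pytest.approx(2 * PAIR.w_failure, rel=1e-12)


def test_reset_value_at_or_above_limit_rejected():
    with pytest.raises(ValueError):
        run_monitored([1], PAIR, h=0.5, reset_policy="to_value", reset_value=0.5)


def test_reset_below_limit_gives_faster_subsequent_alarm():
    h = 2 * PAIR.w_failure - 0.01
    zero = run_monitored([1, 1, 0, 1, 1], PAIR, h=h, reset_policy="to_zero")
    head = run_monitored([1, 1, 0, 1, 1], PAIR, h=h, reset_policy="to_value",
                         reset_value=h / 2)
    assert head.alarms.size >= zero.alarms.size


@pytest.mark.parametrize("bad", [[], [0, 2], [0.5]])
def test_invalid_outcomes_rejected(bad):
    with pytest.raises(ValueError):
        run_unrestricted(bad, PAIR)


def test_per_observation_weight_length_mismatch():
    with pytest.raises(ValueError):
        run_unrestricted([0, 1], (np.zeros(3), np.ones(3)))


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    outcomes=st.lists(st.integers(0, 1), min_size=1, max_size=40),
    c0=st.floats(min_value=0.01, max_value=0.6),
    delta=st.floats(min_value=1.1, max_value=5.0),
)
def test_truncation_at_zero_invariant(outcomes, c0, delta):
    """At every t exactly one of C_t = 0 or C_t = C_{t-1} + W_t holds."""
    run = run_unrestricted(outcomes, st_weights(c0, delta))
    c, w = run.statistics, run.weights_applied
    for t in range(1, len(outcomes) + 1):
        untruncated = c[t - 1] + w[t - 1]
        assert c[t] >= 0.0
        assert abs(c[t]) <= 1e-12 or abs(c[t] - untruncated) <= 1e-12


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    outcomes=st.lists(st.integers(0, 1), min_size=1, max_size=30),
    data=st.data(),
)
def test_alarm_count_nonincreasing_in_limit(outcomes, data):
    hs = sorted(data.draw(st.lists(st.floats(0.0, 5.0), min_size=2, max_size=5)))
    counts = [
        run_monitored(outcomes, PAIR, h=h, reset_policy="to_zero").alarms.size for h in hs
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


@settings(deadline=None, derandomize=True, max_examples=40)
@given(outcomes=st.lists(st.integers(0, 1), min_size=1, max_size=25))
def test_unrestricted_max_is_supremum_of_alarming_limits(outcomes):
    """Monitored runs alarm exactly for limits at or below the unrestricted max."""
    m = max_statistic(run_unrestricted(outcomes, PAIR))
    if m > 0.0:
        below = run_monitored(outcomes, PAIR, h=m - 1e-9, reset_policy="none")
        assert below.alarms.size > 0
    above = run_monitored(outcomes, PAIR, h=m + 1e-6, reset_policy="none")
    assert above.alarms.size == 0


def test_run_detail_frame_shape():
    run = run_monitored([1, 0, 1], PAIR, h=PAIR.w_failure)
    frame = run.to_frame()
    assert list(frame.columns) == ["t", "y", "weight", "cusum", "alarm"]
    assert frame["alarm"].sum() == run.alarms.size
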
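"""Control-limit calibration: exact enumeration, Monte-Carlo, selection rule."""

import numpy as np
import pytest
from scipy import stats

from berncusum import (
    CrudeIndicator,
    RiskAdjustedIndicator,
    exact_control_limit_table,
    select_exact_limit,
    simulate_control_limit,
    simulate_maxima,
    st_weights,
)
from berncusum.engine import LIMIT_TOL


class TestExactTable:
    def test_closed_form_single_failure_tail(self, nec):
        """Only paths with >= 1 failure reach the single-failure weight."""
        table = exact_control_limit_table(nec, 7, 2.0)
        w_failure = st_weights(nec.c0, 2.0).w_failure
        row = table.loc[np.isclose(table["h"], w_failure)]
        assert len(row) == 1
        assert row["exact_alpha"].iloc[0] == pytest.approx(1 - (1 - nec.c0) ** 7, abs=1e-12)

    def test_zero_candidate_has_probability_one(self, nec):
        table = exact_control_limit_table(nec, 5, 2.0)
        assert table["h"].iloc[0] == 0.0
        assert table["exact_alpha"].iloc[0] == 1.0

    def test_tail_probabilities_nonincreasing(self, femur):
        table = exact_control_limit_table(femur, 8, 2.0)
        assert (np.diff(table["exact_alpha"]) <= 1e-15).all()
        assert (table["h"] >= 0).all()

    def test_largest_candidate_is_all_failure_path(self, femur):
        table = exact_control_limit_table(femur, 6, 2.0)
        w_failure = st_weights(femur.c0, 2.0).w_failure
        assert table["h"].iloc[-1] == pytest.approx(6 * w_failure, abs=1e-9)
        assert table["exact_alpha"].iloc[-1] == pytest.approx(femur.c0**6, rel=1e-9)

    def test_ra_with_constant_risk_matches_crude(self, femur):
        """A fixed-order RA enumeration at constant p = c0 is the crude table."""
        ra = RiskAdjustedIndicator(id="ra", risk_scores=np.full(6, femur.c0))
        crude = exact_control_limit_table(femur, 6, 2.0)
        adjusted = exact_control_limit_table(ra, 6, 2.0)
        np.testing.assert_allclose(adjusted["h"], crude["h"], atol=1e-10)
        np.testing.assert_allclose(adjusted["exact_alpha"], crude["exact_alpha"], atol=1e-12)

    def test_enumeration_size_guard(self, nec):
        with pytest.raises(ValueError, match="simulate"):
            exact_control_limit_table(nec, 21, 2.0)


class TestSelection:
    def test_degenerate_rare_event_small_volume(self, nec):
        """No attainable limit is near alpha=5%: the one-failure weight is
        returned with its elevated exact false-alarm probability."""
        table = exact_control_limit_table(nec, 7, 2.0)
        with pytest.warns(UserWarning, match="gap"):
            res = simulate_control_limit(nec, 7, 2.0, 0.05, n_runs=20_000, seed=5)
        assert res.degenerate
        assert res.h == pytest.approx(st_weights(nec.c0, 2.0).w_failure, abs=1e-9)
        exact = select_exact_limit(table, 0.05, n=7)
        assert exact.degenerate
        assert exact.achieved_alpha == pytest.approx(0.0842862612648484, abs=1e-12)

    def test_looser_target_makes_single_failure_weight_regular(self, nec):
        table = exact_control_limit_table(nec, 7, 2.0)
        res = select_exact_limit(table, 0.10, n=7)
        assert not res.degenerate
        assert res.h == pytest.approx(st_weights(nec.c0, 2.0).w_failure, abs=1e-9)
        assert res.achieved_alpha == pytest.approx(0.0842862612648484, abs=1e-12)

    def test_near_one_target_returns_smallest_positive_candidate(self, nec):
        table = exact_control_limit_table(nec, 7, 2.0)
        res = select_exact_limit(table, 0.9999, n=7)
        positive = table.loc[table["h"] > 0, "h"].min()
        assert res.h == pytest.approx(positive, abs=1e-12)

    def test_h_nonincreasing_in_target_alpha(self, femur):
        table = exact_control_limit_table(femur, 10, 2.0)
        hs = [select_exact_limit(table, a, n=10).h for a in (0.001, 0.01, 0.05, 0.2)]
        assert all(a >= b - LIMIT_TOL for a, b in zip(hs, hs[1:]))

    def test_achieved_at_most_target_when_not_degenerate(self, femur):
        table = exact_control_limit_table(femur, 10, 2.0)
        for a in (0.01, 0.05, 0.2):
            res = select_exact_limit(table, a, n=10)
            if not res.degenerate:
                assert res.achieved_alpha <= a + 1e-12


class TestSimulated:
    def test_seed_determinism_bit_identical(self, femur):
        a = simulate_control_limit(femur, 42, 2.0, 0.05, n_runs=5000, seed=42)
        b = simulate_control_limit(femur, 42, 2.0, 0.05, n_runs=5000, seed=42)
        assert a == b

    def test_exact_and_monte_carlo_agree(self, femur):
        """Simulated tail frequencies match enumeration within binomial 3-sigma."""
        table = exact_control_limit_table(femur, 7, 2.0)
        n_runs = 50_000
        maxima = simulate_maxima(femur, 7, 2.0, n_runs=n_runs, seed=7)
        for h, alpha in zip(table["h"], table["exact_alpha"]):
            mc = np.mean(maxima >= h - LIMIT_TOL)
            # one-count continuity correction for the far Poisson tail
            tol = 3 * np.sqrt(alpha * (1 - alpha) / n_runs) + 1.0 / n_runs
            assert abs(mc - alpha) <= tol

    def test_calibration_against_fresh_simulation(self, femur):
        """achieved_alpha is reproduced by an independent seed within 3-sigma."""
        res = simulate_control_limit(femur, 105, 2.0, 0.05, n_runs=30_000, seed=1)
        maxima = simulate_maxima(femur, 105, 2.0, n_runs=30_000, seed=999)
        fresh = np.mean(maxima >= res.h - LIMIT_TOL)
        # both estimates carry binomial error at 30k runs
        se = np.sqrt(2 * 0.05 * 0.95 / 30_000)
        assert abs(fresh - res.achieved_alpha) <= 3 * se

    def test_limit_grows_with_volume(self, femur):
        hs = [
            simulate_control_limit(femur, n, 2.0, 0.05, n_runs=20_000, seed=3).h
            for n in (7, 42, 105)
        ]
        assert hs[0] < hs[1] < hs[2]

    def test_risk_adjusted_limit_runs(self, carotid_pop):
        res = simulate_control_limit(carotid_pop, 42, 2.0, 0.05, n_runs=10_000, seed=9)
        assert res.h > 0
        assert res.achieved_alpha <= 0.05 + 1e-12
        assert res.method == "simulated" and res.n_runs == 10_000

    def test_binomial_oracle_for_single_failure_tail(self, nec):
        """MC tail at the one-failure weight matches 1-(1-c0)^n (binomial oracle)."""
        n, n_runs = 7, 60_000
        maxima = simulate_maxima(nec, n, 2.0, n_runs=n_runs, seed=17)
        w_failure = st_weights(nec.c0, 2.0).w_failure
        mc = np.mean(maxima >= w_failure - LIMIT_TOL)
        exact = float(stats.binom.sf(0, n, nec.c0))
        assert abs(mc - exact) <= 3 * np.sqrt(exact * (1 - exact) / n_runs)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2])
    def test_invalid_target_alpha(self, femur, alpha):
        with pytest.raises(ValueError):
            simulate_control_limit(femur, 10, 2.0, alpha, n_runs=100, seed=0)
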
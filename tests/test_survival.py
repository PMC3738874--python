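"""Weibull/censoring integrals, Edgeworth ingredients, logrank statistic."""

import math

import numpy as np
import pandas as pd
import pytest

from ssrzone import (
    DegenerateTableError,
    DesignError,
    LogrankTable,
    SurvivalModel,
    c_func,
    edgeworth_cdf,
    kappa3_tilde,
    logrank_z,
    sigma1_func,
    simulate_remainder,
    w0_func,
    w1_func,
)
from ssrzone.survival import _c3_integral, _logrank_components, _table_arrays
from scipy import integrate
from scipy.stats import norm


class TestIngredientFunctions:
    def test_c_at_zero_and_hand_value(self):
        m = SurvivalModel(lam=0.5, beta=2.0, mu=0.3)
        assert c_func(0.0, m) == 1.0
        assert c_func(1.0, m) == pytest.approx(math.exp(-0.8), abs=1e-15)

    def test_c_pure_exponential_when_no_censoring(self):
        m = SurvivalModel(lam=0.7, beta=1.0, mu=0.0)
        ys = np.linspace(0, 5, 11)
        assert np.allclose(c_func(ys, m), np.exp(-0.7 * ys), atol=1e-15)

    def test_c_decreasing_and_domain(self):
        m = SurvivalModel(lam=0.5, beta=0.8, mu=0.2)
        ys = np.linspace(0, 10, 50)
        assert np.all(np.diff(c_func(ys, m)) < 0)
        with pytest.raises(DesignError):
            c_func(-0.1, m)

    def test_w1_reduces_to_weibull_cdf_without_censoring(self):
        for beta in (0.6, 1.0, 2.3):
            m = SurvivalModel(lam=0.8, beta=beta, mu=0.0)
            for y in (0.2, 1.0, 3.0):
                assert w1_func(y, m) == pytest.approx(
                    1.0 - math.exp(-0.8 * y**beta), abs=1e-8
                )

    def test_w1_exponential_closed_form(self):
        """beta = 1: W1(y) = lam/(lam+mu) * (1 - exp(-(lam+mu) y))."""
        lam, mu = 0.5, 0.3
        m = SurvivalModel(lam=lam, beta=1.0, mu=mu)
        for y in (0.1, 1.0, 4.0):
            expected = lam / (lam + mu) * (1.0 - math.exp(-(lam + mu) * y))
            assert w1_func(y, m) == pytest.approx(expected, abs=1e-8)
        # y -> inf limit is the overall event probability
        assert w1_func(200.0, m) == pytest.approx(lam / (lam + mu), abs=1e-8)

    def test_event_censor_decomposition(self):
        """W1(y) + W0(y) = 1 - C(y): everything that left the risk set either
        failed or was censored."""
        for lam, beta, mu in [(0.5, 1.0, 0.3), (1.2, 0.7, 0.5), (0.3, 2.0, 0.2)]:
            m = SurvivalModel(lam=lam, beta=beta, mu=mu)
            for y in (0.3, 1.0, 2.5):
                assert w1_func(y, m) + w0_func(y, m) == pytest.approx(
                    1.0 - c_func(y, m), abs=1e-8
                )

    def test_sigma1_zero_at_origin_monotone_and_closed_form(self):
        lam = 0.4
        m = SurvivalModel(lam=lam, beta=1.0, mu=0.0)
        assert sigma1_func(0.0, m) == 0.0
        zs = [0.5, 1.0, 2.0, 3.0]
        vals = [sigma1_func(z, m) for z in zs]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        # beta=1, mu=0: int_0^z lam e^{-lam u} / e^{-2 lam u} du = e^{lam z} - 1
        for z, v in zip(zs, vals):
            assert v == pytest.approx(math.expm1(lam * z), abs=1e-8)

    def test_sigma1_tail_instability_error(self):
        m = SurvivalModel(lam=1.0, beta=1.0, mu=1.0)
        with pytest.raises(DesignError):
            sigma1_func(50.0, m)

    def test_kappa3_closed_form_ingredients(self):
        """beta=1, mu=0: the cubed-at-risk integral is (e^{2 lam z}-1)/2 and
        kappa3 follows in closed form."""
        lam, z = 0.4, 1.5
        m = SurvivalModel(lam=lam, beta=1.0, mu=0.0)
        c3 = _c3_integral(z, m)
        assert c3 == pytest.approx((math.exp(2 * lam * z) - 1.0) / 2.0, abs=1e-8)
        s1 = math.expm1(lam * z)
        assert kappa3_tilde(z, m) == pytest.approx(
            (-7.5 * s1**4 + c3) / s1, abs=1e-7
        )

    def test_kappa3_integral_against_unsubstituted_quadrature(self):
        """The substituted-scale integral matches direct quadrature of
        C^-3 dW1 on the time scale."""
        m = SurvivalModel(lam=0.6, beta=1.7, mu=0.25)
        z = 1.2

        def integrand(x):
            dW1 = m.lam * m.beta * x ** (m.beta - 1.0) * math.exp(
                -m.mu * x - m.lam * x**m.beta
            )
            return dW1 / c_func(x, m) ** 3

        direct, _ = integrate.quad(integrand, 0.0, z, epsabs=1e-12, limit=200)
        assert _c3_integral(z, m) == pytest.approx(direct, abs=1e-10)

    def test_kappa3_variant_flag_is_inert(self):
        m = SurvivalModel(lam=0.5, beta=1.3, mu=0.2)
        assert kappa3_tilde(1.0, m, "methods") == kappa3_tilde(1.0, m, "results")


class TestEdgeworth:
    def test_converges_to_normal(self):
        m = SurvivalModel(lam=0.5, beta=1.2, mu=0.2)
        for x in (-2.0, 0.3, 1.7):
            assert edgeworth_cdf(x, 10**12, 1.0, m) == pytest.approx(
                norm.cdf(x), abs=1e-6
            )

    def test_results_variant_exact_at_unit_abscissa(self):
        """(x^2 - 1) kills the correction at x = +-1 for the default form."""
        m = SurvivalModel(lam=0.5, beta=1.2, mu=0.2)
        assert edgeworth_cdf(1.0, 30, 1.0, m) == norm.cdf(1.0)
        assert edgeworth_cdf(-1.0, 30, 1.0, m) == norm.cdf(-1.0)

    def test_variant_difference_is_exactly_the_sigma_term(self):
        m = SurvivalModel(lam=0.5, beta=1.2, mu=0.2)
        n, z = 40, 1.0
        for x in (-1.5, 0.0, 0.8):
            diff = edgeworth_cdf(x, n, z, m) - edgeworth_cdf(x, n, z, m, "methods")
            expected = norm.pdf(x) * 3.0 * sigma1_func(z, m) / (6.0 * math.sqrt(n))
            assert diff == pytest.approx(expected, abs=1e-14)

    def test_monotone_in_sane_box(self):
        m = SurvivalModel(lam=0.5, beta=1.2, mu=0.2)
        xs = np.linspace(-4, 4, 161)
        for n in (20, 50, 200):
            vals = edgeworth_cdf(xs, n, 0.8, m)
            assert np.all(np.diff(vals) >= 0)

    def test_variant_validation(self):
        m = SurvivalModel(lam=0.5, beta=1.2, mu=0.2)
        with pytest.raises(DesignError):
            edgeworth_cdf(0.0, 30, 1.0, m, variant="bogus")


TOY_ROWS = pd.DataFrame(
    {
        "time": [1.0, 2.0],
        "r_A": [10, 10],
        "r_C": [10, 9],
        "o_A": [0, 1],
        "o_C": [1, 0],
    }
)


class TestLogrank:
    def test_balanced_single_time_is_zero(self):
        table = LogrankTable(
            time=np.array([1.0]),
            r_A=np.array([10]),
            r_C=np.array([10]),
            o_A=np.array([1]),
            o_C=np.array([1]),
        )
        assert logrank_z(table) == pytest.approx(0.0, abs=1e-15)

    def test_two_row_toy_table_hand_arithmetic(self):
        """Row 1: T = (10*1 - 10*0)/20, V = 1*19*10*10/(19*400);
        row 2: T = (10*0 - 9*1)/19, V = 1*18*10*9/(18*361)."""
        t_hand = 0.5 - 9.0 / 19.0
        v_hand = 100.0 / 400.0 + 90.0 / 361.0
        table = LogrankTable.from_dataframe(TOY_ROWS)
        assert logrank_z(table) == pytest.approx(t_hand / math.sqrt(v_hand), abs=1e-12)

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "events.csv"
        table = LogrankTable.from_dataframe(TOY_ROWS)
        table.to_csv(path)
        again = LogrankTable.from_csv(path)
        assert logrank_z(again) == logrank_z(table)

    def test_matches_lifelines_on_raw_data(self, rng):
        """Independent oracle: the table-sum statistic squared equals the
        lifelines logrank chi-square on the same subject-level data."""
        from lifelines.statistics import logrank_test

        for _ in range(5):
            nA, nC = 40, 35
            tA = rng.weibull(1.3, nA) * 2.0
            tC = rng.weibull(1.3, nC) * 1.5
            cA = rng.exponential(4.0, nA)
            cC = rng.exponential(4.0, nC)
            time = np.concatenate([np.minimum(tA, cA), np.minimum(tC, cC)])
            event = np.concatenate([tA <= cA, tC <= cC])
            arm = np.concatenate([np.ones(nA, bool), np.zeros(nC, bool)])
            z = logrank_z(LogrankTable.from_raw(time, event, arm))
            res = logrank_test(
                time[arm], time[~arm], event[arm], event[~arm]
            )
            assert z**2 == pytest.approx(res.test_statistic, rel=1e-9)

    def test_null_distribution_is_standard_normal(self, rng):
        """Identical exponential arms: the statistic's empirical mean and sd
        over simulated trials sit at 0 and 1 to coarse tolerance."""
        zs = []
        n_per_arm = 50
        for _ in range(10_000):
            x = rng.exponential(1.0, 2 * n_per_arm)
            c = rng.exponential(3.0, 2 * n_per_arm)
            time = np.minimum(x, c)
            event = x <= c
            arm = np.zeros(2 * n_per_arm, bool)
            arm[:n_per_arm] = True
            t, rA, rC, oA, oC = _table_arrays(time, event, arm)
            T, V = _logrank_components(rA, rC, oA, oC)
            zs.append(T / math.sqrt(V))
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.05
        assert abs(zs.std() - 1.0) < 0.05

    def test_table_validation(self):
        bad_order = TOY_ROWS.assign(time=[2.0, 1.0]).sort_index()
        with pytest.raises(DegenerateTableError):
            LogrankTable(
                time=np.array([2.0, 1.0]),
                r_A=np.array([10, 10]),
                r_C=np.array([10, 9]),
                o_A=np.array([0, 1]),
                o_C=np.array([1, 0]),
            )
        with pytest.raises(DegenerateTableError):
            LogrankTable.from_dataframe(TOY_ROWS.drop(columns=["o_C"]))
        with pytest.raises(DegenerateTableError):
            LogrankTable(
                time=np.array([1.0]),
                r_A=np.array([3]),
                r_C=np.array([3]),
                o_A=np.array([4]),
                o_C=np.array([0]),
            )
        del bad_order

    def test_degenerate_variance(self):
        # every subject at risk fails at the single time: o = r gives V = 0
        table = LogrankTable(
            time=np.array([1.0]),
            r_A=np.array([5]),
            r_C=np.array([5]),
            o_A=np.array([5]),
            o_C=np.array([5]),
        )
        with pytest.raises(DegenerateTableError):
            logrank_z(table)


class TestSimulateRemainder:
    def test_null_calibration(self):
        m = SurvivalModel(lam=0.5, beta=1.0, mu=0.2)
        rep = simulate_remainder(m, m, n_per_arm=60, n_sims=3000, seed=5, alpha=0.025)
        se = math.sqrt(0.025 * 0.975 / 3000)
        assert abs(rep.rejection_rate - 0.025) <= 3 * se

    def test_separation_limit(self):
        worse = SurvivalModel(lam=50.0, beta=1.0, mu=0.0)
        better = SurvivalModel(lam=0.01, beta=1.0, mu=0.0)
        # active arm with far lower hazard: near-certain rejection
        rep = simulate_remainder(better, worse, n_per_arm=30, n_sims=400, seed=5)
        assert rep.rejection_rate > 0.99

    def test_interim_table_shifts_the_statistic(self):
        """A strongly favourable interim table raises the estimated
        probability of final rejection."""
        m = SurvivalModel(lam=0.5, beta=1.0, mu=0.2)
        favourable = LogrankTable(
            time=np.arange(1.0, 9.0),
            r_A=np.full(8, 40) - np.arange(8) // 4,
            r_C=np.full(8, 40) - np.arange(8),
            o_A=np.array([0, 0, 1, 0, 0, 1, 0, 0]),
            o_C=np.ones(8, dtype=int),
        )
        with_interim = simulate_remainder(
            m, m, n_per_arm=30, n_sims=800, seed=9, interim_table=favourable
        )
        fresh = simulate_remainder(m, m, n_per_arm=30, n_sims=800, seed=9)
        assert with_interim.rejection_rate > fresh.rejection_rate

    def test_mc_se_scaling(self):
        m = SurvivalModel(lam=0.5, beta=1.0, mu=0.2)
        small = simulate_remainder(m, m, n_per_arm=30, n_sims=500, seed=7)
        large = simulate_remainder(m, m, n_per_arm=30, n_sims=2000, seed=7)
        # quadrupling the replicates halves the SE, within stochastic wiggle
        assert large.mc_se < small.mc_se

    def test_reproducibility_and_validation(self):
        m = SurvivalModel(lam=0.5, beta=1.0, mu=0.2)
        a = simulate_remainder(m, m, 20, 300, seed=1)
        b = simulate_remainder(m, m, 20, 300, seed=1)
        assert a == b
        with pytest.raises(DesignError):
            simulate_remainder(m, m, 0, 300, seed=1)
        with pytest.raises(DesignError):
            SurvivalModel(lam=-1.0, beta=1.0)
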
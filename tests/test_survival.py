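"""Survival estimators against hand values, brute force, and lifelines/sksurv."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gbmrec.survival import (SurvivalCurve, breslow_baseline, concordance_index,
                             fit_linear_cox, integrated_brier_score,
                             kaplan_meier, life_table, log_rank,
                             median_survival, neg_log_partial_likelihood,
                             predict_curve, rmst, rmst_diff)


def _sim_exponential(n, beta, rate, cens_scale, rng):
    X = rng.normal(size=(n, len(beta)))
    t = rng.exponential(1.0 / (rate * np.exp(X @ beta)))
    c = rng.exponential(cens_scale, n)
    return X, np.minimum(t, c), (t <= c).astype(int)


# ---------------------------------------------------------------- Cox loss
class TestCoxLoss:
    def test_hand_example(self):
        assert neg_log_partial_likelihood([0, 0], [1, 2], [1, 0]) == pytest.approx(np.log(2))

    def test_shift_invariance(self, rng):
        lp = rng.normal(size=60)
        t = rng.exponential(size=60)
        e = rng.binomial(1, 0.7, 60)
        a = neg_log_partial_likelihood(lp, t, e)
        b = neg_log_partial_likelihood(lp + 11.3, t, e)
        assert a == pytest.approx(b, abs=1e-10)

    def test_matches_direct_product(self, rng):
        for _ in range(20):
            lp = rng.normal(size=5)
            t = rng.exponential(size=5)
            e = rng.binomial(1, 0.6, 5)
            if e.sum() == 0:
                continue
            total, d = 0.0, 0
            for i in range(5):
                if e[i]:
                    d += 1
                    total += lp[i] - np.log(np.exp(lp[t >= t[i]]).sum())
            assert neg_log_partial_likelihood(lp, t, e) == pytest.approx(-total / d, abs=1e-10)

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no events"):
            neg_log_partial_likelihood([0.0, 1.0], [1, 2], [0, 0])


# ---------------------------------------------------------------- Cox fit
class TestLinearCox:
    def test_null_groups_near_zero(self, rng):
        x = rng.binomial(1, 0.5, 2000).astype(float)
        t = rng.exponential(10, 2000)
        e = rng.binomial(1, 0.8, 2000)
        f = fit_linear_cox(x.reshape(-1, 1), t, e)
        assert abs(f.coef[0]) < 0.1

    def test_parameter_recovery(self, rng):
        beta = np.array([0.5, -0.3])
        X, t, e = _sim_exponential(2000, beta, 0.08, 15, rng)
        f = fit_linear_cox(X, t, e)
        assert f.converged
        assert np.abs(f.coef - beta).max() < 0.08

    def test_unit_weights_reproduce_unweighted(self, rng):
        X, t, e = _sim_exponential(300, np.array([0.4]), 0.1, 12, rng)
        f0 = fit_linear_cox(X, t, e)
        f1 = fit_linear_cox(X, t, e, weights=np.ones(len(t)))
        assert np.abs(f0.coef - f1.coef).max() < 1e-8

    def test_agrees_with_lifelines(self, rng):
        import lifelines
        X, t, e = _sim_exponential(500, np.array([0.5, -0.2]), 0.1, 15, rng)
        f = fit_linear_cox(X, t, e)
        df = pd.DataFrame(X, columns=["a", "b"]).assign(T=t, E=e)
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert np.abs(f.coef - cph.params_.values).max() < 5e-6
        assert np.abs(f.se - cph.standard_errors_.values).max() < 5e-6

    def test_weighted_robust_agrees_with_lifelines(self, rng):
        import lifelines
        X, t, e = _sim_exponential(400, np.array([0.3]), 0.1, 15, rng)
        w = rng.uniform(0.5, 2.0, 400)
        f = fit_linear_cox(X, t, e, weights=w)
        df = pd.DataFrame(X, columns=["a"]).assign(T=t, E=e, w=w)
        cph = lifelines.CoxPHFitter().fit(df, "T", "E", weights_col="w", robust=True)
        assert np.abs(f.coef - cph.params_.values).max() < 1e-6
        assert np.abs(f.se - cph.standard_errors_.values).max() < 1e-6

    def test_constant_column_rejected(self, rng):
        X = np.ones((50, 1))
        with pytest.raises(ValueError, match="constant"):
            fit_linear_cox(X, rng.exponential(size=50), np.ones(50, int))


# ---------------------------------------------------------------- Breslow
class TestBreslow:
    def test_hand_nelson_aalen(self):
        bh = breslow_baseline([0, 0, 0], [1, 2, 3], [1, 1, 0])
        assert np.allclose(bh.times, [1, 2])
        assert np.allclose(bh.cumhaz, [1 / 3, 1 / 3 + 1 / 2])

    def test_no_step_without_event(self):
        bh = breslow_baseline([0, 0, 0], [1, 2, 3], [1, 0, 1])
        assert 2.0 not in bh.times

    def test_recovers_exponential_cumhaz(self, rng):
        beta = np.array([0.5])
        X, t, e = _sim_exponential(2000, beta, 0.08, 25, rng)
        bh = breslow_baseline(X @ beta, t, e)
        lo, hi = np.percentile(t, [25, 75])
        sel = (bh.times >= lo) & (bh.times <= hi)
        rel = np.abs(bh.cumhaz[sel] - 0.08 * bh.times[sel]) / (0.08 * bh.times[sel])
        assert rel.max() < 0.10

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            breslow_baseline([], [], [])


# ---------------------------------------------------------------- curves
class TestPredictCurve:
    def setup_method(self):
        self.bh = breslow_baseline([0.0, 0.0, 0.0], [5, 10, 20], [1, 1, 1])
        self.grid = np.arange(0, 25.0)

    def test_zero_lp_is_exp_minus_h0(self):
        c = predict_curve(0.0, self.bh, self.grid)
        assert np.allclose(c.surv, np.exp(-self.bh.evaluate(self.grid)))

    def test_very_negative_lp_tends_to_one(self):
        c = predict_curve(-40.0, self.bh, self.grid)
        assert np.all(c.surv > 1 - 1e-12)

    def test_monotone_in_lp(self):
        c1 = predict_curve(0.5, self.bh, self.grid)
        c2 = predict_curve(-0.5, self.bh, self.grid)
        assert np.all(c1.surv <= c2.surv + 1e-15)

    def test_type_invariants_enforced(self):
        with pytest.raises(ValueError):
            SurvivalCurve(np.array([0.0, 1.0]), np.array([0.9, 0.8]))
        with pytest.raises(ValueError):
            SurvivalCurve(np.array([0.0, 1.0]), np.array([1.0, 1.1]))


# ---------------------------------------------------------------- KM
class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = kaplan_meier([1, 2, 3], [1, 0, 1])
        assert km.evaluate(1) == pytest.approx(2 / 3)
        assert km.evaluate(3) == pytest.approx(0.0)

    def test_all_censored_is_one(self):
        km = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert np.all(km.surv == 1.0)

    def test_no_censoring_reduces_to_ecdf(self, rng):
        t = rng.exponential(10, 200)
        km = kaplan_meier(t, np.ones(200, int))
        for q in (5.0, 10.0, 20.0):
            assert km.evaluate(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_agrees_with_lifelines(self, rng):
        import lifelines
        t = rng.exponential(10, 300)
        e = rng.binomial(1, 0.7, 300)
        km = kaplan_meier(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_at_times(km.times).to_numpy()
        assert np.abs(km.surv - ref).max() < 1e-10


# ---------------------------------------------------------------- log-rank
class TestLogRank:
    def test_identical_groups(self):
        chi2, p = log_rank([1, 2, 3], [1, 0, 1], [1, 2, 3], [1, 0, 1])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_symmetry(self, rng):
        tA, eA = rng.exponential(8, 40), rng.binomial(1, 0.8, 40)
        tB, eB = rng.exponential(12, 50), rng.binomial(1, 0.8, 50)
        c1, _ = log_rank(tA, eA, tB, eB)
        c2, _ = log_rank(tB, eB, tA, eA)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_hand_table_enumeration(self):
        tA, eA = np.array([1.0, 3.0, 5.0]), np.array([1, 1, 0])
        tB, eB = np.array([2.0, 4.0, 6.0]), np.array([1, 0, 1])
        # direct 2x2 hypergeometric accumulation over event times
        O_E, V = 0.0, 0.0
        for t in sorted(np.r_[tA[eA == 1], tB[eB == 1]]):
            nA, nB = (tA >= t).sum(), (tB >= t).sum()
            dA = ((tA == t) & (eA == 1)).sum()
            dB = ((tB == t) & (eB == 1)).sum()
            n, d = nA + nB, dA + dB
            O_E += dA - d * nA / n
            if n > 1:
                V += d * (nA / n) * (nB / n) * (n - d) / (n - 1)
        chi2, _ = log_rank(tA, eA, tB, eB)
        assert chi2 == pytest.approx(O_E**2 / V, abs=1e-10)

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            log_rank([1, 2], [0, 0], [3], [0])


# ---------------------------------------------------------------- RMST
class TestRmst:
    def test_rectangle(self):
        c = SurvivalCurve(np.array([0.0, 5.0]), np.array([1.0, 0.0]))
        assert rmst(c, 10) == pytest.approx(5.0)
        c1 = SurvivalCurve(np.array([0.0, 60.0]), np.array([1.0, 1.0]))
        assert rmst(c1, 60) == pytest.approx(60.0)

    def test_matches_dense_riemann(self, rng):
        for _ in range(5):
            knots = np.sort(rng.uniform(0, 45, 8))
            times = np.r_[0.0, knots, 50.0]
            surv = np.r_[1.0, np.sort(rng.uniform(0, 1, 9))[::-1]]
            c = SurvivalCurve(times, surv)
            tau = 45.0
            grid = np.linspace(0, tau, 1_000_001)
            brute = np.mean(c.evaluate(grid[:-1])) * tau
            assert rmst(c, tau) == pytest.approx(brute, abs=1e-3)

    def test_beyond_grid_raises(self):
        c = SurvivalCurve(np.array([0.0, 5.0]), np.array([1.0, 0.5]))
        with pytest.raises(ValueError, match="beyond"):
            rmst(c, 10.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_additive_over_abutting_intervals(self, seed):
        r = np.random.default_rng(seed)
        times = np.r_[0.0, np.sort(r.uniform(0, 27, 6)), 30.0]
        surv = np.r_[1.0, np.sort(r.uniform(0, 1, 7))[::-1]]
        c = SurvivalCurve(times, surv)
        mid, tau = 12.0, 28.0
        part = rmst(c, mid) + (rmst(c, tau) - rmst(c, mid))
        assert part == pytest.approx(rmst(c, tau), abs=1e-12)


class TestRmstDiff:
    def test_identical_curves(self, rng):
        t = rng.exponential(10, 200)
        e = rng.binomial(1, 0.8, 200)
        km = kaplan_meier(t, e)
        est, (lo, hi) = rmst_diff(km, km, 10.0)
        assert est == pytest.approx(0.0, abs=1e-12)
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_antisymmetry(self, rng):
        kmA = kaplan_meier(rng.exponential(8, 150), rng.binomial(1, 0.8, 150))
        kmB = kaplan_meier(rng.exponential(14, 150), rng.binomial(1, 0.8, 150))
        tau = min(kmA.times[-1], kmB.times[-1])
        e1, ci1 = rmst_diff(kmA, kmB, tau)
        e2, ci2 = rmst_diff(kmB, kmA, tau)
        assert e1 == pytest.approx(-e2, abs=1e-12)
        assert ci1[0] == pytest.approx(-ci2[1], abs=1e-12)

    def test_ci_coverage_of_known_gap(self):
        """Exponential arms with a closed-form RMST gap: >=90% CI coverage."""
        tau = 36.0
        lam_a, lam_b = 1 / 24.0, 1 / 10.0
        truth = (1 - np.exp(-lam_a * tau)) / lam_a - (1 - np.exp(-lam_b * tau)) / lam_b
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            r = np.random.default_rng(1000 + s)
            tA = r.exponential(1 / lam_a, 150)
            tB = r.exponential(1 / lam_b, 150)
            cA = np.minimum(tA, 60.0)
            cB = np.minimum(tB, 60.0)
            kmA = kaplan_meier(cA, (tA <= 60).astype(int))
            kmB = kaplan_meier(cB, (tB <= 60).astype(int))
            _, (lo, hi) = rmst_diff(kmA, kmB, tau)
            hits += lo <= truth <= hi
        assert hits / n_rep >= 0.90


# ---------------------------------------------------------------- median
@pytest.mark.parametrize("times,surv,expected,reached", [
    (np.array([0.0, 16.0, 30.0]), np.array([1.0, 0.45, 0.2]), 16.0, True),
    (np.array([0.0, 10.0]), np.array([1.0, 1.0]), np.inf, False),
    (np.array([0.0, 12.0, 20.0]), np.array([1.0, 0.5, 0.1]), 12.0, True),
])
def test_median_survival_conventions(times, surv, expected, reached):
    value, ok = median_survival(SurvivalCurve(times, surv))
    assert ok is reached
    if reached:
        assert value == expected


# ---------------------------------------------------------------- C-index
class TestConcordance:
    def test_perfect_anti_ordering(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        lp = np.array([4.0, 3.0, 2.0, 1.0])
        assert concordance_index(lp, t, np.ones(4, int)) == pytest.approx(1.0)

    def test_random_scores_near_half(self, rng):
        t = rng.exponential(10, 2000)
        e = rng.binomial(1, 0.8, 2000)
        lp = rng.normal(size=2000)
        assert concordance_index(lp, t, e) == pytest.approx(0.5, abs=0.03)

    def test_matches_brute_force_pairs(self):
        for s in range(100):
            r = np.random.default_rng(s)
            n = int(r.integers(4, 11))
            t = np.round(r.exponential(10, n), 1)  # induce occasional ties
            e = r.binomial(1, 0.6, n)
            if e.sum() == 0:
                continue
            lp = np.round(r.normal(size=n), 1)
            conc = comp = 0.0
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    comparable = (t[i] < t[j] and e[i] == 1) or \
                        (t[i] == t[j] and e[i] == 1 and e[j] == 0)
                    if comparable:
                        comp += 1
                        conc += 1.0 if lp[i] > lp[j] else (0.5 if lp[i] == lp[j] else 0.0)
            if comp == 0:
                continue
            assert concordance_index(lp, t, e) == pytest.approx(conc / comp, abs=1e-12)

    def test_bootstrap_ci_contains_estimate(self, rng):
        t = rng.exponential(10, 150)
        e = rng.binomial(1, 0.8, 150)
        lp = -t + rng.normal(0, 3, 150)
        c, (lo, hi) = concordance_index(lp, t, e, n_boot=100, seed=4)
        assert lo <= c <= hi


# ---------------------------------------------------------------- IBS
class TestIntegratedBrier:
    def test_constant_half_prediction(self, rng):
        t = rng.exponential(10, 150)
        e = np.ones(150, int)
        grid = np.linspace(0, 40, 401)
        ibs = integrated_brier_score(np.full((150, 401), 0.5), grid, t, e, 25.0)
        assert ibs == pytest.approx(0.25, abs=1e-10)

    def test_oracle_predictions_near_deterministic(self, rng):
        # each subject's own death time is predicted exactly (indicator curve)
        t = np.round(rng.uniform(5, 15, 200), 3)
        e = np.ones(200, int)
        grid = np.r_[0.0, np.unique(t), 20.0]
        S = (grid[None, :] < t[:, None]).astype(float)
        ibs = integrated_brier_score(S, grid, t, e, 15.0)
        assert ibs < 0.02

    def test_matches_double_sum(self, rng):
        n = 20
        t = rng.exponential(10, n)
        e = rng.binomial(1, 0.7, n)
        if e.sum() == 0:
            e[0] = 1
        grid = np.linspace(0, 30, 61)
        S = np.exp(-np.outer(rng.uniform(0.05, 0.2, n), grid))
        S[:, 0] = 1
        tau = 20.0
        ibs = integrated_brier_score(S, grid, t, e, tau)
        # independent direct evaluation
        ckm = kaplan_meier(t, 1 - e)
        ev = np.unique(t[e == 1])
        ev = np.append(ev[ev <= tau], tau)
        bs = []
        for tt in ev:
            acc = 0.0
            for i in range(n):
                Si = S[i, np.searchsorted(grid, tt, side="right") - 1]
                if t[i] <= tt and e[i] == 1:
                    acc += Si**2 / ckm.evaluate(t[i] - 1e-9)
                elif t[i] > tt:
                    acc += (1 - Si)**2 / ckm.evaluate(tt)
            bs.append(acc / n)
        brute = np.trapezoid(bs, ev) / (ev[-1] - ev[0])
        assert ibs == pytest.approx(brute, abs=1e-10)

    def test_close_to_scikit_survival(self, rng):
        from sksurv.metrics import integrated_brier_score as sk_ibs
        n = 300
        t = rng.exponential(10, n)
        e = rng.binomial(1, 0.7, n)
        grid = np.linspace(0, 30, 301)
        lam = rng.uniform(0.05, 0.2, n)
        S = np.exp(-np.outer(lam, grid))
        y = np.array([(bool(ev), tt) for ev, tt in zip(e, t)],
                     dtype=[("event", bool), ("time", float)])
        inner = np.linspace(1.0, 15.0, 60)
        Sk = np.exp(-np.outer(lam, inner))
        ref = sk_ibs(y, y, Sk, inner)
        mine = integrated_brier_score(S, grid, t, e, 15.0)
        # integration grids differ (event times vs uniform); close, not equal
        assert mine == pytest.approx(ref, abs=0.03)


# ---------------------------------------------------------------- life table
class TestLifeTable:
    def test_no_deaths(self):
        lt = life_table(np.array([1.5, 2.5, 3.5]), np.zeros(3, int), 1.0)
        assert (lt.table["cum_survival"] == 1.0).all()

    def test_hand_actuarial_single_interval(self):
        times = np.array([0.5] * 2 + [0.6] * 2 + [2.0] * 6)
        events = np.array([1, 1, 0, 0] + [0] * 6)
        lt = life_table(times, events, 1.0)
        assert lt.table["q"].iloc[0] == pytest.approx(2 / 9)

    def test_sat_close_to_km(self, rng):
        t = np.minimum(rng.exponential(30, 2000), 60.0)
        e = (t < 60.0).astype(int)
        lt = life_table(t, e, 1.0, horizon=60)
        km = kaplan_meier(t, e)
        sat, _ = lt.survival_at(60.0)
        assert sat == pytest.approx(km.evaluate(59.999), abs=0.02)
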
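"""RFS computation, Kaplan-Meier, log-rank and Cox with forward selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from pepscreen.survival import (
    SurvivalRecord,
    compute_rfs,
    cox_fit,
    forward_selection,
    km_estimate,
    logrank_test,
)


def brute_force_cox_beta(frame, tie_method="breslow", lo=-10.0, hi=10.0):
    """Independent maximizer of the hand-written one-covariate partial
    likelihood (Breslow ties), by dense grid + golden-section refinement."""
    t = frame["time"].to_numpy(float)
    d = frame["event"].to_numpy(int)
    x = frame["x"].to_numpy(float)

    def negll(beta):
        ll = 0.0
        for ti in np.unique(t[d == 1]):
            tied = (t == ti) & (d == 1)
            risk = t >= ti
            ll += beta * x[tied].sum() - tied.sum() * np.log(
                np.exp(beta * x[risk]).sum()
            )
        return -ll

    grid = np.linspace(lo, hi, 2001)
    beta0 = grid[np.argmin([negll(b) for b in grid])]
    res = optimize.minimize_scalar(
        negll, bounds=(beta0 - 0.02, beta0 + 0.02), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


class TestComputeRfs:
    def test_recurrence_observed(self):
        rec = compute_rfs("2012-01-01", "2012-03-01", subject_id="p1")
        assert (rec.time, rec.event) == (60.0, 1)

    def test_censored_at_followup(self):
        rec = compute_rfs("2012-01-01", None, "2013-01-01")
        assert (rec.time, rec.event) == (366.0, 0)

    def test_recurrence_before_surgery_rejected(self):
        with pytest.raises(ValueError, match="precedes"):
            compute_rfs("2012-01-01", "2011-12-31")

    def test_zero_interval_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            compute_rfs("2012-01-01", "2012-01-01")


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        frame = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": 0})
        curve = km_estimate(frame)
        assert np.allclose(curve.survival, 1.0)

    def test_hand_product_limit(self):
        # event at 1, censored at 2, event at 3: S(1)=2/3, S(3)=0
        frame = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 0, 1]})
        curve = km_estimate(frame)
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(3.0) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(1.0, 40)
        frame = pd.DataFrame({"time": t, "event": 1})
        curve = km_estimate(frame)
        for ti in curve.times:
            assert curve.survival_at(ti) == pytest.approx((t > ti).mean(), abs=1e-12)

    def test_duplication_invariance(self, rng):
        t = rng.exponential(1.0, 20)
        e = rng.integers(0, 2, 20)
        one = km_estimate(pd.DataFrame({"time": t, "event": e}))
        two = km_estimate(pd.DataFrame({"time": np.r_[t, t], "event": np.r_[e, e]}))
        assert np.allclose(one.times, two.times)
        assert np.allclose(one.survival, two.survival)
        assert np.array_equal(2 * one.n_at_risk, two.n_at_risk)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="zero records"):
            km_estimate(pd.DataFrame({"time": [], "event": []}))


class TestLogrank:
    def test_identical_groups_are_null(self):
        g = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 0, 1, 1]})
        stat, p = logrank_test(g, g.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_swap_symmetry(self, rng):
        a = pd.DataFrame({"time": rng.exponential(1, 20), "event": 1})
        b = pd.DataFrame({"time": rng.exponential(2, 20), "event": 1})
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0])

    def test_clear_separation_detected(self, rng):
        early = pd.DataFrame({"time": rng.uniform(1, 30, 20), "event": 1})
        late = pd.DataFrame({"time": rng.uniform(200, 400, 20), "event": 1})
        _, p = logrank_test(early, late)
        assert p < 0.05

    def test_no_events_rejected(self):
        g = pd.DataFrame({"time": [1.0, 2.0], "event": 0})
        with pytest.raises(ValueError, match="no events"):
            logrank_test(g, g.copy())


class TestCoxFit:
    def test_exchangeable_groups_have_null_coefficient(self):
        # mirror-image data: x=0 and x=1 arms share the identical outcome list
        times = [2.0, 4.0, 6.0, 8.0]
        frame = pd.DataFrame(
            {"time": times * 2, "event": 1, "x": [0.0] * 4 + [1.0] * 4}
        )
        fit = cox_fit(frame, ["x"])
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.hazard_ratio[0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_grid_search_oracle_small_n(self, rng):
        """Newton solution equals the brute-force partial-likelihood
        maximizer on random small instances (ties included)."""
        for _ in range(25):
            n = int(rng.integers(4, 9))
            frame = pd.DataFrame(
                {
                    "time": rng.integers(1, 5, n).astype(float),  # forces ties
                    "event": rng.integers(0, 2, n),
                    "x": rng.integers(0, 2, n).astype(float),
                }
            )
            if frame["event"].sum() == 0 or frame["x"].nunique() < 2:
                continue
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = cox_fit(frame, ["x"], tie_method="breslow")
            if not fit.converged:  # monotone-likelihood instances are unbounded
                continue
            assert fit.coef[0] == pytest.approx(
                brute_force_cox_beta(frame), abs=1e-4
            )

    def test_matches_lifelines_efron(self, rng):
        from lifelines import CoxPHFitter

        n = 120
        frame = pd.DataFrame(
            {
                "time": np.ceil(rng.exponential(50, n)),
                "event": rng.integers(0, 2, n),
                "x": rng.normal(size=n),
                "z": rng.integers(0, 2, n).astype(float),
            }
        )
        fit = cox_fit(frame, ["x", "z"], tie_method="efron")
        cph = CoxPHFitter()
        cph.fit(frame[["time", "event", "x", "z"]], "time", "event")
        assert fit.coef == pytest.approx(cph.params_.to_numpy(), abs=1e-5)
        assert fit.se == pytest.approx(cph.standard_errors_.to_numpy(), abs=1e-5)

    def test_hr_equals_exp_coef_and_ci_brackets(self, rng):
        frame = pd.DataFrame(
            {
                "time": rng.exponential(1, 60),
                "event": 1,
                "x": rng.integers(0, 2, 60).astype(float),
            }
        )
        fit = cox_fit(frame, ["x"])
        assert fit.hazard_ratio[0] == pytest.approx(np.exp(fit.coef[0]))
        assert fit.ci_lower[0] < fit.hazard_ratio[0] < fit.ci_upper[0]

    def test_consistency_with_sample_size(self, rng):
        """Bias of the binary-covariate estimate shrinks with n."""
        true = np.log(2.0)
        errs = {}
        for n in (100, 500):
            est = []
            for _ in range(10):
                x = rng.integers(0, 2, n).astype(float)
                t = rng.exponential(1 / np.exp(true * x))
                est.append(
                    cox_fit(pd.DataFrame({"time": t, "event": 1, "x": x}), ["x"]).coef[0]
                )
            errs[n] = abs(np.mean(est) - true)
        assert errs[500] < max(errs[100], 0.08)

    def test_constant_covariate_rejected(self):
        frame = pd.DataFrame({"time": [1.0, 2.0], "event": 1, "x": 1.0})
        with pytest.raises(ValueError, match="'x' is constant"):
            cox_fit(frame, ["x"])

    def test_no_events_rejected(self):
        frame = pd.DataFrame({"time": [1.0, 2.0], "event": 0, "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="no events"):
            cox_fit(frame, ["x"])

    def test_perfect_separation_flagged(self):
        # x=1 subjects all fail before every x=0 subject: monotone likelihood
        frame = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
                "event": [1, 1, 1, 1, 1, 1],
                "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
            }
        )
        with pytest.warns(UserWarning, match="monotone"):
            fit = cox_fit(frame, ["x"])
        assert not fit.converged

    def test_records_interface(self):
        records = [
            SurvivalRecord("a", 5.0, 1, {"x": 1.0}),
            SurvivalRecord("b", 8.0, 1, {"x": 0.0}),
            SurvivalRecord("c", 9.0, 0, {"x": 1.0}),
            SurvivalRecord("d", 12.0, 1, {"x": 0.0}),
        ]
        fit = cox_fit(records, ["x"])
        assert fit.n == 4 and fit.n_events == 3


class TestForwardSelection:
    @staticmethod
    def _simulated(rng, n=150, true_hr=3.0):
        x = rng.integers(0, 2, n).astype(float)
        noise1 = rng.normal(size=n)
        noise2 = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / np.exp(np.log(true_hr) * x))
        return pd.DataFrame(
            {"time": t, "event": 1, "signal": x, "noise1": noise1, "noise2": noise2}
        )

    def test_prognostic_covariate_enters_first(self, rng):
        frame = self._simulated(rng)
        selected, fit = forward_selection(frame, ["noise1", "signal", "noise2"])
        assert selected[0] == "signal"
        assert fit is not None and "signal" in fit.covariates

    def test_all_noise_yields_mostly_empty_selection(self, rng):
        hits = 0
        for _ in range(12):
            frame = self._simulated(rng, true_hr=1.0)
            selected, _ = forward_selection(frame, ["noise1", "noise2"])
            hits += bool(selected)
        # each noise covariate enters ~5% of the time under the null
        assert hits <= 4

    def test_duplicated_covariate_enters_once(self, rng):
        frame = self._simulated(rng)
        frame["signal_copy"] = frame["signal"]
        selected, _ = forward_selection(frame, ["signal", "signal_copy"])
        assert selected == ["signal"]
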
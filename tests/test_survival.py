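"""Survival estimation, risk models, selection, and internal validation.

Independent oracles used here (never the production code path):
brute-force pair enumeration for the concordance index, per-event-time 2x2
accumulation for the log-rank statistic, and the Efron null partial
likelihood written out directly.
"""

import numpy as np
import pandas as pd
import pytest

import glioshape as g
from glioshape.errors import SurvivalError
from glioshape.simulate import CohortSpec, make_cohort, make_survival_fixture
from glioshape.survival import _null_loglik


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def concordance_bruteforce(times, events, scores):
    """O(n^2) pair enumeration; higher score = higher risk = earlier event."""
    conc = disc = ties = 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # pair usable if i's event time is earlier and i had the event
            if events[i] == 1 and (times[i] < times[j]
                                   or (times[i] == times[j] and events[j] == 0)):
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] < scores[j]:
                    disc += 1
                else:
                    ties += 1
    total = conc + disc + ties
    return (conc + 0.5 * ties) / total if total else np.nan


def logrank_bruteforce(t1, e1, t2, e2):
    """Mantel-Cox statistic by direct per-event-time accumulation."""
    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    grp = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    obs = exp = var = 0.0
    for tt in np.unique(all_t[all_e == 1]):
        at_risk = all_t >= tt
        n = at_risk.sum()
        n1 = (at_risk & (grp == 0)).sum()
        d = ((all_t == tt) & (all_e == 1)).sum()
        d1 = ((all_t == tt) & (all_e == 1) & (grp == 0)).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (obs - exp) ** 2 / var


# --------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# --------------------------------------------------------------------------

class TestKaplanMeier:
    def test_all_censored_flat_curve(self):
        df = pd.DataFrame({"pfs_months": [1.0, 2, 3], "event": [0, 0, 0]})
        km = g.km_estimate(df)
        assert len(km.times) == 0
        assert km.median is None

    def test_four_events_hand_computation(self):
        km = g.km_estimate(make_survival_fixture("km4"))
        assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
        assert km.median == 2.0

    def test_mixed_censoring_product_limit_table(self):
        km = g.km_estimate(make_survival_fixture("km6cens"))
        assert np.allclose(km.survival, [5 / 6, 5 / 8, 5 / 12, 0.0])
        assert np.allclose(km.times, [1.0, 3.0, 4.0, 6.0])

    def test_no_censoring_matches_empirical_cdf(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=200).round(1)
        df = pd.DataFrame({"pfs_months": t, "event": 1})
        km = g.km_estimate(df)
        for tt, s in zip(km.times, km.survival):
            assert s == pytest.approx(np.mean(t > tt), abs=1e-12)

    def test_greenwood_variance_positive_before_last_event(self):
        km = g.km_estimate(make_survival_fixture("km6cens"))
        assert (km.variance[:-1] > 0).all()

    def test_negative_time_errors(self):
        with pytest.raises(SurvivalError):
            g.km_estimate(pd.DataFrame({"pfs_months": [-1.0], "event": [1]}))


class TestLogrank:
    def test_identical_groups_zero(self):
        lr = make_survival_fixture("lr-balanced")
        for w in ("mantel-cox", "breslow-wilcoxon"):
            stat, p = g.logrank_test([lr[lr.g == "a"], lr[lr.g == "b"]], w)
            assert stat == pytest.approx(0.0, abs=1e-12)
            assert p == pytest.approx(1.0)

    def test_matches_accumulation_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            t1 = rng.exponential(10, 30).round(1) + 0.1
            t2 = rng.exponential(5, 25).round(1) + 0.1
            e1 = rng.integers(0, 2, 30)
            e2 = rng.integers(0, 2, 25)
            if e1.sum() + e2.sum() == 0:
                continue
            d1 = pd.DataFrame({"pfs_months": t1, "event": e1})
            d2 = pd.DataFrame({"pfs_months": t2, "event": e2})
            stat, _ = g.logrank_test([d1, d2])
            assert stat == pytest.approx(
                logrank_bruteforce(t1, e1, t2, e2), abs=1e-10)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        d1 = pd.DataFrame({"pfs_months": rng.exponential(10, 40),
                           "event": rng.integers(0, 2, 40)})
        d2 = pd.DataFrame({"pfs_months": rng.exponential(6, 40),
                           "event": rng.integers(0, 2, 40)})
        s12, _ = g.logrank_test([d1, d2])
        s21, _ = g.logrank_test([d2, d1])
        assert s12 == pytest.approx(s21, abs=1e-12)

    def test_detects_hazard_ratio_three(self):
        # scaled-down power check: 20 seeded replicates, n=200/arm, HR=3
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d1 = pd.DataFrame({"pfs_months": rng.exponential(30, 200),
                               "event": 1})
            d2 = pd.DataFrame({"pfs_months": rng.exponential(10, 200),
                               "event": 1})
            _, p = g.logrank_test([d1, d2])
            hits += p < 0.01
        assert hits >= 19

    def test_empty_group_errors(self):
        lr = make_survival_fixture("lr-balanced")
        with pytest.raises(SurvivalError):
            g.logrank_test([lr, lr.iloc[:0]])


# --------------------------------------------------------------------------
# Cox fitting and stepwise selection
# --------------------------------------------------------------------------

class TestCoxFit:
    def test_two_group_parameter_recovery(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.02 * np.exp(0.7 * x)))
        c = rng.uniform(0, 120, n)
        df = pd.DataFrame({"x": x, "pfs_months": np.minimum(t, c),
                           "event": (t <= c).astype(int)})
        fit = g.cox_fit(df, ["x"])
        assert fit.params["x"] == pytest.approx(0.7, abs=0.15)

    def test_null_covariate_calibration(self):
        # |estimate| < 2 SE in >= 16 of 20 seeded replicates
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 1000
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(50, n)
            c = rng.uniform(0, 120, n)
            df = pd.DataFrame({"x": x, "pfs_months": np.minimum(t, c),
                               "event": (t <= c).astype(int)})
            fit = g.cox_fit(df, ["x"])
            ok += abs(fit.params["x"]) < 2 * fit.se["x"]
        assert ok >= 16

    def test_zero_covariate_model_null_likelihood(self):
        df = make_survival_fixture("km6cens")
        fit = g.cox_fit(df, [])
        # Efron null partial likelihood written out directly:
        # event times 1,3,4,6 with n at risk 6,4,3,1, single events
        expected = -(np.log(6) + np.log(4) + np.log(3) + np.log(1))
        assert fit.log_likelihood == pytest.approx(expected, abs=1e-12)
        assert _null_loglik(df) == pytest.approx(expected, abs=1e-12)

    def test_no_events_errors(self):
        df = pd.DataFrame({"pfs_months": [1.0, 2.0], "event": [0, 0],
                           "x": [0.0, 1.0]})
        with pytest.raises(SurvivalError):
            g.cox_fit(df, ["x"])


class TestStepwiseWald:
    @staticmethod
    def _simulated(seed, n=500, beta=1.0, k_noise=4):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, (n, 1 + k_noise)).astype(float)
        lam = 0.02 * np.exp(beta * X[:, 0])
        t = rng.exponential(1 / lam)
        c = rng.uniform(0, 120, n)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(1 + k_noise)])
        df["pfs_months"] = np.minimum(t, c)
        df["event"] = (t <= c).astype(int)
        return df

    def test_single_strong_candidate_selected(self):
        df = self._simulated(0, beta=1.0, k_noise=0)
        model, path = g.stepwise_wald(df, ["x0"])
        assert set(model.coefficients) == {"x0"}
        assert path[0]["step"] == "enter"

    def test_true_covariate_always_included(self):
        # the prognostic covariate enters in every replicate; noise may
        # occasionally join it (expected ~18.5% of runs at p_enter=0.05)
        for seed in range(5):
            df = self._simulated(seed, n=1000)
            model, _ = g.stepwise_wald(df, [f"x{i}" for i in range(5)])
            assert "x0" in model.coefficients

    def test_all_noise_rarely_selects_two(self):
        sizes = []
        for seed in range(10):
            df = self._simulated(200 + seed, beta=0.0)
            model, _ = g.stepwise_wald(df, [f"x{i}" for i in range(5)])
            sizes.append(len(model.coefficients))
        assert sum(s <= 1 for s in sizes) >= 9

    def test_null_model_flagged_when_nothing_enters(self):
        df = self._simulated(7, beta=0.0, k_noise=0)
        model, path = g.stepwise_wald(df, ["x0"], p_enter=1e-9)
        assert model.coefficients == {}
        assert path[-1]["step"] == "null-model"

    def test_bad_thresholds(self):
        df = self._simulated(0, k_noise=0)
        with pytest.raises(SurvivalError):
            g.stepwise_wald(df, ["x0"], p_enter=0.2, p_remove=0.1)


# --------------------------------------------------------------------------
# risk scores and points
# --------------------------------------------------------------------------

class TestRiskScore:
    def test_all_indicators_zero(self):
        df = pd.DataFrame({"ki67_index": [0.05], "epilepsy": ["no"],
                           "tp53": ["wild"], "chr1p19q": ["intact"],
                           "volume": [10.0]})
        assert g.risk_score(g.RISK_L, df).iloc[0] == pytest.approx(0.0)

    def test_risk_l_all_indicators_one(self):
        df = pd.DataFrame({"ki67_index": [0.2], "epilepsy": ["yes"],
                           "tp53": ["mutant"], "chr1p19q": ["co-deleted"],
                           "volume": [30.0]})
        assert g.risk_score(g.RISK_L, df).iloc[0] == pytest.approx(0.20)

    def test_risk_c_all_indicators_one(self):
        df = pd.DataFrame({"ki67_index": [0.2, 0.2], "idh1": ["mutant"] * 2,
                           "age": [50.0, 50.0], "volume": [30.0, 30.0],
                           "tortuosity": [1.5, 1.4],
                           "chr1p19q": ["co-deleted"] * 2})
        # tortuosity coded against the in-cohort median: only the larger
        # value is "high", so the first patient carries every indicator
        assert g.risk_score(g.RISK_C, df).iloc[0] == pytest.approx(1.37)

    def test_missing_covariate_errors(self):
        df = pd.DataFrame({"ki67_index": [0.2]})
        with pytest.raises(SurvivalError) as err:
            g.risk_score(g.RISK_L, df)
        assert err.value.code == "missing-covariate"

    def test_score_is_additive_in_indicators(self, riskl_cohort):
        coded = g.code_covariates(g.RISK_L, riskl_cohort.head(50))
        beta = pd.Series(g.RISK_L.coefficients)
        scores = coded @ beta
        for j in beta.index:
            zeroed = coded.copy()
            zeroed[j] = 0.0
            diff = scores - (zeroed @ beta)
            assert np.allclose(diff, coded[j] * beta[j])


class TestPointsScale:
    def test_risk_l_nomogram(self):
        pts = g.to_points(g.RISK_L)
        assert pts["chr1p19q_codel"] == -100     # largest |beta| = 0.90
        assert pts["ki67_high"] == 87            # round(100*0.78/0.90)

    def test_single_covariate_is_full_scale(self):
        model = g.RiskModel("m", {"x": -0.3},
                            {"x": g.CodingRule("x", "identity")})
        assert g.to_points(model) == {"x": -100}

    def test_rescaling_invariance(self):
        doubled = g.RiskModel(
            "m2", {k: 2 * v for k, v in g.RISK_L.coefficients.items()},
            g.RISK_L.coding)
        assert g.to_points(doubled) == g.to_points(g.RISK_L)

    def test_published_thresholds_carried_as_metadata(self):
        assert g.RISK_L.points_threshold == 23
        assert g.RISK_C.points_threshold == 41


class TestThresholdSearch:
    def test_perfect_separation(self):
        df = pd.DataFrame({"pfs_months": [30.0] * 10 + [5.0] * 10,
                           "event": [1] * 20})
        scores = np.array([0.0] * 10 + [1.0] * 10)
        thr, stat, p = g.threshold_search(scores, df, min_group_fraction=0.1)
        assert thr == 0.0
        assert p < 0.001

    def test_matches_bruteforce_scan(self, riskl_cohort):
        df = riskl_cohort.head(120).reset_index(drop=True)
        scores = g.risk_score(g.RISK_L, df).to_numpy()
        thr, stat, _ = g.threshold_search(scores, df, min_group_fraction=0.1)
        # exhaustive oracle over every admissible cut
        best = None
        for v in np.unique(scores)[:-1]:
            low = scores <= v
            if min(low.sum(), (~low).sum()) < 12:
                continue
            o = logrank_bruteforce(
                df.pfs_months[low].to_numpy(), df.event[low].to_numpy(),
                df.pfs_months[~low].to_numpy(), df.event[~low].to_numpy())
            if best is None or o > best[1]:
                best = (v, o)
        assert thr == pytest.approx(best[0])
        assert stat == pytest.approx(best[1], abs=1e-8)

    def test_selection_optimism_demonstrated(self):
        # optimizing the cut on pure-noise scores inflates significance:
        # the uncorrected log-rank p at the selected cut is < 0.05 far more
        # often than the nominal 5%
        hits = 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n = 100
            df = pd.DataFrame({"pfs_months": rng.exponential(20, n),
                               "event": rng.integers(0, 2, n)})
            if df.event.sum() < 5:
                continue
            scores = rng.normal(size=n)
            try:
                _, _, p = g.threshold_search(scores, df)
            except SurvivalError:
                continue
            hits += p < 0.05
        assert hits / reps > 0.15

    def test_degenerate_scores_error(self):
        df = make_survival_fixture("km4")
        with pytest.raises(SurvivalError):
            g.threshold_search(np.ones(4), df)


# --------------------------------------------------------------------------
# concordance and validation
# --------------------------------------------------------------------------

class TestHarrellC:
    def test_perfect_ranking(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(10, 50)
        df = pd.DataFrame({"pfs_months": t, "event": 1})
        assert g.harrell_c(df, -t) == pytest.approx(1.0)

    def test_random_scores_null_band(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"pfs_months": rng.exponential(10, 1000),
                           "event": rng.integers(0, 2, 1000)})
        c = g.harrell_c(df, rng.normal(size=1000))
        assert 0.46 <= c <= 0.54

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            t = rng.exponential(10, n).round(1)
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                continue
            s = rng.normal(size=n).round(1)   # rounded scores force ties
            df = pd.DataFrame({"pfs_months": t, "event": e})
            assert g.harrell_c(df, s) == pytest.approx(
                concordance_bruteforce(t, e, s), abs=1e-12)

    def test_score_negation_complement(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({"pfs_months": rng.exponential(10, 100),
                           "event": rng.integers(0, 2, 100)})
        s = rng.normal(size=100)            # tie-free scores
        assert g.harrell_c(df, s) + g.harrell_c(df, -s) == pytest.approx(1.0)


class TestBootstrapValidation:
    def test_uninformative_model_near_half(self, riskl_cohort):
        df = riskl_cohort.head(300)
        data = df[["pfs_months", "event"]].copy()
        res = g.bootstrap_validate(data, [], B=100, seed=0)
        assert res["corrected_c"] == pytest.approx(0.5, abs=0.02)

    def test_seeding_contract_first_replicate_identical(self, riskl_cohort):
        df = riskl_cohort.head(200)
        coded = g.code_covariates(g.RISK_L, df)
        data = pd.concat([df[["pfs_months", "event"]].reset_index(drop=True),
                          coded.reset_index(drop=True)], axis=1)
        r1 = g.bootstrap_validate(data, list(coded.columns), B=1, seed=5)
        r2 = g.bootstrap_validate(data, list(coded.columns), B=2, seed=5)
        assert r1["optimisms"][0] == r2["optimisms"][0]

    def test_corrected_c_close_to_holdout(self):
        # single strong covariate: optimism-corrected C should approximate
        # the C evaluated on a large independent holdout cohort
        def simulate(n, seed):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(1 / (0.02 * np.exp(1.2 * x)))
            c = rng.uniform(0, 120, n)
            return pd.DataFrame({"x": x, "pfs_months": np.minimum(t, c),
                                 "event": (t <= c).astype(int)})

        train = simulate(500, 20)
        res = g.bootstrap_validate(train, ["x"], B=100, seed=21)
        fit = g.cox_fit(train, ["x"])
        holdout = simulate(10_000, 22)
        c_hold = g.harrell_c(holdout, holdout["x"] * fit.params["x"])
        assert res["corrected_c"] == pytest.approx(c_hold, abs=0.03)


class TestCrossValidation:
    def test_calibrated_by_construction(self):
        df = make_cohort(CohortSpec(n=2000, include_missing=False, seed=31))
        coded = g.code_covariates(g.RISK_L, df)
        data = pd.concat([df[["pfs_months", "event"]].reset_index(drop=True),
                          coded.reset_index(drop=True)], axis=1)
        res = g.crossvalidate(data, list(coded.columns), k=5, horizon=36,
                              seed=32)
        assert res["ici"] < 0.05
        assert res["e50"] >= 0.0
        assert sum(res["fold_sizes"]) == len(data)
        assert max(res["fold_sizes"]) - min(res["fold_sizes"]) <= 1
        assert res["mean_c"] > 0.55

    def test_constructed_miscalibration_detected(self):
        df = make_cohort(CohortSpec(n=2000, include_missing=False, seed=33))
        # true 36-month event probability from the generating exponential PH
        lp = g.risk_score(g.RISK_L, df)
        p_true = 1.0 - np.exp(-0.012 * np.exp(lp) * 36.0)
        ici0, _ = g.calibration_error(p_true.to_numpy(), df, horizon=36.0)
        assert ici0 < 0.04
        shifted = np.clip(p_true.to_numpy() + 0.2, 0, 1)
        ici, _ = g.calibration_error(shifted, df, horizon=36.0)
        assert ici == pytest.approx(0.2, abs=0.03)

    def test_fold_without_events_refused(self):
        df = pd.DataFrame({"pfs_months": np.arange(1.0, 13.0),
                           "event": [1] + [0] * 11,
                           "x": np.tile([0.0, 1.0], 6)})
        with pytest.raises(SurvivalError) as err:
            g.crossvalidate(df, ["x"], k=5, horizon=6.0, seed=0)
        assert err.value.code == "fold-without-events"
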
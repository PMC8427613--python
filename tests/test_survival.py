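import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from cnsig.simulate import simulate_survival_cohort
from cnsig.survival import (
    benjamini_hochberg,
    categorical_assoc,
    cox_fit,
    exposure_activity_correlation,
    km_logrank,
    rank_assoc,
)


def logrank_oracle(times_a, times_b):
    """Direct O-E / V computation for two uncensored groups (d=1 per time)."""
    events = sorted([(t, "a") for t in times_a] + [(t, "b") for t in times_b])
    O = E = V = 0.0
    for i, (t, g) in enumerate(events):
        at_risk = events[i:]
        n = len(at_risk)
        na = sum(1 for _, gg in at_risk if gg == "a")
        O += g == "a"
        E += na / n
        if n > 1:
            V += (na / n) * (1 - na / n)
    return (O - E) ** 2 / V


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        frame = pd.DataFrame({
            "time": [3, 5, 8, 3, 5, 8],
            "event": [True] * 6,
            "group": list("AAABBB"),
        })
        res = km_logrank(frame, "group", "time", "event")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_hand_example(self):
        ta, tb = [1, 3, 5], [2, 4, 6]
        frame = pd.DataFrame({"time": ta + tb, "event": [True] * 6,
                              "group": list("AAABBB")})
        res = km_logrank(frame, "group", "time", "event")
        assert res.statistic == pytest.approx(logrank_oracle(ta, tb), abs=1e-9)

    def test_km_estimate_is_product_limit(self):
        frame = pd.DataFrame({"time": [1, 2, 3, 4], "event": [True, True, False, True],
                              "group": ["A"] * 4 + []})
        frame2 = frame.copy()
        frame2["group"] = "B"
        res = km_logrank(pd.concat([frame, frame2]), "group", "time", "event")
        curve = res.curves["A"]
        # product over event times <= t of (1 - d/n): t=4 ->
        # (1-1/4)(1-1/3)(1-1/1) with censoring at 3
        s_at_2 = (1 - 1 / 4) * (1 - 1 / 3)
        got = curve[curve["time"] <= 2.5]["survival"].iloc[-1]
        assert got == pytest.approx(s_at_2, abs=1e-12)
        assert curve["survival"].iloc[-1] == pytest.approx(0.0, abs=1e-12)

    def test_single_group_raises(self):
        frame = pd.DataFrame({"time": [1, 2], "event": [True, True], "group": ["A", "A"]})
        with pytest.raises(ValueError, match="2"):
            km_logrank(frame, "group", "time", "event")

    def test_zero_event_group_warns_but_computes(self):
        frame = pd.DataFrame({
            "time": [1, 2, 3, 4], "event": [True, True, False, False],
            "group": ["A", "A", "B", "B"],
        })
        with pytest.warns(UserWarning, match="zero events"):
            res = km_logrank(frame, "group", "time", "event")
        assert np.isfinite(res.statistic)

    def test_type_one_error_rate_under_null(self):
        """Log-rank at nominal 0.05 rejects <= 7% under the null."""
        rejections = 0
        reps = 500
        rng = np.random.default_rng(0)
        for _ in range(reps):
            n = 200
            frame = pd.DataFrame({
                "time": rng.exponential(50, n),
                "event": rng.random(n) < 0.7,
                "group": rng.integers(0, 2, n),
            })
            res = km_logrank(frame, "group", "time", "event")
            rejections += res.p_value < 0.05
        assert rejections / reps <= 0.07


class TestCoxFit:
    def test_null_covariate_ci_coverage(self):
        covered = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 500
            frame = pd.DataFrame({
                "time": rng.exponential(50, n),
                "event": rng.random(n) < 0.7,
                "x": rng.integers(0, 2, n).astype(float),
            })
            res = cox_fit(frame, ["x"], "time", "event")
            lo, hi = res.table.loc["x", ["ci_low", "ci_high"]]
            covered += lo <= 1.0 <= hi
        assert covered / n_seeds >= 0.9

    def test_true_hazard_ratio_recovered(self):
        """Exponential PH data with HR 3.2: CI covers truth in >= 90% of seeds."""
        covered = 0
        n_seeds = 20
        for seed in range(n_seeds):
            df = simulate_survival_cohort(n=300, hr=3.2, censoring_rate=0.3, seed=seed)
            res = cox_fit(df.astype({"group": float}), ["group"], "time", "event")
            lo, hi = res.table.loc["group", ["ci_low", "ci_high"]]
            covered += lo <= 3.2 <= hi
        assert covered / n_seeds >= 0.9

    def test_point_estimate_invariant_to_duplication(self):
        df = simulate_survival_cohort(n=150, hr=2.0, censoring_rate=0.2, seed=1)
        df = df.astype({"group": float})
        single = cox_fit(df, ["group"], "time", "event")
        double = cox_fit(pd.concat([df, df], ignore_index=True), ["group"], "time", "event")
        # duplication ties every event time in pairs; Efron's tie correction
        # perturbs the point estimate slightly, so equality is approximate
        assert double.table.loc["group", "hr"] == pytest.approx(
            single.table.loc["group", "hr"], rel=0.02)
        # CI narrows with replication
        assert (double.table.loc["group", "ci_high"] - double.table.loc["group", "ci_low"]) < \
               (single.table.loc["group", "ci_high"] - single.table.loc["group", "ci_low"])

    def test_univariate_mode_loops_covariates(self):
        df = simulate_survival_cohort(n=200, hr=2.0, seed=2).astype({"group": float})
        rng = np.random.default_rng(0)
        df["noise"] = rng.normal(size=len(df))
        res = cox_fit(df, ["group", "noise"], "time", "event", mode="univariate")
        assert list(res.table.index) == ["group", "noise"]
        assert res.mode == "univariate"

    def test_more_covariates_than_events_raises(self):
        df = pd.DataFrame({"time": [1, 2, 3], "event": [True, False, False],
                           "a": [0.0, 1, 0], "b": [1.0, 0, 1]})
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, ["a", "b"], "time", "event")


class TestCategoricalAssoc:
    def test_independent_table(self):
        frame = pd.DataFrame({
            "label": ["x"] * 50 + ["y"] * 50,
            "cov": (["u"] * 25 + ["v"] * 25) * 2,
        })
        stat, p, _ = categorical_assoc(frame, "label", "cov")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        frame = pd.DataFrame({
            "label": ["x"] * 40 + ["y"] * 40,
            "cov": ["u"] * 30 + ["v"] * 10 + ["u"] * 10 + ["v"] * 30,
        })
        stat, p, expected = categorical_assoc(frame, "label", "cov")
        assert stat == pytest.approx(20.0, abs=1e-9)  # sum (O-E)^2/E, E=20
        assert (expected.values == 20).all()

    def test_3x2_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({
            "label": rng.choice(["a", "b", "c"], 120),
            "cov": rng.choice(["u", "v"], 120),
        })
        stat, _, expected = categorical_assoc(frame, "label", "cov")
        obs = pd.crosstab(frame["label"], frame["cov"]).values
        brute = ((obs - expected.values) ** 2 / expected.values).sum()
        assert stat == pytest.approx(brute, abs=1e-9)

    def test_low_expected_count_warns(self):
        frame = pd.DataFrame({"label": ["x"] * 3 + ["y"] * 3,
                              "cov": ["u", "v", "v", "v", "v", "v"]})
        with pytest.warns(UserWarning, match="exact"):
            categorical_assoc(frame, "label", "cov")


class TestRankAssoc:
    def test_identical_distributions_p_one(self):
        frame = pd.DataFrame({"g": list("AB") * 3, "v": [1.0, 1, 1, 1, 1, 1]})
        _, p = rank_assoc(frame, "g", "v")
        assert p == pytest.approx(1.0)

    def test_fully_separated_groups_extreme_ranksum(self):
        frame = pd.DataFrame({"g": ["A"] * 3 + ["B"] * 3,
                              "v": [1.0, 2, 3, 10, 11, 12]})
        w, p = rank_assoc(frame, "g", "v")
        assert w == 6.0  # low group occupies ranks 1+2+3
        assert p < 0.1

    def test_three_group_kruskal_matches_bruteforce(self):
        frame = pd.DataFrame({
            "g": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
            "v": [1.0, 2, 5, 3, 4, 8, 6, 7, 9],
        })
        h, _ = rank_assoc(frame, "g", "v")
        ranks = rankdata(frame["v"])
        n = len(ranks)
        brute = 12 / (n * (n + 1)) * sum(
            len(grp) * (ranks[frame["g"] == g].mean() - (n + 1) / 2) ** 2
            for g, grp in frame.groupby("g")
        )
        assert h == pytest.approx(brute, abs=1e-9)


class TestExposureActivityCorrelation:
    @staticmethod
    def _exposures():
        rng = np.random.default_rng(0)
        return pd.DataFrame(rng.dirichlet([1, 1, 1], size=8),
                            index=[f"S{i}" for i in range(8)],
                            columns=["Sig1", "Sig2", "Sig3"])

    def test_identical_column_correlates_one(self):
        E = self._exposures()
        A = pd.DataFrame({"act": E["Sig2"]})
        C = exposure_activity_correlation(E, A)
        assert C.loc["Sig2", "act"] == pytest.approx(1.0)

    def test_negated_ranks_correlate_minus_one(self):
        E = self._exposures()
        A = pd.DataFrame({"act": -E["Sig1"].rank()})
        C = exposure_activity_correlation(E, A)
        assert C.loc["Sig1", "act"] == pytest.approx(-1.0)

    def test_five_sample_bruteforce(self):
        E = self._exposures().iloc[:5]
        rng = np.random.default_rng(1)
        A = pd.DataFrame({"act": rng.uniform(0, 10, 5)}, index=E.index)
        C = exposure_activity_correlation(E, A)
        ra = rankdata(E["Sig1"])
        rb = rankdata(A["act"])
        assert C.loc["Sig1", "act"] == pytest.approx(np.corrcoef(ra, rb)[0, 1], abs=1e-12)

    def test_too_few_shared_samples_raises(self):
        E = self._exposures().iloc[:2]
        A = pd.DataFrame({"act": [1.0, 2.0]}, index=E.index)
        with pytest.raises(ValueError, match="shared"):
            exposure_activity_correlation(E, A)


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.8, 0.04])
    adj = benjamini_hochberg(p)
    assert (adj >= p - 1e-12).all()
    assert (adj <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
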
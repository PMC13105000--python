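import numpy as np
import pandas as pd
import pytest

from karyotme import (
    CopyNumberProfile,
    ExpressionMatrix,
    SimulationConfig,
    build_multivariate_frame,
    categorize_for_survival,
    cox_landscape,
    km_logrank,
    multivariate_cox,
    score_1q_from_expression,
    select_1q_panel,
    simulate_cohort,
)
from karyotme.errors import ConfigError, DataError, DegenerateDataError


def profile_from(values, features=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    features = features or [f"{i + 1}p" for i in range(values.shape[1])]
    return CopyNumberProfile(level="arm", values=pd.DataFrame(
        values, index=[f"S{i}" for i in range(values.shape[0])],
        columns=features,
    ))


def synthetic_1q_inputs(n_candidates=200, n_samples=100, n_concordant=None,
                        seed=0):
    """Gene-level CN plus expression for 1q panel selection."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(n_samples)]
    genes = [f"1qG{i:03d}" for i in range(n_candidates)]
    cn, expr = {}, {}
    for i, g in enumerate(genes):
        dosage = rng.normal(0, 0.4, n_samples)
        cn[g] = dosage
        concordant = n_concordant is None or i < n_concordant
        slope = 2.0 if concordant else 0.0
        expr[g] = np.clip(5 + slope * dosage + rng.normal(0, 0.3, n_samples),
                          0, None)
    return (
        CopyNumberProfile(level="gene", values=pd.DataFrame(cn, index=samples)),
        ExpressionMatrix(pd.DataFrame(expr, index=samples)),
        genes,
    )


class TestCategorization:
    @pytest.mark.parametrize("value,expected", [
        (0.35, "Gain"),
        (-0.35, "Loss"),
        (0.1, "Neutral"),
        (0.3, "Neutral"),   # strict at the printed threshold
        (-0.3, "Neutral"),
    ])
    def test_strict_thresholds(self, value, expected):
        cats = categorize_for_survival(profile_from([[value]]))
        assert cats.categories.iloc[0, 0] == expected

    def test_missing_preserved(self):
        cats = categorize_for_survival(profile_from([[np.nan]]))
        assert pd.isna(cats.categories.iloc[0, 0])

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            categorize_for_survival(profile_from([[0.0]]),
                                    gain_thr=-0.3, loss_thr=0.3)


class TestCoxLandscape:
    def test_planted_hazard_recovered(self):
        config = SimulationConfig(
            seed=21, n_samples=500,
            planted_survival_effects=[("1p", "gain", np.log(2.0))],
        )
        cohort = simulate_cohort(config)
        cats = categorize_for_survival(cohort.arm_profile)
        res = cox_landscape(cohort.clinical, cats)
        row = res[(res["term"] == "1p") & (res["direction"] == "gain")].iloc[0]
        assert 1.6 <= row["hazard_ratio"] <= 2.5
        assert row["signed_score"] > 0

    def test_null_arm_ci_covers_one(self):
        covered = 0
        reps = 20
        for seed in range(reps):
            cohort = simulate_cohort(SimulationConfig(seed=300 + seed,
                                                      n_samples=300, n_arms=2))
            cats = categorize_for_survival(cohort.arm_profile)
            res = cox_landscape(cohort.clinical, cats)
            row = res[(res["term"] == "1p")
                      & (res["direction"] == "gain")].iloc[0]
            if row["ci_low"] <= 1.0 <= row["ci_high"]:
                covered += 1
        assert covered >= 18  # >= 90%

    def test_log_hr_bias_small(self):
        """Mean log-HR over replicates within 0.1 of the planted value."""
        log_hrs = []
        for seed in range(50):
            cohort = simulate_cohort(SimulationConfig(
                seed=600 + seed, n_samples=1000, n_arms=1,
                planted_survival_effects=[("1p", "gain", np.log(2.0))],
            ))
            cats = categorize_for_survival(cohort.arm_profile)
            res = cox_landscape(cohort.clinical, cats)
            row = res[(res["term"] == "1p")
                      & (res["direction"] == "gain")].iloc[0]
            log_hrs.append(np.log(row["hazard_ratio"]))
        assert abs(np.mean(log_hrs) - np.log(2.0)) < 0.1

    def test_protective_and_deleterious_flip_sign(self):
        scores = []
        for lhr in (np.log(2.0), -np.log(2.0)):
            cohort = simulate_cohort(SimulationConfig(
                seed=33, n_samples=400, n_arms=1,
                planted_survival_effects=[("1p", "gain", lhr)],
            ))
            cats = categorize_for_survival(cohort.arm_profile)
            res = cox_landscape(cohort.clinical, cats)
            scores.append(res[(res["term"] == "1p")
                              & (res["direction"] == "gain")]
                          .iloc[0]["signed_score"])
        assert scores[0] > 0 > scores[1]

    def test_all_neutral_arm_skipped(self):
        rng = np.random.default_rng(0)
        n = 60
        profile = profile_from(rng.normal(0, 0.05, (n, 1)))
        clinical = pd.DataFrame({
            "os_time": rng.exponential(20, n),
            "os_event": rng.random(n) < 0.7,
        }, index=profile.values.index)
        res = cox_landscape(clinical, categorize_for_survival(profile))
        assert (res["skip_reason"] == "no_group_variation").all()


class TestKaplanMeier:
    def clinical(self, times, events, labels):
        idx = [f"S{i}" for i in range(len(times))]
        return (
            pd.DataFrame({"os_time": times, "os_event": events}, index=idx),
            pd.Series(labels, index=idx),
        )

    def test_identical_groups_null(self):
        clin, labels = self.clinical(
            [5, 10, 15, 5, 10, 15], [1, 1, 0, 1, 1, 0],
            ["A", "A", "A", "B", "B", "B"],
        )
        _, test = km_logrank(clin, labels)
        assert test["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert test["p"] == pytest.approx(1.0)

    def test_matches_hand_computed_logrank(self):
        clin, labels = self.clinical(
            [1, 2, 3, 4, 5, 6], [1] * 6, ["A", "A", "A", "B", "B", "B"],
        )
        _, test = km_logrank(clin, labels)
        # O-E oracle: one event per distinct time, no censoring
        at_risk_a, at_risk_b = 3, 3
        observed_a, expected_a, variance = 0, 0.0, 0.0
        for t, grp in zip([1, 2, 3, 4, 5, 6], ["A"] * 3 + ["B"] * 3):
            n = at_risk_a + at_risk_b
            expected_a += at_risk_a / n
            if n > 1:
                variance += at_risk_a * at_risk_b / n ** 2
            if grp == "A":
                observed_a += 1
                at_risk_a -= 1
            else:
                at_risk_b -= 1
        chi2 = (observed_a - expected_a) ** 2 / variance
        assert test["statistic"] == pytest.approx(chi2, rel=1e-9)

    def test_fully_censored_group_curve_flat(self):
        clin, labels = self.clinical(
            [5, 10, 15, 20], [1, 1, 0, 0], ["A", "A", "B", "B"],
        )
        with pytest.raises(DegenerateDataError, match="no events"):
            km_logrank(clin, labels)
        # with at least one event in B the censored tail stays flat at 1
        clin2, labels2 = self.clinical(
            [5, 10, 1, 15, 20], [1, 1, 1, 0, 0], ["A", "A", "B", "B", "B"],
        )
        curves, _ = km_logrank(clin2, labels2)
        b = curves[curves["group"] == "B"]
        assert b[b["time"] >= 15]["survival"].iloc[-1] == b[
            b["time"] == 1.0]["survival"].iloc[0]

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 40).round(2)
        clin, labels = self.clinical(
            np.concatenate([times, [1, 2, 3]]),
            [1] * 43,
            ["A"] * 40 + ["B"] * 3,
        )
        curves, _ = km_logrank(clin, labels)
        a = curves[curves["group"] == "A"].set_index("time")["survival"]
        for t in np.unique(times):
            empirical = (times > t).mean()
            assert a.loc[t] == pytest.approx(empirical)

    def test_single_group_rejected(self):
        clin, labels = self.clinical([1, 2], [1, 1], ["A", "A"])
        with pytest.raises(DegenerateDataError, match="2 groups"):
            km_logrank(clin, labels)


class TestPanelSelection:
    def test_default_panel_has_50_genes(self):
        cn, expr, _ = synthetic_1q_inputs()
        panel = select_1q_panel(cn, expr)
        assert len(panel) == 50

    def test_planted_concordant_genes_selected(self):
        cn, expr, genes = synthetic_1q_inputs(n_concordant=60, seed=1)
        panel = select_1q_panel(cn, expr)
        assert set(panel) <= set(genes[:60])

    def test_shortfall_is_an_error(self):
        cn, expr, _ = synthetic_1q_inputs(n_candidates=49)
        with pytest.raises(DataError, match="49"):
            select_1q_panel(cn, expr)

    def test_ties_break_lexicographically(self):
        n = 30
        rng = np.random.default_rng(2)
        samples = [f"S{i}" for i in range(n)]
        dosage = rng.normal(0, 0.4, n)
        # two genes with identical (perfect) concordance
        cn = pd.DataFrame({"1qB": dosage, "1qA": dosage}, index=samples)
        expr = pd.DataFrame({"1qB": dosage * 2 + 5, "1qA": dosage * 2 + 5},
                            index=samples)
        panel = select_1q_panel(
            CopyNumberProfile(level="gene", values=cn),
            ExpressionMatrix(expr.clip(lower=0)), k=1,
        )
        assert panel == ["1qA"]


class TestExpressionScore:
    def test_top_quartile_classified_gain(self):
        rng = np.random.default_rng(4)
        n = 200
        samples = [f"S{i}" for i in range(n)]
        panel = [f"1qG{i:03d}" for i in range(50)]
        expr = ExpressionMatrix(pd.DataFrame(
            rng.uniform(1, 100, (n, 50)), index=samples, columns=panel))
        score = score_1q_from_expression(expr, panel)
        assert int(score.gain.sum()) == 50  # ceil(200 / 4)

    def test_minimal_cohort_has_one_gain(self):
        rng = np.random.default_rng(5)
        panel = ["G1", "G2"]
        expr = ExpressionMatrix(pd.DataFrame(
            rng.uniform(1, 10, (4, 2)), index=list("ABCD"), columns=panel))
        score = score_1q_from_expression(expr, panel)
        assert int(score.gain.sum()) == 1

    def test_log_scale_shift_invariance(self):
        rng = np.random.default_rng(6)
        panel = [f"G{i}" for i in range(10)]
        base = rng.uniform(1, 50, (30, 10))
        expr = ExpressionMatrix(pd.DataFrame(
            base, index=[f"S{i}" for i in range(30)], columns=panel))
        shifted = ExpressionMatrix(pd.DataFrame(
            np.expm1(np.log1p(base) + 0.7), index=expr.values.index,
            columns=panel))
        a = score_1q_from_expression(expr, panel)
        b = score_1q_from_expression(shifted, panel)
        pd.testing.assert_series_equal(a.gain, b.gain)

    def test_constant_gene_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        panel = ["G1", "G2"]
        df = pd.DataFrame({"G1": rng.uniform(1, 10, 8),
                           "G2": np.full(8, 3.0)},
                          index=[f"S{i}" for i in range(8)])
        with pytest.warns(UserWarning, match="constant"):
            score = score_1q_from_expression(ExpressionMatrix(df), panel)
        assert len(score.scores) == 8

    def test_missing_panel_beyond_tolerance_rejected(self):
        rng = np.random.default_rng(8)
        panel = [f"G{i}" for i in range(10)]
        df = pd.DataFrame({"G0": rng.uniform(1, 10, 5)},
                          index=[f"S{i}" for i in range(5)])
        with pytest.raises(DataError, match="panel genes"):
            score_1q_from_expression(ExpressionMatrix(df), panel)


class TestMultivariateCox:
    def planted_clinical(self, seed, n=1000, hr_1q=1.8):
        rng = np.random.default_rng(seed)
        gain = rng.random(n) < 0.3
        lam = (np.log(2) / 24.0) * np.exp(np.log(hr_1q) * gain)
        times = rng.exponential(1.0 / lam)
        censored = rng.random(n) < 0.3
        return pd.DataFrame({
            "os_time": np.where(censored, times * rng.uniform(0, 1, n), times),
            "os_event": ~censored,
            "gain_1q": gain.astype(float),
            "cd8_fraction": rng.beta(2, 8, n),
            "b_fraction": rng.beta(2, 12, n),
            "tmb": np.exp(rng.normal(1.5, 1, n)),
            "pdl1_positive": rng.random(n) < 0.4,
        }, index=[f"S{i}" for i in range(n)])

    def test_tmb_dichotomized_at_10_inclusive(self):
        clin = self.planted_clinical(0, n=20)
        clin.loc[clin.index[:3], "tmb"] = [5.0, 10.0, 15.0]
        frame = build_multivariate_frame(clin)
        assert list(frame["tmb_high"].iloc[:3]) == [0.0, 1.0, 1.0]

    def test_planted_1q_effect_dominates(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            frame = build_multivariate_frame(self.planted_clinical(40 + seed))
            res = multivariate_cox(frame).set_index("term")
            # significance judged on the FDR-adjusted values the model reports
            only_1q = (res.loc["gain_1q", "q"] < 0.05) and (
                res.drop("gain_1q")["q"] > 0.05).all()
            hits += only_1q
        assert hits >= 16  # >= 80% of replicates

    def test_dropping_null_covariate_barely_moves_hr(self):
        frame = build_multivariate_frame(self.planted_clinical(7))
        full = multivariate_cox(frame).set_index("term")
        reduced = multivariate_cox(
            frame, covariates=["gain_1q", "cd8_high", "b_high", "tmb_high"]
        ).set_index("term")
        hr_full = full.loc["gain_1q", "hazard_ratio"]
        hr_red = reduced.loc["gain_1q", "hazard_ratio"]
        assert abs(hr_red - hr_full) / hr_full < 0.10

    def test_constant_covariate_named_in_error(self):
        frame = build_multivariate_frame(self.planted_clinical(1, n=50))
        frame["pdl1_positive"] = 1.0
        with pytest.raises(DataError, match="pdl1_positive"):
            multivariate_cox(frame)

    def test_duplicate_covariate_named_in_error(self):
        frame = build_multivariate_frame(self.planted_clinical(2, n=50))
        frame["b_high"] = frame["cd8_high"]
        with pytest.raises(DataError, match="cd8_high.*b_high"):
            multivariate_cox(frame)
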
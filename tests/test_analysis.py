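import numpy as np
import pandas as pd
import pytest

from preycat.analysis import (
    AnalysisError,
    FitResult,
    build_design,
    fit_logit,
    fit_model,
    linear_contrast,
    pairwise_groupings,
    prepare_table,
    round_sig,
    simulate_attacks,
    split_value_lrt,
    summarize_effects,
    trait_contrasts,
)
from tests.conftest import grid_search_logit, run_exp1_cohort


@pytest.fixture(scope="module")
def table(small_study):
    return prepare_table(small_study.records)


@pytest.fixture(scope="module")
def fit(table):
    return fit_model(table)


def make_fit(beta: dict, cov: np.ndarray | None = None) -> FitResult:
    names = list(beta)
    values = np.array([beta[k] for k in names], dtype=float)
    if cov is None:
        cov = np.eye(len(names))
    return FitResult(
        params=pd.Series(values, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=0.0,
        converged=True,
        separation=False,
        nobs=1,
    )


class TestPrepareTable:
    def test_recoding_good_bad(self, table):
        good = table[table["reliable_polarity"] == "+"]
        bad = table[table["reliable_polarity"] == "-"]
        assert set(good["R_recoded"]) == {"G"}
        assert set(bad["R_recoded"]) == {"B"}

    def test_test_only_values_eliminated(self, table):
        # design 1 trained only R1+/R1-; the test grid's R2 values must be gone
        exp1 = table[table["experiment"] == 1]
        assert set(exp1["reliable_label"]) == {"R1+", "R1-"}

    def test_only_focal_values_retained(self, table):
        assert set(table["reliable_label"]) <= {"R1+", "R1-", "R2+", "R2-"}

    def test_only_test_trials(self, table):
        assert set(table["trial"]) == {"test"}

    def test_centering(self, table):
        assert abs(table["R_c"].mean()) < 1e-12
        assert abs(table["U_c"].mean()) < 1e-12
        assert abs(table["order_c"].mean()) < 1e-12

    def test_missing_columns_rejected(self):
        with pytest.raises(AnalysisError, match="missing required columns"):
            prepare_table(pd.DataFrame({"subject": [1]}))

    def test_display_columns_irrelevant(self, small_study):
        records = small_study.records.copy()
        with_display = prepare_table(records)
        records["reliable_value"] = "redacted"
        records["unreliable_value"] = "redacted"
        without = prepare_table(records)
        pd.testing.assert_frame_equal(
            with_display.drop(columns=["reliable_value", "unreliable_value"]),
            without.drop(columns=["reliable_value", "unreliable_value"]),
        )


class TestFitModel:
    def test_matches_grid_search_oracle(self):
        # two-parameter toy: traits only, single experiment
        rng = np.random.default_rng(0)
        n = 400
        r = rng.integers(0, 2, n).astype(float)
        u = rng.integers(0, 2, n).astype(float)
        rc, uc = r - r.mean(), u - u.mean()
        eta = 1.3 * rc - 0.7 * uc
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = pd.DataFrame({"R": rc, "U": uc})
        fitted = fit_logit(y, X)
        oracle = grid_search_logit(y, X.to_numpy())
        assert fitted.params.to_numpy() == pytest.approx(oracle, abs=1e-4)

    def test_score_vanishes_at_optimum(self, table, fit):
        y, X = build_design(table)
        eta = X.to_numpy() @ fit.params.to_numpy()
        p = 1 / (1 + np.exp(-eta))
        score = X.to_numpy().T @ (y - p)
        assert np.max(np.abs(score)) < 1e-6

    def test_no_intercept_no_main_effects(self, fit):
        names = set(fit.params.index)
        assert "Intercept" not in names and "const" not in names
        assert "R" not in names and "U" not in names  # only trait:experiment terms
        for e in range(1, 6):
            assert f"R:exp{e}" in names and f"U:exp{e}" in names

    def test_subject_fixed_effects_present(self, fit, table):
        subjects = sorted(table["subject"].unique())
        for s in subjects[1:]:
            assert f"subj[{s}]" in fit.params.index
        assert f"subj[{subjects[0]}]" not in fit.params.index

    def test_covariance_symmetric_psd(self, fit):
        cov = fit.cov.to_numpy()
        assert np.allclose(cov, cov.T, atol=1e-10)
        assert np.min(np.linalg.eigvalsh(cov)) > -1e-8

    def test_null_data_gives_null_trait_effects(self):
        # attacks independent of both traits: coefficients within 2 SE of 0
        # in the bulk of replicates
        hits = total = 0
        for seed in range(40):
            records = run_exp1_cohort("random", n_subjects=6, seed=100 + seed)
            fit = fit_model(prepare_table(records))
            for term in ("R:exp1", "U:exp1"):
                b = fit.params[term]
                se = np.sqrt(fit.cov.loc[term, term])
                hits += abs(b) < 2 * se
                total += 1
        assert hits / total >= 0.9

    def test_ridge_fit_close_to_ml(self, table):
        ml = fit_model(table)
        penalized = fit_model(table, ridge=1e-6)
        assert penalized.params.to_numpy() == pytest.approx(
            ml.params.to_numpy(), abs=1e-3
        )

    def test_rank_deficient_design_rejected(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        X = pd.DataFrame({"a": [1, 1, 0, 0], "b": [1, 1, 0, 0]})
        with pytest.raises(AnalysisError, match="rank deficient"):
            fit_logit(y, X)

    def test_too_few_subjects_rejected(self, table):
        solo = table[table["subject"] == table["subject"].iloc[0]]
        with pytest.raises(AnalysisError, match="two subjects"):
            fit_model(solo)


class TestContrasts:
    def test_worked_example(self):
        # log-odds 3.36 and 0.24: difference 3.12, relative odds 22.6
        fit = make_fit({"R:exp1": 3.36, "U:exp1": 0.24})
        per = trait_contrasts(fit)[1]
        assert per["reliable"].estimate == pytest.approx(3.36)
        assert round_sig(per["reliable"].odds_ratio, 3) == 28.8
        assert round_sig(per["unreliable"].odds_ratio, 3) == 1.27
        assert per["difference"].estimate == pytest.approx(3.12)
        assert round_sig(per["difference"].odds_ratio, 3) == 22.6

    def test_identity_covariance_se(self):
        fit = make_fit({"R:exp1": 0.5, "U:exp1": -0.5})
        diff = trait_contrasts(fit)[1]["difference"]
        assert diff.se == pytest.approx(np.sqrt(2.0), rel=1e-15)

    def test_delta_se_equals_closed_form(self, fit):
        rng = np.random.default_rng(1)
        names = list(fit.params.index)
        c = pd.Series(rng.normal(size=len(names)), index=names)
        res = linear_contrast(fit, dict(c), label="arbitrary")
        manual = float(np.sqrt(c @ fit.cov @ c))
        assert res.se == pytest.approx(manual, rel=1e-14)

    def test_delta_se_matches_reparameterized_refit(self):
        # refit with (R-U)/2 and (R+U)/2 columns: the first coefficient IS
        # the difference, so its Wald SE must equal the delta-method SE
        rng = np.random.default_rng(2)
        n = 500
        r = rng.integers(0, 2, n) - 0.5
        u = rng.integers(0, 2, n) - 0.5
        y = (rng.random(n) < 1 / (1 + np.exp(-(1.1 * r - 0.4 * u)))).astype(float)
        fit_ru = fit_logit(y, pd.DataFrame({"R:exp1": r, "U:exp1": u}))
        delta_se = trait_contrasts(fit_ru)[1]["difference"].se
        fit_ds = fit_logit(
            y, pd.DataFrame({"d": (r - u) / 2, "s": (r + u) / 2})
        )
        refit_se = float(np.sqrt(fit_ds.cov.loc["d", "d"]))
        assert delta_se == pytest.approx(refit_se, rel=1e-6)

    def test_odds_ratio_is_exactly_exp(self, fit):
        for per in trait_contrasts(fit).values():
            for res in per.values():
                assert res.odds_ratio == pytest.approx(
                    np.exp(res.estimate), rel=1e-12
                )

    def test_sum_and_difference_relations(self, fit):
        for per in trait_contrasts(fit).values():
            assert per["difference"].estimate == pytest.approx(
                per["reliable"].estimate - per["unreliable"].estimate
            )
            assert per["sum"].estimate == pytest.approx(
                per["reliable"].estimate + per["unreliable"].estimate
            )

    def test_missing_term_rejected(self, fit):
        with pytest.raises(AnalysisError, match="not in the fitted model"):
            linear_contrast(fit, {"R:exp9": 1.0})

    def test_summarize_effects(self):
        out = summarize_effects(3.36, 0.24)
        assert out["difference"].estimate == pytest.approx(3.12)
        assert out["sum"].estimate == pytest.approx(3.60)
        assert round_sig(out["difference"].odds_ratio, 3) == 22.6


class TestPairwiseGroupings:
    def _fit_for(self, estimates, se):
        beta = {}
        for e, est in estimates.items():
            beta[f"R:exp{e}"] = est
            beta[f"U:exp{e}"] = 0.0
        cov = np.eye(len(beta)) * se**2
        return make_fit(beta, cov)

    def test_identical_estimates_single_group(self):
        fit = self._fit_for({e: 1.0 for e in range(1, 6)}, se=1.0)
        grouping = pairwise_groupings(fit, "difference")
        assert len(set(grouping.letters.values())) == 1
        assert grouping.n_comparisons == 10

    def test_separated_estimates_two_groups(self):
        fit = self._fit_for({1: 0.0, 2: 10.0}, se=0.01)
        grouping = pairwise_groupings(fit, "difference")
        assert grouping.letters[1] != grouping.letters[2]

    def test_bonferroni_widens_intervals(self, fit):
        grouping = pairwise_groupings(fit, "difference", alpha=0.05)
        row = grouping.pairwise.iloc[0]
        # adjusted level 1 - 0.05/10 = 0.995 -> z ~ 2.807 vs plain 1.96
        z_used = (row["ci_hi"] - row["estimate"]) / row["se"]
        assert z_used == pytest.approx(2.807, abs=0.01)

    def test_letters_match_significance(self, fit):
        grouping = pairwise_groupings(fit, "difference")
        for _, row in grouping.pairwise.iterrows():
            a, b = int(row["exp_a"]), int(row["exp_b"])
            shared = set(grouping.letters[a]) & set(grouping.letters[b])
            assert bool(shared) == (not row["significant"])

    def test_single_experiment_rejected(self):
        fit = make_fit({"R:exp1": 1.0, "U:exp1": 0.0})
        with pytest.raises(AnalysisError, match="at least two experiments"):
            pairwise_groupings(fit)


class TestSplitValueLRT:
    def test_split_never_fits_worse(self, table):
        out = split_value_lrt(table)
        assert out["loglik_split"] >= out["loglik_lumped"] - 1e-8
        assert out["chi2"] >= 0.0

    def test_structural_df(self, table):
        # designs 2-5 each have 4 focal values (3 free vs 1 lumped): df = 8
        out = split_value_lrt(table)
        assert out["df"] == 8.0

    def test_single_experiment_cannot_split(self):
        records = run_exp1_cohort("random", n_subjects=8, seed=11)
        with pytest.raises(AnalysisError, match="adds no parameters"):
            split_value_lrt(prepare_table(records))

    def test_lumped_truth_gives_null_chi2(self, table):
        # attacks simulated from the lumped model itself: the split model's
        # improvement is chi-square(8) noise, far below the power regime
        rng = np.random.default_rng(3)
        y, X = build_design(table)
        beta = fit_logit(y, X).params.to_numpy()
        for _ in range(3):
            sim = table.copy()
            sim["attacked"] = simulate_attacks(X, beta, rng)
            out = split_value_lrt(sim)
            assert out["chi2"] < 35.0  # ~99.99th percentile of chi2(8)

    def test_power_against_unequal_good_values(self):
        # agents that attack one good value far more than the other: the
        # split model should win decisively in every replicate
        from preycat import StudyConfig, run_study

        hits = 0
        n_rep = 5
        for seed in range(n_rep):
            study = run_study(
                StudyConfig(
                    n_subjects=20,
                    archetype_mix={"humanlike": 1.0},
                    archetype_params={"humanlike": {"capacity": 2}},
                    master_seed=50 + seed,
                )
            )
            out = split_value_lrt(prepare_table(study.records))
            hits += out["p"] < 0.001
        assert hits == n_rep


class TestRoundSig:
    @pytest.mark.parametrize(
        "x,digits,expected",
        [(28.789, 3, 28.8), (1.2712, 3, 1.27), (22.646, 3, 22.6), (0.0, 3, 0.0)],
    )
    def test_values(self, x, digits, expected):
        assert round_sig(x, digits) == expected
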
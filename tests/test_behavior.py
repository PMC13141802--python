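"""Behavioral models: designs, mixed logistic fit, summary-statistic tests."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import eventseg as es
from _reference import (
    EDUCATION_CHI2,
    EDUCATION_COUNTS,
    EDUCATION_DF,
    EDUCATION_N,
    GROUP_SIZES_BY_DF,
    TABLE1,
)


def simulate_design(seed=1, n_subj=6, n_bins=200, sd=0.5, beta_count=0.3,
                    interaction=-0.09):
    cfg = es.SimConfig(seed=seed, n_subjects_per_group=n_subj, n_bins=n_bins,
                       clip_boundaries=(0.0, n_bins * 2.0), beta_count=beta_count,
                       beta_group_interaction=interaction, random_intercept_sd=sd)
    table = es.simulate_change_table(cfg)
    streams = es.simulate_responses(table, cfg)
    binned = np.array([
        es.classify_bins(s.response_times, cfg.duration, cfg.bin_width) for s in streams
    ])
    groups = np.array([s.group for s in streams])
    return table, binned, groups, [s.subject_id for s in streams]


class TestBuildDesigns:
    def test_row_count_and_columns(self):
        table, binned, groups, ids = simulate_design(n_subj=3, n_bins=50)
        count, types = es.build_designs(table, binned, groups, ids)
        assert len(count) == len(types) == 6 * 50
        assert {"response", "n_changes", "group", "subject_id"} <= set(count.columns)
        assert set(es.CHANGE_TYPES) <= set(types.columns)

    def test_n_changes_equals_active_flag_count(self):
        table, binned, groups, ids = simulate_design(n_subj=2, n_bins=40)
        count, types = es.build_designs(table, binned, groups, ids)
        assert (types[list(es.CHANGE_TYPES)].sum(axis=1).to_numpy()
                == count["n_changes"].to_numpy()).all()

    def test_silent_subject_retained_with_zero_responses(self):
        table, binned, groups, ids = simulate_design(n_subj=2, n_bins=30)
        binned[0] = 0
        count, _ = es.build_designs(table, binned, groups, ids)
        sub = count[count["subject_id"] == ids[0]]
        assert len(sub) == 30 and (sub["response"] == 0).all()

    def test_misaligned_bins_rejected(self):
        table, binned, groups, ids = simulate_design(n_subj=2, n_bins=30)
        with pytest.raises(ValueError):
            es.build_designs(table.iloc[:20], binned, groups, ids)


class TestFitMixedLogit:
    def test_odds_ratio_is_exponentiated_estimate(self):
        table, binned, groups, ids = simulate_design()
        count, _ = es.build_designs(table, binned, groups, ids)
        fit = es.fit_mixed_logit(count, "count", n_quad=21)
        assert np.allclose(fit.odds_ratios, np.exp(fit.estimates))
        assert np.all(fit.conf_int[:, 0] <= fit.estimates)
        assert np.all(fit.estimates <= fit.conf_int[:, 1])

    def test_zero_intercept_sd_matches_plain_logistic(self):
        # simulated without between-subject variability: GLMM coefficients
        # agree with an ordinary logistic fit within 2 SE
        import statsmodels.api as sm

        table, binned, groups, ids = simulate_design(seed=8, n_subj=15, n_bins=300, sd=0.0)
        count, _ = es.build_designs(table, binned, groups, ids)
        fit = es.fit_mixed_logit(count, "count", n_quad=21)
        x = sm.add_constant(
            np.column_stack([
                count["n_changes"],
                count["group"],
                count["n_changes"] * count["group"],
            ])
        )
        ref = sm.Logit(count["response"], x).fit(disp=0)
        assert np.all(np.abs(fit.estimates - ref.params.to_numpy())
                      <= 2 * ref.bse.to_numpy())

    def test_matches_lme4_adaptive_quadrature(self, tmp_path):
        """Dual-route check of the Gauss-Hermite ML fit against glmer."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable for the lme4 cross-check")
        table, binned, groups, ids = simulate_design(seed=3, n_subj=10, n_bins=150)
        count, _ = es.build_designs(table, binned, groups, ids)
        fit = es.fit_mixed_logit(count, "count")
        csv = tmp_path / "design.csv"
        count.to_csv(csv, index=False)
        r_code = f'''
suppressMessages(library(lme4))
d <- read.csv("{csv}")
m <- glmer(response ~ n_changes * group + (1 | subject_id), data = d,
           family = binomial, nAGQ = 15,
           control = glmerControl(optimizer = "bobyqa"))
fe <- fixef(m)
cat(sprintf("%.8f %.8f %.8f %.8f %.8f", fe[1], fe[2], fe[3], fe[4],
    sqrt(unlist(VarCorr(m))[1])))
'''
        out = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                             text=True, check=True)
        ref = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(fit.estimates, ref[:4], atol=5e-3)
        assert fit.random_intercept_sd == pytest.approx(ref[4], abs=5e-3)

    def test_null_interaction_interval_covers_one(self):
        covered = 0
        for seed in range(5):
            table, binned, groups, ids = simulate_design(
                seed=100 + seed, n_subj=10, n_bins=150, interaction=0.0
            )
            count, _ = es.build_designs(table, binned, groups, ids)
            fit = es.fit_mixed_logit(count, "count", n_quad=21)
            lo, hi = fit.or_conf_int[fit.names.index("n_changes:group")]
            covered += lo <= 1.0 <= hi
        assert covered >= 4

    def test_degenerate_response_rejected(self):
        table, binned, groups, ids = simulate_design(n_subj=2, n_bins=20)
        binned[:] = 0
        count, _ = es.build_designs(table, binned, groups, ids)
        with pytest.raises(ValueError):
            es.fit_mixed_logit(count, "count")


class TestEventLength:
    def test_duration_over_count(self):
        assert es.mean_event_length(np.arange(60), 1800.0) == pytest.approx(30.0)

    def test_zero_responses_rejected(self):
        with pytest.raises(ValueError):
            es.mean_event_length([], 1800.0)

    def test_identical_groups_zero_t(self):
        t, p = es.behavior.event_length_group_test([30, 40, 50], [30, 40, 50])
        assert t == pytest.approx(0.0)

    def test_matches_longhand_pooled_t(self, rng):
        a, b = rng.uniform(20, 60, 12), rng.uniform(20, 60, 10)
        t, _ = es.behavior.event_length_group_test(a, b)
        sp2 = ((11 * a.var(ddof=1)) + (9 * b.var(ddof=1))) / 20
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 12 + 1 / 10))
        assert t == pytest.approx(expected)


class TestSummaryStatistics:
    def test_scq_total_row_reproduces_printed_t(self):
        m1, s1, m2, s2, df, _ = TABLE1["SCQ_total"]
        n1, n2 = GROUP_SIZES_BY_DF[df]
        res = es.t_from_summary(m1, s1, n1, m2, s2, n2)
        assert res.statistic == pytest.approx(-9.40, abs=0.01)
        assert res.df == 49

    @pytest.mark.parametrize("scale", sorted(TABLE1))
    def test_all_table_rows_within_three_percent(self, scale):
        m1, s1, m2, s2, df, printed = TABLE1[scale]
        n1, n2 = GROUP_SIZES_BY_DF[df]
        res = es.t_from_summary(m1, s1, n1, m2, s2, n2)
        assert res.df == df
        assert res.statistic == pytest.approx(printed, rel=0.03)

    def test_equal_means_zero_t(self):
        assert es.t_from_summary(5, 1, 10, 5, 2, 12).statistic == 0.0

    def test_matches_textbook_formula(self, rng):
        m1, s1, m2, s2 = rng.uniform(1, 10, 4)
        n1, n2 = 14, 19
        res = es.t_from_summary(m1, s1, n1, m2, s2, n2)
        sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
        assert res.statistic == pytest.approx((m1 - m2) / (sp * np.sqrt(1 / n1 + 1 / n2)))

    def test_invalid_summary_inputs_rejected(self):
        with pytest.raises(ValueError):
            es.t_from_summary(1, 1, 1, 2, 1, 10)
        with pytest.raises(ValueError):
            es.t_from_summary(1, 0, 5, 2, 1, 10)


class TestChiSquare:
    def test_proportional_table_gives_zero(self):
        res = es.chisq_from_table([[10, 20, 30], [20, 40, 60]])
        assert res.statistic == pytest.approx(0.0)

    def test_parental_education_table(self):
        res = es.chisq_from_table(EDUCATION_COUNTS)
        assert np.sum(EDUCATION_COUNTS) == EDUCATION_N
        assert res.df == EDUCATION_DF
        assert res.statistic == pytest.approx(EDUCATION_CHI2, abs=0.01)

    def test_two_by_two_matches_formula(self):
        a, b, c, d = 12, 5, 7, 20
        res = es.chisq_from_table([[a, b], [c, d]])
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(expected)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            es.chisq_from_table([[0, 0], [1, 2]])
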
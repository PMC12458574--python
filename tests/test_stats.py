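"""Feedback-change tests, within-subject correlations, mixed-design ANOVA."""

import numpy as np
import pandas as pd
import pytest

import ruleshift as rs
from ruleshift.pipeline import (
    feedback_change_tests,
    iqr_filter,
    rm_anova,
    within_subject_correlation,
)


class TestIQRFilter:
    def test_extremes_removed_core_kept(self):
        x = np.concatenate([np.random.default_rng(0).normal(0, 1, 50), [40.0]])
        kept = iqr_filter(x)
        assert 40.0 not in kept and len(kept) >= 45


class TestFeedbackChangeTests:
    def test_bonferroni_definition(self, preset_cohort):
        tab = feedback_change_tests(preset_cohort)
        within = tab[tab["group"] != "both"]
        assert len(within) == 4
        assert np.allclose(
            within["p_bonf"], np.minimum(1.0, 4 * within["p"]), atol=1e-12
        )
        between = tab[tab["group"] == "both"]
        assert len(between) == 2
        assert np.allclose(
            between["p_bonf"], np.minimum(1.0, 2 * between["p"]), atol=1e-12
        )

    def test_feedback_blind_confidence_changes_near_zero(self, levels):
        # agents whose confidence ignores the certainty traces entirely
        ocd, ctl = rs.default_group_specs(n_per_group=8)
        flat = dict(ocd.param_means, w_cc=0.0, w_gc=0.0)
        ocd_flat = rs.GroupSpec("OCD", 8, flat, dict(ocd.param_sds, w_cc=0.0, w_gc=0.0))
        ctl_flat = rs.GroupSpec("control", 8, dict(ctl.param_means, w_cc=0.0, w_gc=0.0),
                                dict(ctl.param_sds, w_cc=0.0, w_gc=0.0))
        cohort = rs.simulate_cohort(ocd_flat, ctl_flat, 21)
        tab = feedback_change_tests(cohort)
        within = tab[tab["group"] != "both"]
        assert within["mean_change"].abs().max() < 2.0

    def test_stronger_cc_coupling_gives_larger_post_correct_gain(self, preset_cohort):
        tab = feedback_change_tests(preset_cohort).set_index("comparison")
        ocd_up = tab.loc["OCD post-correct vs 0", "mean_change"]
        ctl_up = tab.loc["control post-correct vs 0", "mean_change"]
        assert ocd_up > ctl_up > 0

    def test_tiny_group_rejected(self, preset_cohort):
        demo = preset_cohort.demographics.iloc[:30]  # 29 OCD + 1 control
        trials = preset_cohort.trials[
            preset_cohort.trials["participant_id"].isin(demo["participant_id"])
        ]
        cohort = rs.CohortDataset(trials, demo, None, None)
        with pytest.raises(ValueError):
            feedback_change_tests(cohort)


class TestWithinSubjectCorrelation:
    @staticmethod
    def _traces(values):
        rows = []
        for pid, (x, y) in values.items():
            rows.append(pd.DataFrame(dict(participant_id=pid, gc_pre=x, cc_pre=y)))
        return pd.concat(rows, ignore_index=True)

    def test_identical_traces_give_r_one(self):
        x = np.linspace(0, 100, 40)
        traces = self._traces({"a": (x, x), "b": (x[::-1], x[::-1])})
        mean, sd, table = within_subject_correlation(traces)
        assert mean == pytest.approx(1.0)

    def test_independent_traces_near_zero(self):
        rng = np.random.default_rng(2)
        traces = self._traces(
            {f"p{i}": (rng.normal(size=200), rng.normal(size=200)) for i in range(20)}
        )
        mean, sd, _ = within_subject_correlation(traces)
        assert abs(mean) < 0.05

    def test_constant_trace_flagged_and_excluded(self):
        x = np.linspace(0, 100, 40)
        traces = self._traces({"a": (x, x), "flat": (np.full(40, 5.0), x)})
        mean, sd, table = within_subject_correlation(traces)
        assert table.set_index("participant_id").loc["flat", "constant"]
        assert mean == pytest.approx(1.0)

    def test_too_few_trials_rejected(self):
        traces = self._traces({"a": (np.arange(5.0), np.arange(5.0))})
        with pytest.raises(ValueError):
            within_subject_correlation(traces)

    def test_positive_on_competent_cohort(self, preset_traces):
        mean, sd, _ = within_subject_correlation(preset_traces)
        assert mean > 0


def _manual_mixed_anova(cell):
    """Textbook two-way mixed ANOVA on a balanced participant x level table."""
    grand = cell["y"].mean()
    n_per_group = cell.groupby("group")["participant_id"].nunique().iloc[0]
    k = cell["level"].nunique()
    g = cell["group"].nunique()
    subj_means = cell.groupby("participant_id")["y"].mean()
    group_means = cell.groupby("group")["y"].mean()
    level_means = cell.groupby("level")["y"].mean()
    cell_means = cell.groupby(["group", "level"])["y"].mean()

    ss_group = k * n_per_group * ((group_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_within_subj_between = ss_subj - ss_group  # error for group effect
    ss_level = g * n_per_group * ((level_means - grand) ** 2).sum()
    ss_cells = n_per_group * ((cell_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_level
    ss_total = ((cell["y"] - grand) ** 2).sum()
    ss_err_within = ss_total - ss_subj - ss_level - ss_inter

    n_subj = g * n_per_group
    df_group, df_err_b = g - 1, n_subj - g
    df_level, df_err_w = k - 1, (k - 1) * (n_subj - g)
    f_group = (ss_group / df_group) / (ss_within_subj_between / df_err_b)
    f_level = (ss_level / df_level) / (ss_err_within / df_err_w)
    f_inter = (ss_inter / (df_group * df_level)) / (ss_err_within / df_err_w)
    return f_group, f_level, f_inter, (df_level, df_err_w)


class TestRMAnova:
    def test_level_effect_on_declining_accuracy(self, preset_cohort):
        tab = rm_anova(preset_cohort, "outcome").set_index("Source")
        assert tab.loc["level", "p_unc"] < 0.001
        # groups are matched: the level effect dwarfs any group effect
        assert tab.loc["level", "F"] > 20 * tab.loc["group", "F"]

    def test_group_effect_on_confidence(self, preset_cohort):
        tab = rm_anova(preset_cohort, "confidence").set_index("Source")
        assert tab.loc["group", "p_unc"] < 0.01
        assert tab.loc["level", "DF1"] == 2
        assert tab.loc["level", "DF2"] == 2 * (58 - 2)

    def test_matches_textbook_oracle_on_toy_data(self):
        rng = np.random.default_rng(4)
        rows = []
        for gi, group in enumerate(["OCD", "control"]):
            for s in range(5):
                pid = f"{group}{s}"
                for lv in (1, 2):
                    rows.append(
                        dict(participant_id=pid, group=group, level=lv,
                             y=10 + 2 * gi + 3 * lv + rng.normal(0, 1))
                    )
        cell = pd.DataFrame(rows)
        # feed through the pipeline via a minimal cohort whose per-cell mean
        # equals y (one trial per cell)
        trials = cell.rename(columns={"y": "outcome"}).drop(columns="group").assign(
            trial=0, block=0, shift=0, shift_type="none", choice=0,
            confidence=50.0, rt=1.0,
        )
        demo = cell[["participant_id", "group"]].drop_duplicates().assign(
            age=30, gender=1, iq=30.0
        )
        cohort = rs.CohortDataset(trials, demo, None, None)
        tab = rm_anova(cohort, "outcome").set_index("Source")
        f_group, f_level, f_inter, dfs = _manual_mixed_anova(cell)
        assert tab.loc["group", "F"] == pytest.approx(f_group, rel=1e-6)
        assert tab.loc["level", "F"] == pytest.approx(f_level, rel=1e-6)
        assert tab.loc["Interaction", "F"] == pytest.approx(f_inter, rel=1e-6)
        assert (tab.loc["level", "DF1"], tab.loc["level", "DF2"]) == dfs

    def test_missing_level_rejected(self, small_cohort):
        trials = small_cohort.trials
        pid = trials["participant_id"].iloc[0]
        trimmed = trials[~((trials["participant_id"] == pid) & (trials["level"] == 3))]
        cohort = rs.CohortDataset(trimmed, small_cohort.demographics, None, None)
        with pytest.raises(ValueError):
            rm_anova(cohort, "outcome")
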
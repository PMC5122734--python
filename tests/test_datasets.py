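"""Synthetic cohort generator and descriptives."""

import numpy as np
import pandas as pd
import pytest

from hierddm import CohortConfig, descriptive_table, generate_cohort
from hierddm.datasets import DEFAULT_GROUP_MEANS, FULL_GROUP_SIZES, GROUPS, TASKS
from hierddm.wfpt import DDMParameters, mean_decision_time, prob_upper

from conftest import make_trials


class TestConfig:
    def test_full_scale_defaults(self):
        cfg = CohortConfig()
        assert cfg.group_sizes == {"young": 384, "high_old": 384, "low_old": 1039}
        assert cfg.tasks == TASKS and cfg.trials_per_task == 80
        assert cfg.deadline == 3.0

    def test_default_means_cover_design(self):
        assert set(DEFAULT_GROUP_MEANS) == set(TASKS)
        for task in TASKS:
            assert set(DEFAULT_GROUP_MEANS[task]) == set(GROUPS)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(group_sizes={"young": 0})
        with pytest.raises(ValueError):
            CohortConfig(contaminant_rate=0.5)
        with pytest.raises(ValueError):
            CohortConfig(between_subject_cv=-0.1)


class TestGenerateCohort:
    @pytest.fixture(scope="class")
    def small(self):
        cfg = CohortConfig(seed=3).desk(n_per_group=8, tasks=("letter", "lexical"))
        return cfg, *generate_cohort(cfg)

    def test_stimulus_split_forty_forty(self, small):
        _, trials, _ = small
        counts = trials.groupby(["subject_id", "task"], observed=True)[
            "stimulus_type"].value_counts().unstack()
        assert (counts["target"] == 40).all()
        assert (counts["nontarget"] == 40).all()

    def test_same_seed_identical_cohort(self, small):
        cfg, trials, truth = small
        trials2, truth2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(trials, trials2)
        pd.testing.assert_frame_equal(truth, truth2)

    def test_truth_table_alignment(self, small):
        _, trials, truth = small
        assert len(truth) == trials["subject_id"].nunique() * 2
        assert set(truth.columns) == {"subject_id", "group", "task", "t", "a", "v"}
        assert (truth["a"] > 0).all() and (truth["t"] > 0).all()

    def test_truth_means_near_config_means(self):
        """Generated group means sit within standard error of the configured
        generating means."""
        cfg = CohortConfig(seed=5).desk(n_per_group=60, tasks=("letter",))
        _, truth = generate_cohort(cfg)
        for group in GROUPS:
            m_t, m_a, m_v = DEFAULT_GROUP_MEANS["letter"][group]
            sub = truth[truth["group"] == group]
            se = 0.10 / np.sqrt(len(sub))  # cv / sqrt(n), as relative error
            assert sub["t"].mean() == pytest.approx(m_t, rel=4 * se)
            assert sub["a"].mean() == pytest.approx(m_a, rel=4 * se)
            assert sub["v"].mean() == pytest.approx(m_v, rel=4 * se)

    def test_deadline_hits_are_flagged_not_dropped(self):
        """Slow parameters under a tight deadline: non-responses appear as
        missing RT and missing correctness."""
        cfg = CohortConfig(group_sizes={"young": 4}, tasks=("phonological",),
                           seed=8)
        trials, _ = generate_cohort(cfg)
        nonresp = trials["rt_ms"].isna()
        assert nonresp.any()
        assert trials.loc[nonresp, "correct"].isna().all()
        assert trials.loc[~nonresp, "rt_ms"].max() <= 3000 + 1

    def test_homogeneous_cohort_matches_closed_forms(self):
        """cv = 0, no contaminants: empirical mean RT and accuracy match the
        analytic values for the generating parameters (~601 ms, ~0.997 for
        young letter identification)."""
        cfg = CohortConfig(group_sizes={"young": 30}, tasks=("letter",),
                           between_subject_cv=0.0, seed=13)
        trials, _ = generate_cohort(cfg)
        ok = trials.dropna(subset=["rt_ms"])
        p = DDMParameters(*DEFAULT_GROUP_MEANS["letter"]["young"])
        expect_rt = (p.t_nd + mean_decision_time(p)) * 1000
        assert ok["rt_ms"].mean() == pytest.approx(expect_rt, rel=0.02)
        assert ok["correct"].mean() == pytest.approx(prob_upper(p), abs=0.005)

    def test_contaminants_injected_at_requested_rate(self):
        cfg = CohortConfig(group_sizes={"young": 20}, tasks=("letter",),
                           contaminant_rate=0.10, seed=19)
        trials, _ = generate_cohort(cfg)
        # contaminant RTs are uniform on [200, 3000] ms: far more mass below
        # the 300 ms floor than the diffusion process produces
        frac_fast = (trials["rt_ms"] < 300).mean()
        assert frac_fast == pytest.approx(0.10 * 100 / 2800, abs=0.01)


class TestDescriptiveTable:
    def test_single_subject_means(self):
        df = make_trials([("s1", "young", "letter", "target", True, 400.0),
                          ("s1", "young", "letter", "nontarget", True, 600.0)])
        out = descriptive_table(df)
        row = out[(out["task"] == "letter") & (out["group"] == "young")].iloc[0]
        assert row["mean_rt_ms"] == 500.0
        assert row["accuracy_pct"] == 100.0
        assert row["n_trials"] == 2

    def test_absent_cells_reported_missing(self):
        df = make_trials([("s1", "young", "letter", "target", True, 400.0),
                          ("s2", "low_old", "lexical", "target", False, 700.0)])
        out = descriptive_table(df).set_index(["task", "group"])
        assert np.isnan(out.loc[("letter", "low_old"), "mean_rt_ms"])
        assert np.isnan(out.loc[("lexical", "young"), "mean_rt_ms"])

    def test_full_default_young_letter_cell(self):
        """A cohort at the default generating means reproduces the published
        descriptive cell (~599-605 ms) for young letter identification."""
        cfg = CohortConfig(seed=23).desk(n_per_group=40, tasks=("letter",))
        trials, _ = generate_cohort(cfg)
        out = descriptive_table(trials.dropna(subset=["rt_ms"]))
        row = out[(out["task"] == "letter") & (out["group"] == "young")].iloc[0]
        assert 580 < row["mean_rt_ms"] < 625
        assert row["accuracy_pct"] > 99.0
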
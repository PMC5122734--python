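"""Shared fixtures.

The two recovery fixtures (letter / lexical) are the expensive session-wide
runs: a desk-scale synthetic cohort generated from the published group
means, preprocessed and fitted with the desk MCMC preset.  Everything else
is cheap and local to its test module.
"""

import numpy as np
import pandas as pd
import pytest

from hierddm import CohortConfig, HierarchicalDDM, TrialFilter, generate_cohort

# fixed study-condition seeds for the recovery runs
LETTER_COHORT_SEED = 11
LETTER_FIT_SEED = 3
LEXICAL_COHORT_SEED = 5
LEXICAL_FIT_SEED = 5
N_PER_GROUP = 30


def make_trials(rows):
    """Build a small trial table from (subject, group, task, stim, correct, rt_ms)."""
    return pd.DataFrame(rows, columns=["subject_id", "group", "task",
                                       "stimulus_type", "correct", "rt_ms"])


@pytest.fixture(scope="session")
def letter_recovery():
    """Desk-scale letter-identification recovery run (cohort, truth, fit)."""
    cfg = CohortConfig(seed=LETTER_COHORT_SEED).desk(n_per_group=N_PER_GROUP,
                                                     tasks=("letter",))
    trials, truth = generate_cohort(cfg)
    filt = TrialFilter()
    clean = filt.fit_transform(trials)
    est = HierarchicalDDM.from_preset("desk", seed=LETTER_FIT_SEED)
    est.fit(clean)
    return {"config": cfg, "trials": trials, "clean": clean, "truth": truth,
            "filter": filt, "est": est}


@pytest.fixture(scope="session")
def lexical_recovery():
    """Desk-scale lexical-decision recovery run."""
    cfg = CohortConfig(seed=LEXICAL_COHORT_SEED).desk(n_per_group=N_PER_GROUP,
                                                      tasks=("lexical",))
    trials, truth = generate_cohort(cfg)
    clean = TrialFilter().fit_transform(trials)
    est = HierarchicalDDM.from_preset("desk", seed=LEXICAL_FIT_SEED)
    est.fit(clean)
    return {"config": cfg, "trials": trials, "clean": clean, "truth": truth,
            "est": est}


@pytest.fixture(scope="session")
def tiny_fit():
    """A very small but genuine fit (2 groups, few subjects, short chains)
    for exercising downstream reporting without the desk cost."""
    means = {"letter": {"young": (0.38, 1.6, 3.5), "low_old": (0.46, 2.0, 3.0)}}
    cfg = CohortConfig(group_sizes={"young": 8, "low_old": 8}, tasks=("letter",),
                       group_params=means, seed=21)
    trials, truth = generate_cohort(cfg)
    clean = TrialFilter().fit_transform(trials)
    est = HierarchicalDDM(n_chains=3, n_iterations=2500, burn_in=1000, seed=9)
    est.fit(clean)
    return {"config": cfg, "trials": trials, "clean": clean, "truth": truth,
            "est": est}
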
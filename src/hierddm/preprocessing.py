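"""Trial-level exclusion rules for two-choice RT tables.

Two rules, applied in order: (1) a fast-guess floor removing RTs strictly
below 300 ms; (2) a per-cell dispersion rule removing RTs deviating more
than 2.5 sample standard deviations from the subject's mean within each
task x stimulus-type cell.  Non-response (deadline) trials carry a missing
RT and are dropped before either rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["exclude_fast_guesses", "exclude_sd_outliers", "TrialFilter"]

TRIAL_COLUMNS = ["subject_id", "group", "task", "stimulus_type", "correct", "rt_ms"]
_CELL_KEYS = ["subject_id", "task", "stimulus_type"]


def exclude_fast_guesses(trials: pd.DataFrame, floor_ms: float = 300.0):
    """Remove trials with rt_ms strictly below floor_ms (fast guesses).

    Returns (kept, n_removed); row order is preserved.  A trial at exactly
    the floor is kept.
    """
    if floor_ms <= 0:
        raise ValueError("floor_ms must be positive")
    keep = trials["rt_ms"] >= floor_ms
    return trials[keep], int((~keep).sum())


def exclude_sd_outliers(trials: pd.DataFrame, k: float = 2.5):
    """Remove trials deviating more than k sample SDs from their cell mean.

    Cells are subject x task x stimulus-type.  Mean and SD (ddof=1) are
    computed once per cell, including candidate outliers; the rule is a
    single pass, not iterated.  Cells with fewer than two trials are left
    untouched.  Returns (kept, n_removed).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if trials.empty:
        return trials, 0
    grp = trials.groupby(_CELL_KEYS, observed=True)["rt_ms"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1; NaN for singleton cells
    dev = (trials["rt_ms"] - mean).abs()
    remove = dev > k * sd
    remove = remove.fillna(False)
    return trials[~remove], int(remove.sum())


class TrialFilter(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer applying both exclusion rules.

    Parameters
    ----------
    floor_ms : fast-guess floor in milliseconds (default 300; strict <).
    sd_multiplier : per-cell SD cutoff (default 2.5).

    After ``transform`` the attributes ``n_nonresponse_``, ``n_fast_`` and
    ``n_sd_outlier_`` hold the counts removed by each step and
    ``exclusion_log_`` a per-rule summary table.
    """

    def __init__(self, floor_ms: float = 300.0, sd_multiplier: float = 2.5):
        self.floor_ms = floor_ms
        self.sd_multiplier = sd_multiplier

    def fit(self, X: pd.DataFrame, y=None):
        # no state is learned; the rules are per-cell at transform time
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        responded = X["rt_ms"].notna()
        kept = X[responded]
        self.n_nonresponse_ = int((~responded).sum())
        kept, self.n_fast_ = exclude_fast_guesses(kept, self.floor_ms)
        kept, self.n_sd_outlier_ = exclude_sd_outliers(kept, self.sd_multiplier)
        n_in = len(X)
        self.removed_fraction_ = (n_in - len(kept)) / n_in if n_in else 0.0
        self.exclusion_log_ = pd.DataFrame(
            {
                "rule": ["nonresponse", "fast_guess_floor", "sd_outlier"],
                "n_removed": [self.n_nonresponse_, self.n_fast_, self.n_sd_outlier_],
            }
        )
        return kept

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).transform(X)
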
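"""High-level estimator tying the pipeline stages together.

``HierarchicalDDM`` is an sklearn-style estimator: construct with sampling
settings, call ``fit`` on a preprocessed long-format trial table, then read
fitted attributes (``samples_``, ``convergence_``, ``summary()``) or derive
posterior-predictive checks and group comparisons from the fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._kernels import DENSITY_TOL
from .diagnostics import RHAT_THRESHOLD, convergence_report, summarize_traces
from .group_inference import ComparisonReport, compare_all
from .model import PARAM_NAMES, build_spec
from .ppc import QUANTILE_PROBS, PPCReport, compare_quantiles, simulate_replicates
from .sampler import find_map, run_chains

__all__ = ["HierarchicalDDM", "PRESETS"]

#: sampling presets: the full-scale profile (3 chains x 15,000 draws,
#: 5,000 burn-in, as in the original analysis) and a reduced desk profile
#: for small synthetic cohorts
PRESETS = {
    "full": {"n_chains": 3, "n_iterations": 15000, "burn_in": 5000},
    "desk": {"n_chains": 3, "n_iterations": 10000, "burn_in": 3000},
}


class HierarchicalDDM(BaseEstimator):
    """Hierarchical Bayesian drift-diffusion model for two-choice RT data.

    One independent hierarchy per task: each subject's non-decision time t,
    boundary separation a and drift rate v are drawn from its age group's
    location/spread, the start point is fixed at 0.5 (no bias) and
    inter-trial variabilities at 0.  Fitting runs a MAP search followed by
    multi-chain adaptive Metropolis-within-Gibbs.

    Parameters
    ----------
    groups, tasks : label orders; default inferred from the data.
    n_chains, n_iterations, burn_in : MCMC profile (see ``PRESETS``).
    seed : base seed for MAP jitter and all chains.
    target_acceptance : adapted per-block proposal acceptance rate.
    rhat_threshold : convergence criterion on the classic R-hat.

    Attributes (after fit)
    ----------------------
    spec_ : the hierarchical declaration (owns the location-parameter count).
    map_state_ : MAP starting state.
    samples_ : PosteriorSamples over all tasks.
    convergence_ : ConvergenceReport; converged_ : bool.
    """

    def __init__(self, groups=None, tasks=None, n_chains: int = 3,
                 n_iterations: int = 3000, burn_in: int = 1000, seed: int = 0,
                 target_acceptance: float = 0.3, tol: float = DENSITY_TOL,
                 rhat_threshold: float = RHAT_THRESHOLD, map_sweeps: int = 2):
        self.groups = groups
        self.tasks = tasks
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.seed = seed
        self.target_acceptance = target_acceptance
        self.tol = tol
        self.rhat_threshold = rhat_threshold
        self.map_sweeps = map_sweeps

    @classmethod
    def from_preset(cls, preset: str, **kwargs) -> "HierarchicalDDM":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        return cls(**{**PRESETS[preset], **kwargs})

    def _labels(self, trials: pd.DataFrame):
        groups = tuple(self.groups) if self.groups is not None else tuple(
            pd.unique(trials["group"]))
        tasks = tuple(self.tasks) if self.tasks is not None else tuple(
            pd.unique(trials["task"]))
        return tasks, groups

    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalDDM":
        """Fit the hierarchy to a preprocessed trial table.

        X needs columns subject_id, group, task, correct, rt_ms; rows with
        missing RTs must already have been removed by preprocessing.
        """
        trials = X
        if trials["rt_ms"].isna().any():
            raise ValueError("trials contain missing RTs; preprocess first")
        tasks, groups = self._labels(trials)
        self.spec_ = build_spec(tasks, groups)
        self.map_state_ = find_map(self.spec_, trials, seed=self.seed,
                                   n_sweeps=self.map_sweeps, tol=self.tol)
        self.samples_ = run_chains(self.spec_, trials, self.map_state_,
                                   n_chains=self.n_chains,
                                   n_iterations=self.n_iterations,
                                   burn_in=self.burn_in, seed=self.seed,
                                   target_acc=self.target_acceptance, tol=self.tol)
        self.convergence_ = convergence_report(self.samples_,
                                               threshold=self.rhat_threshold)
        self.converged_ = self.convergence_.all_passed
        self.n_features_in_ = trials.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "samples_"):
            raise AttributeError("this HierarchicalDDM instance is not fitted yet")

    def summary(self) -> pd.DataFrame:
        """Group-location posterior table: one row per (task, group,
        parameter) with mean, SD and equal-tailed 95% interval."""
        self._check_fitted()
        names = [f"mu_{p}[{task},{g}]"
                 for task in self.samples_.meta["tasks"]
                 for g in self.spec_.groups for p in PARAM_NAMES]
        summ = summarize_traces(self.samples_, parameters=names).reset_index()
        parsed = summ["parameter"].str.extract(r"mu_(\w+)\[([^,]+),([^\]]+)\]")
        summ.insert(0, "task", parsed[1])
        summ.insert(1, "group", parsed[2])
        summ.insert(2, "param", parsed[0])
        return summ.drop(columns="parameter")

    def group_posterior_mean(self, task: str, group: str, param: str) -> float:
        self._check_fitted()
        return float(np.mean(self.samples_.get(f"mu_{param}[{task},{group}]")))

    def compare_groups(self) -> ComparisonReport:
        """Pairwise exceedance probabilities for all group-location params."""
        self._check_fitted()
        return compare_all(self.samples_, self.spec_)

    def ppc(self, trials: pd.DataFrame, n_rep: int = 500, seed: int | None = None,
            deadline: float | None = 3.0, quantile_probs=QUANTILE_PROBS) -> PPCReport:
        """Posterior-predictive check against the fitted trials."""
        self._check_fitted()
        design = (trials.groupby(["subject_id", "group", "task"], observed=True)
                  .size().rename("n_trials").reset_index())
        reps = simulate_replicates(self.samples_, design, n_rep=n_rep,
                                   seed=self.seed if seed is None else seed,
                                   deadline=deadline)
        return compare_quantiles(trials, reps, quantile_probs=quantile_probs)
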
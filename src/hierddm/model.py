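"""Hierarchical model declaration and posterior evaluation.

One independent model per task.  Within a task, each subject's non-decision
time t, boundary separation a and drift rate v are drawn from normal
distributions (truncated to the parameter domain for t and a) centered on
their age group's location with a group spread; the start point is fixed at
z_rel = 0.5 and all inter-trial variabilities at 0.  Group locations get
weakly-informative truncated-normal priors, group spreads half-normal
priors.  The "model size" quoted for the full design counts group
locations: |tasks| x |groups| x |{t, a, v}|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from ._kernels import DENSITY_TOL

__all__ = ["Priors", "HierarchicalSpec", "TaskState", "ParameterState",
           "TaskData", "build_spec", "log_posterior"]

PARAM_NAMES = ("t", "a", "v")
#: domain lower bound of each subject-level parameter (t, a positive; v free)
PARAM_LOWER = np.array([0.0, 0.0, -np.inf])


class SpecificationError(ValueError):
    """Invalid model declaration (duplicate or empty labels)."""


class CoverageError(KeyError):
    """A subject in the data has no parameters in the state."""


@dataclass(frozen=True)
class Priors:
    """Weakly informative priors on the group level.

    Locations: truncated normals on each parameter's natural domain —
    t ~ N(0.4, 0.3) on [0, inf), a ~ N(2, 1.5) on (0, inf), v ~ N(2, 3).
    Spreads: half-normal(1).  Entries are ordered (t, a, v).
    """

    loc: tuple = (0.4, 2.0, 2.0)
    scale: tuple = (0.3, 1.5, 3.0)
    lower: tuple = (0.0, 0.0, -np.inf)
    spread_scale: tuple = (1.0, 1.0, 1.0)

    def arrays(self):
        return (np.asarray(self.loc, float), np.asarray(self.scale, float),
                np.asarray(self.lower, float), np.asarray(self.spread_scale, float))


@dataclass(frozen=True)
class HierarchicalSpec:
    """Which parameters vary by individual/group/task, and the priors.

    Free parameters (t, a, v) vary per individual around group locations,
    separately per task; z_rel is fixed for everyone and inter-trial
    variabilities are zero.
    """

    tasks: tuple
    groups: tuple
    free_params: tuple = PARAM_NAMES
    z_rel: float = 0.5
    priors: Priors = field(default_factory=Priors)

    @property
    def n_location_parameters(self) -> int:
        return len(self.tasks) * len(self.groups) * len(self.free_params)

    def to_dict(self) -> dict:
        """Plain key/value form for config-file serialization."""
        return {
            "tasks": list(self.tasks),
            "groups": list(self.groups),
            "free_params": list(self.free_params),
            "z_rel": self.z_rel,
            "priors": {
                "location_loc": list(self.priors.loc),
                "location_scale": list(self.priors.scale),
                "location_lower": [float(x) for x in self.priors.lower],
                "spread_scale": list(self.priors.spread_scale),
            },
        }


def build_spec(tasks, groups, priors: Priors | None = None) -> HierarchicalSpec:
    """Declare one independent hierarchy per task over the given groups."""
    tasks = tuple(tasks)
    groups = tuple(groups)
    if not tasks or not groups:
        raise SpecificationError("tasks and groups must be non-empty")
    if len(set(tasks)) != len(tasks):
        raise SpecificationError(f"duplicate task labels: {tasks}")
    if len(set(groups)) != len(groups):
        raise SpecificationError(f"duplicate group labels: {groups}")
    return HierarchicalSpec(tasks=tasks, groups=groups,
                            priors=priors if priors is not None else Priors())


@dataclass
class TaskState:
    """Parameter values of one task's hierarchy.

    mu, sigma: (n_groups, 3) group locations/spreads ordered (t, a, v);
    theta: (n_subjects, 3) per-subject parameters; subjects lists the
    subject ids in theta's row order; subj_group maps each row to its
    group index in the spec's group order.
    """

    subjects: list
    subj_group: np.ndarray
    theta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def to_frame(self, task: str, groups) -> pd.DataFrame:
        rows = []
        for g, gname in enumerate(groups):
            for p, pname in enumerate(PARAM_NAMES):
                rows.append((task, gname, f"mu_{pname}", self.mu[g, p]))
                rows.append((task, gname, f"sigma_{pname}", self.sigma[g, p]))
        for i, sid in enumerate(self.subjects):
            for p, pname in enumerate(PARAM_NAMES):
                rows.append((task, sid, pname, self.theta[i, p]))
        return pd.DataFrame(rows, columns=["task", "unit", "parameter", "value"])


@dataclass
class ParameterState:
    """Per-task states keyed by task label."""

    tasks: dict

    def to_frame(self, spec: HierarchicalSpec) -> pd.DataFrame:
        return pd.concat(
            [st.to_frame(task, spec.groups) for task, st in self.tasks.items()],
            ignore_index=True,
        )


@dataclass
class TaskData:
    """One task's trials packed for the numba kernels (RTs in seconds)."""

    rts: np.ndarray
    uppers: np.ndarray
    subj_start: np.ndarray
    subj_end: np.ndarray
    subjects: list
    subj_group: np.ndarray

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, groups) -> "TaskData":
        group_index = {g: i for i, g in enumerate(groups)}
        df = trials.sort_values("subject_id", kind="stable")
        subjects, starts, ends, sgroup = [], [], [], []
        rts = (df["rt_ms"].to_numpy(float)) / 1000.0
        uppers = df["correct"].to_numpy(bool).astype(np.int8)
        sid_arr = df["subject_id"].to_numpy()
        grp_arr = df["group"].to_numpy()
        pos = 0
        n = len(df)
        while pos < n:
            sid = sid_arr[pos]
            end = pos
            while end < n and sid_arr[end] == sid:
                end += 1
            g = grp_arr[pos]
            if g not in group_index:
                raise SpecificationError(f"unknown group label {g!r}")
            subjects.append(sid)
            starts.append(pos)
            ends.append(end)
            sgroup.append(group_index[g])
            pos = end
        return cls(rts=rts, uppers=uppers,
                   subj_start=np.asarray(starts, np.int64),
                   subj_end=np.asarray(ends, np.int64),
                   subjects=subjects,
                   subj_group=np.asarray(sgroup, np.int64))


def _task_log_posterior(data: TaskData, state: TaskState, priors: Priors,
                        tol: float) -> float:
    loc, scale, lower, spread = priors.arrays()
    return _kernels.log_posterior_task(
        data.rts, data.uppers, data.subj_start, data.subj_end, data.subj_group,
        state.theta, state.mu, state.sigma,
        loc, scale, lower, spread, PARAM_LOWER, tol)


def log_posterior(spec: HierarchicalSpec, state: ParameterState,
                  trials: pd.DataFrame, tol: float = DENSITY_TOL) -> float:
    """Joint log posterior: trial likelihood + individual-level density +
    group-level prior, summed over the independent per-task hierarchies.

    Returns -inf for out-of-domain states.  Every subject present in
    ``trials`` must be covered by the state.
    """
    total = 0.0
    for task in spec.tasks:
        tdf = trials[trials["task"] == task]
        if tdf.empty and task not in state.tasks:
            continue
        st = state.tasks[task]
        data = TaskData.from_trials(tdf, spec.groups)
        covered = set(st.subjects)
        missing = [s for s in data.subjects if s not in covered]
        if missing:
            raise CoverageError(f"subjects without parameters in task {task!r}: {missing[:5]}")
        # align data rows with the state's subject order
        order = {s: i for i, s in enumerate(data.subjects)}
        idx = np.array([order[s] for s in st.subjects if s in order], np.int64)
        aligned = TaskData(rts=data.rts, uppers=data.uppers,
                           subj_start=data.subj_start[idx], subj_end=data.subj_end[idx],
                           subjects=[data.subjects[i] for i in idx],
                           subj_group=data.subj_group[idx])
        theta = np.array([st.theta[i] for i, s in enumerate(st.subjects) if s in order])
        st_aligned = TaskState(subjects=aligned.subjects, subj_group=aligned.subj_group,
                               theta=theta, mu=st.mu, sigma=st.sigma)
        lp = _task_log_posterior(aligned, st_aligned, spec.priors, tol)
        if lp == -np.inf:
            return -np.inf
        total += lp
    return total


# ---------------------------------------------------------------------------
# reference (scipy) implementations of the density pieces, used by tests to
# cross-check the numba path and by callers wanting the decomposition
# ---------------------------------------------------------------------------

def log_group_prior(spec: HierarchicalSpec, state: TaskState) -> float:
    """Log prior of one task's group locations and spreads (scipy path)."""
    loc, scale, lower, spread = spec.priors.arrays()
    total = 0.0
    for g in range(state.mu.shape[0]):
        for p in range(3):
            if np.isfinite(lower[p]):
                a_std = (lower[p] - loc[p]) / scale[p]
                total += stats.truncnorm.logpdf(state.mu[g, p], a_std, np.inf,
                                                loc=loc[p], scale=scale[p])
            else:
                total += stats.norm.logpdf(state.mu[g, p], loc[p], scale[p])
            total += stats.halfnorm.logpdf(state.sigma[g, p], scale=spread[p])
    return float(total)


def log_individual_density(spec: HierarchicalSpec, state: TaskState) -> float:
    """Log density of each subject's parameters under its group (scipy path)."""
    total = 0.0
    for i in range(state.theta.shape[0]):
        g = state.subj_group[i]
        for p in range(3):
            m, s = state.mu[g, p], state.sigma[g, p]
            if np.isfinite(PARAM_LOWER[p]):
                a_std = (PARAM_LOWER[p] - m) / s
                total += stats.truncnorm.logpdf(state.theta[i, p], a_std, np.inf,
                                                loc=m, scale=s)
            else:
                total += stats.norm.logpdf(state.theta[i, p], m, s)
    return float(total)
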
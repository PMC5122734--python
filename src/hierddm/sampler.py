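"""MAP initialization and multi-chain MCMC for the hierarchical model.

The sampler is adaptive Metropolis-within-Gibbs: scalar random-walk updates
for every subject-level parameter and every group location, a log-scale
random walk for group spreads.  Proposal scales adapt toward a target
acceptance rate during burn-in only and are frozen afterward, so the
retained portion of each chain satisfies detailed balance.  Independent
per-task hierarchies are sampled separately and their draws concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import _kernels
from ._kernels import DENSITY_TOL
from .model import (PARAM_LOWER, PARAM_NAMES, HierarchicalSpec, ParameterState,
                    TaskData, TaskState)

__all__ = ["PosteriorSamples", "find_map", "run_chains"]


class InitializationError(RuntimeError):
    """The optimizer found no finite-posterior starting point."""


class SamplerStallError(RuntimeError):
    """A proposal block accepted less than 1% of moves after adaptation."""


@dataclass
class PosteriorSamples:
    """Per-chain MCMC draws with burn-in bookkeeping.

    draws has shape (n_chains, n_iterations, n_parameters); burn-in draws
    are stored but flagged by ``burn_in`` and excluded from ``retained``.
    """

    draws: np.ndarray
    param_names: list
    burn_in: int
    seed: int
    acceptance: np.ndarray = None
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.draws.shape[1]

    @property
    def n_retained(self) -> int:
        return self.n_chains * (self.n_iterations - self.burn_in)

    @property
    def retained(self) -> np.ndarray:
        return self.draws[:, self.burn_in:, :]

    def index(self, name: str) -> int:
        try:
            return self.param_names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def get(self, name: str, retained: bool = True) -> np.ndarray:
        """(n_chains, n_draws) array for one parameter."""
        src = self.retained if retained else self.draws
        return src[:, :, self.index(name)]

    def to_frame(self, retained_only: bool = False) -> pd.DataFrame:
        """Long-format (parameter, chain, iteration, value) table."""
        src = self.retained if retained_only else self.draws
        offset = self.burn_in if retained_only else 0
        nc, ni, npar = src.shape
        chain = np.repeat(np.arange(nc), ni * npar)
        iteration = np.tile(np.repeat(np.arange(ni) + offset, npar), nc)
        names = np.tile(np.asarray(self.param_names, dtype=object), nc * ni)
        return pd.DataFrame({"parameter": names, "chain": chain,
                             "iteration": iteration, "value": src.ravel()})


# ---------------------------------------------------------------------------
# moment-based (EZ-style) starting values
# ---------------------------------------------------------------------------

def _moment_start(rts: np.ndarray, uppers: np.ndarray) -> np.ndarray:
    """Closed-form method-of-moments diffusion estimates from accuracy and
    the mean/variance of correct RTs (s = 1).  Used only as a starting
    point, so edge cases are clamped rather than rejected."""
    n = len(rts)
    pc = float(np.mean(uppers))
    eps = 1.0 / (2.0 * n)
    pc = min(max(pc, eps), 1.0 - eps)
    if abs(pc - 0.5) < eps:
        pc = 0.5 + eps
    correct = rts[uppers == 1]
    if len(correct) < 2:
        correct = rts
    mrt = float(np.mean(correct))
    vrt = max(float(np.var(correct, ddof=1)), 1e-4)
    L = np.log(pc / (1.0 - pc))
    x = L * (L * pc * pc - L * pc + pc - 0.5) / vrt
    v = np.sign(pc - 0.5) * abs(x) ** 0.25
    v = float(np.clip(v, -8.0, 8.0))
    a = float(np.clip(L / v if v != 0 else 1.5, 0.3, 5.0))
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(-v * a)) / (1.0 + np.exp(-v * a))
    t_nd = mrt - mdt
    t_nd = float(np.clip(t_nd, 0.05, np.min(rts) - 1e-3))
    return np.array([t_nd, a, v])


def _subject_objective(data: TaskData, i: int, mu, sigma, g: int, tol: float):
    lower = PARAM_LOWER

    def neg(x):
        t_nd, a, v = x
        if a <= 0.0 or t_nd < 0.0:
            return 1e12
        ll = _kernels.loglik_subject(data.rts[data.subj_start[i]:data.subj_end[i]],
                                     data.uppers[data.subj_start[i]:data.subj_end[i]],
                                     t_nd, a, v, tol)
        if ll == -np.inf:
            return 1e12
        for p in range(3):
            lp = _kernels.truncnorm_logpdf(x[p], mu[g, p], sigma[g, p], lower[p])
            if lp == -np.inf:
                return 1e12
            ll += lp
        return -ll

    return neg


def _group_objective(theta_gp: np.ndarray, p: int, priors_arrays):
    loc, scale, lower, spread = priors_arrays

    def neg(x):
        m, log_s = x
        s = np.exp(log_s)
        lp = _kernels.truncnorm_logpdf(m, loc[p], scale[p], lower[p])
        lp += _kernels.halfnorm_logpdf(s, spread[p])
        if lp == -np.inf:
            return 1e12
        for val in theta_gp:
            q = _kernels.truncnorm_logpdf(val, m, s, PARAM_LOWER[p])
            if q == -np.inf:
                return 1e12
            lp += q
        return -lp

    return neg


def _map_task(data: TaskData, spec: HierarchicalSpec, n_sweeps: int,
              tol: float) -> TaskState:
    S = len(data.subjects)
    G = len(spec.groups)
    pa = spec.priors.arrays()
    loc = pa[0]
    if S == 0:
        # no data: the posterior is the prior; locations at the prior mode,
        # spreads at a small floor standing in for the boundary mode at 0
        return TaskState(subjects=[], subj_group=np.empty(0, np.int64),
                         theta=np.empty((0, 3)),
                         mu=np.tile(loc, (G, 1)), sigma=np.full((G, 3), 1e-3))

    theta = np.empty((S, 3))
    for i in range(S):
        theta[i] = _moment_start(data.rts[data.subj_start[i]:data.subj_end[i]],
                                 data.uppers[data.subj_start[i]:data.subj_end[i]])
    mu = np.empty((G, 3))
    sigma = np.empty((G, 3))

    def refresh_group():
        for g in range(G):
            sel = data.subj_group == g
            if not sel.any():
                mu[g] = loc
                sigma[g] = 0.1
                continue
            th = theta[sel]
            mu[g] = th.mean(axis=0)
            sd = th.std(axis=0, ddof=1) if sel.sum() > 1 else np.zeros(3)
            sigma[g] = np.maximum(sd, np.maximum(0.03 * np.abs(mu[g]), 0.01))

    refresh_group()
    for _ in range(n_sweeps):
        for i in range(S):
            g = data.subj_group[i]
            res = optimize.minimize(_subject_objective(data, i, mu, sigma, g, tol),
                                    theta[i], method="Nelder-Mead",
                                    options={"maxiter": 200, "xatol": 1e-4, "fatol": 1e-4})
            if np.isfinite(res.fun) and res.fun < 1e11:
                theta[i] = res.x
        for g in range(G):
            sel = data.subj_group == g
            if not sel.any():
                continue
            for p in range(3):
                res = optimize.minimize(_group_objective(theta[sel, p], p, pa),
                                        np.array([mu[g, p], np.log(sigma[g, p])]),
                                        method="Nelder-Mead",
                                        options={"maxiter": 200})
                if np.isfinite(res.fun) and res.fun < 1e11:
                    mu[g, p] = res.x[0]
                    sigma[g, p] = np.exp(res.x[1])
    return TaskState(subjects=list(data.subjects), subj_group=data.subj_group.copy(),
                     theta=theta, mu=mu, sigma=sigma)


def find_map(spec: HierarchicalSpec, trials: pd.DataFrame, start_grid=None,
             seed: int = 0, n_sweeps: int = 2, tol: float = DENSITY_TOL) -> ParameterState:
    """Approximate posterior-mode state by coordinate ascent.

    Subjects start at method-of-moments estimates (or at ``start_grid``
    points when given) and are refined by derivative-free optimization,
    alternating with group-level updates.  With no trials the prior mode is
    returned.  Deterministic given (data, seed).
    """
    from .model import log_posterior  # local import to avoid cycle at module load

    states = {}
    for task in spec.tasks:
        tdf = trials[trials["task"] == task] if len(trials) else trials
        data = TaskData.from_trials(tdf, spec.groups) if len(tdf) else TaskData(
            rts=np.empty(0), uppers=np.empty(0, np.int8),
            subj_start=np.empty(0, np.int64), subj_end=np.empty(0, np.int64),
            subjects=[], subj_group=np.empty(0, np.int64))
        states[task] = _map_task(data, spec, n_sweeps, tol)
    state = ParameterState(tasks=states)
    if len(trials):
        lp = log_posterior(spec, state, trials, tol)
        if not np.isfinite(lp):
            raise InitializationError("MAP search ended at a non-finite posterior; "
                                      "check RT units (expected ms) and group labels")
    return state


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------

def _jitter_state(st: TaskState, rng: np.random.Generator, rel: float,
                  data: TaskData) -> TaskState:
    theta = st.theta * (1.0 + rel * rng.standard_normal(st.theta.shape))
    theta[:, 0] = np.abs(theta[:, 0])
    theta[:, 1] = np.abs(theta[:, 1])
    # keep every subject's non-decision time below its fastest trial
    for i in range(len(st.subjects)):
        min_rt = data.rts[data.subj_start[i]:data.subj_end[i]].min()
        theta[i, 0] = min(theta[i, 0], min_rt - 1e-3)
    mu = st.mu * (1.0 + rel * rng.standard_normal(st.mu.shape))
    mu[:, :2] = np.abs(mu[:, :2])
    sigma = st.sigma * np.exp(rel * rng.standard_normal(st.sigma.shape))
    return TaskState(subjects=st.subjects, subj_group=st.subj_group,
                     theta=theta, mu=mu, sigma=sigma)


def _param_names_task(task: str, groups, subjects) -> list:
    names = [f"mu_{p}[{task},{g}]" for g in groups for p in PARAM_NAMES]
    names += [f"sigma_{p}[{task},{g}]" for g in groups for p in PARAM_NAMES]
    names += [f"{p}[{task},{s}]" for s in subjects for p in PARAM_NAMES]
    return names


def run_chains(spec: HierarchicalSpec, trials: pd.DataFrame, init: ParameterState,
               n_chains: int = 3, n_iterations: int = 15000, burn_in: int = 5000,
               seed: int = 0, target_acc: float = 0.3, jitter: float = 0.01,
               tol: float = DENSITY_TOL) -> PosteriorSamples:
    """Sample the posterior with ``n_chains`` independent chains.

    Chains start from ``init`` with small multiplicative jitter (different
    per chain); adaptation of proposal scales stops at ``burn_in``.
    Bit-reproducible under identical (seed, data, init).
    """
    if n_chains < 2:
        raise ValueError("n_chains must be >= 2 for convergence assessment")
    if n_iterations <= burn_in:
        raise ValueError("n_iterations must exceed burn_in")

    all_names = []
    per_task = []
    per_task_acc = []
    pa_loc, pa_scale, pa_lower, pa_spread = spec.priors.arrays()
    for ti, task in enumerate(spec.tasks):
        tdf = trials[trials["task"] == task]
        if tdf.empty:
            continue
        data = TaskData.from_trials(tdf, spec.groups)
        st = init.tasks[task]
        if list(st.subjects) != list(data.subjects):
            raise ValueError(f"init state and data disagree on subjects for task {task!r}")
        names = _param_names_task(task, spec.groups, data.subjects)
        chains = []
        accs = []
        for c in range(n_chains):
            chain_seed = (seed + 100003 * c + 7919 * ti) % 2**31
            rng = np.random.default_rng(chain_seed)
            st_c = _jitter_state(st, rng, jitter, data)
            draws, rates = _kernels.run_mcmc_task(
                data.rts, data.uppers, data.subj_start, data.subj_end,
                data.subj_group, len(spec.groups),
                st_c.theta, st_c.mu, st_c.sigma,
                pa_loc, pa_scale, pa_lower, pa_spread, PARAM_LOWER,
                n_iterations, burn_in, target_acc, chain_seed, tol)
            chains.append(draws)
            accs.append(rates)
        acc = np.vstack(accs)
        if np.any(acc < 0.01):
            worst = names[int(np.argmin(acc.min(axis=0)))]
            raise SamplerStallError(
                f"block {worst} accepted {acc.min():.3%} of moves after adaptation")
        per_task.append(np.stack(chains))
        per_task_acc.append(acc)
        all_names.extend(names)
    if not per_task:
        raise ValueError("no trials for any task in the spec")
    draws = np.concatenate(per_task, axis=2)
    return PosteriorSamples(draws=draws, param_names=all_names, burn_in=burn_in,
                            seed=seed, acceptance=np.concatenate(per_task_acc, axis=1),
                            meta={"n_chains": n_chains, "n_iterations": n_iterations,
                                  "groups": list(spec.groups),
                                  "tasks": [t for t in spec.tasks
                                            if not trials[trials["task"] == t].empty]})
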
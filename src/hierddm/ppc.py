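"""Posterior-predictive checking against RT quantiles of correct responses.

For each replicate dataset, one posterior draw is selected uniformly from
the retained draws per subject (propagating full parameter uncertainty) and
that subject's complete trial set is re-simulated.  Observed and simulated
RT quantiles (0.1, 0.3, 0.5, 0.7, 0.9 by default) of correct responses are
then compared: Pearson correlation of observed vs replicate-mean quantiles,
and coverage of the equal-tailed 95% replicate band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .sampler import PosteriorSamples

__all__ = ["PPCReport", "ReplicateSet", "simulate_replicates", "compare_quantiles"]

QUANTILE_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class ReplicateSet:
    """Simulated replicate trial sets in long form.

    trials: DataFrame with columns rep, subject_id, group, task, rt_ms,
    correct (NaN rt / NA correct for deadline non-responses).
    """

    trials: pd.DataFrame
    n_rep: int
    seed: int

    def accuracy_per_rep(self) -> pd.Series:
        resp = self.trials.dropna(subset=["rt_ms"])
        return resp.groupby("rep")["correct"].mean()


def simulate_replicates(samples: PosteriorSamples, design: pd.DataFrame,
                        n_rep: int = 500, seed: int = 0,
                        deadline: float | None = 3.0, dt: float = 1e-4) -> ReplicateSet:
    """Simulate ``n_rep`` replicate datasets from the fitted posterior.

    design: one row per (subject_id, group, task) with an ``n_trials``
    column matching the fitted data.  Each replicate draws one retained
    posterior draw per subject and simulates that subject's full trial set.
    """
    if samples.n_retained == 0:
        raise ValueError("no retained draws: remove burn-in before simulating replicates")
    rng = np.random.default_rng(seed)
    dl = -1.0 if deadline is None else float(deadline)
    recs_rep, recs_sid, recs_grp, recs_task = [], [], [], []
    rts_all, corr_all = [], []
    for row in design.itertuples(index=False):
        sid, group, task, n_tr = row.subject_id, row.group, row.task, int(row.n_trials)
        tnd = samples.get(f"t[{task},{sid}]").ravel()
        a = samples.get(f"a[{task},{sid}]").ravel()
        v = samples.get(f"v[{task},{sid}]").ravel()
        idx = rng.integers(0, tnd.size, size=n_rep)
        for r in range(n_rep):
            j = idx[r]
            sim_seed = int(rng.integers(0, 2**31))
            rts, boundary = _kernels.simulate_euler(n_tr, tnd[j], a[j], v[j],
                                                    0.5, dt, dl, sim_seed)
            rts_all.append(rts * 1000.0)
            corr_all.append(boundary)
            recs_rep.append(np.full(n_tr, r))
            recs_sid.append(np.full(n_tr, sid, dtype=object))
            recs_grp.append(np.full(n_tr, group, dtype=object))
            recs_task.append(np.full(n_tr, task, dtype=object))
    boundary = np.concatenate(corr_all)
    trials = pd.DataFrame({
        "rep": np.concatenate(recs_rep),
        "subject_id": np.concatenate(recs_sid),
        "group": np.concatenate(recs_grp),
        "task": np.concatenate(recs_task),
        "rt_ms": np.concatenate(rts_all),
        "correct": np.where(boundary < 0, np.nan, boundary == 1),
    })
    trials.loc[boundary < 0, "rt_ms"] = np.nan
    return ReplicateSet(trials=trials, n_rep=n_rep, seed=seed)


@dataclass
class PPCReport:
    """Quantile-level model-fit summary.

    subject_table: per (subject, task, quantile) observed value, replicate
    mean and 95% band, and band coverage; group_table: the same after
    averaging subject quantiles within group (the usual group-panel view);
    r: Pearson correlation of observed vs replicate-mean quantiles, per
    task and pooled; coverage: fraction of subject-level observed
    quantiles inside the 95% band.
    """

    quantile_probs: tuple
    subject_table: pd.DataFrame
    group_table: pd.DataFrame
    r: dict
    coverage: float
    n_rep: int
    replicate_mean_accuracy: float
    excluded_cells: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _cell_quantiles(df: pd.DataFrame, probs) -> pd.DataFrame:
    """Per (subject, task) RT quantiles of correct responded trials."""
    ok = df.dropna(subset=["rt_ms"])
    ok = ok[ok["correct"].astype(bool)]
    rows = []
    for (sid, task), cell in ok.groupby(["subject_id", "task"], observed=True):
        q = np.quantile(cell["rt_ms"].to_numpy(float), probs)
        group = cell["group"].iloc[0]
        for p, val in zip(probs, q):
            rows.append((sid, group, task, p, val))
    return pd.DataFrame(rows, columns=["subject_id", "group", "task", "prob", "rt_ms"])


def compare_quantiles(observed: pd.DataFrame, replicates: ReplicateSet,
                      quantile_probs=QUANTILE_PROBS) -> PPCReport:
    """Compare observed RT quantiles of correct responses with replicates.

    Subjects with no correct responses observed (or in a replicate) are
    flagged and excluded from the correlation.  The correlation is pooled
    within task across (subject, quantile) pairs.
    """
    probs = tuple(quantile_probs)
    obs_q = _cell_quantiles(observed, probs)

    # per-replicate subject quantiles
    rep_rows = []
    for rep, df in replicates.trials.groupby("rep"):
        q = _cell_quantiles(df, probs)
        q["rep"] = rep
        rep_rows.append(q)
    rep_q = pd.concat(rep_rows, ignore_index=True)

    sim = (rep_q.groupby(["subject_id", "group", "task", "prob"], observed=True)["rt_ms"]
           .agg(sim_mean="mean",
                lo=lambda x: np.percentile(x, 2.5),
                hi=lambda x: np.percentile(x, 97.5))
           .reset_index())
    table = obs_q.rename(columns={"rt_ms": "observed"}).merge(
        sim, on=["subject_id", "group", "task", "prob"], how="outer", indicator=True)
    excluded = table.loc[table["_merge"] != "both",
                         ["subject_id", "task"]].drop_duplicates().to_records(index=False)
    table = table[table["_merge"] == "both"].drop(columns="_merge")
    table["covered"] = (table["observed"] >= table["lo"]) & (table["observed"] <= table["hi"])

    r = {}
    for task, tdf in table.groupby("task"):
        if len(tdf) >= 3 and tdf["observed"].std() > 0:
            r[task] = float(np.corrcoef(tdf["observed"], tdf["sim_mean"])[0, 1])
    if len(table) >= 3:
        r["pooled"] = float(np.corrcoef(table["observed"], table["sim_mean"])[0, 1])

    group_obs = (obs_q.groupby(["group", "task", "prob"], observed=True)["rt_ms"]
                 .mean().rename("observed"))
    group_rep = (rep_q.groupby(["group", "task", "prob", "rep"], observed=True)["rt_ms"]
                 .mean().reset_index())
    group_sim = (group_rep.groupby(["group", "task", "prob"], observed=True)["rt_ms"]
                 .agg(sim_mean="mean",
                      lo=lambda x: np.percentile(x, 2.5),
                      hi=lambda x: np.percentile(x, 97.5)))
    group_table = pd.concat([group_obs, group_sim], axis=1).reset_index()
    group_table["covered"] = ((group_table["observed"] >= group_table["lo"])
                              & (group_table["observed"] <= group_table["hi"]))

    return PPCReport(
        quantile_probs=probs,
        subject_table=table,
        group_table=group_table,
        r=r,
        coverage=float(table["covered"].mean()) if len(table) else float("nan"),
        n_rep=replicates.n_rep,
        replicate_mean_accuracy=float(replicates.accuracy_per_rep().mean()),
        excluded_cells=list(excluded),
        meta={"correlation_scope": "pooled (subject, quantile) pairs within task"},
    )


def plot_ppc(report: PPCReport, path=None):
    """Optional group-panel plot: observed quantile points over the 95%
    replicate bands (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gt = report.group_table
    tasks = gt["task"].unique()
    groups = gt["group"].unique()
    fig, axes = plt.subplots(1, len(tasks), figsize=(4 * len(tasks), 3.2),
                             squeeze=False)
    for ax, task in zip(axes[0], tasks):
        for g, group in enumerate(groups):
            sub = gt[(gt["task"] == task) & (gt["group"] == group)].sort_values("prob")
            x = np.asarray(sub["prob"]) + 0.01 * g
            ax.fill_between(x, sub["lo"], sub["hi"], alpha=0.25, label=f"{group} band")
            ax.plot(x, sub["observed"], "o", ms=4, label=f"{group} observed")
        ax.set_title(task)
        ax.set_xlabel("quantile")
        ax.set_ylabel("RT (ms)")
    axes[0, -1].legend(fontsize="x-small")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
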
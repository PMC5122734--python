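"""Synthetic cohorts emulating the aging-and-reading study design.

The emulated design: three age groups (young, high-performing older,
low-performing older; full-scale sizes 384/384/1039), four two-choice
reading tasks (letter identification, lexical, phonological and semantic
decision), 80 trials per task (40 targets, 40 non-targets) with a 3 s
response deadline.  Group-mean diffusion parameters default to the
published group-level posterior means for this design; between-subject
spreads are a synthetic assumption (10% of the group mean) because only
group-level posteriors are published.  Stimulus type is carried as a label
only — the generating model uses one drift per subject per task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .preprocessing import TRIAL_COLUMNS

__all__ = ["GROUPS", "TASKS", "DEFAULT_GROUP_MEANS", "CohortConfig",
           "generate_cohort", "descriptive_table"]

GROUPS = ("young", "high_old", "low_old")
TASKS = ("letter", "lexical", "phonological", "semantic")

#: group-level mean (t_nd [s], a, v) per task and group — the published
#: posterior means for this study design (s = 1 scaling)
DEFAULT_GROUP_MEANS = {
    "letter": {
        "young": (0.376, 1.62, 3.58),
        "high_old": (0.453, 1.92, 3.18),
        "low_old": (0.459, 1.99, 3.04),
    },
    "lexical": {
        "young": (0.426, 1.59, 2.52),
        "high_old": (0.484, 2.00, 2.80),
        "low_old": (0.506, 1.97, 2.42),
    },
    "phonological": {
        "young": (0.537, 2.08, 1.29),
        "high_old": (0.620, 2.14, 1.17),
        "low_old": (0.641, 2.17, 1.10),
    },
    "semantic": {
        "young": (0.430, 1.59, 2.84),
        "high_old": (0.487, 1.90, 2.88),
        "low_old": (0.505, 1.88, 2.61),
    },
}

FULL_GROUP_SIZES = {"young": 384, "high_old": 384, "low_old": 1039}


@dataclass(frozen=True)
class CohortConfig:
    """Design and generating parameters of a synthetic cohort.

    group_sizes: subjects per group; tasks: task labels to generate;
    group_params: per task -> group -> (t_nd, a, v) generating means;
    between_subject_cv: per-parameter SD as a fraction of the group mean;
    contaminant_rate: fraction of trials replaced by uniform-RT guesses.
    """

    group_sizes: dict = field(default_factory=lambda: dict(FULL_GROUP_SIZES))
    tasks: tuple = TASKS
    trials_per_task: int = 80
    group_params: dict = field(default_factory=lambda: DEFAULT_GROUP_MEANS)
    between_subject_cv: float = 0.10
    deadline: float = 3.0
    contaminant_rate: float = 0.0
    seed: int = 0
    dt: float = 1e-4

    def __post_init__(self):
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if self.between_subject_cv < 0:
            raise ValueError("between_subject_cv must be >= 0")
        if not (0.0 <= self.contaminant_rate <= 0.2):
            raise ValueError("contaminant_rate must be in [0, 0.2]")

    def desk(self, n_per_group: int = 30, tasks=None, seed=None) -> "CohortConfig":
        """Reduced-size copy for desk-scale runs."""
        return replace(self,
                       group_sizes={g: n_per_group for g in self.group_sizes},
                       tasks=tuple(tasks) if tasks is not None else self.tasks,
                       seed=self.seed if seed is None else seed)


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float,
                    lower: float) -> float:
    """Truncated-normal draw by redrawing (never silent clipping)."""
    if sd == 0.0:
        if mean <= lower:
            raise ValueError(f"degenerate draw at {mean} below bound {lower}")
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > lower:
            return x
    raise ValueError(f"truncated draw failed: mean={mean}, sd={sd}, lower={lower}")


def generate_cohort(config: CohortConfig):
    """Generate a trial table and its ground-truth parameter table.

    Each subject's (t_nd, a, v) per task is drawn from a truncated normal
    around the group mean (SD = between_subject_cv * mean); trials are then
    simulated from the diffusion process with z_rel = 0.5 under the
    response deadline.  Deadline hits are emitted with missing RT/correct.
    Contaminant trials (if requested) are uniform-RT guesses on
    [200 ms, deadline] with random correctness.  Returns
    (trials, truth): the trial table in the standard long format and one
    row per (subject, task) with the generating parameters.
    """
    rng = np.random.default_rng(config.seed)
    cv = config.between_subject_cv
    n_tr = config.trials_per_task
    n_target = n_tr // 2

    frames = []
    truth_rows = []
    for group in config.group_sizes:
        for s in range(config.group_sizes[group]):
            sid = f"{group}_{s:04d}"
            for task in config.tasks:
                m_t, m_a, m_v = config.group_params[task][group]
                t_nd = _draw_truncated(rng, m_t, cv * abs(m_t), 0.0)
                a = _draw_truncated(rng, m_a, cv * abs(m_a), 0.0)
                v = rng.normal(m_v, cv * abs(m_v))
                truth_rows.append((sid, group, task, t_nd, a, v))
                sim_seed = int(rng.integers(0, 2**31))
                rts, boundary = _kernels.simulate_euler(
                    n_tr, t_nd, a, v, 0.5, config.dt, config.deadline, sim_seed)
                stim = np.array(["target"] * n_target + ["nontarget"] * (n_tr - n_target))
                rng.shuffle(stim)
                rt_ms = rts * 1000.0
                correct = np.where(boundary < 0, np.nan, boundary == 1)
                if config.contaminant_rate > 0.0:
                    contam = rng.random(n_tr) < config.contaminant_rate
                    rt_ms = np.where(contam,
                                     rng.uniform(200.0, config.deadline * 1000.0, n_tr),
                                     rt_ms)
                    correct = np.where(contam, rng.random(n_tr) < 0.5, correct)
                frames.append(pd.DataFrame({
                    "subject_id": sid, "group": group, "task": task,
                    "stimulus_type": stim, "correct": correct, "rt_ms": rt_ms,
                }))
    trials = pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
    truth = pd.DataFrame(truth_rows,
                         columns=["subject_id", "group", "task", "t", "a", "v"])
    return trials, truth


def descriptive_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Group x task table of mean RT (SD) in ms and accuracy % (SD).

    Accuracy SDs are trial-level SDs of the 0/100 correctness indicator.
    Cells with no trials are reported as missing, not zero.  Apply this to
    preprocessed trials for a descriptives table in the conventional
    4-task x 3-group layout.
    """
    resp = trials.dropna(subset=["rt_ms"])
    rows = []
    for (task, group), cell in resp.groupby(["task", "group"], observed=True):
        acc = cell["correct"].astype(float) * 100.0
        rows.append((task, group,
                     cell["rt_ms"].mean(), cell["rt_ms"].std(ddof=1),
                     acc.mean(), acc.std(ddof=1), len(cell)))
    out = pd.DataFrame(rows, columns=["task", "group", "mean_rt_ms", "sd_rt_ms",
                                      "accuracy_pct", "sd_accuracy_pct", "n_trials"])
    # flag absent cells explicitly
    tasks = trials["task"].unique()
    groups = trials["group"].unique()
    full = pd.MultiIndex.from_product([tasks, groups], names=["task", "group"])
    return (out.set_index(["task", "group"]).reindex(full).reset_index())
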
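"""Convergence assessment (classic Gelman–Rubin R-hat) and trace summaries.

The classic potential-scale-reduction factor is used — no chain splitting,
no rank normalization — with the conventional pass criterion R-hat <= 1.02.
Credibility intervals are equal-tailed (2.5%–97.5%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampler import PosteriorSamples

__all__ = ["ConvergenceReport", "gelman_rubin", "convergence_report",
           "summarize_traces"]

RHAT_THRESHOLD = 1.02


class DegenerateChainsError(RuntimeError):
    """Within-chain variance is zero; R-hat is undefined."""


def _rhat_from_array(chains: np.ndarray) -> float:
    """Classic R-hat from an (n_chains, n_draws) array of retained draws.

    W = mean within-chain variance, B/n = variance of chain means;
    pooled Var+ = (n-1)/n W + B/n; R-hat = sqrt(Var+ / W).
    """
    m, n = chains.shape
    if m < 2 or n < 10:
        raise ValueError("need >= 2 chains and >= 10 retained draws per chain")
    w = np.mean(np.var(chains, axis=1, ddof=1))
    if w <= 0.0:
        raise DegenerateChainsError("zero within-chain variance")
    b_over_n = np.var(np.mean(chains, axis=1), ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


def gelman_rubin(samples: PosteriorSamples, parameter: str) -> float:
    """Classic (non-split) R-hat for one parameter, post-burn-in draws only."""
    return _rhat_from_array(samples.get(parameter, retained=True))


@dataclass
class ConvergenceReport:
    """Per-parameter R-hat against a threshold; overall pass iff all pass."""

    rhat: pd.Series
    threshold: float = RHAT_THRESHOLD

    @property
    def passed(self) -> pd.Series:
        return self.rhat <= self.threshold

    @property
    def all_passed(self) -> bool:
        return bool(self.passed.all())

    @property
    def max_rhat(self) -> float:
        return float(self.rhat.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rhat": self.rhat, "passed": self.passed})


def convergence_report(samples: PosteriorSamples,
                       threshold: float = RHAT_THRESHOLD,
                       parameters=None) -> ConvergenceReport:
    """R-hat for every parameter (or a subset) of a fit."""
    names = list(parameters) if parameters is not None else samples.param_names
    vals = {}
    for name in names:
        vals[name] = _rhat_from_array(samples.get(name, retained=True))
    return ConvergenceReport(rhat=pd.Series(vals, name="rhat"), threshold=threshold)


def summarize_traces(samples: PosteriorSamples, parameters=None) -> pd.DataFrame:
    """Mean, SD and equal-tailed 95% interval per parameter (retained draws).

    Output columns: mean, sd, ci_lower, ci_upper — one row per parameter,
    the same shape as a posterior-estimate table with bracketed 95% bounds.
    """
    names = list(parameters) if parameters is not None else samples.param_names
    rows = []
    for name in names:
        x = samples.get(name, retained=True).ravel()
        lo, hi = np.percentile(x, [2.5, 97.5])
        rows.append((name, float(np.mean(x)), float(np.std(x, ddof=1)),
                     float(lo), float(hi)))
    return pd.DataFrame(rows, columns=["parameter", "mean", "sd",
                                       "ci_lower", "ci_upper"]).set_index("parameter")


def format_summary_line(mean: float, lo: float, hi: float, digits: int = 3) -> str:
    """Render one posterior line as 'mean [lower; upper]'."""
    f = f"{{:.{digits}f}}"
    return f"{f.format(mean)} [{f.format(lo)}; {f.format(hi)}]"


def plot_trace(samples: PosteriorSamples, parameter: str, path=None):
    """Optional per-parameter trace plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    draws = samples.get(parameter, retained=False)
    for c in range(draws.shape[0]):
        ax.plot(draws[c], lw=0.5, alpha=0.8, label=f"chain {c}")
    ax.axvline(samples.burn_in, color="k", ls="--", lw=0.8)
    ax.set_xlabel("iteration")
    ax.set_ylabel(parameter)
    ax.legend(loc="upper right", fontsize="small")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
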
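"""Single-trial diffusion-decision numerics.

The decision process is a Wiener diffusion with drift v between absorbing
boundaries 0 and a, starting at z_rel * a, diffusion coefficient s = 1, plus
a non-decision offset t_nd.  Under accuracy coding the upper boundary is the
correct response.  This module provides the defective first-passage-time
(FPT) log density, closed-form absorption probability and mean decision
time, and a trial simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import _kernels
from ._kernels import DENSITY_TOL

__all__ = [
    "DDMParameters",
    "TrialSet",
    "wfpt_log_density",
    "prob_upper",
    "mean_decision_time",
    "simulate_trials",
]


class ParameterDomainError(ValueError):
    """A diffusion parameter is outside its domain."""


@dataclass(frozen=True)
class DDMParameters:
    """Diffusion parameters for one subject in one task.

    t_nd: non-decision time (s); a: boundary separation; v: drift rate
    (evidence units / s); z_rel: relative start point in (0, 1).  The
    diffusion scaling constant is fixed at s = 1 throughout.
    """

    t_nd: float
    a: float
    v: float
    z_rel: float = 0.5

    def __post_init__(self):
        if not (math.isfinite(self.t_nd) and self.t_nd >= 0.0):
            raise ParameterDomainError(f"t_nd must be >= 0, got {self.t_nd}")
        if not (math.isfinite(self.a) and self.a > 0.0):
            raise ParameterDomainError(f"a must be > 0, got {self.a}")
        if not math.isfinite(self.v):
            raise ParameterDomainError(f"v must be finite, got {self.v}")
        if not (0.0 < self.z_rel < 1.0):
            raise ParameterDomainError(f"z_rel must be in (0, 1), got {self.z_rel}")


class TrialSet(NamedTuple):
    """Simulated trials: rt in seconds (NaN for deadline hits), boundary
    1 = upper, 0 = lower, -1 = non-response (deadline exceeded)."""

    rt: np.ndarray
    boundary: np.ndarray

    @property
    def responded(self) -> np.ndarray:
        return self.boundary >= 0


def _check_boundary(boundary) -> bool:
    if boundary in ("upper", 1, True):
        return True
    if boundary in ("lower", 0, False):
        return False
    raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")


def wfpt_log_density(rt, boundary, params: DDMParameters, tol: float = DENSITY_TOL):
    """Log of the defective FPT density at the given boundary.

    Vectorized over rt.  Returns -inf for rt <= t_nd.  The series is
    truncated so the absolute density error is below tol.
    """
    if tol <= 0.0:
        raise ValueError(f"tol must be positive, got {tol}")
    upper = _check_boundary(boundary)
    rt_arr = np.asarray(rt, dtype=float)
    out = np.empty(rt_arr.shape, dtype=float)
    flat = rt_arr.ravel()
    oflat = out.ravel()
    for i in range(flat.size):
        oflat[i] = _kernels.wfpt_logpdf(flat[i], upper, params.t_nd, params.a,
                                        params.v, params.z_rel, tol)
    return out[()] if rt_arr.ndim == 0 else out


def prob_upper(params: DDMParameters) -> float:
    """Closed-form probability of absorption at the upper boundary.

    P = (1 - exp(-2 v z)) / (1 - exp(-2 v a)) with z = z_rel * a; the v -> 0
    limit is z_rel.  For z_rel = 0.5 this reduces to 1 / (1 + exp(-a v)).
    """
    a, v, w = params.a, params.v, params.z_rel
    if abs(v) < 1e-10:
        return w
    # numerically stable form of expm1 ratio
    num = -math.expm1(-2.0 * v * w * a)
    den = -math.expm1(-2.0 * v * a)
    return num / den


def mean_decision_time(params: DDMParameters) -> float:
    """Closed-form mean decision time for the unbiased (z_rel = 0.5) case.

    (a / 2v) * tanh(a v / 2), with limit a^2 / 4 at v = 0.  Add t_nd to get
    the expected mean RT.  Other start points are not supported.
    """
    if params.z_rel != 0.5:
        raise NotImplementedError("mean_decision_time requires z_rel = 0.5")
    a, v = params.a, params.v
    if abs(v) < 1e-8:
        return a * a / 4.0
    return (a / (2.0 * v)) * math.tanh(a * v / 2.0)


def simulate_trials(params: DDMParameters, n: int, deadline: float | None = None,
                    seed: int = 0, dt: float = 1e-4) -> TrialSet:
    """Simulate n independent trials by Euler–Maruyama with step dt (s).

    Trials whose total RT would exceed the deadline are flagged as
    non-responses (boundary -1, rt NaN) rather than assigned a boundary.
    Reproducible under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if deadline is not None and deadline <= params.t_nd:
        raise ValueError("deadline must exceed the non-decision time")
    dl = -1.0 if deadline is None else float(deadline)
    rts, boundary = _kernels.simulate_euler(int(n), params.t_nd, params.a, params.v,
                                            params.z_rel, dt, dl, int(seed) % 2**31)
    return TrialSet(rt=rts, boundary=boundary)
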
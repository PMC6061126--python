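"""Reduction-fidelity metric: maximal relative error.

For a reference output y(t) and an approximation ybar(t) on a shared grid,

    eps = || y - ybar ||_inf / || y ||_inf,

evaluated per output channel on the discrete simulation grid; the headline
value is the maximum across channels ("in either compartment").  The metric
is scale invariant, so reductions can be compared across dose levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, UndefinedErrorMetric

__all__ = ["ErrorReport", "maximal_relative_error"]


@dataclass
class ErrorReport:
    """Maximal relative error of an approximate model's outputs."""

    epsilon: float
    per_output_epsilon: dict[str, float]
    horizon: float
    n_grid: int

    @property
    def percent(self) -> float:
        return 100.0 * self.epsilon

    def __str__(self) -> str:
        per = ", ".join(f"{k}: {100 * v:.2f}%" for k, v in self.per_output_epsilon.items())
        return f"eps = {self.percent:.2f}% (per output: {per})"

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "epsilon_percent": self.percent,
            "per_output_epsilon": dict(self.per_output_epsilon),
            "horizon": self.horizon,
            "n_grid": self.n_grid,
        }


def maximal_relative_error(y_ref, y_approx, times=None,
                           output_names=None) -> ErrorReport:
    """Sup-norm relative error between two output trajectories.

    Parameters
    ----------
    y_ref, y_approx : Trajectory or ndarray (T,) / (T, p)
        Reference and approximate outputs.  Trajectories must share the
        same time grid and output dimension.
    times : ndarray, optional
        Required when passing raw arrays (used only for reporting).
    output_names : list of str, optional

    Raises
    ------
    UndefinedErrorMetric
        If a reference channel is identically zero (division by zero).
    """
    from .core import Trajectory

    if isinstance(y_ref, Trajectory):
        if output_names is None:
            output_names = list(y_ref.output_names)
        times = y_ref.times
        yr = y_ref.outputs
    else:
        yr = np.atleast_2d(np.asarray(y_ref, dtype=float).T).T
    if isinstance(y_approx, Trajectory):
        if times is not None and (len(y_approx.times) != len(times)
                                  or not np.allclose(y_approx.times, times)):
            raise ConfigurationError("trajectories are not on the same time grid")
        ya = y_approx.outputs
    else:
        ya = np.atleast_2d(np.asarray(y_approx, dtype=float).T).T

    if yr.shape != ya.shape:
        raise ConfigurationError(
            f"output shapes differ: {yr.shape} vs {ya.shape}")
    p = yr.shape[1]
    if output_names is None:
        output_names = [f"y{j}" for j in range(p)]

    per = {}
    for j in range(p):
        denom = np.max(np.abs(yr[:, j]))
        if denom == 0.0:
            raise UndefinedErrorMetric(
                f"reference output {output_names[j]!r} is identically zero; "
                "relative error undefined")
        per[output_names[j]] = float(np.max(np.abs(yr[:, j] - ya[:, j])) / denom)

    horizon = float(times[-1] - times[0]) if times is not None else float("nan")
    n_grid = int(yr.shape[0])
    return ErrorReport(epsilon=max(per.values()), per_output_epsilon=per,
                       horizon=horizon, n_grid=n_grid)
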
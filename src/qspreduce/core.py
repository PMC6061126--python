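"""Model representations, dose regimens and simulation.

The universal model currency is the control-affine system

    dx/dt = f(x) + sum_i g_i(x) u_i(t),      y = h(x),   x(0) = x0,

with named states, inputs and outputs.  Linear time-invariant systems
(A, B, C) are a special case held in :class:`LinearStateSpaceModel`,
which simulation exploits (exact matrix-exponential stepping) and the
reduction machinery requires.

Doses are timed events on named input channels.  A bolus is applied as
an instantaneous state increment through the corresponding input field
(``x <- x + g_i(x) * amount``; for a linear model, ``B[:, i] * amount``),
so a bolus at t = 0 is exactly equivalent to amending the initial state.
An infusion enters as a piecewise-constant rate on u_i(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .errors import ConfigurationError, IntegrationError, ValidationError

__all__ = [
    "ControlAffineModel",
    "LinearStateSpaceModel",
    "DoseEvent",
    "DoseRegimen",
    "Trajectory",
    "simulate",
    "is_asymptotically_stable",
    "marginal_eigenvalues",
    "STABILITY_TOL",
    "default_time_grid",
]

#: Eigenvalues with real part above -STABILITY_TOL are not counted as stable;
#: those within +/- STABILITY_TOL of the imaginary axis are flagged marginal.
STABILITY_TOL = 1e-9

#: Default solver tolerances.  Reduction-error metrics must not be polluted
#: by integration error, so these are tight; both are overridable per call.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


def default_time_grid(horizon: float = 48.0, n_points: int = 2000) -> np.ndarray:
    """Linearly spaced output grid starting at 0 (default: 48 h, 2000 points)."""
    return np.linspace(0.0, float(horizon), int(n_points))


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------

@dataclass
class ControlAffineModel:
    """Nonlinear input-affine ODE model with named I/O channels.

    Parameters
    ----------
    state_names : list of str
    drift : callable
        ``f(x) -> ndarray (n,)``, the autonomous vector field.
    input_fields : list of callables
        One ``g_i(x) -> ndarray (n,)`` per input channel.
    output_map : callable
        ``h(x) -> ndarray (p,)``.
    initial_state : ndarray (n,)
    input_names, output_names : lists of str
    """

    state_names: list[str]
    drift: Callable[[np.ndarray], np.ndarray]
    input_fields: list[Callable[[np.ndarray], np.ndarray]]
    output_map: Callable[[np.ndarray], np.ndarray]
    initial_state: np.ndarray
    input_names: list[str]
    output_names: list[str]

    def __post_init__(self):
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        n = len(self.state_names)
        if self.initial_state.shape != (n,):
            raise ValidationError(
                f"initial_state has shape {self.initial_state.shape}, expected ({n},)"
            )
        if len(self.input_fields) != len(self.input_names):
            raise ValidationError(
                f"{len(self.input_fields)} input fields but "
                f"{len(self.input_names)} input names"
            )
        f0 = np.asarray(self.drift(self.initial_state), dtype=float)
        if f0.shape != (n,):
            raise ValidationError(f"drift returns shape {f0.shape}, expected ({n},)")
        h0 = np.asarray(self.output_map(self.initial_state), dtype=float)
        if h0.shape != (len(self.output_names),):
            raise ValidationError(
                f"output_map returns shape {h0.shape}, expected "
                f"({len(self.output_names)},)"
            )

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    @property
    def n_outputs(self) -> int:
        return len(self.output_names)

    def input_index(self, channel: str) -> int:
        try:
            return self.input_names.index(channel)
        except ValueError:
            raise ConfigurationError(
                f"unknown input channel {channel!r}; model has {self.input_names}"
            ) from None


@dataclass
class LinearStateSpaceModel:
    """Linear time-invariant state-space model dx/dt = Ax + Bu, y = Cx.

    ``A`` carries rate units (1/h for the PBPK application); ``B`` maps the
    input channels into the states and ``C`` selects/combines states into
    outputs.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    state_names: list[str]
    input_names: list[str]
    output_names: list[str]
    initial_state: np.ndarray | None = None

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValidationError(f"A must be square, got {self.A.shape}")
        if self.B.shape[0] != n:
            raise ValidationError(f"B has {self.B.shape[0]} rows, expected {n}")
        if self.C.shape[1] != n:
            raise ValidationError(f"C has {self.C.shape[1]} columns, expected {n}")
        if len(self.state_names) != n:
            raise ValidationError("state_names length does not match A")
        if len(self.input_names) != self.B.shape[1]:
            raise ValidationError("input_names length does not match B")
        if len(self.output_names) != self.C.shape[0]:
            raise ValidationError("output_names length does not match C")
        if self.initial_state is None:
            self.initial_state = np.zeros(n)
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        if self.initial_state.shape != (n,):
            raise ValidationError("initial_state shape does not match A")

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.C.shape[0]

    def input_index(self, channel: str) -> int:
        try:
            return self.input_names.index(channel)
        except ValueError:
            raise ConfigurationError(
                f"unknown input channel {channel!r}; model has {self.input_names}"
            ) from None

    def to_control_affine(self) -> ControlAffineModel:
        """View as a control-affine model: f(x)=Ax, g_i(x)=B[:,i], h(x)=Cx."""
        A, B, C = self.A, self.B, self.C
        return ControlAffineModel(
            state_names=list(self.state_names),
            drift=lambda x: A @ x,
            input_fields=[
                (lambda x, col=B[:, i]: col) for i in range(self.n_inputs)
            ],
            output_map=lambda x: C @ x,
            initial_state=self.initial_state.copy(),
            input_names=list(self.input_names),
            output_names=list(self.output_names),
        )

    def with_outputs(self, C: np.ndarray, output_names: Sequence[str]) -> "LinearStateSpaceModel":
        return LinearStateSpaceModel(
            A=self.A, B=self.B, C=np.asarray(C, dtype=float),
            state_names=list(self.state_names),
            input_names=list(self.input_names),
            output_names=list(output_names),
            initial_state=self.initial_state.copy(),
        )


# ---------------------------------------------------------------------------
# dosing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseEvent:
    """A single dose: bolus (instantaneous) or infusion over ``duration`` hours."""

    time: float
    channel: str
    amount: float
    kind: str = "bolus"          # "bolus" | "infusion"
    duration: float = 0.0        # h, infusions only

    def __post_init__(self):
        if self.time < 0:
            raise ConfigurationError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise ConfigurationError(f"dose amount must be >= 0, got {self.amount}")
        if self.kind not in ("bolus", "infusion"):
            raise ConfigurationError(f"unknown dose kind {self.kind!r}")
        if self.kind == "infusion" and self.duration <= 0:
            raise ConfigurationError("infusion requires a positive duration")


@dataclass
class DoseRegimen:
    """Ordered collection of dose events mapped onto model input channels."""

    events: list[DoseEvent] = field(default_factory=list)

    @classmethod
    def single_oral_bolus(cls, amount: float, time: float = 0.0,
                          channel: str = "oral") -> "DoseRegimen":
        return cls([DoseEvent(time=time, channel=channel, amount=amount)])

    @classmethod
    def single_iv_bolus(cls, amount: float, time: float = 0.0,
                        channel: str = "IV") -> "DoseRegimen":
        return cls([DoseEvent(time=time, channel=channel, amount=amount)])

    def scaled(self, factor: float) -> "DoseRegimen":
        """Same schedule with all amounts multiplied by ``factor``."""
        return DoseRegimen([
            DoseEvent(e.time, e.channel, e.amount * factor, e.kind, e.duration)
            for e in self.events
        ])

    def validate_against(self, model) -> None:
        for e in self.events:
            model.input_index(e.channel)  # raises ConfigurationError if unknown


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Simulated states and outputs on a common time grid."""

    times: np.ndarray
    states: np.ndarray   # (len(times), n)
    outputs: np.ndarray  # (len(times), p)
    state_names: list[str]
    output_names: list[str]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        if not (len(self.times) == self.states.shape[0] == self.outputs.shape[0]):
            raise ValidationError("times, states and outputs lengths differ")

    def output(self, name: str) -> np.ndarray:
        return self.outputs[:, self.output_names.index(name)]

    def to_frame(self):
        """Outputs as a pandas DataFrame with a leading time column."""
        import pandas as pd

        data = {"time": self.times}
        for j, name in enumerate(self.output_names):
            data[name] = self.outputs[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _segment_boundaries(doses: DoseRegimen, grid: np.ndarray) -> np.ndarray:
    """Times at which the input signal changes discontinuously."""
    pts = {float(grid[0]), float(grid[-1])}
    for e in doses.events:
        pts.add(float(e.time))
        if e.kind == "infusion":
            pts.add(float(e.time + e.duration))
    t0, t1 = float(grid[0]), float(grid[-1])
    return np.array(sorted(p for p in pts if t0 <= p <= t1))


def _infusion_rate(doses: DoseRegimen, t0: float, t1: float, model) -> np.ndarray:
    """Constant input vector u (rate units) active on the open segment (t0, t1)."""
    u = np.zeros(model.n_inputs)
    tm = 0.5 * (t0 + t1)
    for e in doses.events:
        if e.kind == "infusion" and e.time <= tm < e.time + e.duration:
            u[model.input_index(e.channel)] += e.amount / e.duration
    return u


def simulate(model, doses: DoseRegimen | None = None,
             time_grid: np.ndarray | None = None,
             rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
             method: str = "LSODA") -> Trajectory:
    """Simulate a model under a dose regimen on an output time grid.

    Linear models are propagated exactly by matrix-exponential stepping with
    zero-order hold on the inputs (no ODE-solver error); control-affine
    models are integrated with a stiff-capable solver, restarted at every
    dose event.

    Parameters
    ----------
    model : ControlAffineModel or LinearStateSpaceModel
    doses : DoseRegimen, optional
    time_grid : ndarray, optional
        Monotone grid starting at the initial time (default 0..48 h, 2000 pts).
    rtol, atol : float
        Solver tolerances (ignored by the exact linear path).
    method : str
        scipy ``solve_ivp`` method for the nonlinear path.

    Returns
    -------
    Trajectory
    """
    if doses is None:
        doses = DoseRegimen([])
    if time_grid is None:
        time_grid = default_time_grid()
    grid = np.asarray(time_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ConfigurationError("time_grid must be 1-D strictly increasing")
    doses.validate_against(model)

    if isinstance(model, LinearStateSpaceModel):
        states = _simulate_linear(model, doses, grid)
        outputs = states @ model.C.T
    else:
        states = _simulate_nonlinear(model, doses, grid, rtol, atol, method)
        outputs = np.array([model.output_map(x) for x in states])
    return Trajectory(grid, states, np.atleast_2d(outputs),
                      list(model.state_names), list(model.output_names))


def _apply_boluses_linear(model, doses, t, x):
    for e in doses.events:
        if e.kind == "bolus" and e.time == t:
            x = x + model.B[:, model.input_index(e.channel)] * e.amount
    return x


def _simulate_linear(model: LinearStateSpaceModel, doses: DoseRegimen,
                     grid: np.ndarray) -> np.ndarray:
    """Exact ZOH propagation: per step x+ = e^{A dt} x + (int_0^dt e^{As} ds) B u."""
    n = model.n_states
    A = model.A
    boundaries = _segment_boundaries(doses, grid)
    # stepping times: union of grid and signal-change points
    times = np.unique(np.concatenate([grid, boundaries]))
    on_grid = np.isin(times, grid)

    # discretisation cache keyed by rounded dt; Phi = [[A, B],[0,0]] trick
    cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def discretise(dt: float):
        key = round(dt, 15)
        if key not in cache:
            m = model.n_inputs
            M = np.zeros((n + m, n + m))
            M[:n, :n] = A * dt
            M[:n, n:] = model.B * dt
            E = expm(M)
            cache[key] = (E[:n, :n], E[:n, n:])
        return cache[key]

    x = model.initial_state.copy()
    x = _apply_boluses_linear(model, doses, times[0], x)
    out = np.empty((len(grid), n))
    gi = 0
    if on_grid[0]:
        out[gi] = x
        gi += 1
    for k in range(len(times) - 1):
        t0, t1 = times[k], times[k + 1]
        u = _infusion_rate(doses, t0, t1, model)
        Ad, Bd = discretise(t1 - t0)
        x = Ad @ x + Bd @ u
        x = _apply_boluses_linear(model, doses, t1, x)
        if on_grid[k + 1]:
            out[gi] = x
            gi += 1
    return out


def _simulate_nonlinear(model: ControlAffineModel, doses: DoseRegimen,
                        grid: np.ndarray, rtol: float, atol: float,
                        method: str) -> np.ndarray:
    boundaries = _segment_boundaries(doses, grid)
    x = model.initial_state.copy()
    # bolus through the input field, evaluated at the pre-jump state
    for e in doses.events:
        if e.kind == "bolus" and e.time == boundaries[0]:
            g = model.input_fields[model.input_index(e.channel)]
            x = x + np.asarray(g(x), dtype=float) * e.amount

    out = np.empty((len(grid), model.n_states))
    gi = 0
    if grid[0] == boundaries[0]:
        out[gi] = x
        gi += 1
    for k in range(len(boundaries) - 1):
        t0, t1 = boundaries[k], boundaries[k + 1]
        u = _infusion_rate(doses, t0, t1, model)

        def rhs(t, xv, u=u):
            dx = np.asarray(model.drift(xv), dtype=float)
            for i, ui in enumerate(u):
                if ui != 0.0:
                    dx = dx + np.asarray(model.input_fields[i](xv), dtype=float) * ui
            return dx

        seg_mask = (grid > t0) & (grid <= t1)
        t_eval = grid[seg_mask]
        sol = solve_ivp(rhs, (t0, t1), x, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval if len(t_eval) else None, dense_output=False)
        if not sol.success:
            raise IntegrationError(
                f"integration failed in segment [{t0}, {t1}]: {sol.message}",
                time=sol.t[-1] if len(sol.t) else t0,
            )
        if len(t_eval):
            out[gi:gi + len(t_eval)] = sol.y.T if sol.t[0] != t0 else sol.y.T
            gi += len(t_eval)
        x = sol.y[:, -1] if len(sol.t) else x
        if len(t_eval) == 0 or sol.t[-1] < t1:
            # ensure we land exactly on the boundary for the next segment
            sol2 = solve_ivp(rhs, (sol.t[-1] if len(sol.t) else t0, t1), x,
                             method=method, rtol=rtol, atol=atol)
            if not sol2.success:
                raise IntegrationError(
                    f"integration failed approaching t={t1}: {sol2.message}",
                    time=t1)
            x = sol2.y[:, -1]
        for e in doses.events:
            if e.kind == "bolus" and e.time == t1:
                g = model.input_fields[model.input_index(e.channel)]
                x = x + np.asarray(g(x), dtype=float) * e.amount
    return out


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

def is_asymptotically_stable(model: LinearStateSpaceModel,
                             tol: float = STABILITY_TOL) -> bool:
    """True iff every eigenvalue of A has real part < -tol (Hurwitz A)."""
    eig = np.linalg.eigvals(model.A)
    return bool(np.all(eig.real < -tol))


def marginal_eigenvalues(model: LinearStateSpaceModel,
                         tol: float = STABILITY_TOL) -> np.ndarray:
    """Eigenvalues within +/-tol of the imaginary axis (marginal diagnostic)."""
    eig = np.linalg.eigvals(model.A)
    return eig[np.abs(eig.real) <= tol]
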
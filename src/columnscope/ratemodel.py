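"""Excitatory/inhibitory rate model of approach- and withdrawal-biased columns.

A two-population Wilson-Cowan-type model: excitatory (E) and inhibitory (I)
populations couple through a sigmoid nonlinearity and receive a common
external drive I (stronger drive ~ closer faces),

    dr_E/dt = -r_E + W_EE f(r_E) + W_EI f(r_I) + theta_E + W_E * I
    dr_I/dt = -r_I + W_IE f(r_E) + W_II f(r_I) + theta_I + W_I * I

with f a logistic function with soft threshold ``theta``. Two published
parameter presets produce the two observed column response regimes: strong
recurrent excitation with weak inhibition yields a rapid, monotone rise of
the steady-state excitatory rate with input ("approach" columns); weak
excitation with strong inhibition yields a decrease followed by a plateau
("withdrawal" columns).

Threshold convention: the preset source prints f(x) = 1/(1 + exp(-(x + theta)))
with theta = 20, which leaves f saturated at rest and cannot produce the
withdrawal regime; this package therefore defaults to the standard
threshold-subtracting form f(x - theta) and keeps the printed form available
via ``RateParams.threshold_convention = "add"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp


def f_sigmoid(x: float | np.ndarray, theta: float) -> float | np.ndarray:
    """Logistic nonlinearity f(x) = 1 / (1 + exp(-(x + theta))), in (0, 1)."""
    with np.errstate(over="ignore"):  # exp overflow saturates harmlessly to 0
        return 1.0 / (1.0 + np.exp(-(np.asarray(x, float) + theta)))


@dataclass(frozen=True)
class RateParams:
    """Synaptic weights, baseline inputs, input weights, and soft threshold."""

    w_ee: float
    w_ei: float
    w_ie: float
    w_ii: float
    theta_e: float
    theta_i: float
    w_e: float
    w_i: float
    theta: float = 20.0
    #: "subtract" uses f(x - theta) (default; reproduces both response
    #: regimes); "add" uses the printed f(x + theta).
    threshold_convention: str = "subtract"

    def __post_init__(self) -> None:
        vals = (self.w_ee, self.w_ei, self.w_ie, self.w_ii, self.theta_e,
                self.theta_i, self.w_e, self.w_i, self.theta)
        if not all(np.isfinite(vals)):
            raise ValueError("all rate-model parameters must be finite")
        if self.threshold_convention not in ("subtract", "add"):
            raise ValueError("threshold_convention must be 'subtract' or 'add'")

    @property
    def effective_theta(self) -> float:
        return -self.theta if self.threshold_convention == "subtract" else self.theta

    def f(self, x: float | np.ndarray) -> float | np.ndarray:
        return f_sigmoid(x, self.effective_theta)


PRESETS: dict[str, dict[str, float]] = {
    "approach": dict(w_ee=5.0, w_ei=-0.1, w_ie=0.1, w_ii=-1.0,
                     theta_e=10.0, theta_i=10.0, w_e=1.0, w_i=10.0, theta=20.0),
    "withdrawal": dict(w_ee=0.1, w_ei=-10.0, w_ie=10.0, w_ii=-0.1,
                       theta_e=10.0, theta_i=1.0, w_e=0.1, w_i=1.0, theta=20.0),
}


def preset(name: str, threshold_convention: str = "subtract") -> RateParams:
    """Published parameter preset for 'approach' or 'withdrawal' columns."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return RateParams(**PRESETS[name], threshold_convention=threshold_convention)


@dataclass
class RateState:
    """Population firing rates under an external input strength."""

    r_e: float
    r_i: float
    i: float = 0.0


def rate_derivatives(state: RateState, params: RateParams) -> tuple[float, float]:
    """(dr_E/dt, dr_I/dt) of the two-population rate equations."""
    f = params.f
    dre = (-state.r_e + params.w_ee * f(state.r_e) + params.w_ei * f(state.r_i)
           + params.theta_e + params.w_e * state.i)
    dri = (-state.r_i + params.w_ie * f(state.r_e) + params.w_ii * f(state.r_i)
           + params.theta_i + params.w_i * state.i)
    return float(dre), float(dri)


@dataclass
class SteadyState:
    """Converged (or flagged) fixed point of the rate equations."""

    r_e: float
    r_i: float
    i: float
    converged: bool
    residual: float  # max |dr/dt| at the returned state

    def as_state(self) -> RateState:
        return RateState(r_e=self.r_e, r_i=self.r_i, i=self.i)


def steady_state(
    params: RateParams,
    i: float,
    init: RateState | tuple[float, float] = (0.0, 0.0),
    tol: float = 1e-8,
    t_max: float = 1000.0,
) -> SteadyState:
    """Integrate the rate equations to a stable fixed point.

    Adaptive-step integration from ``init`` in chunks until
    max(|dr_E/dt|, |dr_I/dt|) < tol or ``t_max`` time units elapse; a
    non-converged result is returned flagged, never silently.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if isinstance(init, RateState):
        y = np.array([init.r_e, init.r_i], float)
    else:
        y = np.array(init, float)

    def rhs(_t: float, yy: np.ndarray) -> list[float]:
        return list(rate_derivatives(RateState(yy[0], yy[1], i), params))

    t, chunk = 0.0, 50.0
    resid = max(abs(v) for v in rhs(0.0, y))
    while resid >= tol and t < t_max:
        sol = solve_ivp(rhs, (t, min(t + chunk, t_max)), y,
                        method="RK45", rtol=1e-10, atol=1e-12)
        y = sol.y[:, -1]
        t = sol.t[-1]
        resid = max(abs(v) for v in rhs(t, y))
        if resid < 1e-3:
            # integration error bounds the residual near the fixed point;
            # polish with Newton, which converges quadratically there
            y, resid = _newton_polish(params, i, y, tol)
            break
    return SteadyState(r_e=float(y[0]), r_i=float(y[1]), i=float(i),
                       converged=bool(resid < tol), residual=float(resid))


def _newton_polish(params: RateParams, i: float, y: np.ndarray,
                   tol: float, max_iter: int = 50) -> tuple[np.ndarray, float]:
    """Newton iterations on dr/dt = 0 with the analytic Jacobian."""
    y = y.copy()
    for _ in range(max_iter):
        dre, dri = rate_derivatives(RateState(y[0], y[1], i), params)
        resid = max(abs(dre), abs(dri))
        if resid < min(tol, 1e-12):
            break
        fe, fi = params.f(y[0]), params.f(y[1])
        jac = np.array([
            [-1.0 + params.w_ee * fe * (1 - fe), params.w_ei * fi * (1 - fi)],
            [params.w_ie * fe * (1 - fe), -1.0 + params.w_ii * fi * (1 - fi)],
        ])
        try:
            step = np.linalg.solve(jac, [-dre, -dri])
        except np.linalg.LinAlgError:
            break
        y = y + step
    dre, dri = rate_derivatives(RateState(y[0], y[1], i), params)
    return y, max(abs(dre), abs(dri))


def steady_state_fixed_point(
    params: RateParams,
    i: float,
    init: tuple[float, float] = (0.0, 0.0),
    damping: float = 0.2,
    tol: float = 1e-8,
    max_iter: int = 200_000,
) -> SteadyState:
    """Damped fixed-point iteration r <- (1-a) r + a G(r), G(r) = r + dr/dt.

    An independent solver for cross-checking the time-integration route; both
    converge to the same stable branch from the same initial state.
    """
    r_e, r_i = float(init[0]), float(init[1])
    for _ in range(max_iter):
        dre, dri = rate_derivatives(RateState(r_e, r_i, i), params)
        if max(abs(dre), abs(dri)) < tol:
            return SteadyState(r_e=r_e, r_i=r_i, i=float(i), converged=True,
                               residual=max(abs(dre), abs(dri)))
        r_e += damping * dre
        r_i += damping * dri
    dre, dri = rate_derivatives(RateState(r_e, r_i, i), params)
    return SteadyState(r_e=r_e, r_i=r_i, i=float(i), converged=False,
                       residual=max(abs(dre), abs(dri)))


def response_profile(
    params: RateParams,
    i_grid: np.ndarray,
    init: tuple[float, float] = (0.0, 0.0),
    continuation: bool = True,
    tol: float = 1e-8,
    t_max: float = 1000.0,
    solver: str = "ode",
) -> pd.DataFrame:
    """Steady-state excitatory rate as a function of external input strength.

    With ``continuation=True`` each input level starts from the previous
    fixed point (warm start), tracking a single stable branch across the
    grid. Returns a frame with columns I, r_e, r_i, converged, residual.
    """
    i_grid = np.asarray(i_grid, float)
    if i_grid.ndim != 1 or np.any(np.diff(i_grid) <= 0):
        raise ValueError("i_grid must be 1-D and strictly increasing")
    if solver not in ("ode", "fixed_point"):
        raise ValueError("solver must be 'ode' or 'fixed_point'")
    rows = []
    start = init
    for i in i_grid:
        if solver == "ode":
            ss = steady_state(params, float(i), start, tol=tol, t_max=t_max)
        else:
            ss = steady_state_fixed_point(params, float(i), init=start, tol=tol)
        rows.append({"I": float(i), "r_e": ss.r_e, "r_i": ss.r_i,
                     "converged": ss.converged, "residual": ss.residual})
        if continuation:
            start = (ss.r_e, ss.r_i)
    return pd.DataFrame(rows)


def rate_bound(params: RateParams, i_max: float) -> float:
    """|r_E*| bound from f in (0,1): |theta_E| + |W_EE| + |W_EI| + |W_E i|."""
    return (abs(params.theta_e) + abs(params.w_ee) + abs(params.w_ei)
            + abs(params.w_e * i_max))


def classify_profile(
    profile: pd.DataFrame,
    plateau_slope_ratio: float = 0.1,
) -> str:
    """Label a steady-state profile's qualitative regime.

    'monotone_rise': r_E*(I) non-decreasing over the grid.
    'decrease_then_plateau': an initial net decrease to the curve minimum,
    after which the slope magnitude stays below ``plateau_slope_ratio`` times
    the steepest descent slope. Anything else is 'other'. Slopes (d r/d I)
    make the labels insensitive to the grid resolution.
    """
    r = profile["r_e"].to_numpy()
    i_vals = profile["I"].to_numpy()
    slopes = np.diff(r) / np.diff(i_vals)
    rng_ = r.max() - r.min()
    if np.all(slopes >= -1e-9):
        return "monotone_rise" if rng_ > 0 else "other"
    i_min = int(np.argmin(r))
    decreased = r[i_min] < r[0] - 0.05 * max(rng_, 1e-12)
    max_descent = -slopes.min()
    tail = slopes[i_min:]
    plateau = (len(tail) == 0
               or np.all(np.abs(tail) <= plateau_slope_ratio * max_descent))
    if decreased and plateau:
        return "decrease_then_plateau"
    return "other"


def distance_to_input(
    virtual_distance_cm: float | np.ndarray,
    scale: float = 1000.0,
) -> np.ndarray:
    """Map virtual face distance to model input strength, I = scale / distance.

    Closer faces are larger on the retina, hence drive stronger upstream
    input; the inverse-distance shape is an explicit modeling assumption and
    the scale factor is configurable.
    """
    d = np.asarray(virtual_distance_cm, float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    return scale / d
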
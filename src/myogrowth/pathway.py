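"""Biochemical dynamical system of the IGF1-AKT-mTOR-FOXO pathway.

Four molecular populations interact as a Lotka-Volterra system,

    dx1/dt = x1 (a1(t) - b1 x1)                       IGF1
    dx2/dt = x2 (a2(t) - b2 x2 + c21 x1)              AKT
    dx3/dt = x3 (a3    - b3 x3 - c32 x2)              FOXO
    dx4/dt = x4 (a4    - b4 x4 + c42 x2 - c43 x3)     mTOR

and drive the myofibril population z through a thresholded synthesis /
degradation law (see :func:`myofibril_rate`).  Exercise enters through the
two-state training signal a1(t) and the post-session pulse a2(t).  The
system is integrated with a fixed-step classical Runge-Kutta scheme, the
same discretization used to produce the published trajectories.
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence

import numpy as np

from .params import PathwayParameters, PathwayState, StimulusParameters

__all__ = [
    "pathway_rates",
    "myofibril_rate",
    "a1_signal",
    "a2_signal",
    "a2_signal_step",
    "rk4_step",
    "integrate",
    "steady_state",
]

Driver = Callable[[float], float]


def pathway_rates(
    state: PathwayState | Sequence[float],
    params: PathwayParameters,
    a1: float,
    a2: float,
) -> np.ndarray:
    """Time derivatives (dx1..dx4)/dt of the four molecular populations.

    ``state`` may be a :class:`PathwayState` or any length >= 4 sequence
    ``(x1, x2, x3, x4, ...)``.  Populations must be non-negative.
    """
    if isinstance(state, PathwayState):
        x1, x2, x3, x4 = state.populations()
    else:
        x1, x2, x3, x4 = float(state[0]), float(state[1]), float(state[2]), float(state[3])
    if min(x1, x2, x3, x4) < 0:
        raise ValueError("populations must be non-negative")
    p = params
    return np.array([
        x1 * (a1 - p.b1 * x1),
        x2 * (a2 - p.b2 * x2 + p.c21 * x1),
        x3 * (p.a3 - p.b3 * x3 - p.c32 * x2),
        x4 * (p.a4 - p.b4 * x4 + p.c42 * x2 - p.c43 * x3),
    ])


def myofibril_rate(
    x3: float,
    x4: float,
    z: float,
    params: PathwayParameters,
    k1: Optional[float] = None,
) -> float:
    """Rate of change f(x3, x4) of the myofibril population z (a.u./hour).

    Synthesis k1 (x4 - x4_thr) engages only while mTOR exceeds its
    threshold, degradation k2 (x3 - x3_thr) only while FOXO exceeds its
    threshold; both vanish on their threshold lines, so the law is
    continuous.  The rate is hard zero once z sits at or beyond its
    physiological bounds [z_min, z_max].  ``k1`` overrides the stored
    synthesis rate (used by the mechanical feedback).
    """
    p = params
    if z <= p.z_min or z >= p.z_max:
        return 0.0
    k1_eff = p.k1 if k1 is None else k1
    rate = 0.0
    if x4 > p.x4_thr:
        rate += k1_eff * (x4 - p.x4_thr)
    if x3 > p.x3_thr:
        rate -= p.k2 * (x3 - p.x3_thr)
    return rate


def a1_signal(
    t: float | np.ndarray,
    sessions: Sequence[tuple[float, float]] | np.ndarray,
    stim: StimulusParameters,
) -> float | np.ndarray:
    """Two-state training input a1(t).

    Inside a session a1 = stim_gain * intensity * f_max (the load-scaled
    drive); during growth periods a1 = a10.  ``sessions`` is a sequence of
    disjoint, sorted ``(start, end)`` half-open intervals in hours.
    """
    if stim.f_max is None:
        raise ValueError("stim.f_max must be set to evaluate the training signal")
    amp = stim.stim_gain * stim.intensity * stim.f_max
    starts, ends = _session_arrays(sessions)
    scalar = np.ndim(t) == 0
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    in_session = np.zeros(t_arr.shape, dtype=bool)
    if starts.size:
        idx = np.searchsorted(starts, t_arr, side="right") - 1
        valid = idx >= 0
        in_session[valid] = t_arr[valid] < ends[idx[valid]]
    out = np.where(in_session, amp, stim.a10)
    return float(out[0]) if scalar else out


def a2_signal(
    t_since_session: float | np.ndarray,
    stim: StimulusParameters,
) -> float | np.ndarray:
    """Pulsed AKT intrinsic rate a2 as a function of hours since the most
    recent session start.

    Exact integral of the published pulse ODE
    da2/dt = (1/2)(-1/tau_h - (t - t1)/tau_h^2) exp((t - t1)/tau_h),
    a2(0) = a20, i.e. a2 = a20 - (1/2)[u e^u - u0 e^{u0}] with
    u = (t - t1)/tau_h.  The pulse is applied on the window [0, t1_pulse)
    after a session start and a2 is held at a20 outside it (the printed
    form is unbounded past t1); ``inf`` (no session yet) returns a20.
    """
    scalar = np.ndim(t_since_session) == 0
    ts = np.atleast_1d(np.asarray(t_since_session, dtype=float))
    u = (ts - stim.t1_pulse) / stim.tau_h
    u0 = -stim.t1_pulse / stim.tau_h
    with np.errstate(over="ignore", invalid="ignore"):
        pulse = -0.5 * (u * np.exp(u) - u0 * math.exp(u0))
    active = (ts >= 0) & (ts < stim.t1_pulse)
    out = stim.a20 + np.where(active, pulse, 0.0)
    return float(out[0]) if scalar else out


def a2_signal_step(
    a2_cur: float,
    t_since_session: float,
    dt: float,
    stim: StimulusParameters,
) -> float:
    """Advance a2 by ``dt`` hours; returns a2 at ``t_since_session + dt``.

    Uses the exact pulse integral, so the step is free of discretization
    error; ``a2_cur`` is accepted for interface symmetry with the ODE
    stepper but the pulse value depends only on the elapsed time.
    """
    del a2_cur
    if t_since_session < 0:
        raise ValueError("t_since_session must be non-negative")
    return float(a2_signal(t_since_session + dt, stim))


def _session_arrays(sessions) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(sessions, dtype=float)
    if arr.size == 0:
        return np.empty(0), np.empty(0)
    return arr[:, 0], arr[:, 1]


def _rhs(
    t: float,
    y: np.ndarray,
    params: PathwayParameters,
    a1_of_t: Driver,
    a2_of_t: Driver,
    k1: Optional[float],
) -> np.ndarray:
    rates = pathway_rates(y[:4], params, a1_of_t(t), a2_of_t(t))
    f = myofibril_rate(y[2], y[3], y[4], params, k1=k1)
    return np.append(rates, f)


def rk4_step(
    state: PathwayState,
    dt: float,
    a1_of_t: Driver,
    a2_of_t: Driver,
    params: PathwayParameters,
    k1: Optional[float] = None,
) -> PathwayState:
    """One classical fourth-order Runge-Kutta step of the 5-state system.

    The drivers a1(t), a2(t) are re-evaluated at the substage times.  The
    myofibril population is clamped to [z_min, z_max] after the step
    (post-step projection; the overshoot is O(dt f)).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t, y = state.t, np.array([state.x1, state.x2, state.x3, state.x4, state.z])
    k1v = _rhs(t, y, params, a1_of_t, a2_of_t, k1)
    k2v = _rhs(t + dt / 2, y + dt / 2 * k1v, params, a1_of_t, a2_of_t, k1)
    k3v = _rhs(t + dt / 2, y + dt / 2 * k2v, params, a1_of_t, a2_of_t, k1)
    k4v = _rhs(t + dt, y + dt * k3v, params, a1_of_t, a2_of_t, k1)
    y_new = y + dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
    if not np.all(np.isfinite(y_new)):
        raise FloatingPointError(f"non-finite state after step at t={t} h: {y_new}")
    z = min(max(y_new[4], params.z_min), params.z_max)
    return PathwayState(t=t + dt, x1=y_new[0], x2=y_new[1], x3=y_new[2],
                        x4=y_new[3], z=z, a2_cur=a2_of_t(t + dt))


def integrate(
    state: PathwayState,
    t_end: float,
    dt: float,
    a1_of_t: Driver,
    a2_of_t: Driver,
    params: PathwayParameters,
    k1: Optional[float] = None,
) -> PathwayState:
    """Integrate from ``state.t`` to ``t_end`` with fixed step ``dt``."""
    n = round((t_end - state.t) / dt)
    if not math.isclose(state.t + n * dt, t_end, rel_tol=0, abs_tol=1e-9 * max(1.0, t_end)):
        raise ValueError("t_end must be a whole number of steps away")
    for _ in range(n):
        state = rk4_step(state, dt, a1_of_t, a2_of_t, params, k1=k1)
    return state


def steady_state(
    params: PathwayParameters,
    a1: Optional[float] = None,
    a2: Optional[float] = None,
) -> tuple[float, float, float, float]:
    """Positive fixed point of the molecular subsystem at constant inputs.

    The interaction graph is triangular (IGF1 -> AKT -> FOXO -> mTOR), so
    the fixed point follows in closed form by cascading the zero-rate
    conditions:

        x1* = a1/b1,  x2* = (a2 + c21 x1*)/b2,
        x3* = (a3 - c32 x2*)/b3,
        x4* = (a4 + c42 x2* - c43 x3*)/b4.

    Defaults to the resting inputs (a10, a20), whose fixed point sits on
    the myofibril thresholds (homeostasis).
    """
    p = params
    a1 = p.a10 if a1 is None else a1
    a2 = p.a20 if a2 is None else a2
    x1 = a1 / p.b1
    x2 = (a2 + p.c21 * x1) / p.b2
    x3 = (p.a3 - p.c32 * x2) / p.b3
    x4 = (p.a4 + p.c42 * x2 - p.c43 * x3) / p.b4
    if min(x1, x2, x3, x4) <= 0:
        raise ValueError(f"fixed point not positive: {(x1, x2, x3, x4)}")
    return (x1, x2, x3, x4)
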
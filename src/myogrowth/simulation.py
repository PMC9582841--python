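"""The mechanobiological coupling loop.

One simulation alternates two stages.  During a *training session* (one
hour, three times a week by default) the training signal a1(t) drives the
pathway, growth is frozen (the growth tensor is the identity) and,
immediately before the session, the mechanics is interrogated: the
activation required to hold the fixed training load at the current CSA is
computed and converted into an updated protein-synthesis rate
k1 = k10 (d1 beta_req - d2).  During the *growth period* between sessions
the myofibril rate f(x3, x4) is sampled once per growth step (1 h), turned
into a growth multiplier G = f dt/(kappa A) + 1, composed into the
structure, and the fixed-end equilibrium is re-solved for the new CSA.

The loop is fully deterministic: identical configurations produce
bit-identical output tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import pathway as pw
from .constitutive import GrowthInputs, growth_multiplier
from .mechanics import (
    MuscleStructure,
    activation_required,
    isometric_equilibrium,
    isometric_force,
)
from .params import (
    CM2_TO_M2,
    FeedbackParameters,
    MaterialParameters,
    PathwayParameters,
    PathwayState,
    ProtocolConfig,
    SimulationConfig,
    StimulusParameters,
    initial_state,
)

__all__ = ["SimulationResult", "schedule_sessions", "k1_update", "run_protocol"]

logger = logging.getLogger(__name__)


def schedule_sessions(protocol: ProtocolConfig) -> np.ndarray:
    """Disjoint training-session intervals [start, start + duration), hours.

    With a weekly day pattern, sessions fall on the given days of each week
    (day 1 is t = 0); with ``every_n_days`` they repeat at a fixed interval
    from t = 0.  Starts and durations are snapped to integration-step
    boundaries.  Raises on overlapping sessions.
    """
    dt = protocol.dt
    duration = round(protocol.session_hours / dt) * dt
    if duration <= 0:
        raise ValueError("session_hours must be at least one time step")
    if protocol.every_n_days is not None:
        period = protocol.every_n_days * 24.0
        starts = np.arange(0.0, protocol.total_hours, period)
    else:
        starts_list = [
            week * 168.0 + (day - 1) * 24.0
            for week in range(protocol.total_weeks)
            for day in sorted(protocol.session_days)
        ]
        starts = np.array(starts_list)
    starts = np.round(starts / dt) * dt
    if protocol.n_sessions is not None:
        starts = starts[: protocol.n_sessions]
        if len(starts) < protocol.n_sessions:
            raise ValueError(
                f"schedule provides only {len(starts)} of "
                f"{protocol.n_sessions} requested sessions"
            )
    sessions = np.column_stack([starts, starts + duration])
    if np.any(sessions[1:, 0] < sessions[:-1, 1]):
        raise ValueError("training sessions overlap")
    return sessions


def k1_update(
    beta_req: float,
    fb: FeedbackParameters,
    area_m2: Optional[float] = None,
) -> float:
    """Protein-synthesis rate from the mechanical feedback (1/hour).

    beta mode: k1 = k10 (d1 beta_req - d2); linear mode:
    k1 = k10 (b - m A) with the CSA ``A`` in m^2; baseline: k1 = k10.
    A negative synthesis rate would invert the meaning of the hypertrophy
    branch, so k1 is floored at zero.
    """
    if fb.mode == "baseline":
        return fb.k10
    if fb.mode == "beta":
        return max(0.0, fb.k10 * (fb.d1 * beta_req - fb.d2))
    if fb.intercept_b is None:
        raise ValueError("linear feedback requires intercept_b (resolved at run start)")
    if area_m2 is None:
        raise ValueError("linear feedback requires the current CSA")
    return max(0.0, fb.k10 * (fb.intercept_b - fb.slope_m * area_m2))


@dataclass
class SimulationResult:
    """Hourly time series plus per-session feedback events of one run.

    ``frame`` columns: t_hours, x1..x4, z, a1, a2, f_rate, G_step, G_acc,
    area_cm2, area_norm, beta_required, k1_current, force_load_kgf.
    ``feedback`` has one row per k1 update (session start).
    """

    frame: pd.DataFrame
    feedback: pd.DataFrame
    f_max_kgf: float
    load_kgf: float
    config: SimulationConfig = field(repr=False)

    @property
    def area_norm(self) -> np.ndarray:
        return self.frame["area_norm"].to_numpy()

    @property
    def max_area_norm(self) -> float:
        return float(self.frame["area_norm"].max())

    @property
    def final_area_norm(self) -> float:
        return float(self.frame["area_norm"].iloc[-1])

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.12g")


def run_protocol(
    config: Optional[SimulationConfig] = None,
    *,
    protocol: Optional[ProtocolConfig] = None,
    pathway_params: Optional[PathwayParameters] = None,
    mat: Optional[MaterialParameters] = None,
    fb: Optional[FeedbackParameters] = None,
    stim: Optional[StimulusParameters] = None,
    structure0: Optional[MuscleStructure] = None,
    state0: Optional[PathwayState] = None,
) -> SimulationResult:
    """Run a full training protocol and return its time series.

    All blocks default to the published study conditions; keyword blocks
    override the corresponding entry of ``config``.  ``state0`` overrides
    the published biochemical initial conditions (e.g. to start exactly on
    the homeostatic fixed point).
    """
    cfg = config if config is not None else SimulationConfig()
    protocol = protocol if protocol is not None else cfg.protocol
    p = pathway_params if pathway_params is not None else cfg.pathway
    mat = mat if mat is not None else cfg.material
    fb = fb if fb is not None else cfg.feedback
    stim = stim if stim is not None else cfg.stimulus
    structure = (
        replace(structure0)
        if structure0 is not None
        else MuscleStructure(length0=cfg.length0, diam_mid=cfg.diam_mid,
                             diam_end=cfg.diam_end)
    )

    dt = protocol.dt
    n_steps = round(protocol.total_hours / dt)
    g_every = round(protocol.dt_growth / dt)
    rec_every = round(1.0 / dt)
    if rec_every == 0 or abs(rec_every * dt - 1.0) > 1e-9:
        raise ValueError("dt must divide one hour for hourly records")

    sessions = schedule_sessions(protocol)
    starts = sessions[:, 0]

    # the 1-RM proxy: maximal isometric force of the initial structure,
    # measured once and held fixed for the whole protocol
    f_max = stim.f_max
    if f_max is None:
        f_max = isometric_force(structure, 1.0, mat).kgf
    load_kgf = protocol.intensity * f_max
    # stimulus carries the resting rates of the pathway block and the
    # measured maximal force, so perturbing a10/a20 perturbs the drivers too
    stim_run = replace(stim, a10=p.a10, a20=p.a20, f_max=f_max,
                       intensity=protocol.intensity)

    # driver values on the half-step grid used by the RK4 substages
    t_half = np.arange(2 * n_steps + 1) * (dt / 2.0)
    a1_grid = np.asarray(pw.a1_signal(t_half, sessions, stim_run), dtype=float)
    if starts.size:
        idx = np.searchsorted(starts, t_half, side="right") - 1
        t_since = np.where(idx >= 0, t_half - starts[np.clip(idx, 0, None)], np.inf)
    else:
        t_since = np.full_like(t_half, np.inf)
    a2_grid = np.asarray(pw.a2_signal(t_since, stim_run), dtype=float)
    duration = sessions[0, 1] - sessions[0, 0] if len(sessions) else 0.0
    in_session = t_since < duration

    start_steps = {int(round(s / dt)): k for k, s in enumerate(starts)}

    # feedback state: k1 stays at its reference until the first update
    fb_run = fb
    if fb.mode == "linear" and fb.intercept_b is None:
        area0_m2 = structure.area0 * CM2_TO_M2
        fb_run = replace(fb, intercept_b=(fb.d1 - fb.d2) + fb.slope_m * area0_m2)
    k1_cur = fb_run.k10
    beta_req = math.nan

    # myofibril areal density kappa = kappa_ratio * z(0) / A(0)
    if state0 is None:
        state0 = initial_state(p)
    area_cm2 = isometric_equilibrium(structure, 0.0, mat).area_current
    area_ref = area_cm2
    kappa = protocol.kappa_ratio * state0.z / area_cm2

    # working state as plain floats for speed
    x1, x2, x3, x4, z = state0.x1, state0.x2, state0.x3, state0.x4, state0.z
    b1, b2, b3, b4 = p.b1, p.b2, p.b3, p.b4
    c21, c32, c42, c43 = p.c21, p.c32, p.c42, p.c43
    a3c, a4c = p.a3, p.a4
    x3t, x4t, k2 = p.x3_thr, p.x4_thr, p.k2
    z_lo, z_hi = p.z_min, p.z_max

    def f_of(x3v: float, x4v: float, zv: float) -> float:
        if zv <= z_lo or zv >= z_hi:
            return 0.0
        r = 0.0
        if x4v > x4t:
            r += k1_cur * (x4v - x4t)
        if x3v > x3t:
            r -= k2 * (x3v - x3t)
        return r

    def rhs(u1, u2, u3, u4, uz, a1v, a2v):
        return (
            u1 * (a1v - b1 * u1),
            u2 * (a2v - b2 * u2 + c21 * u1),
            u3 * (a3c - b3 * u3 - c32 * u2),
            u4 * (a4c - b4 * u4 + c42 * u2 - c43 * u3),
            f_of(u3, u4, uz),
        )

    n_rec = n_steps // rec_every + 1
    rec = np.empty((n_rec, 14))
    fb_events: list[tuple[float, int, float, float, float]] = []
    G_step_last = 1.0
    r_i = 0

    for i in range(n_steps + 1):
        t = i * dt
        node = 2 * i
        if i in start_steps:
            beta_req = activation_required(structure, f_max, mat)
            area_m2 = area_cm2 * CM2_TO_M2
            k1_cur = k1_update(beta_req, fb_run, area_m2)
            fb_events.append((t, start_steps[i], area_cm2, beta_req, k1_cur))
            logger.info(
                "session %d at t=%.1f h: beta_req=%.6f, k1/k10=%.4f",
                start_steps[i] + 1, t, beta_req, k1_cur / fb_run.k10,
            )
        if i > 0 and i % g_every == 0 and not in_session[node]:
            f_cur = f_of(x3, x4, z)
            G_step_last = growth_multiplier(
                GrowthInputs(f_rate=f_cur, dt_growth=protocol.dt_growth,
                             kappa=kappa, area_prev=area_cm2)
            )
            if G_step_last != 1.0:
                structure = replace(structure, G_acc=structure.G_acc * G_step_last)
                area_cm2 = isometric_equilibrium(structure, 0.0, mat).area_current
        if i % rec_every == 0:
            rec[r_i] = (
                t, x1, x2, x3, x4, z, a1_grid[node], a2_grid[node],
                f_of(x3, x4, z), G_step_last, structure.G_acc, area_cm2,
                area_cm2 / area_ref, k1_cur,
            )
            r_i += 1
        if i == n_steps:
            break

        # classical RK4 on (x1..x4, z); drivers at substage times
        a1a, a2a = a1_grid[node], a2_grid[node]
        a1b, a2b = a1_grid[node + 1], a2_grid[node + 1]
        a1c, a2c = a1_grid[node + 2], a2_grid[node + 2]
        h = dt
        k1a = rhs(x1, x2, x3, x4, z, a1a, a2a)
        k2a = rhs(x1 + h / 2 * k1a[0], x2 + h / 2 * k1a[1], x3 + h / 2 * k1a[2],
                  x4 + h / 2 * k1a[3], z + h / 2 * k1a[4], a1b, a2b)
        k3a = rhs(x1 + h / 2 * k2a[0], x2 + h / 2 * k2a[1], x3 + h / 2 * k2a[2],
                  x4 + h / 2 * k2a[3], z + h / 2 * k2a[4], a1b, a2b)
        k4a = rhs(x1 + h * k3a[0], x2 + h * k3a[1], x3 + h * k3a[2],
                  x4 + h * k3a[3], z + h * k3a[4], a1c, a2c)
        x1 += h / 6 * (k1a[0] + 2 * k2a[0] + 2 * k3a[0] + k4a[0])
        x2 += h / 6 * (k1a[1] + 2 * k2a[1] + 2 * k3a[1] + k4a[1])
        x3 += h / 6 * (k1a[2] + 2 * k2a[2] + 2 * k3a[2] + k4a[2])
        x4 += h / 6 * (k1a[3] + 2 * k2a[3] + 2 * k3a[3] + k4a[3])
        z += h / 6 * (k1a[4] + 2 * k2a[4] + 2 * k3a[4] + k4a[4])
        z = min(max(z, z_lo), z_hi)
        if not (math.isfinite(x1) and math.isfinite(x2) and math.isfinite(x3)
                and math.isfinite(x4)):
            raise FloatingPointError(f"non-finite pathway state at t={t} h")

    columns = [
        "t_hours", "x1", "x2", "x3", "x4", "z", "a1", "a2", "f_rate",
        "G_step", "G_acc", "area_cm2", "area_norm", "k1_current",
    ]
    frame = pd.DataFrame(rec[:r_i], columns=columns)
    frame["beta_required"] = np.nan
    frame["force_load_kgf"] = load_kgf
    if fb_events:
        ev = np.array([(e[0], e[3]) for e in fb_events])
        hourly_t = frame["t_hours"].to_numpy()
        pos = np.searchsorted(ev[:, 0], hourly_t, side="right") - 1
        frame.loc[pos >= 0, "beta_required"] = ev[np.clip(pos, 0, None), 1][pos >= 0]
    feedback = pd.DataFrame(
        fb_events, columns=["t_hours", "session", "area_cm2", "beta_req", "k1"]
    )
    feedback["area_m2"] = feedback["area_cm2"] * CM2_TO_M2
    feedback["k1_ratio"] = feedback["k1"] / fb_run.k10
    return SimulationResult(
        frame=frame, feedback=feedback, f_max_kgf=f_max, load_kgf=load_kgf,
        config=replace(cfg, protocol=protocol, pathway=p, material=mat,
                       feedback=fb_run, stimulus=stim_run),
    )
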
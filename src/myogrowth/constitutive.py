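"""Continuum building blocks: strain energy, active contraction, growth.

The tissue is a nearly incompressible, transversely isotropic hyperelastic
solid.  The deformation gradient is split multiplicatively, F = Fe Fg, into
a stress-free growth part Fg (unit stretch along the fiber axis, sqrt(G)
transverse to it) and an elastic part Fe that alone generates stress.  The
elastic part is further split into volumetric and isochoric contributions,
and the isochoric part during contraction into elastic and active factors,
F_bar = F_bar_e F_bar_a.

Strain energy (MPa):

    Psi = (1/D)(J - 1)^2                                volumetric
        + c1 (I1_bar - 3) + Psi_f(I4_bar)               passive
        + sigma_o f1(lambda_a) f2 f3(J4_bar) beta       active

with the exponential collagen term Psi_f engaging only above the uncurling
stretch invariant, the Gaussian force-stretch factor f1, the force-velocity
factor f2 = 1 (adaptation is slow against contraction dynamics), and the
cross-bridge/titin elastic energy f3.  Cauchy stress is the exact
push-forward of the energy derivative; the growth part enters only through
the change of reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import MaterialParameters

__all__ = [
    "AXIS",
    "DeformationState",
    "GrowthInputs",
    "psi_volumetric",
    "psi_passive",
    "collagen_energy",
    "collagen_denergy",
    "active_stress_factors",
    "psi_active",
    "growth_multiplier",
    "growth_tensor",
    "growth_tensor_inv",
    "active_deformation",
    "total_energy",
    "cauchy_stress",
]

#: default fiber (and collagen) direction: the muscle's long axis.
AXIS = np.array([1.0, 0.0, 0.0])

_I3 = np.eye(3)


# ---------------------------------------------------------------------------
# scalar energy contributions


def psi_volumetric(J: float, mat: MaterialParameters) -> float:
    """Volumetric energy (1/D)(J - 1)^2, MPa.  Requires J > 0."""
    if J <= 0:
        raise ValueError("volume ratio J must be positive")
    return mat.inv_D * (J - 1.0) ** 2


def collagen_energy(I4bar: float, mat: MaterialParameters) -> float:
    """Exponential collagen energy; identically zero at or below the
    uncurling invariant, and C1-continuous there."""
    dI = I4bar - mat.I4_uncurl
    if dI <= 0:
        return 0.0
    return (mat.c3 / mat.c4) * (math.exp(mat.c4 * dI) - mat.c4 * dI - 1.0)


def collagen_denergy(I4bar: float, mat: MaterialParameters) -> float:
    """d Psi_f / d I4_bar (zero at and below the uncurling invariant)."""
    dI = I4bar - mat.I4_uncurl
    if dI <= 0:
        return 0.0
    return mat.c3 * (math.exp(mat.c4 * dI) - 1.0)


def psi_passive(I1bar: float, I4bar: float, mat: MaterialParameters) -> float:
    """Passive energy: neo-Hookean matrix plus collagen fibers, MPa."""
    if I4bar <= 0:
        raise ValueError("I4bar must be positive")
    return mat.c1 * (I1bar - 3.0) + collagen_energy(I4bar, mat)


def active_stress_factors(
    lambda_a: float, J4bar: float, mat: MaterialParameters
) -> tuple[float, float, float, float]:
    """Active factors (f1, f2, f3, df3/dJ4bar).

    f1 is the Gaussian force-stretch relation centred on lambda_opt with
    width (1 - alpha); f2 = 1 (no force-velocity dependence); f3 is the
    cross-bridge/titin energy (2/3)(2 J^{3/2} - (3/2) J - 1/2) whose
    derivative 2 sqrt(J) - 1 equals one in the reference (J4bar = 1).
    """
    if J4bar <= 0:
        raise ValueError("J4bar must be positive")
    f1 = math.exp(-0.5 * ((lambda_a - mat.lambda_opt) / (1.0 - mat.alpha)) ** 2)
    f2 = 1.0
    sqrtJ = math.sqrt(J4bar)
    f3 = (2.0 / 3.0) * (2.0 * J4bar * sqrtJ - 1.5 * J4bar - 0.5)
    df3 = 2.0 * sqrtJ - 1.0
    return (f1, f2, f3, df3)


def psi_active(
    J4bar: float, lambda_a: float, beta_act: float, mat: MaterialParameters
) -> float:
    """Active energy sigma_o f1 f2 f3 beta, MPa.  beta_act in [0, 1]."""
    if not 0.0 <= beta_act <= 1.0:
        raise ValueError("beta_act must lie in [0, 1]")
    f1, f2, f3, _ = active_stress_factors(lambda_a, J4bar, mat)
    return mat.sigma_o * f1 * f2 * f3 * beta_act


# ---------------------------------------------------------------------------
# growth


@dataclass
class GrowthInputs:
    """Inputs of one growth increment.

    ``f_rate`` is the myofibril rate (a.u./hour), ``dt_growth`` the growth
    step (hours), ``kappa`` the myofibril areal density (a.u./cm^2) and
    ``area_prev`` the CSA at the previous growth step (cm^2).
    """

    f_rate: float
    dt_growth: float
    kappa: float
    area_prev: float

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.area_prev <= 0:
            raise ValueError("area_prev must be positive")


def growth_multiplier(g: GrowthInputs) -> float:
    """Growth multiplier G = f dt / (kappa A_prev) + 1.

    Converts the myofibril production of one growth step into a relative
    area increase through the areal density kappa.  Aborts if the implied
    atrophy would be so extreme that G <= 0.
    """
    G = g.f_rate * g.dt_growth / (g.kappa * g.area_prev) + 1.0
    if G <= 0:
        raise ValueError(f"growth multiplier must stay positive, got {G}")
    return G


def growth_tensor(G_mult: float, m0: np.ndarray = AXIS) -> np.ndarray:
    """Growth tensor Fg = m0 (x) m0 + sqrt(G) (I - m0 (x) m0).

    Unit stretch along the fiber direction, sqrt(G) transverse to it, so
    det Fg = G: grown tissue adds cross-sectional area, not length.
    """
    if G_mult <= 0:
        raise ValueError("G_mult must be positive")
    mm = np.outer(m0, m0)
    return mm + math.sqrt(G_mult) * (_I3 - mm)


def growth_tensor_inv(G_mult: float, m0: np.ndarray = AXIS) -> np.ndarray:
    """Closed-form inverse of :func:`growth_tensor`."""
    if G_mult <= 0:
        raise ValueError("G_mult must be positive")
    mm = np.outer(m0, m0)
    return mm + (_I3 - mm) / math.sqrt(G_mult)


def active_deformation(lambda_a: float, m0: np.ndarray = AXIS) -> np.ndarray:
    """Volume-preserving active split F_bar_a = lambda_a m0 (x) m0 +
    lambda_a^{-1/2} (I - m0 (x) m0)."""
    if lambda_a <= 0:
        raise ValueError("lambda_a must be positive")
    mm = np.outer(m0, m0)
    return lambda_a * mm + (_I3 - mm) / math.sqrt(lambda_a)


# ---------------------------------------------------------------------------
# full deformation state and stress


@dataclass
class DeformationState:
    """A deformation point: total gradient plus growth/active state.

    ``F`` is the total deformation gradient relative to the ungrown
    reference, ``G_mult`` the accumulated growth multiplier, ``lambda_a``
    the active fiber stretch, ``beta_act`` the activation level, ``m0`` the
    fiber and ``a0`` the collagen direction (unit vectors; collagen defaults
    to the fiber axis of this single-family fusiform idealization).
    Invariants and split tensors are derived on demand.
    """

    F: np.ndarray
    G_mult: float = 1.0
    lambda_a: float = 1.0
    beta_act: float = 0.0
    m0: np.ndarray = field(default_factory=lambda: AXIS.copy())
    a0: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (3, 3):
            raise ValueError("F must be 3x3")
        if np.linalg.det(self.F) <= 0:
            raise ValueError("det F must be positive")
        if self.a0 is None:
            self.a0 = self.m0
        for name in ("m0", "a0"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not math.isclose(float(np.linalg.norm(v)), 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValueError(f"{name} must be a unit vector")
            setattr(self, name, v)
        if not 0.0 <= self.beta_act <= 1.0:
            raise ValueError("beta_act must lie in [0, 1]")

    # -- derived kinematics ------------------------------------------------
    @property
    def Fg(self) -> np.ndarray:
        return growth_tensor(self.G_mult, self.m0)

    @property
    def Fe(self) -> np.ndarray:
        return self.F @ growth_tensor_inv(self.G_mult, self.m0)

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.Fe))

    @property
    def Fbar(self) -> np.ndarray:
        return self.J ** (-1.0 / 3.0) * self.Fe

    @property
    def Cbar(self) -> np.ndarray:
        Fb = self.Fbar
        return Fb.T @ Fb

    @property
    def I1bar(self) -> float:
        return float(np.trace(self.Cbar))

    @property
    def I4bar(self) -> float:
        return float(self.a0 @ self.Cbar @ self.a0)

    @property
    def J4bar(self) -> float:
        # elastic fiber invariant m0 . Cbar_e m0 with Cbar_e = Fa^-T Cbar Fa^-1;
        # Fa is diagonal in the fiber frame, so this reduces to I4(m0)/lambda_a^2
        return float(self.m0 @ self.Cbar @ self.m0) / self.lambda_a**2


def total_energy(state: DeformationState, mat: MaterialParameters) -> float:
    """Total strain energy density Psi(Fe), MPa."""
    return (
        psi_volumetric(state.J, mat)
        + psi_passive(state.I1bar, state.I4bar, mat)
        + psi_active(state.J4bar, state.lambda_a, state.beta_act, mat)
    )


def cauchy_stress(state: DeformationState, mat: MaterialParameters) -> np.ndarray:
    """Cauchy stress of the total strain energy (MPa), analytic.

    Standard push-forward of the decoupled energy: the volumetric part
    gives the pressure 2 (1/D)(J - 1) I, each isochoric term pushes as
    (2/J) dev[psi' * (F_bar v) (x) (F_bar v)] with the relevant structural
    vector v (identity for the neo-Hookean matrix).  Growth carries no
    stress: only Fe enters.
    """
    J = state.J
    if J <= 0 or not np.isfinite(J):
        raise ValueError("elastic deformation must have positive finite volume")
    Fb = state.Fbar
    Bb = Fb @ Fb.T
    fa = Fb @ state.a0
    fm = Fb @ state.m0
    I4b = float(fa @ fa)
    J4b = float(fm @ fm) / state.lambda_a**2

    psi4 = collagen_denergy(I4b, mat)
    f1, f2, _, df3 = active_stress_factors(state.lambda_a, J4b, mat)
    psi_a4 = mat.sigma_o * f1 * f2 * df3 * state.beta_act / state.lambda_a**2

    T = mat.c1 * Bb + psi4 * np.outer(fa, fa) + psi_a4 * np.outer(fm, fm)
    dev_T = T - (np.trace(T) / 3.0) * _I3
    sigma = (2.0 / J) * dev_T + 2.0 * mat.inv_D * (J - 1.0) * _I3
    return sigma
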
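"""Reduced-order isometric mechanics of a grown fusiform muscle.

The organ-scale problem is reduced to a homogeneous deformation of the
mid-belly section: with both ends fixed the total axial stretch is pinned
at one, the transverse stretch lambda_t is free, and lateral traction-free
equilibrium requires the transverse Cauchy stress to vanish.  That single
scalar condition determines the deformed cross-sectional area (CSA) and the
axial force at any activation level, and its numerical inverse gives the
activation required to hold a prescribed load -- the quantity fed back into
the protein-synthesis rate.

Because the growth tensor stretches only transverse to the fiber axis, a
grown state with no activation is stress-free at lambda_t = sqrt(G): purely
transverse growth is geometrically compatible with fixed ends.  Activation
perturbs this state through the active fiber tension, and the solver finds
the accommodating transverse stretch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

from .constitutive import active_stress_factors, collagen_denergy
from .params import KGF_TO_N, MPA_CM2_TO_N, MaterialParameters

__all__ = [
    "MuscleStructure",
    "EquilibriumState",
    "ForceResult",
    "UnreachableLoadError",
    "isometric_equilibrium",
    "isometric_force",
    "activation_required",
    "apply_growth",
]


class UnreachableLoadError(ValueError):
    """The requested load exceeds the muscle's current maximal force."""


@dataclass
class MuscleStructure:
    """Reference fusiform geometry plus accumulated growth.

    Lengths in cm.  ``diam_mid`` is the mid-belly diameter whose circular
    section carries the force/CSA readout; ``diam_end`` (tendon ends) is
    retained for completeness but unused by the reduced solver.  ``G_acc``
    is the accumulated growth multiplier (initially one); the grown
    reference CSA is ``area0 * G_acc``.
    """

    length0: float = 20.0
    diam_mid: float = 6.5
    diam_end: float = 2.34
    G_acc: float = 1.0

    def __post_init__(self) -> None:
        if self.length0 <= 0 or self.diam_mid <= 0:
            raise ValueError("geometry must be positive")
        if self.G_acc <= 0:
            raise ValueError("G_acc must be positive")

    @property
    def area0(self) -> float:
        """Reference mid-belly CSA, cm^2."""
        return math.pi * self.diam_mid**2 / 4.0

    @property
    def area_grown(self) -> float:
        """Grown (stress-free reference) mid-belly CSA, cm^2."""
        return self.area0 * self.G_acc


@dataclass
class EquilibriumState:
    """Solution of the fixed-end, laterally traction-free equilibrium."""

    lambda_axial: float
    lambda_trans: float
    J: float                 # elastic volume ratio det Fe
    sigma_axial: float       # MPa
    sigma_trans: float       # MPa (residual, ~0 at solution)
    area_current: float      # deformed CSA, cm^2


def _stress_components(
    lambda_t: float,
    G_acc: float,
    beta_act: float,
    mat: MaterialParameters,
    lambda_a: float = 1.0,
) -> tuple[float, float, float]:
    """(sigma_axial, sigma_transverse, J) for F = diag(1, lt, lt).

    Closed-form specialization of the full Cauchy stress to the axisymmetric
    diagonal state with fiber and collagen along the axis; cross-checked
    against :func:`myogrowth.constitutive.cauchy_stress` in the test suite.
    """
    q = lambda_t / math.sqrt(G_acc)   # elastic transverse stretch
    J = q * q                         # det Fe (elastic axial stretch is 1)
    lm2 = J ** (-2.0 / 3.0)           # modified axial stretch squared
    lt2 = J ** (1.0 / 3.0)            # modified transverse stretch squared
    I4b = lm2
    J4b = lm2 / lambda_a**2
    psi4 = collagen_denergy(I4b, mat)
    f1, f2, _, df3 = active_stress_factors(lambda_a, J4b, mat)
    psi_a4 = mat.sigma_o * f1 * f2 * df3 * beta_act / lambda_a**2
    t_ax = (mat.c1 + psi4 + psi_a4) * lm2
    t_tr = mat.c1 * lt2
    tr_mean = (t_ax + 2.0 * t_tr) / 3.0
    p_vol = 2.0 * mat.inv_D * (J - 1.0)
    sigma_ax = (2.0 / J) * (t_ax - tr_mean) + p_vol
    sigma_tr = (2.0 / J) * (t_tr - tr_mean) + p_vol
    return sigma_ax, sigma_tr, J


def isometric_equilibrium(
    structure: MuscleStructure,
    beta_act: float,
    mat: MaterialParameters,
    lambda_a: float = 1.0,
    xtol: float = 1e-12,
) -> EquilibriumState:
    """Equilibrium of the grown muscle at fixed ends and activation beta.

    Solves sigma_trans(lambda_t) = 0 for the transverse stretch of the
    total deformation F = diag(1, lambda_t, lambda_t) (relative to the
    ungrown reference) by safeguarded bracketing root finding.  The active
    fiber stretch is held at ``lambda_a`` (optimal stretch by default:
    isometric protocol, no force-velocity dependence).
    """
    if not 0.0 <= beta_act <= 1.0:
        raise ValueError("beta_act must lie in [0, 1]")
    sqrtG = math.sqrt(structure.G_acc)

    def residual(lt: float) -> float:
        return _stress_components(lt, structure.G_acc, beta_act, mat, lambda_a)[1]

    lo, hi = 0.95 * sqrtG, 1.05 * sqrtG
    widen = 0
    while residual(lo) * residual(hi) > 0:
        lo, hi = max(0.5 * sqrtG, lo * 0.8), min(2.0 * sqrtG, hi * 1.25)
        widen += 1
        if widen > 12 or (lo == 0.5 * sqrtG and hi == 2.0 * sqrtG
                          and residual(lo) * residual(hi) > 0):
            raise RuntimeError(
                "no transverse-equilibrium bracket in [0.5, 2.0]*sqrt(G_acc); "
                f"G_acc={structure.G_acc}, beta={beta_act}"
            )
    lt = brentq(residual, lo, hi, xtol=xtol, rtol=8.9e-16)
    sigma_ax, sigma_tr, J = _stress_components(
        lt, structure.G_acc, beta_act, mat, lambda_a
    )
    return EquilibriumState(
        lambda_axial=1.0,
        lambda_trans=lt,
        J=J,
        sigma_axial=sigma_ax,
        sigma_trans=sigma_tr,
        area_current=structure.area0 * lt * lt,
    )


@dataclass
class ForceResult:
    """Axial isometric force with its equilibrium state."""

    newtons: float
    kgf: float
    equilibrium: EquilibriumState


def isometric_force(
    structure: MuscleStructure,
    beta_act: float,
    mat: MaterialParameters,
) -> ForceResult:
    """Axial force transmitted at the fixed ends at activation beta.

    Force = axial Cauchy stress x deformed CSA (1 MPa cm^2 = 100 N),
    reported in newtons and kilograms-force.  Strictly increasing in
    beta_act.
    """
    eq = isometric_equilibrium(structure, beta_act, mat)
    newtons = eq.sigma_axial * eq.area_current * MPA_CM2_TO_N
    return ForceResult(newtons=newtons, kgf=newtons / KGF_TO_N, equilibrium=eq)


def activation_required(
    structure: MuscleStructure,
    force_target_kgf: float,
    mat: MaterialParameters,
    tol: float = 1e-8,
) -> float:
    """Activation beta in [0, 1] producing the target axial force (kgf).

    Numerical inverse of :func:`isometric_force` in beta by bracketed
    bisection/Brent iteration; the round-trip error
    |beta - activation_required(F(beta))| stays below 1e-6.  Raises
    :class:`UnreachableLoadError` when the load exceeds the current
    maximal force (the protocol load exceeds the current 1-RM).
    """
    if force_target_kgf < 0:
        raise ValueError("force target must be non-negative")

    def gap(beta: float) -> float:
        return isometric_force(structure, beta, mat).kgf - force_target_kgf

    g0, g1 = gap(0.0), gap(1.0)
    scale = max(1.0, abs(force_target_kgf))
    if g0 >= 0:
        return 0.0
    if g1 < 0:
        if g1 > -1e-9 * scale:   # target equals the maximum to round-off
            return 1.0
        raise UnreachableLoadError(
            f"load {force_target_kgf:.6g} kgf exceeds maximal force "
            f"{force_target_kgf + g1:.6g} kgf at the current CSA"
        )
    return brentq(gap, 0.0, 1.0, xtol=tol, rtol=8.9e-16)


def apply_growth(structure: MuscleStructure, G_step: float) -> MuscleStructure:
    """Compose one growth increment: G_acc <- G_acc * G_step.

    Growth tensors sharing the fiber axis compose multiplicatively on the
    transverse block, so accumulation is a scalar product.
    """
    if G_step <= 0:
        raise ValueError("G_step must be positive")
    return replace(structure, G_acc=structure.G_acc * G_step)
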
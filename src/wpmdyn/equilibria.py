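"""Equilibria of the WPM model and its basic reproduction number.

The model always admits the debris-free steady state::

    E0 = (W0, M0, R0) = ((mu+theta)*lambda/(theta*gamma), 0, lambda/theta)

and, whenever the basic reproduction number BR exceeds one, a unique positive
(debris-persistent) steady state::

    E* = (W*, M*, R*) = (alpha/beta, (mu+theta)*lambda/(theta*alpha) - gamma/beta, lambda/theta)

BR is the number of secondary units of marine debris produced per unit of
debris near the debris-free state,

    BR = beta*lambda*(mu+theta) / (alpha*gamma*theta),

and satisfies the identity M* = (gamma/beta) * (BR - 1), so debris persists
exactly when BR > 1.  Both equilibria share R = lambda/theta.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import sympy

from .model import ParameterSet, State, rhs

__all__ = [
    "Equilibrium",
    "ReproductionNumber",
    "reproduction_number",
    "reproduction_number_ngm",
    "debris_free_equilibrium",
    "positive_equilibrium",
    "THRESHOLD_TOL",
]

#: |BR - 1| below this is treated as the critical (threshold) case
THRESHOLD_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class ReproductionNumber:
    """Basic reproduction number together with its next-generation factors.

    ``f`` is the linearised new-debris generation rate at the debris-free
    state (``beta * W0``) and ``v`` the linearised debris removal rate
    (``alpha``); ``value = f / v``.
    """

    value: float
    f: float
    v: float


@dataclasses.dataclass(frozen=True)
class Equilibrium:
    """A named fixed point of the model.

    ``label`` is ``"debris_free"`` or ``"positive"``.  ``point`` carries
    named components (never positional tuples — published formats for these
    points are inconsistent about component order).  ``residual`` is the
    max-abs of the vector field at the point.  ``at_threshold`` marks the
    critical case |BR - 1| < THRESHOLD_TOL, where the positive branch
    coincides with the debris-free one.
    """

    label: str
    point: State | None
    exists: bool
    residual: float | None = None
    at_threshold: bool = False

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "exists": self.exists,
            "point": None if self.point is None else self.point.to_dict(),
            "residual": self.residual,
            "at_threshold": self.at_threshold,
        }


def reproduction_number(params: ParameterSet) -> ReproductionNumber:
    """BR from its closed form, with the generation/removal factors f and v."""
    w0 = (params.mu + params.theta) * params.lambda_ / (params.theta * params.gamma)
    f = params.beta * w0
    v = params.alpha
    return ReproductionNumber(value=f / v, f=f, v=v)


# Next-generation factors by genuine differentiation: F = beta*M*W generates
# new debris, V = alpha*M removes it; f = dF/dM and v = dV/dM are formed
# symbolically once and evaluated at the debris-free state.
_W_s, _M_s, _beta_s, _alpha_s = sympy.symbols("W M beta alpha", positive=True)
_dF_dM = sympy.lambdify((_W_s, _M_s, _beta_s), sympy.diff(_beta_s * _M_s * _W_s, _M_s), "numpy")
_dV_dM = sympy.lambdify((_M_s, _alpha_s), sympy.diff(_alpha_s * _M_s, _M_s), "numpy")


def reproduction_number_ngm(params: ParameterSet) -> ReproductionNumber:
    """BR via the next-generation-matrix construction.

    The generation and removal terms of the debris equation are linearised
    (by symbolic differentiation, not by substituting the closed form) at the
    debris-free equilibrium, and BR is the spectral radius of ``f * v^{-1}``.
    Agrees with :func:`reproduction_number` to floating-point accuracy.
    """
    e0 = debris_free_equilibrium(params)
    f = float(_dF_dM(e0.point.W, e0.point.M, params.beta))
    v = float(_dV_dM(e0.point.M, params.alpha))
    ngm = np.array([[f]]) @ np.linalg.inv(np.array([[v]]))
    value = float(np.max(np.abs(np.linalg.eigvals(ngm))))
    return ReproductionNumber(value=value, f=f, v=v)


def _residual(point: State, params: ParameterSet) -> float:
    return float(np.max(np.abs(rhs(point, params))))


def debris_free_equilibrium(params: ParameterSet) -> Equilibrium:
    """The debris-free steady state E0; exists for every parameter set."""
    point = State(
        W=(params.mu + params.theta) * params.lambda_ / (params.theta * params.gamma),
        M=0.0,
        R=params.lambda_ / params.theta,
    )
    return Equilibrium(
        label="debris_free",
        point=point,
        exists=True,
        residual=_residual(point, params),
    )


def positive_equilibrium(params: ParameterSet) -> Equilibrium:
    """The positive steady state E*; exists iff BR > 1.

    Non-existence (BR <= 1) is a result, not an error: the returned record
    has ``exists=False`` and no point.  |BR - 1| < THRESHOLD_TOL is reported
    as the threshold case (``at_threshold=True``), where M* = 0 and the
    branch merges with the debris-free one.
    """
    br = reproduction_number(params).value
    if abs(br - 1.0) < THRESHOLD_TOL:
        return Equilibrium(label="positive", point=None, exists=False, at_threshold=True)
    if br < 1.0:
        return Equilibrium(label="positive", point=None, exists=False)
    point = State(
        W=params.alpha / params.beta,
        M=(params.mu + params.theta) * params.lambda_ / (params.theta * params.alpha)
        - params.gamma / params.beta,
        R=params.lambda_ / params.theta,
    )
    return Equilibrium(
        label="positive",
        point=point,
        exists=True,
        residual=_residual(point, params),
    )
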
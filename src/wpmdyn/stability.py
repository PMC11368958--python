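"""Local and global stability analysis of the WPM equilibria.

Local classification is by the eigenvalues of the analytic Jacobian.  The
threshold structure is the classical one for compartment models: the
debris-free state E0 is locally (indeed globally) stable when BR <= 1 and
unstable when BR > 1, in which case the positive state E* takes over.

Global stability of E* is backed by the Lyapunov function

    L(W, M, R) = theta/2 * (R - R*)^2 + alpha/2 * [(W-W*) + (M-M*) + (R-R*)]^2

whose orbital derivative reduces, when alpha = gamma, to the non-positive
closed form ``-((mu+theta)*theta + alpha*theta) * (R - R*)^2``.  For
alpha != gamma the theorem does not apply; this module still evaluates the
chain-rule derivative for exploratory use, and global convergence can be
probed empirically with :func:`verify_global_convergence` (an ensemble
surrogate, not a proof).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model import ParameterSet, State, jacobian, rhs
from .equilibria import (
    Equilibrium,
    debris_free_equilibrium,
    positive_equilibrium,
    reproduction_number,
)
from . import simulate

__all__ = [
    "StabilityReport",
    "ConvergenceReport",
    "local_stability",
    "psi_submatrix",
    "lyapunov",
    "lyapunov_decay_closed_form",
    "verify_global_convergence",
    "convergence_from_trajectories",
    "EIGENVALUE_TOL",
]

#: eigenvalue real parts within this of zero are classified marginal
EIGENVALUE_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class StabilityReport:
    """Eigenvalue classification of one equilibrium.

    ``classification`` is ``stable`` (all real parts < -tol), ``unstable``
    (some real part > +tol) or ``marginal``.  For the debris-free
    equilibrium the report also carries the trace and determinant of the
    2x2 sub-matrix Psi = [[-gamma, mu], [gamma, -(mu+theta)]] that governs
    the non-critical directions at the bifurcation threshold.
    """

    equilibrium_label: str
    eigenvalues: tuple[complex, complex, complex]
    classification: str
    psi_trace: float | None = None
    psi_det: float | None = None

    def to_dict(self) -> dict:
        return {
            "equilibrium_label": self.equilibrium_label,
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "classification": self.classification,
            "psi_trace": self.psi_trace,
            "psi_det": self.psi_det,
        }


@dataclasses.dataclass(frozen=True)
class ConvergenceReport:
    """Summary of an ensemble convergence experiment toward one equilibrium."""

    target: Equilibrium
    n_runs: int
    n_converged: int
    max_final_distance: float
    horizon: float
    failures: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "target": self.target.to_dict(),
            "n_runs": self.n_runs,
            "n_converged": self.n_converged,
            "max_final_distance": self.max_final_distance,
            "horizon": self.horizon,
            "failures": list(self.failures),
        }


def psi_submatrix(params: ParameterSet) -> tuple[np.ndarray, float, float]:
    """The (W, R) sub-matrix at the threshold and its trace/determinant.

    trace(Psi) = -(mu + theta + gamma) < 0 and det(Psi) = gamma*theta > 0
    for every valid parameter set, so the two non-critical eigenvalues at
    the bifurcation point always have negative real parts.
    """
    g, m, t = params.gamma, params.mu, params.theta
    psi = np.array([[-g, m], [g, -(m + t)]])
    return psi, float(np.trace(psi)), float(np.linalg.det(psi))


def local_stability(
    eq: Equilibrium, params: ParameterSet, tol: float = EIGENVALUE_TOL
) -> StabilityReport:
    """Classify an existing equilibrium by the Jacobian eigenvalues."""
    if not eq.exists or eq.point is None:
        raise ValueError(f"equilibrium '{eq.label}' does not exist for these parameters")
    eigenvalues = np.linalg.eigvals(jacobian(eq.point, params))
    re = eigenvalues.real
    if np.all(re < -tol):
        classification = "stable"
    elif np.any(re > tol):
        classification = "unstable"
    else:
        classification = "marginal"
    psi_trace = psi_det = None
    if eq.label == "debris_free":
        _, psi_trace, psi_det = psi_submatrix(params)
    return StabilityReport(
        equilibrium_label=eq.label,
        eigenvalues=tuple(complex(ev) for ev in eigenvalues),
        classification=classification,
        psi_trace=psi_trace,
        psi_det=psi_det,
    )


def lyapunov(state, params: ParameterSet, eq: Equilibrium) -> tuple[float, float]:
    """Evaluate the Lyapunov function L and its orbital derivative dL/dt.

    ``eq`` must be the positive equilibrium.  dL/dt is the gradient of L
    contracted with the vector field (chain rule), so it is meaningful for
    any parameter set; it coincides with the closed form of
    :func:`lyapunov_decay_closed_form` up to rounding.
    """
    if eq.label != "positive" or not eq.exists or eq.point is None:
        raise ValueError("lyapunov requires the existing positive equilibrium")
    s = State.from_array(np.asarray(state, dtype=float)) if not isinstance(state, State) else state
    if not (s.W > 0 and s.M > 0 and s.R > 0):
        raise ValueError(f"lyapunov is defined on strictly positive states, got {s}")
    a, t = params.alpha, params.theta
    dW = s.W - eq.point.W
    dM = s.M - eq.point.M
    dR = s.R - eq.point.R
    total = dW + dM + dR
    L = 0.5 * t * dR**2 + 0.5 * a * total**2
    dy = rhs(s, params)
    # grad L = (a*total, a*total, theta*dR + a*total)
    dLdt = a * total * (dy[0] + dy[1] + dy[2]) + t * dR * dy[2]
    return float(L), float(dLdt)


def lyapunov_decay_closed_form(state, params: ParameterSet, eq: Equilibrium) -> float:
    """Closed form of dL/dt using the equilibrium relations:

        dL/dt = (gamma - alpha)*theta*(W - W*)*(R - R*)
                - ((mu + theta)*theta + alpha*theta)*(R - R*)^2

    For alpha = gamma the cross term vanishes and dL/dt <= 0 everywhere,
    which is the global-stability certificate for E*.
    """
    if eq.label != "positive" or not eq.exists or eq.point is None:
        raise ValueError("closed-form decay requires the existing positive equilibrium")
    s = State.from_array(np.asarray(state, dtype=float)) if not isinstance(state, State) else state
    g, a, m, t = params.gamma, params.alpha, params.mu, params.theta
    dW = s.W - eq.point.W
    dR = s.R - eq.point.R
    return float((g - a) * t * dW * dR - ((m + t) * t + a * t) * dR**2)


def convergence_from_trajectories(
    trajectories, params: ParameterSet, tol: float = 1e-3
) -> ConvergenceReport:
    """Build a :class:`ConvergenceReport` for trajectories already integrated.

    The target is E0 when BR <= 1 (or at the threshold) and E* when BR > 1.
    Failed integrations count as non-converged and are listed by index.
    """
    br = reproduction_number(params).value
    pos = positive_equilibrium(params)
    target = pos if pos.exists and br > 1.0 else debris_free_equilibrium(params)
    target_y = target.point.as_array()
    n_converged = 0
    max_dist = 0.0
    failures = []
    for i, traj in enumerate(trajectories):
        if not traj.success:
            failures.append(i)
            continue
        dist = float(np.max(np.abs(traj.final_state.as_array() - target_y)))
        max_dist = max(max_dist, dist)
        if dist < tol:
            n_converged += 1
    return ConvergenceReport(
        target=target,
        n_runs=len(trajectories),
        n_converged=n_converged,
        max_final_distance=max_dist,
        horizon=float(trajectories[-1].times[-1]) if trajectories else 0.0,
        failures=tuple(failures),
    )


def verify_global_convergence(
    params: ParameterSet,
    n_init: int = 20,
    seed: int = 0,
    init_box: tuple[float, float] = simulate.DEFAULT_INIT_BOX,
    horizon: float = 500.0,
    tol: float = 1e-3,
) -> ConvergenceReport:
    """Empirical surrogate for the global-stability theorems.

    Draws ``n_init`` strictly positive initial states uniformly in
    ``init_box``^3 (seeded), integrates each to ``horizon``, and counts how
    many end within ``tol`` (infinity norm) of the attracting equilibrium
    selected by BR.  Evidence, not proof: for alpha != gamma and BR > 1 no
    global theorem is claimed.
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    _, report = simulate.ensemble(
        params, n_init, seed, init_box=init_box, horizon=horizon, tol=tol
    )
    return report
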
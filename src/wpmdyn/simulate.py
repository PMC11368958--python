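"""Numerical integration of the WPM model and seeded ensemble runs.

Trajectories are computed with an adaptive high-order explicit Runge-Kutta
scheme (DOP853) and reported on a uniform time grid decoupled from the
internal steps.  With non-negative initial values the exact flow stays in
the non-negative octant; stored trajectories are post-checked against a
small floor (-1e-8) that tolerates solver-level noise only.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import ParameterSet, State, _coerce_state, rhs

__all__ = ["Trajectory", "integrate", "ensemble", "sample_initial_states",
           "POSITIVITY_FLOOR", "DEFAULT_INIT_BOX"]

#: allowed numerical undershoot below zero on stored trajectories
POSITIVITY_FLOOR = -1e-8

#: default per-component bounds for random initial states; covers the
#: worked-example initial point (1.5, 2, 1)
DEFAULT_INIT_BOX = (0.1, 5.0)


@dataclasses.dataclass
class Trajectory:
    """One simulated solution of the model.

    ``states`` has one row per reporting time, columns ordered (W, M, R).
    ``diagnostics`` records solver tolerances, the minimum component value
    encountered, the positivity check against :data:`POSITIVITY_FLOOR`, and
    the solver success flag/message.
    """

    times: np.ndarray
    states: np.ndarray
    params: ParameterSet
    initial: State
    diagnostics: dict

    @property
    def success(self) -> bool:
        return bool(self.diagnostics.get("success", False))

    @property
    def final_state(self) -> State:
        return State.from_array(self.states[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "W": self.states[:, 0],
             "M": self.states[:, 1], "R": self.states[:, 2]}
        )

    def to_csv(self, path=None) -> str | None:
        """Write columns t, W, M, R at full (repr round-trip) precision."""
        df = self.to_dataframe()
        if path is None:
            buf = io.StringIO()
            df.to_csv(buf, index=False)
            return buf.getvalue()
        df.to_csv(Path(path), index=False)
        return None


def integrate(
    params: ParameterSet,
    initial,
    horizon: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_points: int = 1000,
) -> Trajectory:
    """Integrate the model from ``initial`` over [0, horizon].

    ``initial`` must lie in the non-negative octant.  Solver failure is not
    raised: the trajectory is returned flagged unsuccessful with whatever
    partial output exists.
    """
    y0 = _coerce_state(initial)
    if np.any(y0 < 0):
        raise ValueError(f"initial state must be non-negative, got {y0}")
    if not horizon > 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    initial_state = State.from_array(y0)
    t_eval = np.linspace(0.0, horizon, n_points)
    sol = solve_ivp(
        lambda t, y: rhs(y, params),
        (0.0, horizon),
        y0,
        method="DOP853",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    states = sol.y.T
    min_component = float(states.min()) if states.size else float("nan")
    diagnostics = {
        "success": bool(sol.success),
        "message": sol.message,
        "rtol": rtol,
        "atol": atol,
        "min_component": min_component,
        "positivity_ok": bool(states.size and min_component >= POSITIVITY_FLOOR),
    }
    return Trajectory(
        times=sol.t,
        states=states,
        params=params,
        initial=initial_state,
        diagnostics=diagnostics,
    )


def sample_initial_states(
    n: int,
    seed: int,
    init_box: tuple[float, float] = DEFAULT_INIT_BOX,
    floor: float = 1e-3,
) -> list[State]:
    """Draw ``n`` strictly positive initial states uniformly in ``init_box``^3.

    Each run gets its own deterministic child stream of ``seed``, so growing
    ``n`` appends new draws without reshuffling earlier ones.  Components
    are kept at or above ``floor`` (the global-stability argument for the
    positive equilibrium needs strictly positive states).
    """
    lo, hi = init_box
    if not (0 <= lo < hi):
        raise ValueError(f"init_box must satisfy 0 <= lo < hi, got {init_box}")
    children = np.random.SeedSequence(seed).spawn(n)
    states = []
    for child in children:
        draw = np.random.default_rng(child).uniform(lo, hi, size=3)
        states.append(State.from_array(np.maximum(draw, floor)))
    return states


def ensemble(
    params: ParameterSet,
    n: int,
    seed: int,
    init_box: tuple[float, float] = DEFAULT_INIT_BOX,
    horizon: float = 500.0,
    tol: float = 1e-3,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Integrate ``n`` seeded random initial states and summarise convergence.

    Returns ``(trajectories, report)`` where ``report`` is a
    :class:`wpmdyn.stability.ConvergenceReport` against the attracting
    equilibrium selected by the reproduction number (E0 when BR <= 1,
    E* when BR > 1).
    """
    from . import stability  # deferred: stability imports this module

    if n < 1:
        raise ValueError("ensemble size n must be >= 1")
    trajectories = [
        integrate(params, s, horizon, rtol=rtol, atol=atol)
        for s in sample_initial_states(n, seed, init_box)
    ]
    report = stability.convergence_from_trajectories(trajectories, params, tol=tol)
    return trajectories, report
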
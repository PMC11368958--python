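"""Core definition of the waste-plastic-management (WPM) compartment model.

The model tracks three pools of plastic material in the ocean system:

* ``W`` — waste plastic on land / entering the system,
* ``M`` — marine debris,
* ``R`` — material in the recycling process.

Their dynamics are the nonlinear ODE system::

    W' = lambda - gamma*W - beta*M*W + mu*R
    M' = beta*M*W - alpha*M
    R' = gamma*W + alpha*M - (mu + theta)*R

with six strictly positive rate constants.  Adding the three equations gives
the bookkeeping identity ``(W + M + R)' = lambda - theta*R``: material enters
at rate ``lambda`` and is permanently lost only from the recycling pool at
rate ``theta``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "State",
    "rhs",
    "jacobian",
    "load_config",
    "save_config",
]

#: order of the parameter keys in config files and tabular output
PARAM_KEYS = ("lambda", "gamma", "beta", "mu", "alpha", "theta")

# attribute name on ParameterSet for each config key ("lambda" is a Python keyword)
_ATTR_FOR_KEY = {
    "lambda": "lambda_",
    "gamma": "gamma",
    "beta": "beta",
    "mu": "mu",
    "alpha": "alpha",
    "theta": "theta",
}
_KEY_FOR_ATTR = {v: k for k, v in _ATTR_FOR_KEY.items()}


@dataclasses.dataclass(frozen=True)
class ParameterSet:
    """The six positive rates of the WPM model.

    Parameters
    ----------
    lambda_ : float
        Rate of new waste production (amount / time).
    gamma : float
        Rate of direct recycling of waste (1 / time).
    beta : float
        Waste-to-marine-debris contact rate (1 / (amount * time)).
    mu : float
        Recycled-to-new-waste return rate (1 / time).
    alpha : float
        Marine-debris recycling rate (1 / time).
    theta : float
        Recycled-waste loss rate (1 / time).

    All rates must be strictly positive: the closed-form equilibria and the
    reproduction number divide by ``gamma``, ``theta``, ``alpha`` and
    ``beta``, so zero rates are rejected at construction rather than
    special-cased downstream.
    """

    lambda_: float
    gamma: float
    beta: float
    mu: float
    alpha: float
    theta: float

    def __post_init__(self) -> None:
        for attr in _KEY_FOR_ATTR:
            value = getattr(self, attr)
            key = _KEY_FOR_ATTR[attr]
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ValueError(f"parameter '{key}' must be a real number, got {value!r}")
            value = float(value)
            if not math.isfinite(value):
                raise ValueError(f"parameter '{key}' must be finite, got {value!r}")
            if value <= 0.0:
                raise ValueError(f"parameter '{key}' must be strictly positive, got {value!r}")
            object.__setattr__(self, attr, value)

    def to_dict(self) -> dict[str, float]:
        """Return the parameters keyed by their config names, in canonical order."""
        return {key: getattr(self, _ATTR_FOR_KEY[key]) for key in PARAM_KEYS}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ParameterSet":
        missing = [k for k in PARAM_KEYS if k not in d]
        if missing:
            raise ValueError(f"missing parameter(s): {', '.join(missing)}")
        extra = [k for k in d if k not in PARAM_KEYS and k != "initial"]
        if extra:
            raise ValueError(f"unknown parameter(s): {', '.join(extra)}")
        return cls(**{_ATTR_FOR_KEY[k]: float(d[k]) for k in PARAM_KEYS})

    def replace(self, **kwargs: float) -> "ParameterSet":
        """Return a copy with some rates replaced; accepts config-style names too."""
        mapped = {_ATTR_FOR_KEY.get(k, k): v for k, v in kwargs.items()}
        return dataclasses.replace(self, **mapped)

    def as_array(self) -> np.ndarray:
        """Rates as an array ordered (lambda, gamma, beta, mu, alpha, theta)."""
        return np.array(
            [self.lambda_, self.gamma, self.beta, self.mu, self.alpha, self.theta]
        )


@dataclasses.dataclass(frozen=True)
class State:
    """A point (W, M, R) of the model's phase space.

    The physically meaningful region is the non-negative octant
    ``Omega = {W >= 0, M >= 0, R >= 0}``, which is positively invariant for
    the flow; construction only requires finiteness so that integrator
    internals and perturbation probes can represent transiently negative
    points.  Use :meth:`in_omega` to test octant membership.
    """

    W: float
    M: float
    R: float

    def __post_init__(self) -> None:
        for name in ("W", "M", "R"):
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ValueError(f"state component '{name}' must be a real number, got {value!r}")
            if not math.isfinite(float(value)):
                raise ValueError(f"state component '{name}' must be finite, got {value!r}")
            object.__setattr__(self, name, float(value))

    def as_array(self) -> np.ndarray:
        return np.array([self.W, self.M, self.R])

    @classmethod
    def from_array(cls, y) -> "State":
        y = np.asarray(y, dtype=float)
        if y.shape != (3,):
            raise ValueError(f"state array must have shape (3,), got {y.shape}")
        return cls(W=float(y[0]), M=float(y[1]), R=float(y[2]))

    def in_omega(self, floor: float = 0.0) -> bool:
        """Whether all components lie at or above ``floor`` (default: octant membership)."""
        return self.W >= floor and self.M >= floor and self.R >= floor

    def to_dict(self) -> dict[str, float]:
        return {"W": self.W, "M": self.M, "R": self.R}


def _coerce_state(state) -> np.ndarray:
    if isinstance(state, State):
        return state.as_array()
    y = np.asarray(state, dtype=float)
    if y.shape != (3,):
        raise ValueError(f"state must have 3 components (W, M, R), got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"state components must be finite, got {y}")
    return y


def _rhs_raw(y: np.ndarray, lam: float, gamma: float, beta: float,
             mu: float, alpha: float, theta: float) -> np.ndarray:
    # used directly by the bifurcation sweep at beta = 0, where a ParameterSet
    # cannot be constructed
    W, M, R = y
    return np.array(
        [
            lam - gamma * W - beta * M * W + mu * R,
            beta * M * W - alpha * M,
            gamma * W + alpha * M - (mu + theta) * R,
        ]
    )


def rhs(state, params: ParameterSet) -> np.ndarray:
    """Time derivative (W', M', R') of the model at ``state``.

    Negative components are accepted (adaptive integrators probe outside the
    octant); non-finite components raise ``ValueError``.  In exact arithmetic
    the components sum to ``lambda - theta*R``.
    """
    y = _coerce_state(state)
    return _rhs_raw(y, params.lambda_, params.gamma, params.beta,
                    params.mu, params.alpha, params.theta)


def jacobian(state, params: ParameterSet) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs`, rows/columns ordered (W, M, R)."""
    y = _coerce_state(state)
    W, M, _R = y
    g, b, m, a, t = params.gamma, params.beta, params.mu, params.alpha, params.theta
    return np.array(
        [
            [-g - b * M, -b * W, m],
            [b * M, b * W - a, 0.0],
            [g, a, -(m + t)],
        ]
    )


def load_config(path) -> tuple[ParameterSet, State | None]:
    """Read a YAML or JSON config file.

    The file holds the six rate keys (``lambda``, ``gamma``, ``beta``,
    ``mu``, ``alpha``, ``theta``) and optionally ``initial: {W, M, R}``.
    Returns the parameter set and the initial state (or ``None``).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"config file {path} must contain a mapping")
    params = ParameterSet.from_dict(data)
    initial = None
    if "initial" in data:
        init = data["initial"]
        if not isinstance(init, Mapping) or set(init) != {"W", "M", "R"}:
            raise ValueError("'initial' must be a mapping with exactly the keys W, M, R")
        initial = State(W=float(init["W"]), M=float(init["M"]), R=float(init["R"]))
    return params, initial


def save_config(path, params: ParameterSet, initial: State | None = None) -> None:
    """Write a config file (format chosen by suffix) preserving full float precision."""
    path = Path(path)
    data: dict = params.to_dict()
    if initial is not None:
        data["initial"] = initial.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
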
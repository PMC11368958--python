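"""Normalized forward sensitivity of the reproduction number.

The elasticity of BR with respect to a parameter p is

    SI_p = (p / BR) * dBR/dp.

Because BR = beta*lambda*(mu+theta)/(alpha*gamma*theta) is a product of
powers except in (mu, theta), the indices are closed-form constants:

    SI_beta = +1        SI_lambda = +1
    SI_mu = mu/(mu+theta)            SI_alpha = -1
    SI_gamma = -1       SI_theta = -mu/(mu+theta)

The mu and theta indices are equal in magnitude, opposite in sign, and
strictly inside (-1, 1); pairwise the indices sum to zero (beta/alpha,
lambda/gamma, mu/theta), reflecting the log-derivative structure of BR.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .model import ParameterSet
from .equilibria import reproduction_number

__all__ = [
    "SensitivityEntry",
    "SensitivityReport",
    "PerturbationResult",
    "sensitivity_report",
    "perturb_scenario",
    "PARAM_ORDER",
]

#: reporting order of the parameters
PARAM_ORDER = ("beta", "lambda", "mu", "alpha", "gamma", "theta")


@dataclasses.dataclass(frozen=True)
class SensitivityEntry:
    name: str
    value: float
    index_closed_form: float
    index_numeric: float


@dataclasses.dataclass(frozen=True)
class SensitivityReport:
    entries: tuple[SensitivityEntry, ...]

    def __getitem__(self, name: str) -> SensitivityEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(e) for e in self.entries])

    def to_dict(self) -> dict:
        return {"entries": [dataclasses.asdict(e) for e in self.entries]}


@dataclasses.dataclass(frozen=True)
class PerturbationResult:
    """Effect on BR of scaling one parameter by (1 + pct/100)."""

    name: str
    pct: float
    br_baseline: float
    br_exact: float
    br_linear: float
    pct_change_exact: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _closed_form_indices(params: ParameterSet) -> dict[str, float]:
    frac = params.mu / (params.mu + params.theta)
    return {
        "beta": 1.0,
        "lambda": 1.0,
        "mu": frac,
        "alpha": -1.0,
        "gamma": -1.0,
        "theta": -frac,
    }


def _numeric_index(params: ParameterSet, name: str, step: float) -> float:
    """Central finite difference of BR in one parameter, as an elasticity."""
    value = params.to_dict()[name]
    h = step * value if value >= 1e-6 else step  # absolute fallback for tiny rates
    br = reproduction_number(params).value
    up = reproduction_number(params.replace(**{name: value + h})).value
    down = reproduction_number(params.replace(**{name: value - h})).value
    return (up - down) / (2.0 * h) * value / br


def sensitivity_report(params: ParameterSet, step: float = 1e-6) -> SensitivityReport:
    """Closed-form and finite-difference sensitivity indices for all six rates.

    ``step`` is the relative step of the central difference used for the
    numeric cross-check; it must satisfy 0 < step << 1.
    """
    if not 0 < step < 0.1:
        raise ValueError(f"step must be a small positive relative step, got {step}")
    closed = _closed_form_indices(params)
    values = params.to_dict()
    entries = tuple(
        SensitivityEntry(
            name=name,
            value=values[name],
            index_closed_form=closed[name],
            index_numeric=_numeric_index(params, name, step),
        )
        for name in PARAM_ORDER
    )
    return SensitivityReport(entries=entries)


def perturb_scenario(params: ParameterSet, name: str, pct: float) -> PerturbationResult:
    """Recompute BR with one parameter scaled by (1 + pct/100).

    Returns both the exact recomputation and the first-order estimate
    ``BR * (1 + SI * pct/100)`` from the sensitivity index.  For the
    parameters in which BR is linear (beta and lambda) the two coincide and
    the percent change equals ``pct`` exactly; for the reciprocal (alpha,
    gamma) and ratio (mu, theta) parameters they differ at second order.
    """
    name = "lambda" if name == "lambda_" else name
    if name not in PARAM_ORDER:
        raise ValueError(f"unknown parameter {name!r}; expected one of {PARAM_ORDER}")
    value = params.to_dict()[name]
    new_value = value * (1.0 + pct / 100.0)
    if new_value <= 0:
        raise ValueError(
            f"perturbing '{name}' by {pct}% drives it to {new_value}, which is not positive"
        )
    br0 = reproduction_number(params).value
    br_exact = reproduction_number(params.replace(**{name: new_value})).value
    index = _closed_form_indices(params)[name]
    br_linear = br0 * (1.0 + index * pct / 100.0)
    return PerturbationResult(
        name=name,
        pct=float(pct),
        br_baseline=br0,
        br_exact=br_exact,
        br_linear=br_linear,
        pct_change_exact=100.0 * (br_exact - br0) / br0,
    )
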
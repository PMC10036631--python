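"""Parametric Lorenz-curve models and their Gini indices.

Three functional forms for the Lorenz curve y(x), where x is the cumulative
normalized rank of observations sorted ascending by size and y the cumulative
normalized share of total size:

* the universal four-parameter model — a weighted combination of a
  piecewise-linear component, a power ("exponential") component and a
  Pareto-implied component, with closed-form Gini
  ``1 - 2*(1 - delta)/(P + 1)``;
* the three-parameter SCS comparator ``y = x**gamma * (1-(1-x)**alpha)**beta``
  whose Gini requires numerical integration;
* the four-parameter S comparator mixing the diagonal, a power curve and a
  classical Pareto curve, with closed-form Gini.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import integrate

__all__ = [
    "ProposedParams",
    "SCSParams",
    "SParams",
    "CurveEvaluation",
    "ConditionReport",
    "proposed_lorenz",
    "proposed_area",
    "gini_proposed",
    "scs_lorenz",
    "gini_scs",
    "s_lorenz",
    "gini_s",
    "evaluate_model",
    "quadrature_area",
    "check_lorenz_conditions",
    "MODEL_IDS",
]

MODEL_IDS = ("proposed", "scs", "s")

ArrayLike = Union[float, np.ndarray]

# strict bounds realized as closed numerical boxes
DELTA_MAX = 1.0 - 1e-6
ALPHA_MIN = 1e-6


@dataclass(frozen=True)
class ProposedParams:
    """Parameters of the universal Lorenz model.

    delta : length of the initial horizontal segment (the rank share held by
        zero-size observations), 0 <= delta < 1.
    rho : weight on the convex component (the remainder 1-rho goes to the
        linear component), 0 <= rho <= 1.
    omega : weight on the Pareto-implied term inside the convex mix (1-omega
        on the power term); controls curvature at constant Gini, 0 <= omega <= 1.
    P : inequality parameter, P >= 1; together with delta it fixes the Gini.
    """

    delta: float
    rho: float
    omega: float
    P: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta < 1.0):
            raise ValueError(f"delta must satisfy 0 <= delta < 1, got {self.delta}")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must satisfy 0 <= rho <= 1, got {self.rho}")
        if not (0.0 <= self.omega <= 1.0):
            raise ValueError(f"omega must satisfy 0 <= omega <= 1, got {self.omega}")
        if not self.P >= 1.0:
            raise ValueError(f"P must satisfy P >= 1, got {self.P}")

    def to_dict(self) -> dict:
        return {"delta": self.delta, "rho": self.rho, "omega": self.omega, "P": self.P}

    @classmethod
    def from_dict(cls, d: dict) -> "ProposedParams":
        return cls(delta=d["delta"], rho=d["rho"], omega=d["omega"], P=d["P"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class SCSParams:
    """Parameters of the SCS comparator ``y = x**gamma * (1-(1-x)**alpha)**beta``."""

    gamma: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not self.gamma >= 0.0:
            raise ValueError(f"gamma must satisfy gamma >= 0, got {self.gamma}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must satisfy 0 < alpha <= 1, got {self.alpha}")
        if not self.beta >= 1.0:
            raise ValueError(f"beta must satisfy beta >= 1, got {self.beta}")

    def to_dict(self) -> dict:
        return {"gamma": self.gamma, "alpha": self.alpha, "beta": self.beta}

    @classmethod
    def from_dict(cls, d: dict) -> "SCSParams":
        return cls(gamma=d["gamma"], alpha=d["alpha"], beta=d["beta"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class SParams:
    """Parameters of the S comparator
    ``y = (1-lambda+eta)*x + lambda*x**(a1+1) - eta*(1-(1-x)**(a2+1))``.

    Constraints: lambda >= 0, a1 >= 0, a2 + 1 > 0, eta*a2 >= 0,
    eta*a2 + lambda <= 1; eta >= 0 is additionally assumed (all published
    parameterizations are non-negative).
    """

    lam: float
    eta: float
    a1: float
    a2: float

    def __post_init__(self) -> None:
        if not self.lam >= 0.0:
            raise ValueError(f"lambda must satisfy lambda >= 0, got {self.lam}")
        if not self.eta >= 0.0:
            raise ValueError(f"eta must satisfy eta >= 0, got {self.eta}")
        if not self.a1 >= 0.0:
            raise ValueError(f"a1 must satisfy a1 >= 0, got {self.a1}")
        if not self.a2 + 1.0 > 0.0:
            raise ValueError(f"a2 must satisfy a2 + 1 > 0, got {self.a2}")
        if self.eta * self.a2 < 0.0:
            raise ValueError("eta*a2 must be non-negative")
        if self.eta * self.a2 + self.lam > 1.0 + 1e-12:
            raise ValueError(
                f"eta*a2 + lambda must be <= 1, got {self.eta * self.a2 + self.lam}"
            )

    def to_dict(self) -> dict:
        return {"lambda": self.lam, "eta": self.eta, "a1": self.a1, "a2": self.a2}

    @classmethod
    def from_dict(cls, d: dict) -> "SParams":
        lam = d.get("lambda", d.get("lam"))
        return cls(lam=lam, eta=d["eta"], a1=d["a1"], a2=d["a2"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class CurveEvaluation:
    """A model curve evaluated on a grid: x in [0,1], y in [0,1]."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape:
            raise ValueError("x and y must have the same shape")


def _check_x(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > 1.0 + 1e-12):
        raise ValueError("x must lie in [0, 1]")
    return np.clip(x, 0.0, 1.0)


def proposed_lorenz(x: ArrayLike, params: ProposedParams) -> ArrayLike:
    """Evaluate the universal Lorenz model.

    All three components vanish for x < delta.  The linear component is 1 at
    x = 1 by its piecewise definition, so y(1) = 1 always; when rho < 1 and
    P > 1 this produces a jump at the top rank (the one-large/many-equal
    regime).
    """
    scalar = np.isscalar(x)
    xa = _check_x(np.atleast_1d(x))
    d, rho, omega, P = params.delta, params.rho, params.omega, params.P
    # u < 0 clips to 0, where every component is exactly 0
    u = np.clip((xa - d) / (1.0 - d), 0.0, 1.0)
    lin = np.where(xa >= 1.0, 1.0, (2.0 / (P + 1.0)) * u)
    power = u**P
    pareto = 1.0 - (1.0 - u) ** (1.0 / P)
    y = (1.0 - rho) * lin + rho * ((1.0 - omega) * power + omega * pareto)
    return float(y[0]) if scalar else y


def proposed_area(params: ProposedParams) -> float:
    """Closed-form area under the universal model: (1 - delta)/(P + 1).

    Each of the three components integrates to the same value, so the area is
    independent of rho and omega.
    """
    return (1.0 - params.delta) / (params.P + 1.0)


def gini_proposed(params: ProposedParams) -> float:
    """Closed-form Gini index of the universal model: 1 - 2*(1-delta)/(P+1)."""
    return 1.0 - 2.0 * proposed_area(params)


def scs_lorenz(x: ArrayLike, params: SCSParams) -> ArrayLike:
    """Evaluate the SCS model ``y = x**gamma * (1-(1-x)**alpha)**beta``.

    0**0 is taken as 1 by continuity, so y(1) = 1 for every valid parameter
    set (including gamma = 0).
    """
    scalar = np.isscalar(x)
    xa = _check_x(np.atleast_1d(x))
    g, a, b = params.gamma, params.alpha, params.beta
    y = xa**g * (1.0 - (1.0 - xa) ** a) ** b
    return float(y[0]) if scalar else y


def gini_scs(params: SCSParams, tol: float = 1e-9) -> float:
    """Gini of the SCS model by adaptive quadrature: 1 - 2*integral(y).

    The SCS model has no closed-form Gini.  Raises RuntimeError if the
    quadrature error estimate exceeds the requested absolute tolerance by
    more than two orders of magnitude.
    """
    val, err = integrate.quad(
        lambda t: scs_lorenz(t, params), 0.0, 1.0, epsabs=tol, epsrel=1e-10, limit=400
    )
    if err > max(100.0 * tol, 1e-7):
        raise RuntimeError(
            f"quadrature for the SCS Gini did not converge (error estimate {err:g})"
        )
    return 1.0 - 2.0 * val


def s_lorenz(x: ArrayLike, params: SParams) -> ArrayLike:
    """Evaluate the S model; y(0)=0 and y(1)=1 hold algebraically."""
    scalar = np.isscalar(x)
    xa = _check_x(np.atleast_1d(x))
    lam, eta, a1, a2 = params.lam, params.eta, params.a1, params.a2
    y = (
        (1.0 - lam + eta) * xa
        + lam * xa ** (a1 + 1.0)
        - eta * (1.0 - (1.0 - xa) ** (a2 + 1.0))
    )
    return float(y[0]) if scalar else y


def gini_s(params: SParams) -> float:
    """Closed-form Gini of the S model:
    lambda*(1 - 2/(2+a1)) + eta*(1 - 2/(2+a2))."""
    return params.lam * (1.0 - 2.0 / (2.0 + params.a1)) + params.eta * (
        1.0 - 2.0 / (2.0 + params.a2)
    )


_EVALUATORS = {"proposed": proposed_lorenz, "scs": scs_lorenz, "s": s_lorenz}


def evaluate_model(model: str, x: ArrayLike, params) -> ArrayLike:
    """Dispatch evaluation by model id ('proposed', 'scs' or 's')."""
    try:
        fn = _EVALUATORS[model]
    except KeyError:
        raise ValueError(f"unknown model id {model!r}; expected one of {MODEL_IDS}")
    return fn(x, params)


def quadrature_area(model: str, params, tol: float = 1e-9) -> float:
    """Area under a model curve by adaptive quadrature.

    For the universal model the integrand is split at delta (kink) and the
    value of the curve exactly at x=1 is irrelevant to the integral, so the
    jump there does not affect the result.
    """
    pts = None
    if model == "proposed" and params.delta > 0.0:
        pts = [params.delta]
    val, err = integrate.quad(
        lambda t: evaluate_model(model, t, params),
        0.0,
        1.0,
        points=pts,
        epsabs=tol,
        epsrel=1e-10,
        limit=400,
    )
    if err > max(100.0 * tol, 1e-7):
        raise RuntimeError(f"area quadrature did not converge (error estimate {err:g})")
    return val


@dataclass
class ConditionReport:
    """Report on the theoretical Lorenz-curve conditions for a model curve.

    The conditions are y(0)=0, y(1)=1, non-negative first differences
    (monotonicity) and non-negative second differences on the convex portion.
    A jump at x=1 (a mass atom at the top rank, arising in the universal
    model whenever rho < 1 and P > 1) is reported, not treated as a failure.
    """

    boundary_zero_ok: bool
    boundary_one_ok: bool
    monotone_ok: bool
    convex_ok: bool
    jump_at_one: float
    grid_size: int
    notes: list = field(default_factory=list)

    @property
    def all_ok(self) -> bool:
        return (
            self.boundary_zero_ok
            and self.boundary_one_ok
            and self.monotone_ok
            and self.convex_ok
        )

    def to_dict(self) -> dict:
        return {
            "boundary_zero_ok": self.boundary_zero_ok,
            "boundary_one_ok": self.boundary_one_ok,
            "monotone_ok": self.monotone_ok,
            "convex_ok": self.convex_ok,
            "jump_at_one": self.jump_at_one,
            "grid_size": self.grid_size,
            "notes": list(self.notes),
        }


def check_lorenz_conditions(model: str, params, grid_size: int = 1000) -> ConditionReport:
    """Verify the Lorenz-curve conditions on a uniform grid.

    Monotonicity tolerance: first differences >= -1e-12.  Convexity
    tolerance: second differences >= -1e-10, checked on the convex portion
    only (x > delta for the universal model) and excluding the top grid cell
    when the curve jumps at x=1.
    """
    if grid_size < 10:
        raise ValueError("grid_size must be >= 10")
    x = np.linspace(0.0, 1.0, grid_size + 1)
    y = np.asarray(evaluate_model(model, x, params), dtype=float)

    notes: list = []
    b0 = bool(abs(y[0]) <= 1e-12)
    b1 = bool(abs(y[-1] - 1.0) <= 1e-12)

    jump = 0.0
    if model == "proposed":
        # analytic left limit at x=1: (1-rho)*2/(P+1) + rho
        y_left = (1.0 - params.rho) * 2.0 / (params.P + 1.0) + params.rho
        jump = max(0.0, 1.0 - y_left)
        if jump > 1e-9:
            notes.append(
                f"discontinuity at x=1: mass atom of size {jump:.6g} at the top rank"
            )

    d1 = np.diff(y)
    monotone = bool(np.all(d1 >= -1e-12))

    if model == "proposed":
        interior = x[1:-1] > params.delta + 1e-12
    else:
        interior = np.ones(len(x) - 2, dtype=bool)
    if jump > 1e-9:
        interior = interior.copy()
        interior[-1] = False  # second difference spanning the jump
    d2 = np.diff(y, 2)[interior]
    convex = bool(d2.size == 0 or np.all(d2 >= -1e-10))

    if model == "proposed" and params.delta == 0.0 and params.P == 1.0:
        notes.append("delta=0 and P=1: the curve is the egalitarian line")

    return ConditionReport(
        boundary_zero_ok=b0,
        boundary_one_ok=b1,
        monotone_ok=monotone,
        convex_ok=convex,
        jump_at_one=jump,
        grid_size=grid_size,
        notes=notes,
    )
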
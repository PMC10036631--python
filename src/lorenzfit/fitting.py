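"""Constrained least-squares estimation of Lorenz-curve model parameters.

Parameters are estimated by minimizing the sum of squared errors
SSE = sum_i (y_i - yhat_i)^2 between the empirical cumulative shares y_i and
the model curve evaluated at the empirical ranks x_i, over the bounded
parameter box given by each model's constraints.  The SSE surface is
multimodal (and exactly flat in omega when rho = 0), so the minimization uses
multistart bounded local optimization: deterministic data-driven and corner
starts followed by seeded random starts, with the best final SSE returned.
Runs are fully deterministic given (points, config).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import optimize

from .data import LorenzPoints, discrete_gini
from .gof import GofReport, gof, sse as _sse
from .models import (
    ALPHA_MIN,
    DELTA_MAX,
    MODEL_IDS,
    ProposedParams,
    SCSParams,
    SParams,
    evaluate_model,
    gini_proposed,
    gini_s,
    gini_scs,
)

__all__ = ["FitConfig", "FitResult", "FitError", "fit", "canonicalize", "profile_omega"]

DEFAULT_SEED = 20230323
CANON_EPS = 1e-6
# tie tolerance between equally good local optima
_TIE_TOL = 1e-12

# parameter boxes: (names, lower, upper)
_BOXES = {
    "proposed": (
        ("delta", "rho", "omega", "P"),
        np.array([0.0, 0.0, 0.0, 1.0]),
        np.array([DELTA_MAX, 1.0, 1.0, 1000.0]),
    ),
    "scs": (
        ("gamma", "alpha", "beta"),
        np.array([0.0, ALPHA_MIN, 1.0]),
        np.array([100.0, 1.0, 500.0]),
    ),
    "s": (
        ("lambda", "eta", "a1", "a2"),
        np.array([0.0, 0.0, 0.0, 0.0]),
        np.array([1.0, 1e6, 1000.0, 1000.0]),
    ),
}


class FitError(RuntimeError):
    """Raised when every local optimization start fails."""


@dataclass(frozen=True)
class FitConfig:
    """Configuration of a model fit.

    model : 'proposed', 'scs' or 's'.
    n_starts : number of local-optimization starts (>= 1); the start sequence
        is prefix-stable, so increasing n_starts never worsens the result.
    seed : seed of the random starts.
    grid_points : optional quantile thinning of the objective for very large
        samples (None = use all empirical points, the default).
    canonicalize : snap non-identifiable directions of the universal model
        (omega when rho ~ 0; rho, omega on the egalitarian line).
    """

    model: str = "proposed"
    n_starts: int = 32
    seed: int = DEFAULT_SEED
    grid_points: Optional[int] = None
    canonicalize: bool = True
    xtol: float = 1e-15
    ftol: float = 1e-15
    gtol: float = 1e-15
    max_nfev: int = 5000

    def __post_init__(self) -> None:
        if self.model not in MODEL_IDS:
            raise ValueError(f"model must be one of {MODEL_IDS}, got {self.model!r}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.grid_points is not None and self.grid_points < 8:
            raise ValueError("grid_points must be >= 8 when set")

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "grid_points": self.grid_points,
            "canonicalize": self.canonicalize,
            "xtol": self.xtol,
            "ftol": self.ftol,
            "gtol": self.gtol,
            "max_nfev": self.max_nfev,
        }


@dataclass(frozen=True)
class FitResult:
    """Outcome of a model fit: parameters, SSE, GoF report and Gini.

    gini is the closed-form value for the universal and S models and the
    quadrature value for SCS.
    """

    model: str
    params: object
    sse: float
    gof: GofReport
    gini: float
    n_points: int
    n_starts: int
    converged: bool
    notes: tuple = ()

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params.to_dict(),
            "sse": self.sse,
            "gof": self.gof.to_dict(),
            "gini": self.gini,
            "n_points": self.n_points,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "notes": list(self.notes),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_csv_row(self) -> dict:
        """Human-readable row: parameters 2 dp, GoF 4 dp, Gini 3 dp."""
        row = {"model": self.model}
        row.update({k: f"{v:.2f}" for k, v in self.params.to_dict().items()})
        row.update(self.gof.to_csv_row())
        row["gini"] = f"{self.gini:.3f}"
        return row


def _n_free(model: str) -> int:
    return len(_BOXES[model][0])


def _make_params(model: str, vec: np.ndarray):
    lo, hi = _BOXES[model][1], _BOXES[model][2]
    vec = [float(v) for v in np.clip(np.asarray(vec, dtype=float), lo, hi)]
    if model == "proposed":
        return ProposedParams(delta=vec[0], rho=vec[1], omega=vec[2], P=vec[3])
    if model == "scs":
        return SCSParams(gamma=vec[0], alpha=vec[1], beta=vec[2])
    lam, eta, a1, a2 = vec
    if eta * a2 + lam > 1.0:  # project onto the constraint
        if a2 > 0 and eta > 0:
            eta = min(eta, max(0.0, (1.0 - lam) / a2))
        else:
            lam = min(lam, 1.0)
    return SParams(lam=lam, eta=eta, a1=a1, a2=a2)


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _heuristic_starts(model: str, x: np.ndarray, y: np.ndarray) -> list:
    """Deterministic data-driven and corner starting points."""
    # initial horizontal run (zero sizes) and a Gini-matched inequality level
    zero_run = x[y <= 1e-12]
    delta0 = min(float(zero_run[-1]) if zero_run.size else 0.0, DELTA_MAX - 1e-3)
    pts = LorenzPoints(x=x, y=np.minimum(y, x))
    g = min(max(discrete_gini(pts, "population"), 0.0), 1.0 - 1e-6)
    p0 = float(np.clip(2.0 * (1.0 - delta0) / (1.0 - g) - 1.0, 1.0, 999.0))
    if model == "proposed":
        return [
            np.array([delta0, 1.0, 0.5, p0]),
            np.array([delta0, 0.0, 0.0, p0]),
            np.array([delta0, 1.0, 0.0, p0]),
            np.array([delta0, 1.0, 1.0, p0]),
            np.array([0.0, 0.5, 0.5, 2.0]),
            np.array([0.0, 0.05, 0.5, p0]),
        ]
    if model == "scs":
        return [
            np.array([0.0, 0.5, 2.0]),
            np.array([0.0, 1.0, max(p0, 1.0)]),
            np.array([1.0, 1.0, 1.0]),
            np.array([0.5, 0.3, 1.5]),
        ]
    return [
        np.array([0.5, 0.1, 1.0, 1.0]),
        np.array([min(1.0, g * 2.0), 0.0, max(p0 - 1.0, 0.1), 0.5]),
        np.array([1.0, 0.0, max(p0 - 1.0, 0.1), 0.0]),
        np.array([0.3, 0.3, 2.0, 1.0]),
    ]


def _random_start(model: str, rng: np.random.Generator) -> np.ndarray:
    if model == "proposed":
        return np.array(
            [
                rng.uniform(0.0, 0.95),
                rng.uniform(),
                rng.uniform(),
                _loguniform(rng, 1.0, 1000.0),
            ]
        )
    if model == "scs":
        return np.array(
            [
                rng.uniform(0.0, 3.0),
                rng.uniform(0.05, 1.0),
                _loguniform(rng, 1.0, 500.0),
            ]
        )
    lam = rng.uniform()
    a1 = _loguniform(rng, 1e-2, 500.0)
    a2 = _loguniform(rng, 1e-2, 500.0)
    q = rng.uniform(0.0, 1.0 - lam)  # q = eta*a2 keeps the constraint satisfied
    eta = q / a2
    return np.array([lam, eta, a1, a2])


def _local_fit(model: str, x0: np.ndarray, x: np.ndarray, y: np.ndarray, config: FitConfig):
    """One bounded local optimization; returns (sse, vec) or None on failure."""
    names, lo, hi = _BOXES[model]
    x0 = np.clip(x0, lo, hi)

    def resid(vec: np.ndarray) -> np.ndarray:
        p = _make_params(model, vec)
        return np.nan_to_num(
            np.asarray(evaluate_model(model, x, p)) - y, nan=1e6, posinf=1e6, neginf=-1e6
        )

    try:
        if model == "s":
            # explicit inequality constraint eta*a2 + lambda <= 1
            def obj(vec):
                r = resid(vec)
                return float(r @ r)

            res = optimize.minimize(
                obj,
                x0,
                method="SLSQP",
                bounds=list(zip(lo, hi)),
                constraints=[
                    {"type": "ineq", "fun": lambda v: 1.0 - v[0] - v[1] * v[3]}
                ],
                options={"maxiter": 500, "ftol": 1e-16},
            )
            vec = res.x
            # trust-region polish when the constraint is inactive at the optimum
            if 1.0 - vec[0] - vec[1] * vec[3] > 1e-6:
                polish = optimize.least_squares(
                    resid,
                    np.clip(vec, lo, hi),
                    bounds=(lo, hi),
                    method="trf",
                    xtol=config.xtol,
                    ftol=config.ftol,
                    gtol=config.gtol,
                    max_nfev=config.max_nfev,
                )
                pv = polish.x
                if 1.0 - pv[0] - pv[1] * pv[3] >= -1e-9 and 2.0 * polish.cost <= obj(vec):
                    vec = pv
        else:
            res = optimize.least_squares(
                resid,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=config.xtol,
                ftol=config.ftol,
                gtol=config.gtol,
                max_nfev=config.max_nfev,
            )
            vec = res.x
    except Exception:
        return None
    p = _make_params(model, vec)
    r = np.asarray(evaluate_model(model, x, p)) - y
    return float(r @ r), np.asarray(
        [p.to_dict()[k] for k in names], dtype=float
    )


def _thin(x: np.ndarray, y: np.ndarray, m: int):
    """Quantile-grid thinning for very large samples (keeps the endpoint)."""
    idx = np.unique(np.round(np.linspace(0, x.size - 1, m)).astype(int))
    return x[idx], y[idx]


def fit(points: LorenzPoints, config: FitConfig = FitConfig()) -> FitResult:
    """Fit a Lorenz-curve model to empirical Lorenz points.

    Minimizes the SSE over the model's bounded parameter box via multistart
    local optimization.  Deterministic given (points, config).  Among starts
    whose final SSE ties within 1e-12, the parameter vector with the smallest
    rho, then omega, then delta is preferred (universal model), so redundant
    components are reported as 0.
    """
    x_full = np.asarray(points.x, dtype=float)
    y_full = np.asarray(points.y, dtype=float)
    k = _n_free(config.model)
    if points.n < k:
        raise ValueError(
            f"need at least {k} points to fit the {config.model} model, got {points.n}"
        )
    if config.grid_points is not None and config.grid_points < points.n:
        x_obj, y_obj = _thin(x_full, y_full, config.grid_points)
    else:
        x_obj, y_obj = x_full, y_full

    starts = _heuristic_starts(config.model, x_obj, y_obj)[: config.n_starts]
    rng = np.random.default_rng(config.seed)
    while len(starts) < config.n_starts:
        starts.append(_random_start(config.model, rng))

    candidates = []
    for s0 in starts:
        out = _local_fit(config.model, s0, x_obj, y_obj, config)
        if out is not None and np.isfinite(out[0]):
            candidates.append(out)
    if not candidates:
        raise FitError(f"all {config.n_starts} optimization starts failed")

    best_sse = min(c[0] for c in candidates)
    ties = [c for c in candidates if c[0] <= best_sse + _TIE_TOL]
    if config.model == "proposed":
        # prefer smallest rho, then omega, then delta among equal optima
        ties.sort(key=lambda c: (c[1][1], c[1][2], c[1][0]))
    else:
        ties.sort(key=lambda c: tuple(c[1]))
    sse_val, vec = ties[0]
    params = _make_params(config.model, vec)

    notes: list = []
    if config.model == "proposed" and config.canonicalize:
        params, canon_notes = canonicalize(params, (x_obj, y_obj))
        notes.extend(canon_notes)
        sse_val = _sse(y_obj, evaluate_model("proposed", x_obj, params))

    yhat = np.asarray(evaluate_model(config.model, x_full, params))
    report = gof(y_full, np.clip(yhat, 0.0, 1.0))
    if config.model == "proposed":
        gini = gini_proposed(params)
    elif config.model == "s":
        gini = gini_s(params)
    else:
        gini = gini_scs(params)

    return FitResult(
        model=config.model,
        params=params,
        sse=sse_val,
        gof=report,
        gini=gini,
        n_points=points.n,
        n_starts=config.n_starts,
        converged=True,
        notes=tuple(notes),
    )


def canonicalize(params: ProposedParams, sse_context) -> tuple:
    """Resolve non-identifiable directions of the universal model.

    If rho <= 1e-6 the fit is effectively linear and omega has no effect:
    both are snapped to 0.  If P = 1 and delta = 0 all three components
    coincide with the diagonal: rho and omega are snapped to 0.  The SSE is
    asserted unchanged up to the analytic bound implied by perturbing each
    fitted value by at most the snap threshold.

    sse_context is the (x, y) pair the SSE is evaluated on.  Returns
    (canonical_params, notes).
    """
    x, y = sse_context
    before = _sse(y, evaluate_model("proposed", x, params))
    notes = []
    out = params
    if out.rho <= CANON_EPS:
        if out.rho != 0.0 or out.omega != 0.0:
            notes.append("rho ~ 0: linear-only fit, omega is unidentified; both set to 0")
        out = replace(out, rho=0.0, omega=0.0)
    if out.P == 1.0 and out.delta == 0.0 and (out.rho != 0.0 or out.omega != 0.0):
        notes.append(
            "P=1 and delta=0: all components coincide with the diagonal; rho, omega set to 0"
        )
        out = replace(out, rho=0.0, omega=0.0)
    after = _sse(y, evaluate_model("proposed", x, out))
    n = np.asarray(y).size
    bound = 2.0 * CANON_EPS * np.sqrt(n * max(before, after)) + n * CANON_EPS**2
    if abs(after - before) > bound + 1e-15:
        raise AssertionError(
            f"canonicalization changed the SSE ({before:g} -> {after:g})"
        )
    return out, notes


def profile_omega(
    points: LorenzPoints, delta: float, P: float, num: int = 101
) -> tuple:
    """SSE profile along omega with rho = 1 and (delta, P) fixed.

    omega moves the curvature of the curve while the closed-form Gini
    1 - 2*(1-delta)/(P+1) stays constant, so this profile shows how the data
    pick a curvature at fixed inequality.  Returns (omegas, sses).
    """
    omegas = np.linspace(0.0, 1.0, num)
    x = np.asarray(points.x, dtype=float)
    y = np.asarray(points.y, dtype=float)
    sses = np.empty(num)
    for i, w in enumerate(omegas):
        p = ProposedParams(delta=delta, rho=1.0, omega=float(w), P=P)
        sses[i] = _sse(y, evaluate_model("proposed", x, p))
    return omegas, sses
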
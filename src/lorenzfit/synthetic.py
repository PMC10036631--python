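"""Generators for the dataset structures the models are designed for.

Three regimes matter for Lorenz-curve fitting of non-negative sizes:

* extreme one-large/many-equal inequality — the hypothetical society of 99
  persons with income 1 and one person with income 99 (two positive-slope
  linear segments on the Lorenz plot);
* zero-inflated samples — a fraction of zero sizes plus positives drawn from
  a heavy-tailed law, producing a horizontal initial segment;
* model-conformant samples — sizes whose empirical Lorenz points lie exactly
  on a prescribed universal-model curve, used for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import SizeSample
from .models import ProposedParams, proposed_lorenz

__all__ = [
    "ScenarioSpec",
    "make_hypothetical",
    "make_zero_inflated",
    "make_model_conformant",
    "make_scenario",
]

DEFAULT_SEED = 20230323

SCENARIOS = ("hypothetical", "zero_inflated", "model_conformant", "equal")


def make_hypothetical(
    n_small: int = 99, small: float = 1.0, large: float = 99.0
) -> SizeSample:
    """n_small equal small sizes plus one large size.

    The defaults reproduce the extreme-inequality benchmark: 99 observations
    of size 1 and a single observation of size 99 (n = 100, total = 198,
    actual sample-corrected Gini 0.495).
    """
    if n_small < 1:
        raise ValueError("n_small must be >= 1")
    if small <= 0 or large <= 0:
        raise ValueError("sizes must be positive")
    values = np.concatenate([np.full(n_small, float(small)), [float(large)]])
    return SizeSample(values=values, label=f"hypothetical({n_small}x{small}+1x{large})")


def make_zero_inflated(
    n: int,
    zero_fraction: float,
    positive_law: str = "pareto",
    law_params: Optional[dict] = None,
    seed: int = DEFAULT_SEED,
) -> SizeSample:
    """floor(n*zero_fraction) zeros plus positives drawn from a named law.

    positive_law 'pareto' draws classical Pareto sizes with minimum 1 and
    tail exponent ``b`` (default 1.5); 'lognormal' uses ``mu`` (default 0)
    and ``sigma`` (default 1).  Deterministic given the seed.
    """
    if not (0.0 <= zero_fraction < 1.0):
        raise ValueError("zero_fraction must lie in [0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    law_params = dict(law_params or {})
    rng = np.random.default_rng(seed)
    n_zero = int(np.floor(n * zero_fraction))
    n_pos = n - n_zero
    if positive_law == "pareto":
        b = float(law_params.pop("b", 1.5))
        if law_params or b <= 0:
            raise ValueError(f"invalid pareto parameters: b={b}, extra={law_params}")
        pos = rng.pareto(b, size=n_pos) + 1.0
    elif positive_law == "lognormal":
        mu = float(law_params.pop("mu", 0.0))
        sigma = float(law_params.pop("sigma", 1.0))
        if law_params or sigma <= 0:
            raise ValueError(
                f"invalid lognormal parameters: mu={mu}, sigma={sigma}, extra={law_params}"
            )
        pos = rng.lognormal(mu, sigma, size=n_pos)
    else:
        raise ValueError(f"unknown positive_law {positive_law!r}")
    values = np.concatenate([np.zeros(n_zero), pos])
    return SizeSample(
        values=values,
        label=f"zero_inflated(n={n}, zf={zero_fraction}, law={positive_law}, seed={seed})",
    )


def make_model_conformant(params: ProposedParams, n: int) -> SizeSample:
    """Sizes whose empirical Lorenz points lie exactly on a universal-model
    curve.

    s_i = y(i/n) - y((i-1)/n) for i = 1..n (non-negative by monotonicity);
    the jump at x=1 when rho < 1 lands in the single largest observation —
    exactly the one-large/many-equal regime.  The empirical Lorenz points of
    the output equal the curve at x_i = i/n by construction.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    grid = np.arange(0, n + 1, dtype=float) / n
    y = np.asarray(proposed_lorenz(grid, params), dtype=float)
    sizes = np.maximum(np.diff(y), 0.0)  # guard float dust; y is non-decreasing
    return SizeSample(values=sizes, label=f"model_conformant(n={n}, {params.to_dict()})")


@dataclass(frozen=True)
class ScenarioSpec:
    """A reproducible synthetic-data scenario (id, size, parameters, seed)."""

    scenario: str
    n: int = 100
    seed: int = DEFAULT_SEED
    zero_fraction: float = 0.5
    positive_law: str = "pareto"
    law_params: Optional[dict] = None
    n_small: int = 99
    small: float = 1.0
    large: float = 99.0
    params: Optional[ProposedParams] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    def to_dict(self) -> dict:
        d = {
            "scenario": self.scenario,
            "n": self.n,
            "seed": self.seed,
        }
        if self.scenario == "zero_inflated":
            d.update(
                zero_fraction=self.zero_fraction,
                positive_law=self.positive_law,
                law_params=self.law_params or {},
            )
        elif self.scenario == "hypothetical":
            d.update(n_small=self.n_small, small=self.small, large=self.large)
        elif self.scenario == "model_conformant":
            d["params"] = (self.params or _DEFAULT_CONFORMANT).to_dict()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


_DEFAULT_CONFORMANT = ProposedParams(delta=0.2, rho=0.9, omega=0.5, P=3.0)


def make_scenario(spec: ScenarioSpec) -> SizeSample:
    """Generate the sample a ScenarioSpec describes (reproducible)."""
    if spec.scenario == "hypothetical":
        return make_hypothetical(spec.n_small, spec.small, spec.large)
    if spec.scenario == "zero_inflated":
        return make_zero_inflated(
            spec.n, spec.zero_fraction, spec.positive_law, spec.law_params, spec.seed
        )
    if spec.scenario == "model_conformant":
        return make_model_conformant(spec.params or _DEFAULT_CONFORMANT, spec.n)
    return SizeSample(values=np.ones(spec.n), label=f"equal(n={spec.n})")
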
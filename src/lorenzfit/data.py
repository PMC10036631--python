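"""Ingest raw size data and build empirical Lorenz points.

Sizes are non-negative quantities in domain units (grams, dollars, counts,
scintillation counts...).  The empirical Lorenz plot pairs the cumulative
normalized rank x_i = i/n (observations sorted ascending) with the cumulative
normalized size y_i = (sum of the i smallest sizes)/(total size); the origin
(0,0) is an implicit anchor.  Zeros are legal sizes and produce an initial
horizontal run y = 0.
"""

from __future__ import annotations

import csv as _csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

__all__ = [
    "SizeSample",
    "LorenzPoints",
    "DescriptiveStats",
    "read_sizes",
    "empirical_lorenz",
    "descriptive_stats",
    "discrete_gini",
]


@dataclass(frozen=True)
class SizeSample:
    """Raw non-negative sizes with a provenance label."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("values must be a non-empty 1-d sequence")
        if np.any(~np.isfinite(v)):
            raise ValueError("values must be finite")
        if np.any(v < 0):
            raise ValueError("sizes must be non-negative")
        if not np.any(v > 0):
            raise ValueError("at least one size must be positive (total > 0)")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class LorenzPoints:
    """Empirical Lorenz points: x strictly increasing in (0,1], y
    non-decreasing in [0,1], final point (1,1), y_i <= x_i everywhere.
    The origin (0,0) is implicit (``includes_origin`` is a flag, the arrays
    never store it)."""

    x: np.ndarray
    y: np.ndarray
    includes_origin: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1 or x.size == 0:
            raise ValueError("x and y must be matching non-empty 1-d arrays")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(np.diff(y) < -1e-12):
            raise ValueError("y must be non-decreasing")
        if not (abs(x[-1] - 1.0) <= 1e-12 and abs(y[-1] - 1.0) <= 1e-9):
            raise ValueError("final point must be (1, 1)")
        if x[0] <= 0:
            raise ValueError("x must be positive (origin is implicit)")
        if np.any(y > x + 1e-9):
            raise ValueError("Lorenz points must lie on or below the diagonal")

    @property
    def n(self) -> int:
        return int(self.x.size)

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["x", "y"])
            for xi, yi in zip(self.x, self.y):
                w.writerow([repr(float(xi)), repr(float(yi))])

    def to_dict(self) -> dict:
        return {
            "x": self.x.tolist(),
            "y": self.y.tolist(),
            "includes_origin": self.includes_origin,
            "label": self.label,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class DescriptiveStats:
    """Five-number descriptive summary; standard deviation uses the n-1
    (sample) denominator."""

    minimum: float
    maximum: float
    mean: float
    standard_deviation: float
    n: int

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError("minimum <= mean <= maximum must hold")
        if self.standard_deviation < 0:
            raise ValueError("standard deviation must be non-negative")

    def to_dict(self) -> dict:
        return {
            "minimum": self.minimum,
            "maximum": self.maximum,
            "mean": self.mean,
            "standard_deviation": self.standard_deviation,
            "n": self.n,
        }


_DIALECTS = ("csv", "tsv", "whitespace", "auto")


def _tokenize(line: str, dialect: str) -> list:
    if dialect == "csv":
        return [t for t in line.split(",") if t.strip() != ""]
    if dialect == "tsv":
        return [t for t in line.split("\t") if t.strip() != ""]
    return line.split()


def read_sizes(
    path: Union[str, Path], dialect: str = "auto", label: str = ""
) -> SizeSample:
    """Read a single column of non-negative sizes.

    dialect 'auto' picks csv/tsv from the file suffix and falls back to
    whitespace separation.  A non-numeric first record is treated as a header
    and skipped.  Negative or non-numeric values are rejected with the
    offending line number.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}, got {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if dialect == "auto":
        suffix = path.suffix.lower()
        dialect = {"csv": "csv", ".csv": "csv", ".tsv": "tsv"}.get(suffix, "whitespace")

    values: list = []
    first_record = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = _tokenize(line, dialect)
            if not tokens:
                continue
            record: list = []
            header = False
            for tok in tokens:
                tok = tok.strip()
                try:
                    v = float(tok)
                except ValueError:
                    if first_record:  # whole first record is a header
                        header = True
                        break
                    raise ValueError(
                        f"{path}, line {lineno}: non-numeric token {tok!r}"
                    ) from None
                if not np.isfinite(v):
                    raise ValueError(f"{path}, line {lineno}: non-finite value {tok!r}")
                if v < 0:
                    raise ValueError(
                        f"{path}, line {lineno}: negative size {tok!r} is not allowed"
                    )
                record.append(v)
            first_record = False
            if not header:
                values.extend(record)
    if not values:
        raise ValueError(f"{path}: no numeric data found")
    return SizeSample(values=np.asarray(values, dtype=float), label=label or path.name)


def empirical_lorenz(sample: SizeSample) -> LorenzPoints:
    """Construct the empirical Lorenz points of a sample.

    Sizes are sorted ascending (ties kept as distinct observations, one equal
    rank weight 1/n each); x_i = i/n, y_i = cumsum_i/total for i = 1..n.
    """
    v = np.sort(sample.values, kind="stable")
    total = v.sum()
    if total <= 0:
        raise ValueError("total size must be positive to normalize the Lorenz curve")
    n = v.size
    x = np.arange(1, n + 1, dtype=float) / n
    y = np.cumsum(v) / total
    y[-1] = 1.0  # exact endpoint despite rounding
    return LorenzPoints(x=x, y=y, includes_origin=True, label=sample.label)


def descriptive_stats(sample: SizeSample) -> DescriptiveStats:
    """Minimum, maximum, mean and sample (n-1) standard deviation."""
    v = sample.values
    if v.size < 2:
        raise ValueError("at least two observations are required (sd uses n-1)")
    return DescriptiveStats(
        minimum=float(v.min()),
        maximum=float(v.max()),
        mean=float(v.mean()),
        standard_deviation=float(v.std(ddof=1)),
        n=int(v.size),
    )


def discrete_gini(points: LorenzPoints, correction: str = "sample") -> float:
    """Discrete ("actual") Gini index from empirical Lorenz points.

    population: trapezoid rule with the implicit origin prepended,
    G = 1 - sum (x_i - x_{i-1}) * (y_i + y_{i-1}).
    sample: the population value times n/(n-1), removing the small-sample
    bias of comparing each observation against itself.
    """
    if correction not in ("population", "sample"):
        raise ValueError("correction must be 'population' or 'sample'")
    x = np.concatenate([[0.0], points.x])
    y = np.concatenate([[0.0], points.y])
    g = 1.0 - float(np.sum(np.diff(x) * (y[1:] + y[:-1])))
    if correction == "sample":
        n = points.n
        if n < 2:
            raise ValueError("sample correction requires n >= 2")
        g *= n / (n - 1)
    return g
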
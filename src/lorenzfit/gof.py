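"""Goodness-of-fit statistics for fitted Lorenz curves.

Five statistics compare empirical cumulative shares y with fitted shares
yhat: the coefficient of determination R^2 = 1 - SSE/SST (SST about the mean
of y), mean squared error, mean absolute error, maximum absolute error, and
Theil's information inaccuracy measure IIM = sum y_i * log10(y_i / yhat_i).
R^2 closer to 1 and MSE/MAE/MAS closer to 0 indicate a better fit; for IIM a
smaller absolute value is better (individual terms may be negative).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["GofReport", "gof", "sse"]

ZERO_TERM_POLICY = (
    "terms with y=0 contribute 0 (continuity limit); "
    "a term with y>0 and yhat=0 makes IIM infinite (flagged, not raised)"
)


@dataclass(frozen=True)
class GofReport:
    """The five goodness-of-fit statistics over n compared points.

    r2 is NaN when SST = 0 (constant y), in which case ``r2_defined`` is
    False.  iim is +inf when some y_i > 0 has yhat_i = 0.
    """

    r2: float
    mse: float
    mae: float
    mas: float
    iim: float
    n: int
    r2_defined: bool = True
    zero_term_policy: str = ZERO_TERM_POLICY

    @property
    def iim_infinite(self) -> bool:
        return math.isinf(self.iim)

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "mse": self.mse,
            "mae": self.mae,
            "mas": self.mas,
            "iim": self.iim,
            "n": self.n,
            "r2_defined": self.r2_defined,
            "zero_term_policy": self.zero_term_policy,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def to_csv_row(self) -> dict:
        """Row in the layout of a model-comparison table (4 dp)."""
        return {
            "r2": f"{self.r2:.4f}",
            "mse": f"{self.mse:.4f}",
            "mae": f"{self.mae:.4f}",
            "mas": f"{self.mas:.4f}",
            "iim": f"{self.iim:.4f}",
        }


def sse(y, yhat) -> float:
    """Sum of squared errors between observed and fitted cumulative shares."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    return float(np.sum((y - yhat) ** 2))


def gof(y, yhat) -> GofReport:
    """Compute the five goodness-of-fit statistics.

    Both inputs are cumulative shares in [0, 1] of equal length.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-d arrays of equal length")
    if y.size == 0:
        raise ValueError("empty input")
    tol = 1e-9
    if np.any(y < -tol) or np.any(y > 1 + tol) or np.any(yhat < -tol) or np.any(yhat > 1 + tol):
        raise ValueError("cumulative shares must lie in [0, 1]")

    err = y - yhat
    mse_ = float(np.mean(err**2))
    mae_ = float(np.mean(np.abs(err)))
    mas_ = float(np.max(np.abs(err)))

    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        r2_, defined = float("nan"), False
    else:
        r2_, defined = 1.0 - float(np.sum(err**2)) / sst, True

    pos = y > 0
    if np.any(pos & (yhat <= 0)):
        iim_ = float("inf")
    else:
        yp, yhp = y[pos], yhat[pos]
        # difference of logs avoids overflow when yhat is subnormal
        iim_ = float(np.sum(yp * (np.log10(yp) - np.log10(yhp))))

    return GofReport(
        r2=r2_, mse=mse_, mae=mae_, mas=mas_, iim=iim_, n=int(y.size), r2_defined=defined
    )
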
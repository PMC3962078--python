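"""Performance and model-size criteria for regression models.

All measures derive from the residuals e_i = y_i - yhat_i.  The standard
error of prediction (SEP) is the sample standard deviation of test-set
residuals (divisor z-1, mean subtracted); the same statistic computed on
calibration residuals is called SEC and is optimistic.  Under roughly
normal errors about 95% of prediction errors fall inside +-2*SEP.

Model-size criteria for variable selection (natural logarithms):

    BIC = n ln(RSS/n) + m ln(n)
    AIC = n ln(RSS/n) + 2 m

with m the number of selected variables; their absolute values are
meaningless, only differences within one data set matter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResidualSummary",
    "residual_summary",
    "tolerance_interval",
    "adjusted_r2",
    "information_criterion",
]


@dataclass
class ResidualSummary:
    """Residual-based performance measures for one prediction exercise.

    ``SEP`` is the bias-corrected standard deviation of the residuals; for
    ``context='calibration'`` the same number is conventionally labelled
    SEC.  ``R2`` is the squared Pearson correlation between y and yhat, or
    NaN when it is undefined (constant y or constant yhat).
    """

    residuals: np.ndarray
    bias: float
    SEP: float
    MSE: float
    RMSE: float
    PRESS: float
    R2: float
    z: int
    context: str = "test"

    @property
    def SEC(self) -> float:
        """Alias for SEP when the residuals come from the calibration set."""
        return self.SEP

    def to_dict(self) -> dict:
        return {
            "context": self.context,
            "z": self.z,
            "bias": self.bias,
            "SEP": self.SEP,
            "MSE": self.MSE,
            "RMSE": self.RMSE,
            "PRESS": self.PRESS,
            "R2": self.R2,
        }


def residual_summary(
    y: np.ndarray,
    y_hat: np.ndarray,
    context: str = "test",
) -> ResidualSummary:
    """Compute bias, SEP, MSE, RMSE, PRESS and R2 from observed/predicted y."""
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: y has {y.size}, y_hat has {y_hat.size}")
    z = y.size
    if z < 2:
        raise ValueError("need at least 2 residuals (SEP undefined for z < 2)")
    if np.isnan(y).any() or np.isnan(y_hat).any():
        raise ValueError("missing values in y or y_hat")
    if context not in ("test", "calibration"):
        raise ValueError(f"context must be 'test' or 'calibration', got {context!r}")

    e = y - y_hat
    bias = float(e.mean())
    sep = float(e.std(ddof=1))
    mse = float(np.mean(e**2))
    if y.std() == 0.0 or y_hat.std() == 0.0:
        warnings.warn("R2 undefined (constant y or y_hat); reported as NaN", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(y, y_hat)[0, 1] ** 2)
    return ResidualSummary(
        residuals=e,
        bias=bias,
        SEP=sep,
        MSE=mse,
        RMSE=math.sqrt(mse),
        PRESS=z * mse,
        R2=r2,
        z=z,
        context=context,
    )


def tolerance_interval(sep: float) -> tuple[float, float]:
    """95% tolerance interval (-2*SEP, +2*SEP) for roughly normal errors."""
    if sep < 0:
        raise ValueError(f"SEP must be non-negative, got {sep}")
    return (-2.0 * sep, 2.0 * sep)


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Adjusted squared correlation: 1 - (n-1)(1-R2)/(n-m-1)."""
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"R2 must be in [0, 1], got {r2}")
    if n <= m + 1:
        raise ValueError(f"adjusted R2 requires n > m + 1 (n={n}, m={m})")
    return 1.0 - (n - 1) * (1.0 - r2) / (n - m - 1)


def information_criterion(rss: float, n: int, m: int, kind: str = "BIC") -> float:
    """BIC or AIC from the residual sum of squares of a fitted model.

    ``m`` counts the selected variables (the intercept is not counted);
    the constant offset is irrelevant when comparing subsets on one data
    set.  RSS must be strictly positive — callers must handle perfect fits
    before scoring.
    """
    if rss <= 0:
        raise ValueError(f"RSS must be > 0 (got {rss}); log undefined")
    if n < 1 or m < 0:
        raise ValueError(f"invalid n={n} or m={m}")
    base = n * math.log(rss / n)
    if kind == "BIC":
        return base + m * math.log(n)
    if kind == "AIC":
        return base + 2 * m
    raise ValueError(f"kind must be 'BIC' or 'AIC', got {kind!r}")
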
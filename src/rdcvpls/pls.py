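"""PLS1 regression (NIPALS with X-deflation).

A PLS component is a latent variable t = X p computed from the centred
descriptor matrix; the first weight direction maximizes the empirical
covariance y'.t/(n-1) between the scores and the property, and successive
components repeat the criterion on the deflated matrix, which makes the
score vectors mutually orthogonal.  The fitted model is expressed, for
every usable component count a, as an ordinary linear model

    y_hat = X b(a) + b0(a)

on the original variable scale, so downstream code never needs to know the
latent structure.  With m < n and full-rank X the model at a = m coincides
with the ordinary least-squares fit.

Variables are always mean-centred; autoscaling (unit variance) is an
explicit option and is required where coefficients must be comparable
across descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "fit_pls", "predict", "standardized_coefficients"]

# components whose weight or score norm falls below this fraction of the
# initial X norm are considered degenerate and not extracted
_DEGENERATE_TOL = 1e-12


@dataclass
class PLSModel:
    """A fitted PLS1 model for every component count 1..A_max_fitted.

    ``coefs[:, a-1]`` and ``intercepts[a-1]`` are the Eq.-style regression
    coefficients b and intercept b0 on the original variable scale for the
    a-component model.  ``weights``/``loadings``/``y_loadings`` retain the
    per-component NIPALS vectors (on the centred/scaled scale) so scores
    and loadings can be reproduced.
    """

    center: np.ndarray
    scale: np.ndarray
    y_center: float
    autoscaled: bool
    A_max_fitted: int
    coefs: np.ndarray  # (m, A_max_fitted), original scale
    intercepts: np.ndarray  # (A_max_fitted,)
    weights: np.ndarray = field(repr=False)  # (m, A) w vectors
    loadings: np.ndarray = field(repr=False)  # (m, A) p vectors
    y_loadings: np.ndarray = field(repr=False)  # (A,) q values

    @property
    def m(self) -> int:
        return self.coefs.shape[0]

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "y_center": self.y_center,
            "autoscaled": self.autoscaled,
            "A_max_fitted": self.A_max_fitted,
            "coefs": self.coefs.tolist(),
            "intercepts": self.intercepts.tolist(),
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            center=np.array(d["center"], float),
            scale=np.array(d["scale"], float),
            y_center=float(d["y_center"]),
            autoscaled=bool(d["autoscaled"]),
            A_max_fitted=int(d["A_max_fitted"]),
            coefs=np.array(d["coefs"], float),
            intercepts=np.array(d["intercepts"], float),
            weights=np.array(d["weights"], float),
            loadings=np.array(d["loadings"], float),
            y_loadings=np.array(d["y_loadings"], float),
        )


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    A_max: int,
    autoscale: bool = False,
) -> PLSModel:
    """Fit PLS1 models with 1..min(A_max, n-1, m) components.

    Parameters
    ----------
    X, y
        Complete (no NaN) training data, n >= 3 objects.
    A_max
        Requested maximum number of latent components; capped at
        min(n-1, m) and reduced further if the residual matrix degenerates.
    autoscale
        Scale every variable to unit variance in addition to centring.
        Requires no zero-variance columns.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, m = X.shape
    if y.shape != (n,):
        raise ValueError(f"y has length {y.size}, X has {n} rows")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in X or y; clean the data first")
    if n < 3:
        raise ValueError(f"need at least 3 objects, got {n}")
    if A_max < 1:
        raise ValueError(f"A_max must be >= 1, got {A_max}")

    center = X.mean(axis=0)
    if autoscale:
        scale = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(scale == 0.0)
        if zero.size:
            raise ValueError(
                f"zero-variance column(s) {zero.tolist()} cannot be autoscaled; "
                "remove them with the almost-constant filter"
            )
    else:
        scale = np.ones(m)
    y_center = float(y.mean())

    Xc = (X - center) / scale
    yc = y - y_center

    a_cap = min(A_max, n - 1, m)
    x_norm0 = np.linalg.norm(Xc)
    if x_norm0 == 0.0:
        x_norm0 = 1.0

    W = np.zeros((m, a_cap))
    P = np.zeros((m, a_cap))
    Q = np.zeros(a_cap)
    n_comp = 0
    for a in range(a_cap):
        w = Xc.T @ yc
        w_norm = np.linalg.norm(w)
        if w_norm <= _DEGENERATE_TOL * x_norm0:
            break
        w /= w_norm
        t = Xc @ w
        tt = float(t @ t)
        if tt <= (_DEGENERATE_TOL * x_norm0) ** 2:
            break
        p = Xc.T @ t / tt
        q = float(yc @ t) / tt
        Xc = Xc - np.outer(t, p)
        yc = yc - q * t
        W[:, a], P[:, a], Q[a] = w, p, q
        n_comp += 1

    if n_comp == 0:
        # y uncorrelated with X to machine precision: intercept-only model
        n_comp = 1
        # W stays zero; coefficients are zero, prediction is the mean of y

    W, P, Q = W[:, :n_comp], P[:, :n_comp], Q[:n_comp]
    coefs = np.zeros((m, n_comp))
    intercepts = np.zeros(n_comp)
    for a in range(1, n_comp + 1):
        Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:a]
        if np.allclose(Wa, 0.0):
            b_scaled = np.zeros(m)
        else:
            # b on the centred/scaled scale: W (P'W)^-1 q
            b_scaled = Wa @ np.linalg.solve(Pa.T @ Wa, Qa)
        b = b_scaled / scale
        coefs[:, a - 1] = b
        intercepts[a - 1] = y_center - center @ b

    return PLSModel(
        center=center,
        scale=scale,
        y_center=y_center,
        autoscaled=autoscale,
        A_max_fitted=n_comp,
        coefs=coefs,
        intercepts=intercepts,
        weights=W,
        loadings=P,
        y_loadings=Q,
    )


def predict(model: PLSModel, X_new: np.ndarray, a: int) -> np.ndarray:
    """Predict y for new objects with the a-component model."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if not 1 <= a <= model.A_max_fitted:
        raise ValueError(
            f"a={a} out of fitted range 1..{model.A_max_fitted}"
        )
    if X_new.shape[1] != model.m:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.m}"
        )
    if X_new.shape[0] == 0:
        return np.empty(0)
    if np.isnan(X_new).any():
        raise ValueError("missing values in X_new")
    return X_new @ model.coefs[:, a - 1] + model.intercepts[a - 1]


def predict_all(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predictions for all component counts at once: (z, A_max_fitted)."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    return X_new @ model.coefs + model.intercepts


def standardized_coefficients(model: PLSModel, a: int) -> np.ndarray:
    """Coefficients on the autoscaled (unit-variance) variable scale.

    On that scale |b_j| is comparable across descriptors and can rank them
    by their contribution to the model.  Only defined for models fitted
    with ``autoscale=True``.
    """
    if not model.autoscaled:
        raise ValueError(
            "standardized coefficients require a model fitted with autoscale=True"
        )
    if not 1 <= a <= model.A_max_fitted:
        raise ValueError(f"a={a} out of fitted range 1..{model.A_max_fitted}")
    return model.coefs[:, a - 1] * model.scale
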
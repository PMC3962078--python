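"""Repeated double cross-validation (rdCV) for PLS models.

rdCV separates two questions that a single cross-validation conflates:
how complex should the model be, and how well will it predict new cases.
An outer CV loop splits the n objects into calibration and test sets; for
each calibration set an inner CV loop estimates the optimal number of PLS
components A_OPT (by the global MSE minimum or the one-standard-error
rule), a model with A_OPT components is fitted on the whole calibration
set, and the held-out segment is predicted.  One complete double-CV run
yields a test-set prediction for every object, from which one SEP is
computed.  Repeating with r fresh random splits gives a distribution of r
SEP values and r*s_outer estimates of A_OPT; the modal A_OPT becomes
A_FINAL, and a final model is fitted on all n objects with A_FINAL
components — without further optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import DescriptorTable, SelectionMask
from .metrics import ResidualSummary, residual_summary
from .pls import PLSModel, fit_pls, predict, predict_all

__all__ = [
    "CVConfig",
    "InnerCVResult",
    "RdcvResult",
    "segment_split",
    "inner_cv",
    "a_opt_by_one_se",
    "double_cv",
    "rdcv",
    "final_model",
]


@dataclass(frozen=True)
class CVConfig:
    """Parameters of an rdCV run.

    Defaults follow common chemometric practice: 4 outer segments, 5 inner
    segments, up to 10 latent components, 50 repetitions, and the
    one-standard-error rule for picking A_OPT.
    """

    r: int = 50
    s_outer: int = 4
    s_inner: int = 5
    A_max: int = 10
    seed: int = 0
    a_opt_rule: str = "one_se"  # or "global_min"
    autoscale: bool = False

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError(f"r must be >= 1, got {self.r}")
        if self.s_outer < 2 or self.s_inner < 2:
            raise ValueError("segment counts must be >= 2")
        if self.A_max < 1:
            raise ValueError(f"A_max must be >= 1, got {self.A_max}")
        if self.a_opt_rule not in ("one_se", "global_min"):
            raise ValueError(f"unknown a_opt_rule {self.a_opt_rule!r}")


@dataclass
class InnerCVResult:
    """Inner-loop CV output for one calibration set."""

    mse_means: np.ndarray  # (A,) MSE_CV per component count
    segment_mse: np.ndarray  # (s_inner, A) per-segment MSE
    predictions: np.ndarray  # (n_cal, A) CV-predicted y
    a_opt: int


@dataclass
class RdcvResult:
    """Everything an rdCV run produces.

    ``predictions[i, k]`` is the test-set prediction for object i in
    repetition k (every object is in a test set exactly once per
    repetition, so the matrix has no gaps).
    """

    sep_per_repetition: np.ndarray  # (r,)
    a_opt_estimates: np.ndarray  # (r, s_outer)
    predictions: np.ndarray  # (n, r)
    A_FINAL: int
    config: CVConfig
    summaries: list[ResidualSummary] = field(default_factory=list)

    @property
    def sep_median(self) -> float:
        return float(np.median(self.sep_per_repetition))

    def to_dict(self) -> dict:
        return {
            "sep_per_repetition": self.sep_per_repetition.tolist(),
            "a_opt_estimates": self.a_opt_estimates.tolist(),
            "predictions": self.predictions.tolist(),
            "A_FINAL": self.A_FINAL,
            "config": vars(self.config).copy(),
        }


def segment_split(n: int, s: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly partition n objects into s segments of near-equal size.

    Returns an array of n segment labels in 0..s-1; segment sizes differ by
    at most one, and the assignment is a uniformly random permutation split.
    """
    if not 2 <= s <= n:
        raise ValueError(f"need 2 <= s <= n, got s={s}, n={n}")
    labels = np.empty(n, dtype=int)
    labels[rng.permutation(n)] = np.arange(n) % s
    return labels


def a_opt_by_one_se(means: np.ndarray, ses: np.ndarray) -> int:
    """One-standard-error rule for the number of components.

    Let a* minimize the CV error (smallest index on ties); return the
    smallest a whose mean error is within one standard error of the
    minimum — a deliberately more parsimonious choice than the global
    minimum, guarding against overfitting.
    """
    means = np.asarray(means, float)
    ses = np.asarray(ses, float)
    if means.size == 0 or means.shape != ses.shape:
        raise ValueError("means and ses must be non-empty and of equal length")
    a_star = int(np.argmin(means))
    threshold = means[a_star] + ses[a_star]
    return int(np.flatnonzero(means <= threshold)[0]) + 1


def _effective_a_max(n_cal: int, m: int, s: int, a_max: int, labels: np.ndarray) -> int:
    fold_train_sizes = [n_cal - int((labels == seg).sum()) for seg in range(s)]
    min_train = min(fold_train_sizes)
    if min_train < 3:
        raise ValueError(
            f"a CV training fold has only {min_train} objects; "
            "use fewer segments or more objects"
        )
    cap = min(a_max, min_train - 1, m)
    if cap < a_max:
        warnings.warn(
            f"A_max reduced from {a_max} to {cap} (training-fold size or "
            "variable count limit)",
            stacklevel=3,
        )
    return cap


def inner_cv(
    X: np.ndarray,
    y: np.ndarray,
    s_inner: int,
    A_max: int,
    rng: np.random.Generator,
    a_opt_rule: str = "one_se",
    autoscale: bool = False,
) -> InnerCVResult:
    """Cross-validate component counts 1..A_max on one calibration set.

    Produces the n_cal x A matrix of CV-predicted y, the MSE_CV curve, the
    per-segment MSE table (for the one-SE rule), and A_OPT.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n_cal, m = X.shape
    if n_cal <= s_inner:
        raise ValueError(f"need n_cal > s_inner (n_cal={n_cal}, s_inner={s_inner})")
    labels = segment_split(n_cal, s_inner, rng)
    a_cap = _effective_a_max(n_cal, m, s_inner, A_max, labels)

    preds = np.full((n_cal, a_cap), np.nan)
    seg_mse = np.zeros((s_inner, a_cap))
    for seg in range(s_inner):
        val = labels == seg
        model = fit_pls(X[~val], y[~val], A_max=a_cap, autoscale=autoscale)
        p = predict_all(model, X[val])  # (n_val, A_fitted)
        if model.A_max_fitted < a_cap:
            # degenerate extraction: pad with the last usable component
            pad = np.repeat(p[:, -1:], a_cap - model.A_max_fitted, axis=1)
            p = np.hstack([p, pad])
        preds[val] = p
        seg_mse[seg] = np.mean((y[val][:, None] - p) ** 2, axis=0)

    mse_means = np.mean((y[:, None] - preds) ** 2, axis=0)
    if a_opt_rule == "global_min":
        a_opt = int(np.argmin(mse_means)) + 1
    else:
        ses = seg_mse.std(axis=0, ddof=1) / np.sqrt(s_inner)
        a_opt = a_opt_by_one_se(mse_means, ses)
    return InnerCVResult(
        mse_means=mse_means, segment_mse=seg_mse, predictions=preds, a_opt=a_opt
    )


def _resolve_xy(
    table: DescriptorTable, mask: SelectionMask | np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    y = table.require_y()
    sub = table if mask is None else table.subset(mask)
    sub.require_complete()
    return sub.X, y


def double_cv(
    table: DescriptorTable,
    config: CVConfig,
    rng: np.random.Generator,
    mask: SelectionMask | np.ndarray | None = None,
    recorder=None,
) -> tuple[np.ndarray, np.ndarray]:
    """One double-CV pass: a test-set prediction for every object.

    For each outer segment, the remaining objects form the calibration set
    on which the inner CV fixes A_OPT; a PLS model with A_OPT components is
    fitted on the whole calibration set and predicts the held-out segment.
    ``recorder``, if given, is called with (calibration_indices,
    test_indices) per outer fold — used to audit that no test object ever
    enters model fitting.
    """
    X, y = _resolve_xy(table, mask)
    n = X.shape[0]
    labels = segment_split(n, config.s_outer, rng)
    y_hat = np.full(n, np.nan)
    a_opts = np.zeros(config.s_outer, dtype=int)
    for seg in range(config.s_outer):
        test = labels == seg
        cal_idx = np.flatnonzero(~test)
        if recorder is not None:
            recorder(cal_idx, np.flatnonzero(test))
        inner = inner_cv(
            X[cal_idx],
            y[cal_idx],
            config.s_inner,
            config.A_max,
            rng,
            a_opt_rule=config.a_opt_rule,
            autoscale=config.autoscale,
        )
        a_opts[seg] = inner.a_opt
        model = fit_pls(
            X[cal_idx], y[cal_idx], A_max=inner.a_opt, autoscale=config.autoscale
        )
        y_hat[test] = predict(model, X[test], min(inner.a_opt, model.A_max_fitted))
    return y_hat, a_opts


def rdcv(
    table: DescriptorTable,
    config: CVConfig | None = None,
    mask: SelectionMask | np.ndarray | None = None,
    recorder=None,
) -> RdcvResult:
    """Repeated double CV: r independent double-CV runs.

    Each repetition uses its own random-number stream spawned from the
    config seed, so results are reproducible and repetition-order
    independent.  Per repetition, SEP is computed from the pooled n
    test-set residuals; A_FINAL is the most frequent A_OPT over all
    r*s_outer estimates, ties broken toward the smaller (more
    parsimonious) value.
    """
    config = config or CVConfig()
    X, y = _resolve_xy(table, mask)
    n = X.shape[0]
    streams = np.random.SeedSequence(config.seed).spawn(config.r)
    predictions = np.zeros((n, config.r))
    a_opt_estimates = np.zeros((config.r, config.s_outer), dtype=int)
    seps = np.zeros(config.r)
    summaries: list[ResidualSummary] = []
    for k, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        y_hat, a_opts = double_cv(table, config, rng, mask=mask, recorder=recorder)
        predictions[:, k] = y_hat
        a_opt_estimates[k] = a_opts
        summ = residual_summary(y, y_hat, context="test")
        summaries.append(summ)
        seps[k] = summ.SEP

    values, counts = np.unique(a_opt_estimates, return_counts=True)
    a_final = int(values[np.argmax(counts)])  # np.unique sorts: ties -> smaller A
    return RdcvResult(
        sep_per_repetition=seps,
        a_opt_estimates=a_opt_estimates,
        predictions=predictions,
        A_FINAL=a_final,
        config=config,
        summaries=summaries,
    )


def final_model(
    table: DescriptorTable,
    a_final: int,
    mask: SelectionMask | np.ndarray | None = None,
    autoscale: bool = False,
) -> tuple[PLSModel, ResidualSummary]:
    """Fit the final PLS model on all n objects with A_FINAL components.

    Returns the model and its calibration residual summary.  The SEC it
    carries is only a plausibility measure; the rdCV SEP distribution is
    the honest estimate of performance on new cases.
    """
    X, y = _resolve_xy(table, mask)
    model = fit_pls(X, y, A_max=a_final, autoscale=autoscale)
    if model.A_max_fitted < a_final:
        raise ValueError(
            f"A_FINAL={a_final} exceeds the {model.A_max_fitted} extractable "
            "components for this data"
        )
    sec = residual_summary(y, predict(model, X, a_final), context="calibration")
    return model, sec
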
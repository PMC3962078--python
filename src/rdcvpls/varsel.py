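"""Variable-selection operators for descriptor matrices.

Each operator returns a :class:`~rdcvpls.data_io.SelectionMask` of length m
aligned with the table's variables; operators never reorder columns and
compose by logical AND.  Selection deliberately uses all n objects — the
resulting subsets are *suggestions*, and only rdCV on genuinely held-out
objects judges their worth.  No fit statistic computed here is a
performance estimate.

Operators
---------
filter_almost_constant
    Cleaning step: drop variables taking one value in all but at most k
    objects (after rounding).
select_top_corr_y / filter_low_corr_y
    Univariate screens on the squared Pearson correlation with y.
eliminate_corr_xx
    Drop one member of every variable pair whose mutual R^2 exceeds a
    limit (the member with the larger total squared correlation to all
    other variables).
select_by_pls_coeff
    Rank variables by |standardized PLS coefficient| from an
    rdCV-optimized model on autoscaled data.
stepwise_bic
    Greedy forward (or forward/backward) OLS search minimizing BIC,
    starting from the empty model.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .crossval import CVConfig, final_model, rdcv
from .data_io import DescriptorTable, SelectionMask
from .metrics import information_criterion
from .pls import standardized_coefficients

__all__ = [
    "StepwiseTrace",
    "filter_almost_constant",
    "select_top_corr_y",
    "filter_low_corr_y",
    "eliminate_corr_xx",
    "select_by_pls_coeff",
    "stepwise_bic",
    "combine_prefilter_stepwise",
]

# residual sums of squares below this fraction of the total sum of squares
# count as a perfect fit: the move is accepted and the search stops
_PERFECT_FIT_TOL = 1e-12


@dataclass
class StepwiseStep:
    step: int
    action: str  # "add" | "remove"
    variable: int
    bic: float
    note: str = ""


@dataclass
class StepwiseTrace:
    """Audit record of a stepwise search: accepted steps and the stop reason."""

    steps: list[StepwiseStep] = field(default_factory=list)
    stop_reason: str = ""
    notes: list[str] = field(default_factory=list)

    def bic_values(self) -> list[float]:
        return [s.bic for s in self.steps]


def _as_matrix(X) -> np.ndarray:
    X = X.X if isinstance(X, DescriptorTable) else np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    return X


def filter_almost_constant(
    X, k: int = 3, round_decimals: int = 6
) -> SelectionMask:
    """Drop constant or almost-constant variables.

    After rounding to ``round_decimals`` decimals, a variable is dropped if
    its most frequent value occurs in at least n-k objects — i.e. it is
    constant except in at most k objects.
    """
    X = _as_matrix(X)
    if k < 0 or round_decimals < 0:
        raise ValueError("k and round_decimals must be >= 0")
    n, m = X.shape
    Xr = np.round(X, round_decimals)
    keep = np.ones(m, dtype=bool)
    for j in range(m):
        _, counts = np.unique(Xr[:, j], return_counts=True)
        if counts.max() >= n - k:
            keep[j] = False
    if not keep.any():
        warnings.warn("almost-constant filter removed every variable", stacklevel=2)
    return SelectionMask(keep, provenance=f"almost_const(k={k}, decimals={round_decimals})")


def _r2_with_y(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of each column with y; 0 for zero variance."""
    y = np.asarray(y, float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    r2 = np.zeros(X.shape[1])
    ok = sx > 0
    if sy == 0:
        warnings.warn("y is constant; all correlations treated as 0", stacklevel=3)
        return r2
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} zero-variance column(s): correlation treated as 0",
            stacklevel=3,
        )
    r2[ok] = (xc[:, ok].T @ yc / (sx[ok] * sy)) ** 2
    return r2


def select_top_corr_y(X, y, m_sel: int) -> SelectionMask:
    """Keep the m_sel variables with the largest squared Pearson R^2 with y.

    Ties are broken by original column order (stable sort).
    """
    X = _as_matrix(X)
    m = X.shape[1]
    if not 1 <= m_sel <= m:
        raise ValueError(f"need 1 <= m_sel <= m, got m_sel={m_sel}, m={m}")
    r2 = _r2_with_y(X, y)
    order = np.argsort(-r2, kind="stable")
    keep = np.zeros(m, dtype=bool)
    keep[order[:m_sel]] = True
    return SelectionMask(keep, provenance=f"top_corr_y(m_sel={m_sel})")


def filter_low_corr_y(X, y, r2_min: float) -> SelectionMask:
    """Keep variables whose squared Pearson R^2 with y is at least r2_min."""
    X = _as_matrix(X)
    if not 0.0 <= r2_min <= 1.0:
        raise ValueError(f"r2_min must be in [0, 1], got {r2_min}")
    keep = _r2_with_y(X, y) >= r2_min
    if not keep.any():
        warnings.warn("correlation filter removed every variable", stacklevel=2)
    return SelectionMask(keep, provenance=f"low_corr_y(r2_min={r2_min})")


def eliminate_corr_xx(X, r2_limit: float) -> SelectionMask:
    """Delete one member of every variable pair with mutual R^2 above the limit.

    The full m x m squared-correlation matrix is computed once; offending
    pairs are processed in descending R^2 order, skipping pairs with an
    already-deleted member.  The deleted member is the one with the larger
    sum of squared correlations to all other variables (sums fixed from
    the full matrix); ties go to the larger column index.  Survivors are
    guaranteed to contain no pair above the limit.
    """
    X = _as_matrix(X)
    if not 0.0 < r2_limit <= 1.0:
        raise ValueError(f"r2_limit must be in (0, 1], got {r2_limit}")
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError(
            f"zero-variance column(s) {np.flatnonzero(sd == 0).tolist()}; "
            "apply filter_almost_constant first"
        )
    m = X.shape[1]
    R2 = np.corrcoef(X, rowvar=False) ** 2
    np.fill_diagonal(R2, 0.0)
    corr_sums = R2.sum(axis=1)  # fixed once on the full matrix

    gi, hj = np.triu_indices(m, k=1)
    offending = R2[gi, hj] > r2_limit
    gi, hj = gi[offending], hj[offending]
    order = np.argsort(-R2[gi, hj], kind="stable")

    deleted = np.zeros(m, dtype=bool)
    for idx in order:
        g, h = int(gi[idx]), int(hj[idx])
        if deleted[g] or deleted[h]:
            continue
        if corr_sums[g] > corr_sums[h]:
            deleted[g] = True
        elif corr_sums[h] > corr_sums[g]:
            deleted[h] = True
        else:
            deleted[max(g, h)] = True
    # pairs skipped because one member was already gone cannot leave an
    # offending survivor pair: a pair is only skipped when one member is
    # deleted, and both members of every processed pair are checked.
    return SelectionMask(~deleted, provenance=f"corr_xx(r2_limit={r2_limit})")


def select_by_pls_coeff(
    table: DescriptorTable,
    m_sel: int,
    cv: CVConfig | None = None,
) -> SelectionMask:
    """Keep the m_sel variables with the largest |standardized PLS coefficient|.

    An rdCV run on the autoscaled data fixes A_FINAL; a single PLS model is
    then fitted on all n objects with A_FINAL components and its
    standardized coefficients rank the variables.
    """
    m = table.m
    if not 1 <= m_sel <= m:
        raise ValueError(f"need 1 <= m_sel <= m, got m_sel={m_sel}, m={m}")
    cv = cv or CVConfig(r=20, s_outer=3, s_inner=5)
    if not cv.autoscale:
        cv = CVConfig(**{**vars(cv), "autoscale": True})
    result = rdcv(table, cv)
    model, _ = final_model(table, result.A_FINAL, autoscale=True)
    ranking = np.argsort(-np.abs(standardized_coefficients(model, result.A_FINAL)),
                         kind="stable")
    keep = np.zeros(m, dtype=bool)
    keep[ranking[:m_sel]] = True
    return SelectionMask(
        keep,
        provenance=f"pls_coeff(m_sel={m_sel}, A_FINAL={result.A_FINAL}, "
        f"r={cv.r}, s_outer={cv.s_outer}, s_inner={cv.s_inner}, seed={cv.seed})",
    )


def _ols_rss(Xs: np.ndarray, y: np.ndarray) -> float:
    """RSS of the OLS fit of y on Xs plus an intercept."""
    n = y.size
    design = np.column_stack([np.ones(n), Xs])
    _, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    fitted = design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(((y - fitted) ** 2).sum())


def stepwise_bic(
    table_or_X,
    y=None,
    mode: str = "forward",
    max_steps: int = 500,
    max_time: float = float("inf"),
    max_model_size: int | None = None,
) -> tuple[SelectionMask, StepwiseTrace]:
    """Greedy stepwise variable selection minimizing BIC.

    Starts from the empty model (y explained by the intercept only — the
    only feasible start when m > n).  At each step every single-variable
    addition (and, in mode ``"both"``, every single-variable removal) is
    scored by BIC of its OLS fit; the best move is accepted if it lowers
    the current BIC, otherwise the search stops.  Step and time budgets
    are normal stop conditions, recorded in the trace.

    Candidate additions are scored incrementally: an orthonormal basis of
    the current design is maintained, so one step costs O(n*m) for all m
    candidates rather than m separate refits.
    """
    if isinstance(table_or_X, DescriptorTable):
        X = table_or_X.X
        y = table_or_X.require_y() if y is None else np.asarray(y, float)
    else:
        X = np.asarray(table_or_X, float)
        if y is None:
            raise ValueError("y is required when X is a plain matrix")
        y = np.asarray(y, float)
    if mode not in ("forward", "both"):
        raise ValueError(f"mode must be 'forward' or 'both', got {mode!r}")
    n, m = X.shape
    if n < 5:
        raise ValueError(f"need at least 5 objects for stepwise selection, got {n}")
    if max_model_size is None:
        max_model_size = n - 2

    trace = StepwiseTrace()
    selected: list[int] = []
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        trace.stop_reason = "no_improvement"
        trace.notes.append("y is constant; nothing to select")
        return SelectionMask(np.zeros(m, bool), provenance="stepwise(empty)"), trace

    # orthonormal basis Q of the current design (intercept + selected vars)
    Q = np.ones((n, 1)) / np.sqrt(n)
    resid = y - Q @ (Q.T @ y)
    current_rss = float(resid @ resid)
    current_bic = information_criterion(current_rss, n, 0, "BIC")

    t0 = time.monotonic()
    step_no = 0
    while True:
        if step_no >= max_steps:
            trace.stop_reason = "max_steps"
            break
        if time.monotonic() - t0 > max_time:
            trace.stop_reason = "max_time"
            break

        best: tuple[float, str, int, float] | None = None  # (bic, action, var, rss)

        if len(selected) < max_model_size:
            # score all additions at once: residual of x_j against Q
            Xres = X - Q @ (Q.T @ X)
            norms = np.linalg.norm(Xres, axis=0)
            col_scale = np.linalg.norm(X - X.mean(axis=0), axis=0)
            usable = (norms > 1e-10 * np.maximum(col_scale, 1.0)) & ~np.isin(
                np.arange(m), selected
            )
            if usable.any():
                gain = np.zeros(m)
                gain[usable] = (Xres[:, usable].T @ resid / norms[usable]) ** 2
                rss_add = np.maximum(current_rss - gain, 0.0)
                m_new = len(selected) + 1
                with np.errstate(divide="ignore"):
                    bic_add = np.where(
                        rss_add > _PERFECT_FIT_TOL * tss,
                        n * np.log(np.maximum(rss_add, 1e-300) / n)
                        + m_new * np.log(n),
                        -np.inf,
                    )
                bic_add[~usable] = np.inf
                j = int(np.argmin(bic_add))
                if np.isfinite(bic_add[j]) or bic_add[j] == -np.inf:
                    best = (float(bic_add[j]), "add", j, float(rss_add[j]))

        if mode == "both" and selected:
            for j in selected:
                rest = [v for v in selected if v != j]
                try:
                    rss_rm = _ols_rss(X[:, rest], y) if rest else tss
                except np.linalg.LinAlgError:
                    trace.notes.append(f"removal of {j}: rank-deficient, skipped")
                    continue
                if rss_rm <= _PERFECT_FIT_TOL * tss:
                    bic_rm = -np.inf
                else:
                    bic_rm = information_criterion(rss_rm, n, len(rest), "BIC")
                if best is None or bic_rm < best[0]:
                    best = (bic_rm, "remove", j, rss_rm)

        if best is None or best[0] >= current_bic:
            trace.stop_reason = "no_improvement"
            break

        bic_new, action, j, rss_new = best
        step_no += 1
        if action == "add":
            selected.append(j)
            xres = X[:, j] - Q @ (Q.T @ X[:, j])
            Q = np.column_stack([Q, xres / np.linalg.norm(xres)])
        else:
            selected.remove(j)
            # rebuild the basis for the reduced design
            design = np.column_stack([np.ones(n), X[:, selected]]) if selected else \
                np.ones((n, 1))
            Q, _ = np.linalg.qr(design)
        resid = y - Q @ (Q.T @ y)
        current_rss = float(resid @ resid)
        current_bic = bic_new
        trace.steps.append(StepwiseStep(step_no, action, j, bic_new))
        if bic_new == -np.inf:
            trace.stop_reason = "no_improvement"
            trace.notes.append("perfect fit reached; search stopped")
            break

    mask = np.zeros(m, dtype=bool)
    mask[selected] = True
    prov = f"stepwise(mode={mode}, steps={step_no}, stop={trace.stop_reason})"
    return SelectionMask(mask, provenance=prov), trace


def combine_prefilter_stepwise(
    table: DescriptorTable,
    prefilters: list,
    stepwise_kwargs: dict | None = None,
) -> tuple[SelectionMask, StepwiseTrace]:
    """Apply a chain of pre-filters, then stepwise BIC on the survivors.

    ``prefilters`` is an ordered list of callables ``f(X, y) -> SelectionMask``
    over the *current* survivor matrix; masks compose by AND in application
    order and the provenance records the full chain.  An empty intermediate
    mask raises, naming the stage.
    """
    stepwise_kwargs = stepwise_kwargs or {}
    y = table.require_y()
    m = table.m
    alive = np.ones(m, dtype=bool)
    chain: list[str] = []
    for stage, f in enumerate(prefilters, start=1):
        sub_mask = f(table.X[:, alive], y)
        if not sub_mask.mask.any():
            raise ValueError(
                f"pre-filter stage {stage} ({sub_mask.provenance or f!r}) "
                "removed every remaining variable"
            )
        alive[np.flatnonzero(alive)[~sub_mask.mask]] = False
        chain.append(sub_mask.provenance or f"stage{stage}")

    sub_sel, trace = stepwise_bic(table.X[:, alive], y, **stepwise_kwargs)
    final = np.zeros(m, dtype=bool)
    final[np.flatnonzero(alive)[sub_sel.mask]] = True
    chain.append(sub_sel.provenance)
    return (
        SelectionMask(final, provenance=" then ".join(chain),
                      variable_names=list(table.variable_names)),
        trace,
    )
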
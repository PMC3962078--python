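"""Numeric diagnostics for rdCV results.

The tested surface is numeric: boxplot five-number summaries of the r SEP
estimates, frequency tables of the A_OPT estimates, and per-object
predicted-vs-observed tables.  Plot rendering (matplotlib) is a thin
optional layer on top of these tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossval import RdcvResult

__all__ = ["SepSummary", "sep_summary", "aopt_histogram", "pred_vs_obs_table"]


@dataclass
class SepSummary:
    """Five-number summary of a SEP distribution, with 1.5*IQR whiskers.

    Quartiles use linear interpolation of the empirical distribution
    (numpy's default, the common "type 7" convention).  Whiskers extend to
    the most extreme observed values within Q1 - 1.5*IQR and Q3 + 1.5*IQR;
    values beyond them are listed as outliers.
    """

    label: str
    count: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "count": self.count,
            "min": self.min,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "max": self.max,
            "whisker_low": self.whisker_low,
            "whisker_high": self.whisker_high,
            "outliers": list(self.outliers),
        }


def sep_summary(sep_values, label: str = "") -> SepSummary:
    """Summarize r SEP estimates as boxplot statistics."""
    v = np.asarray(sep_values, float).ravel()
    if v.size == 0:
        raise ValueError("empty SEP vector")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return SepSummary(
        label=label,
        count=int(v.size),
        min=float(v.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(v.max()),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=sorted(float(x) for x in v[(v < lo_fence) | (v > hi_fence)]),
    )


def aopt_histogram(a_opt_estimates) -> tuple[dict[int, int], int]:
    """Frequency table of A_OPT estimates and the modal value.

    The mode is the most frequent component count; ties break toward the
    smaller (more parsimonious) value — the same rule that fixes A_FINAL.
    """
    flat = np.asarray(a_opt_estimates, dtype=int).ravel()
    if flat.size == 0:
        raise ValueError("empty A_OPT list")
    counts = Counter(int(a) for a in flat)
    modal = min(counts, key=lambda a: (-counts[a], a))
    return dict(sorted(counts.items())), modal


def pred_vs_obs_table(result: RdcvResult, y, object_names=None) -> pd.DataFrame:
    """Per-object table of observed y, each repetition's prediction, and the mean.

    Columns: ``y``, ``rep_1`` .. ``rep_r``, ``y_hat_mean``.  Averaging over
    repetitions reduces split-to-split variance, which is why the mean
    column usually tracks y more closely than any single repetition.
    """
    y = np.asarray(y, float).ravel()
    preds = result.predictions
    if preds.shape[0] != y.size:
        raise ValueError(
            f"predictions have {preds.shape[0]} rows, y has length {y.size}"
        )
    r = preds.shape[1]
    df = pd.DataFrame(
        preds, columns=[f"rep_{k + 1}" for k in range(r)],
        index=object_names if object_names is not None else range(y.size),
    )
    df.insert(0, "y", y)
    df["y_hat_mean"] = preds.mean(axis=1)
    return df


def plot_rdcv(result: RdcvResult, y, path=None):  # pragma: no cover - thin wrapper
    """Optional matplotlib panel: SEP boxplot, A_OPT histogram, pred-vs-obs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    axes[0].boxplot(result.sep_per_repetition)
    axes[0].set_ylabel("SEP")
    axes[0].set_title("SEP over repetitions")
    counts, modal = aopt_histogram(result.a_opt_estimates)
    axes[1].bar(list(counts), list(counts.values()))
    axes[1].axvline(modal, ls="--", color="k")
    axes[1].set_xlabel("A_OPT")
    axes[1].set_title(f"A_FINAL = {modal}")
    mean_hat = result.predictions.mean(axis=1)
    axes[2].scatter(y, mean_hat, s=10)
    lims = [min(np.min(y), mean_hat.min()), max(np.max(y), mean_hat.max())]
    axes[2].plot(lims, lims, "k-", lw=0.5)
    axes[2].set_xlabel("observed y")
    axes[2].set_ylabel("mean predicted y")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
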
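"""Agreement and classification statistics.

Covers the method-comparison toolbox: mean absolute percentage error,
mean/SD of paired differences with 1.96-sigma limits of agreement
(Bland-Altman), squared Pearson correlation, a two-tailed paired t-test
with 95% confidence interval, and confusion-matrix accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "ConfusionMatrix",
    "agreement",
    "confusion_accuracy",
    "method_comparison",
]


@dataclass(frozen=True)
class PairedSeries:
    """Estimated and reference measurements of the same samples."""

    estimated: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        est = np.asarray(self.estimated, dtype=float)
        ref = np.asarray(self.reference, dtype=float)
        if est.shape != ref.shape or est.ndim != 1:
            raise ValueError("estimated and reference must be equal-length 1-D series")
        if len(est) < 2:
            raise ValueError("need at least 2 paired samples")
        if np.any(~np.isfinite(est)) or np.any(~np.isfinite(ref)):
            raise ValueError("series contain non-finite values")


@dataclass(frozen=True)
class AgreementReport:
    mean_abs_pct_error: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    r_squared: float
    t_stat: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int


def agreement(series: PairedSeries) -> AgreementReport:
    """Full agreement report between two paired measurement series.

    Differences are estimated - reference.  SD uses the n-1 denominator;
    limits of agreement are mean +/- 1.96 SD; R^2 is the squared Pearson
    correlation of the two series; the t-test is the two-tailed paired test
    with a 95% confidence interval on the mean difference.
    """
    est = np.asarray(series.estimated, dtype=float)
    ref = np.asarray(series.reference, dtype=float)
    d = est - ref
    n = len(d)

    nonzero = ref != 0
    if not nonzero.all():
        warnings.warn(
            "reference values of 0 excluded from percentage error", stacklevel=2
        )
    if nonzero.any():
        mape = float(np.mean(100.0 * np.abs(d[nonzero]) / np.abs(ref[nonzero])))
    else:
        mape = float("nan")

    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))

    if est.std() == 0 or ref.std() == 0:
        r2 = 1.0 if np.allclose(est, ref) else 0.0
    else:
        r2 = float(stats.pearsonr(est, ref).statistic ** 2)

    if sd_diff == 0:
        t_stat, p_value = 0.0, 1.0
        ci_half = 0.0
    else:
        t_res = stats.ttest_rel(est, ref)
        t_stat, p_value = float(t_res.statistic), float(t_res.pvalue)
        ci_half = float(stats.t.ppf(0.975, n - 1) * sd_diff / np.sqrt(n))

    return AgreementReport(
        mean_abs_pct_error=mape,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        r_squared=r2,
        t_stat=t_stat,
        p_value=p_value,
        ci_low=mean_diff - ci_half,
        ci_high=mean_diff + ci_half,
        n=n,
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows = true class, columns = predicted class."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        k = len(self.labels)
        if c.shape != (k, k):
            raise ValueError("counts must be a square matrix matching labels")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if c.sum() == 0:
            raise ValueError("confusion matrix is empty")

    @classmethod
    def from_labels(
        cls, true: Sequence[str], predicted: Sequence[str], labels: Sequence[str]
    ) -> "ConfusionMatrix":
        if len(true) != len(predicted):
            raise ValueError("label sequences must have the same length")
        index = {lbl: i for i, lbl in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(true, predicted):
            counts[index[t], index[p]] += 1
        return cls(labels=tuple(labels), counts=counts)


def confusion_accuracy(cm: ConfusionMatrix) -> tuple[float, float]:
    """(accuracy %, error %) = (100 * trace / total, the complement)."""
    counts = np.asarray(cm.counts, dtype=float)
    accuracy = 100.0 * np.trace(counts) / counts.sum()
    return float(accuracy), float(100.0 - accuracy)


def method_comparison(
    estimates: Mapping[str, Sequence[float]], reference: Sequence[float]
) -> pd.DataFrame:
    """Per-method mean error %, R^2 and SD of differences (mL).

    Every method must be evaluated on the same reference series.
    """
    if not estimates:
        raise ValueError("no methods to compare")
    ref = np.asarray(reference, dtype=float)
    rows = []
    for method, est in estimates.items():
        est_arr = np.asarray(est, dtype=float)
        if est_arr.shape != ref.shape:
            raise ValueError(f"method {method!r} sample count does not match reference")
        rep = agreement(PairedSeries(estimated=est_arr, reference=ref))
        rows.append(
            {
                "method": method,
                "mean_error_pct": rep.mean_abs_pct_error,
                "r_squared": rep.r_squared,
                "sd_ml": rep.sd_diff,
            }
        )
    return pd.DataFrame(rows)
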
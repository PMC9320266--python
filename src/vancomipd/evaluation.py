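"""Predictive-performance metrics and agreement statistics.

For predicted/observed concentration pairs (one per analysis pair):

    bias  = mean(pred - obs)                                  [mg/L]
    rBias = mean((pred - obs) / obs) * 100                    [%]
    rRMSE = sqrt(mean(((pred - obs) / obs)^2)) * 100          [%]

Individual acceptability follows analytical TDM quality criteria: absolute
error <= 2 mg/L for observed concentrations below 20 mg/L, relative error
<= 10% at 20 mg/L and above (thresholds applied to the observed value,
boundaries inclusive).  Exposure categories use the therapeutic ranges
12.5-17.5 mg/L (intermittent trough) and 20-25 mg/L (continuous),
boundaries inclusive; below is subtherapeutic, above supratherapeutic.

The intraclass correlation between predicted and prescribed doses is the
two-way, absolute-agreement, single-measurement ICC(A,1), computed from
the two-way ANOVA mean squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "THERAPEUTIC_RANGES",
    "PredictionRecord",
    "bias",
    "rbias",
    "rrmse",
    "ci95_mean",
    "individually_acceptable",
    "classify_exposure",
    "classification_accuracy",
    "exposure_summary",
    "icc_absolute_agreement",
    "wilcoxon_paired",
    "performance_table",
]

#: inclusive therapeutic concentration ranges (mg/L) by infusion mode
THERAPEUTIC_RANGES: dict[str, tuple[float, float]] = {
    "intermittent": (12.5, 17.5),
    "continuous": (20.0, 25.0),
}

APPROACHES = ("GOTI", "MSA_OFV", "MSA_SSE", "MAA_OFV", "MAA_SSE")

CATEGORIES = ("subtherapeutic", "therapeutic", "supratherapeutic")


@dataclass(frozen=True)
class PredictionRecord:
    """One predicted/observed second concentration for one approach."""

    pair_id: str
    approach: str
    predicted: float
    observed: float
    mode: str
    icu: bool = False

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")
        if not self.observed > 0:
            raise ValueError("observed concentration must be > 0")


def _arrays(predicted, observed) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("predicted and observed must be equal-length non-empty 1-d arrays")
    if np.any(o <= 0):
        raise ValueError("observed concentrations must be > 0")
    return p, o


def bias(predicted, observed) -> float:
    """Mean prediction error (mg/L)."""
    p, o = _arrays(predicted, observed)
    return float(np.mean(p - o))


def rbias(predicted, observed) -> float:
    """Mean relative prediction error, %."""
    p, o = _arrays(predicted, observed)
    return float(np.mean((p - o) / o) * 100.0)


def rrmse(predicted, observed) -> float:
    """Root mean squared relative prediction error, %."""
    p, o = _arrays(predicted, observed)
    return float(np.sqrt(np.mean(((p - o) / o) ** 2)) * 100.0)


def ci95_mean(values) -> tuple[float, float]:
    """95% t confidence interval of the mean: mean +/- t_{.975,n-1} sd/sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("values must be a non-empty 1-d array")
    m = float(np.mean(x))
    if x.size == 1:
        return m, m
    half = stats.t.ppf(0.975, x.size - 1) * np.std(x, ddof=1) / np.sqrt(x.size)
    return m - float(half), m + float(half)


def individually_acceptable(predicted: float, observed: float) -> bool:
    """Per-pair acceptability: |error| <= 2 mg/L below 20 mg/L observed,
    relative error <= 10% at >= 20 mg/L (inclusive)."""
    if observed < 20.0:
        return abs(predicted - observed) <= 2.0
    return abs(predicted - observed) / observed <= 0.10


def classify_exposure(conc: float, mode: str) -> str:
    """Exposure category relative to the mode's therapeutic range."""
    try:
        lo, hi = THERAPEUTIC_RANGES[mode]
    except KeyError:
        raise ValueError(f"unknown infusion mode {mode!r}") from None
    if conc < lo:
        return "subtherapeutic"
    if conc > hi:
        return "supratherapeutic"
    return "therapeutic"


def classification_accuracy(predicted, observed, modes) -> float:
    """% of pairs whose predicted and observed concentrations fall in the
    same exposure category."""
    p, o = _arrays(predicted, observed)
    modes = list(modes)
    if len(modes) != p.size:
        raise ValueError("modes must match predictions")
    same = [
        classify_exposure(pi, m) == classify_exposure(oi, m)
        for pi, oi, m in zip(p, o, modes)
    ]
    return float(100.0 * np.mean(same))


def exposure_summary(categories) -> pd.DataFrame:
    """Counts and percentages (1 decimal) per exposure category.

    ``categories`` is an iterable of category labels (order-invariant).
    """
    cats = list(categories)
    if not cats:
        raise ValueError("no records to summarize")
    n = len(cats)
    rows = []
    for c in CATEGORIES:
        count = sum(1 for x in cats if x == c)
        rows.append({"category": c, "count": count, "percent": round(100.0 * count / n, 1)})
    out = pd.DataFrame(rows).set_index("category")
    assert int(out["count"].sum()) == n
    return out


def icc_absolute_agreement(x, y) -> float:
    """Two-way, absolute-agreement, single-measurement ICC(A,1) between two
    raters (e.g. predicted and prescribed dose), from mean squares:

        (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),  k = 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = x.size
    if n < 3:
        raise ValueError("ICC needs at least 3 pairs")
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse)))


def wilcoxon_paired(first, second) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (Wilcoxon's original treatment); if all
    differences are zero the test is degenerate and p = 1.0 is returned.
    """
    x = np.asarray(first, dtype=float)
    y = np.asarray(second, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("paired samples must be equal-length non-empty 1-d arrays")
    if np.all(x == y):
        return 1.0
    return float(stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided").pvalue)


def performance_table(records: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-approach / per-subgroup performance report.

    ``records`` needs columns approach, predicted, observed, mode, icu.
    Subgroups: overall, intermittent, continuous, icu, non_icu.  Columns:
    bias (+CI), rbias (+CI), rrmse, pct_acceptable, classification_accuracy, n.
    """
    required = {"approach", "predicted", "observed", "mode", "icu"}
    if not required <= set(records.columns):
        raise ValueError(f"records missing columns {sorted(required - set(records.columns))}")
    subgroups = {
        "overall": np.ones(len(records), dtype=bool),
        "intermittent": (records["mode"] == "intermittent").to_numpy(),
        "continuous": (records["mode"] == "continuous").to_numpy(),
        "icu": records["icu"].to_numpy(dtype=bool),
        "non_icu": ~records["icu"].to_numpy(dtype=bool),
    }
    rows = []
    for approach, grp in records.groupby("approach", sort=False):
        in_grp = records["approach"].to_numpy() == approach
        for name, mask in subgroups.items():
            sel = records[in_grp & mask]
            if len(sel) == 0:
                continue
            p = sel["predicted"].to_numpy()
            o = sel["observed"].to_numpy()
            err = p - o
            rel = (p - o) / o * 100.0
            b_lo, b_hi = ci95_mean(err)
            r_lo, r_hi = ci95_mean(rel)
            acc = [individually_acceptable(pi, oi) for pi, oi in zip(p, o)]
            rows.append(
                {
                    "approach": approach,
                    "subgroup": name,
                    "n": len(sel),
                    "bias": bias(p, o),
                    "bias_lo": b_lo,
                    "bias_hi": b_hi,
                    "rbias": rbias(p, o),
                    "rbias_lo": r_lo,
                    "rbias_hi": r_hi,
                    "rrmse": rrmse(p, o),
                    "pct_acceptable": round(100.0 * float(np.mean(acc)), 1),
                    "classification_accuracy": round(
                        classification_accuracy(p, o, sel["mode"]), 1
                    ),
                }
            )
    return pd.DataFrame(rows)
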
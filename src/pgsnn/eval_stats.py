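"""Comparison metrics: r^2, baseline-relative performance, paired tests, QC.

Performance of every model is measured as the squared Pearson
correlation between observed and predicted phenotypes on the held-out
test split.  To put different phenotypes on a common scale, results are
expressed relative to the additive LD-aware PGS baseline: the
fraction-of-baseline r^2 per model, and the nonlinear-vs-linear gap

    gap% = 100 * (r2_nonlinear - r2_linear) / r2_baseline,

whose sign is the evidence for exploitable nonlinearity.  Replicate
gaps are tested with a classical two-sided paired t-test.  The
result-QC filter drops phenotypes whose relative metric is a gross
outlier (> 500% away from the collection mean by default) or where any
of the three models failed to reach nominal significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScenarioResult",
    "ComparisonSummary",
    "r_squared",
    "prediction_p_value",
    "relative_metrics",
    "paired_t",
    "qc_filter",
]


@dataclass
class ScenarioResult:
    """Per-replicate model performances for one simulation scenario."""

    scenario: str
    epistasis_percent: float
    additive_percent: float
    joint_tagging: bool
    mitigation: str
    r2_nonlinear: list[float]
    r2_linear: list[float]
    r2_baseline: list[float]
    p_nonlinear: list[float] = field(default_factory=list)
    p_linear: list[float] = field(default_factory=list)
    p_baseline: list[float] = field(default_factory=list)
    replicate_seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.r2_nonlinear)
        if n < 1 or len(self.r2_linear) != n or len(self.r2_baseline) != n:
            raise ValueError("replicate r^2 lists must be non-empty and equal length")
        for vals in (self.r2_nonlinear, self.r2_linear, self.r2_baseline):
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError("r^2 values must lie in [0, 1]")

    @property
    def n_replicates(self) -> int:
        return len(self.r2_nonlinear)

    def gaps_percent(self) -> np.ndarray:
        out = []
        for nl, li, ba in zip(self.r2_nonlinear, self.r2_linear, self.r2_baseline):
            out.append(relative_metrics(nl, li, ba)["gap_percent"])
        return np.array(out)

    def summarize(self) -> "ComparisonSummary":
        return paired_t(self.gaps_percent())

    def to_row(self) -> dict:
        s = self.summarize()
        return {
            "scenario": self.scenario,
            "epistasis_percent": self.epistasis_percent,
            "additive_percent": self.additive_percent,
            "joint_tagging": self.joint_tagging,
            "mitigation": self.mitigation,
            "mean_gap_percent": s.mean_gap,
            "t_statistic": s.t_statistic,
            "t_test_p": s.p_value,
            "n_replicates": s.n,
        }


@dataclass
class ComparisonSummary:
    """Mean nonlinear-vs-linear gap with its paired-t significance."""

    mean_gap: float
    t_statistic: float
    p_value: float
    n: int
    gaps: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(observed) != len(predicted) or len(observed) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if observed.std() == 0:
        raise ValueError("observed phenotype is constant")
    if predicted.std() == 0:
        warnings.warn("constant predictions: r^2 reported as 0")
        return 0.0
    r = np.corrcoef(observed, predicted)[0, 1]
    return float(r * r)


def prediction_p_value(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Two-sided p for association between predictions and observations.

    Pearson correlation test on the test split; used as the nominal
    significance of a network's predictions.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if predicted.std() == 0 or observed.std() == 0:
        return 1.0
    return float(stats.pearsonr(observed, predicted).pvalue)


def relative_metrics(r2_nl: float, r2_lin: float, r2_base: float) -> dict[str, float]:
    """Baseline-relative performance of the two network variants.

    fraction_of_baseline below 1.0 means the network lost to the
    additive PGS baseline; gap_percent is the nonlinear advantage in
    percent of baseline r^2.
    """
    if r2_base <= 0:
        raise ValueError("baseline r^2 must be positive")
    return {
        "fraction_of_baseline_nl": r2_nl / r2_base,
        "fraction_of_baseline_lin": r2_lin / r2_base,
        "gap_percent": 100.0 * (r2_nl - r2_lin) / r2_base,
    }


def paired_t(
    gaps: Optional[Sequence[float]] = None,
    a: Optional[Sequence[float]] = None,
    b: Optional[Sequence[float]] = None,
) -> ComparisonSummary:
    """Two-sided paired t-test on per-replicate differences.

    Call either with precomputed per-replicate gaps, or with the two
    paired arms ``a`` and ``b`` (differences a - b).  Zero-variance
    differences with zero mean report p = 1 exactly; a nonzero mean with
    zero variance is degenerate and raises.
    """
    if gaps is None:
        if a is None or b is None:
            raise ValueError("provide gaps, or both paired arms")
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired arms must have equal length")
        diffs = a - b
    else:
        diffs = np.asarray(gaps, dtype=float)
    n = len(diffs)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0:
        if mean == 0:
            return ComparisonSummary(0.0, 0.0, 1.0, n, diffs)
        raise ValueError("degenerate paired t: zero variance, nonzero mean")
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return ComparisonSummary(mean, float(t), p, n, diffs)


def qc_filter(
    results: pd.DataFrame,
    outlier_percent: float = 500.0,
    alpha: float = 0.05,
    metric_column: str = "fraction_of_baseline",
    p_columns: tuple[str, str, str] = ("p_linear", "p_nonlinear", "p_baseline"),
) -> pd.DataFrame:
    """Drop low-signal or outlying phenotype results.

    A record is removed when its relative metric deviates from the
    collection mean by more than ``outlier_percent`` percent of the
    mean's magnitude (|x - mean| > (outlier_percent/100) * |mean|, mean
    computed once before removal), or when any of the three model
    p-values is missing or >= ``alpha``.
    """
    if results.empty:
        return results.copy()
    for col in (metric_column, *p_columns):
        if col not in results.columns:
            raise ValueError(f"qc_filter: missing column {col!r}")
    x = results[metric_column].to_numpy(dtype=float)
    mean = x.mean()
    within = np.abs(x - mean) <= (outlier_percent / 100.0) * abs(mean)
    significant = np.ones(len(results), dtype=bool)
    for col in p_columns:
        p = results[col].to_numpy(dtype=float)
        significant &= np.isfinite(p) & (p < alpha)
    return results[within & significant].copy()


def results_table(scenarios: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Scenario-by-scenario summary table (one row per scenario)."""
    return pd.DataFrame([s.to_row() for s in scenarios])


def long_format_results(per_phenotype: pd.DataFrame) -> pd.DataFrame:
    """Long-format (phenotype, model, fraction_of_baseline) table."""
    rows = []
    for rec in per_phenotype.itertuples():
        for model in ("linear", "nonlinear"):
            rows.append(
                {
                    "phenotype": rec.phenotype,
                    "model": model,
                    "fraction_of_baseline": getattr(rec, f"fraction_of_baseline_{'lin' if model == 'linear' else 'nl'}"),
                }
            )
    return pd.DataFrame(rows)
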
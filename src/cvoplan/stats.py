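"""Validation statistics for measured osteotomy cohorts.

Pearson correlation with a two-sided t-test p-value, single-measure
intraclass correlation coefficients (ICC) from two-way / one-way ANOVA mean
squares, and cohort summaries including the proportion of hips with
clinically relevant (>= 5 mm) leg shortening.

The ICC forms follow the Shrout–Fleiss naming: ``oneway`` (ICC(1,1), raters
not crossed with subjects — the usual intra-rater choice),
``two_way_random_absolute`` (ICC(2,1), absolute agreement between
interchangeable raters — the usual inter-rater choice) and
``two_way_mixed_consistency`` (ICC(3,1)).  Every result carries its form
label, since the three can differ substantially on the same table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrResult",
    "ICCResult",
    "CohortSummary",
    "UndefinedCorrelationError",
    "pearson",
    "icc",
    "cohort_summary",
    "validate_cohort",
]

ICC_FORMS = ("oneway", "two_way_random_absolute", "two_way_mixed_consistency")

#: Leg-shortening threshold (mm) separating clinically relevant cases.
SHORTENING_THRESHOLD_MM = 5.0


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested on a zero-variance series."""


@dataclass(frozen=True)
class CorrResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class ICCResult:
    icc: float
    form: str
    n_subjects: int
    n_raters: int


@dataclass(frozen=True)
class CohortSummary:
    """Per-variable mean/min/max plus the >=5 mm shortening tally."""

    variables: Mapping[str, tuple[float, float, float]]  # name -> (mean, min, max)
    n: int
    n_shortening_ge_threshold: int
    threshold_mm: float = SHORTENING_THRESHOLD_MM

    @property
    def proportion_shortening_ge_threshold(self) -> float:
        return self.n_shortening_ge_threshold / self.n


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrResult:
    """Pearson product-moment correlation with a two-sided p-value.

    The p-value comes from the exact t transform ``t = r sqrt((n-2)/(1-r²))``
    on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    res = sps.pearsonr(x, y)
    return CorrResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def _anova_mean_squares(table: np.ndarray) -> tuple[float, float, float, float]:
    """Two-way and one-way ANOVA mean squares for a subjects x raters table.

    Returns ``(ms_rows, ms_cols, ms_error, ms_within)`` — between-subjects,
    between-raters, residual (two-way), and within-subjects (one-way).
    """
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((table - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    ms_within = (ss_total - ss_rows) / (n * (k - 1))
    return ms_rows, ms_cols, ms_err, ms_within


def icc(
    ratings: np.ndarray | pd.DataFrame,
    form: str = "two_way_random_absolute",
) -> ICCResult:
    """Single-measure intraclass correlation for a subjects x raters table.

    The table must be complete (no missing cells; no imputation is
    attempted).  Fewer than five subjects triggers a warning, not an error.
    """
    if form not in ICC_FORMS:
        raise ValueError(f"unknown ICC form {form!r}; choose one of {ICC_FORMS}")
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters table")
    n, k = table.shape
    if k < 2:
        raise ValueError("need at least 2 raters/repeats")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.isnan(table).any():
        raise ValueError("ratings table has missing cells; ICC requires a complete table")
    if n < 5:
        import warnings

        warnings.warn(f"ICC on only {n} subjects is unstable", stacklevel=2)

    ms_rows, ms_cols, ms_err, ms_within = _anova_mean_squares(table)
    if form == "oneway":
        denom = ms_rows + (k - 1) * ms_within
        value = 0.0 if denom == 0 else (ms_rows - ms_within) / denom
    elif form == "two_way_random_absolute":
        denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        value = 0.0 if denom == 0 else (ms_rows - ms_err) / denom
    else:  # two_way_mixed_consistency
        denom = ms_rows + (k - 1) * ms_err
        value = 0.0 if denom == 0 else (ms_rows - ms_err) / denom
    return ICCResult(icc=float(value), form=form, n_subjects=n, n_raters=k)


_SUMMARY_FIELDS = (
    "theta",
    "A",
    "B",
    "actual_shortening",
    "actual_lateralization",
    "predicted_shortening",
    "predicted_lateralization",
    "lhi_pre",
    "lhi_post",
)


def _as_dataframe(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    from .radiometrics import records_to_dataframe

    return records_to_dataframe(list(records))


def cohort_summary(records) -> CohortSummary:
    """Mean/min/max of the headline variables and the >=5 mm shortening tally.

    Accepts a sequence of MeasurementRecords or their exported DataFrame.
    """
    df = _as_dataframe(records)
    if df.empty:
        raise ValueError("cohort is empty")
    variables = {
        name: (float(df[name].mean()), float(df[name].min()), float(df[name].max()))
        for name in _SUMMARY_FIELDS
        if name in df.columns
    }
    n_ge = int((df["actual_shortening"] >= SHORTENING_THRESHOLD_MM).sum())
    return CohortSummary(variables=variables, n=len(df), n_shortening_ge_threshold=n_ge)


#: The four relationships examined in cohort validation: model vs measurement
#: for both displacement components, and the two univariate drivers of
#: shortening (varus angle, lateral shift).
VALIDATION_PAIRS = {
    "predicted_vs_actual_shortening": ("predicted_shortening", "actual_shortening"),
    "predicted_vs_actual_lateralization": ("predicted_lateralization", "actual_lateralization"),
    "theta_vs_actual_shortening": ("theta", "actual_shortening"),
    "lateral_shift_vs_actual_shortening": ("A", "actual_shortening"),
}


def validate_cohort(records) -> dict:
    """Correlation battery plus cohort summary for a measured cohort.

    Returns a JSON-serializable report: one entry per correlation (r, p, n —
    or a flag when the correlation is degenerate), the summary statistics,
    and the scatter data behind each correlation for plotting or export.
    """
    df = _as_dataframe(records)
    if len(df) < 3:
        raise ValueError(f"need at least 3 hips to validate, got {len(df)}")
    correlations: dict[str, dict] = {}
    scatter: dict[str, dict] = {}
    for label, (xcol, ycol) in VALIDATION_PAIRS.items():
        scatter[label] = {
            "x": df[xcol].tolist(),
            "y": df[ycol].tolist(),
            "x_name": xcol,
            "y_name": ycol,
        }
        try:
            res = pearson(df[xcol], df[ycol])
            correlations[label] = {"r": res.r, "p": res.p, "n": res.n}
        except UndefinedCorrelationError as exc:
            correlations[label] = {"r": None, "p": None, "n": len(df), "flag": str(exc)}
    summary = cohort_summary(df)
    return {
        "n_hips": summary.n,
        "correlations": correlations,
        "summary": {
            "variables": {k: {"mean": m, "min": lo, "max": hi} for k, (m, lo, hi) in summary.variables.items()},
            "n_shortening_ge_5mm": summary.n_shortening_ge_threshold,
            "proportion_shortening_ge_5mm": summary.proportion_shortening_ge_threshold,
        },
        "scatter": scatter,
    }
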
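"""WHO immunological staging of CD4 counts and baseline descriptive statistics.

The four-category WHO immunological classification codes CD4 counts as
1 = normal (>= 500 cells/mm3), 2 = mild (350-499), 3 = advanced (200-349)
and 4 = severe (< 200).  Band boundaries follow the closed-left convention
[500, inf), [350, 500), [200, 350), [0, 200): the WHO prose uses strict
inequalities on both sides, which leaves the exact cut points undefined,
while the tabulated bands ("350-499", ">= 500") imply closed-left intervals.

The module also produces baseline frequency/percentage summaries (counts,
one-decimal percentages with round-half-up, median and IQR for continuous
variables) and a correlation screen with significance stars.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OrdinalStage",
    "STAGE_LABELS",
    "CD4_BANDS",
    "who_stage",
    "who_stage_codes",
    "FrequencySummary",
    "baseline_table",
    "CorrelationReport",
    "correlation_significance",
]

STAGE_LABELS: dict[int, str] = {1: "normal", 2: "mild", 3: "advanced", 4: "severe"}

#: stage code -> half-open CD4 interval [lo, hi); stage 1 is unbounded above.
CD4_BANDS: dict[int, tuple[float, float]] = {
    1: (500.0, math.inf),
    2: (350.0, 500.0),
    3: (200.0, 350.0),
    4: (0.0, 200.0),
}

_CUTS = np.array([200.0, 350.0, 500.0])


@dataclass(frozen=True)
class OrdinalStage:
    """One ordinal immunological stage (code 1..K, label per WHO band)."""

    code: int
    label: str
    K: int = 4

    def __post_init__(self) -> None:
        if not 1 <= self.code <= self.K:
            raise ValueError(f"stage code {self.code} outside 1..{self.K}")
        if STAGE_LABELS.get(self.code) != self.label:
            raise ValueError(f"label {self.label!r} does not match code {self.code}")


def who_stage(cd4: float) -> OrdinalStage:
    """Map a CD4 count (cells/mm3) to its WHO immunological stage.

    >>> who_stage(520).code, who_stage(150).code, who_stage(350).code
    (1, 4, 2)
    """
    if not np.isfinite(cd4) or cd4 < 0:
        raise ValueError(f"CD4 count must be finite and non-negative, got {cd4!r}")
    code = 4 - int(np.digitize(cd4, _CUTS))
    return OrdinalStage(code=code, label=STAGE_LABELS[code])


def who_stage_codes(cd4: np.ndarray) -> np.ndarray:
    """Vectorized :func:`who_stage`, returning integer codes 1..4."""
    cd4 = np.asarray(cd4, dtype=float)
    if np.any(~np.isfinite(cd4)) or np.any(cd4 < 0):
        raise ValueError("CD4 counts must be finite and non-negative")
    return 4 - np.digitize(cd4, _CUTS)


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FrequencySummary:
    """Counts/percentages for categorical and median/IQR for continuous variables."""

    categorical: pd.DataFrame  # columns: variable, category, count, percent
    continuous: pd.DataFrame  # columns: variable, median, q1, q3

    def to_text(self) -> str:
        """Plain-text rendering mirroring a baseline-characteristics table."""
        lines = ["Variables                          Count (percentage)"]
        for var, grp in self.categorical.groupby("variable", sort=False):
            lines.append(f"{var}, n (%)")
            for _, row in grp.iterrows():
                lines.append(f"  {row['category']:<30} {row['count']} ({row['percent']})")
        for _, row in self.continuous.iterrows():
            lines.append(
                f"{row['variable']}, Median (IQR)          "
                f"{row['median']:g} ({row['q1']:g}-{row['q3']:g})"
            )
        return "\n".join(lines)


def baseline_table(
    data: pd.DataFrame,
    categorical: dict[str, list] | None = None,
    continuous: list[str] | None = None,
) -> FrequencySummary:
    """Baseline descriptive statistics for a subject-level table.

    Parameters
    ----------
    data
        One row per subject.
    categorical
        Mapping variable -> ordered list of admissible categories.  A value
        outside the declared set raises; missing values are excluded and the
        percentage denominator is the per-variable non-missing count.
    continuous
        Variables summarised by median and IQR (linear-interpolation
        quantiles).
    """
    categorical = categorical or {}
    continuous = continuous or []
    cat_rows = []
    for var, levels in categorical.items():
        col = data[var].dropna()
        bad = set(col.unique()) - set(levels)
        if bad:
            raise ValueError(f"variable {var!r} has undeclared categories: {sorted(map(str, bad))}")
        denom = len(col)
        counts = col.value_counts()
        for level in levels:
            n = int(counts.get(level, 0))
            pct = _round_half_up(100.0 * n / denom) if denom else float("nan")
            cat_rows.append({"variable": var, "category": level, "count": n, "percent": pct})
    cont_rows = []
    for var in continuous:
        col = data[var].dropna().astype(float)
        q1, med, q3 = np.percentile(col, [25, 50, 75])  # type-7 linear interpolation
        cont_rows.append({"variable": var, "median": med, "q1": q1, "q3": q3})
    return FrequencySummary(
        categorical=pd.DataFrame(cat_rows, columns=["variable", "category", "count", "percent"]),
        continuous=pd.DataFrame(cont_rows, columns=["variable", "median", "q1", "q3"]),
    )


def _star_band(p: float) -> str:
    if np.isnan(p):
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations with significance bands.

    ``stars`` uses the conventional three-band key: (*) P<0.05,
    (**) P<0.01, (***) P<0.001.
    """

    corr: pd.DataFrame
    p_values: pd.DataFrame
    stars: pd.DataFrame
    warnings: list = field(default_factory=list)


def correlation_significance(X: pd.DataFrame) -> CorrelationReport:
    """Correlation screen across columns of ``X`` (pairwise-complete).

    Two-sided p-values come from the t approximation
    ``t = r * sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.  Columns with
    zero variance yield undefined correlations, reported as NaN with a
    warning record.
    """
    cols = list(X.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    warn_records: list[str] = []
    arr = X.to_numpy(dtype=float)
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        for j in range(i + 1, k):
            mask = np.isfinite(arr[:, i]) & np.isfinite(arr[:, j])
            xi, xj = arr[mask, i], arr[mask, j]
            n = mask.sum()
            if n < 3:
                warn_records.append(f"{cols[i]}~{cols[j]}: fewer than 3 complete pairs")
                continue
            if np.std(xi) == 0 or np.std(xj) == 0:
                warn_records.append(f"{cols[i]}~{cols[j]}: zero-variance column")
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rij, pij = sps.pearsonr(xi, xj)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    stars = np.vectorize(_star_band)(p)
    np.fill_diagonal(stars, "")
    return CorrelationReport(
        corr=pd.DataFrame(r, index=cols, columns=cols),
        p_values=pd.DataFrame(p, index=cols, columns=cols),
        stars=pd.DataFrame(stars, index=cols, columns=cols),
        warnings=warn_records,
    )
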
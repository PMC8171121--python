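"""Two-group demographic table machinery: mean/SD summaries, pooled
t-tests, uncorrected 2x2 chi-square, and Shapiro-Wilk normality.

The dispersion convention is the population (divide-by-n) standard
deviation, and binary traits use the Pearson chi-square without continuity
correction — both verified to reproduce the reference comparison table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import t_test_two_sample

__all__ = [
    "GroupSummary",
    "mean_sd",
    "chi_square_2x2",
    "shapiro_wilk",
    "demographic_table",
]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float | None = None
    sd: float | None = None
    count: int | None = None
    percentage: float | None = None


def mean_sd(values: Sequence[float], population: bool = True) -> tuple[float, float]:
    """Mean and standard deviation; population (÷n) by default, sample (÷n-1)
    otherwise."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    ddof = 0 if population else 1
    if not population and arr.size < 2:
        raise ValueError("sample sd needs n >= 2")
    return float(arr.mean()), float(arr.std(ddof=ddof))


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table (a, b; c, d) with 1 df.

    A zero margin gives (0, 1) by convention.  Yates continuity correction
    is available but off by default.
    """
    for cell in (a, b, c, d):
        if cell < 0 or int(cell) != cell:
            raise ValueError("cells must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff * diff / math.prod(margins)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000 non-constant data."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3 or arr.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if arr.std() == 0:
        raise ValueError("degenerate (constant) input")
    w, p = stats.shapiro(arr)
    return float(w), float(p)


def demographic_table(
    subjects: pd.DataFrame,
    group_column: str,
    case_label: str,
    control_label: str,
    continuous: Sequence[str],
    binary: Mapping[str, object],
) -> pd.DataFrame:
    """Two-group comparison table.

    Continuous columns are summarized as ``mean (population sd)`` per group
    and compared with the pooled two-sided t-test; binary columns (declared
    as ``column -> positive value``) as ``count (%)`` with the uncorrected
    chi-square.  Rows come back in declaration order.
    """
    if subjects[group_column].isna().any():
        missing = subjects.index[subjects[group_column].isna()].tolist()
        raise ValueError(f"subjects with missing group: {missing}")
    unknown = set(subjects[group_column]) - {case_label, control_label}
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    case = subjects[subjects[group_column] == case_label]
    ctrl = subjects[subjects[group_column] == control_label]
    rows = []
    for col in continuous:
        xs = case[col].to_numpy(dtype=float)
        ys = ctrl[col].to_numpy(dtype=float)
        m1, s1 = mean_sd(xs, population=True)
        m2, s2 = mean_sd(ys, population=True)
        if np.concatenate([xs, ys]).std() == 0:
            p = 1.0
        else:
            _, p, _ = t_test_two_sample(xs, ys, equal_variance=True)
        rows.append(
            {
                "characteristic": col,
                "kind": "continuous",
                "case": f"{_sig4(m1)} ({s1:.2f})",
                "control": f"{_sig4(m2)} ({s2:.2f})",
                "case_mean": m1,
                "case_sd": s1,
                "control_mean": m2,
                "control_sd": s2,
                "p": p,
            }
        )
    for col, positive in binary.items():
        a = int((case[col] == positive).sum())
        b = len(case) - a
        c = int((ctrl[col] == positive).sum())
        d = len(ctrl) - c
        _, p = chi_square_2x2(a, b, c, d, yates=False)
        rows.append(
            {
                "characteristic": col,
                "kind": "binary",
                "case": f"{a} ({100.0 * a / len(case):g})",
                "control": f"{c} ({100.0 * c / len(ctrl):g})",
                "case_count": a,
                "control_count": c,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def _sig4(x: float) -> str:
    """Render a mean to 4 significant digits, rounding halves up (the
    convention of the reference table, e.g. 141.25 -> 141.3)."""
    from decimal import ROUND_HALF_UP, Decimal

    d = Decimal(repr(float(x)))
    if d == 0:
        return "0"
    exponent = d.adjusted()  # position of the leading digit
    quantum = Decimal(1).scaleb(exponent - 3)
    return f"{float(d.quantize(quantum, rounding=ROUND_HALF_UP)):g}"
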
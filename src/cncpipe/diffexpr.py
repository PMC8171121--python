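"""Two-group differential expression, validation-candidate selection,
microarray/qPCR concordance and hierarchical leaf ordering.

Fold changes are linear-scale ratios of group means; t-tests run on the
log2 signal (the log signal is the quantity expected to be normal).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .io_formats import ExpressionBundle, GroupDesign

__all__ = [
    "DERecord",
    "QpcrOutcome",
    "t_test_two_sample",
    "fold_change_linear",
    "call_de",
    "de_table",
    "select_validation_candidates",
    "concordance_rate",
    "cluster_order",
]


@dataclass
class DERecord:
    feature_id: str
    biotype: str
    mean_case: float
    mean_control: float
    fold_change: float
    direction: str  # 'up' | 'down', relative to the case group
    t_statistic: float
    p_value: float
    raw_intensity: float
    is_de: bool = False

    def __post_init__(self) -> None:
        if self.fold_change < 1.0:
            raise ValueError(f"{self.feature_id}: fold_change {self.fold_change} < 1")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.feature_id}: p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class QpcrOutcome:
    feature_id: str
    qpcr_call: str  # 'up' | 'down' | 'unchanged'

    def __post_init__(self) -> None:
        if self.qpcr_call not in ("up", "down", "unchanged"):
            raise ValueError(f"invalid qpcr_call {self.qpcr_call!r}")


def t_test_two_sample(
    xs: Sequence[float],
    ys: Sequence[float],
    equal_variance: bool = True,
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; pooled (Student) or Welch variance.

    Degenerate zero-variance input follows the documented convention:
    equal means give (0, 1), unequal means give p -> 0 with a warning.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.isfinite(xs).all() and np.isfinite(ys).all()):
        raise ValueError("non-finite values in input")
    nx, ny = len(xs), len(ys)
    if equal_variance:
        df = nx + ny - 2.0
    else:
        vx, vy = xs.var(ddof=1), ys.var(ddof=1)
        if vx == 0 and vy == 0:
            df = float(nx + ny - 2)
        else:
            num = (vx / nx + vy / ny) ** 2
            den = (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            df = num / den
    if xs.var(ddof=1) == 0 and ys.var(ddof=1) == 0:
        if xs.mean() == ys.mean():
            return 0.0, 1.0, df
        warnings.warn("zero variance with unequal means; p = 0 limit", RuntimeWarning)
        t = math.inf if xs.mean() > ys.mean() else -math.inf
        return t, 0.0, df
    res = stats.ttest_ind(xs, ys, equal_var=equal_variance)
    return float(res.statistic), float(res.pvalue), float(df)


def fold_change_linear(mean_case: float, mean_control: float) -> tuple[float, str]:
    """Linear fold change >= 1 plus direction relative to the case group.

    A ratio of exactly 1 is labeled 'down' by convention (it can never pass
    any fold-change gate > 1, so the label is inert).
    """
    if mean_case <= 0 or mean_control <= 0:
        raise ValueError("group means must be positive for a linear fold change")
    ratio = mean_case / mean_control
    if ratio > 1:
        return ratio, "up"
    return 1.0 / ratio, "down"


def call_de(
    bundle: ExpressionBundle,
    design: GroupDesign,
    biotypes: Mapping[str, str] | None = None,
    fc_min: float = 1.5,
    p_max: float = 0.05,
    equal_variance: bool = True,
) -> list[DERecord]:
    """Per-feature DE records; the DE set is {FC >= fc_min and p < p_max}.

    ``bundle`` must be linear-scale, normalized and strictly positive.
    ``biotypes`` maps feature_id -> biotype; unmapped features get 'mRNA'.
    """
    if bundle.scale != "linear":
        raise ValueError("call_de expects a linear-scale bundle")
    case = design.case_samples
    ctrl = design.control_samples
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("each group needs >= 2 samples")
    missing = [s for s in (*case, *ctrl) if s not in bundle.sample_ids]
    if missing:
        raise ValueError(f"design samples absent from bundle: {missing}")
    lin = bundle.values.to_numpy(dtype=float)
    if (lin <= 0).any():
        raise ValueError("call_de requires strictly positive intensities")
    log_vals = np.log2(lin)
    col_index = {s: i for i, s in enumerate(bundle.sample_ids)}
    case_idx = [col_index[s] for s in case]
    ctrl_idx = [col_index[s] for s in ctrl]
    # vectorized t-tests on the log2 signal
    lx, ly = log_vals[:, case_idx], log_vals[:, ctrl_idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tt = stats.ttest_ind(lx, ly, axis=1, equal_var=equal_variance)
    t_arr = np.asarray(tt.statistic, dtype=float)
    p_arr = np.asarray(tt.pvalue, dtype=float)
    # degenerate zero-variance rows per the documented convention
    degenerate = (lx.var(axis=1, ddof=1) == 0) & (ly.var(axis=1, ddof=1) == 0)
    equal_means = lx.mean(axis=1) == ly.mean(axis=1)
    t_arr[degenerate & equal_means] = 0.0
    p_arr[degenerate & equal_means] = 1.0
    p_arr[degenerate & ~equal_means] = 0.0
    flagged = degenerate & ~equal_means
    t_arr[flagged] = np.where(lx.mean(axis=1) > ly.mean(axis=1), np.inf, -np.inf)[flagged]
    records: list[DERecord] = []
    for i, fid in enumerate(bundle.feature_ids):
        mean_case = float(lin[i, case_idx].mean())
        mean_ctrl = float(lin[i, ctrl_idx].mean())
        fc, direction = fold_change_linear(mean_case, mean_ctrl)
        t, p = float(t_arr[i]), float(p_arr[i])
        biotype = (biotypes or {}).get(fid, "mRNA")
        rec = DERecord(
            feature_id=fid,
            biotype=biotype,
            mean_case=mean_case,
            mean_control=mean_ctrl,
            fold_change=fc,
            direction=direction,
            t_statistic=t,
            p_value=p,
            raw_intensity=max(mean_case, mean_ctrl),
            is_de=(fc >= fc_min and p < p_max),
        )
        records.append(rec)
    return records


def de_table(records: Iterable[DERecord], bh_fdr: bool = True) -> pd.DataFrame:
    """Tabulate DE records; optionally append a Benjamini-Hochberg column."""
    rows = [
        {
            "feature_id": r.feature_id,
            "biotype": r.biotype,
            "mean_case": r.mean_case,
            "mean_control": r.mean_control,
            "fold_change": r.fold_change,
            "direction": r.direction,
            "t": r.t_statistic,
            "p": r.p_value,
            "raw_intensity": r.raw_intensity,
            "de_flag": r.is_de,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    if bh_fdr and len(df):
        p = df["p"].to_numpy()
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.clip(ranked, 0, 1)
        df["q_bh"] = q
    return df


def select_validation_candidates(
    records: Sequence[DERecord],
    fc_min: float = 2.0,
    p_max: float = 0.05,
    intensity_min: float = 500.0,
    n_each: int = 10,
) -> dict[str, list[DERecord]]:
    """Strict-inequality gates (FC > fc_min, p < p_max, intensity > min),
    then the top ``n_each`` per (biotype, direction) by fold change.

    Tie-break: fold change descending, p ascending, feature id ascending.
    Returns a dict keyed by ``(biotype, direction)`` joined with ':'.
    """
    qualifying = [
        r
        for r in records
        if r.fold_change > fc_min and r.p_value < p_max and r.raw_intensity > intensity_min
    ]
    out: dict[str, list[DERecord]] = {}
    keys = sorted({(r.biotype, r.direction) for r in qualifying})
    for biotype, direction in keys:
        pool = [r for r in qualifying if r.biotype == biotype and r.direction == direction]
        pool.sort(key=lambda r: (-r.fold_change, r.p_value, r.feature_id))
        if len(pool) < n_each:
            warnings.warn(
                f"{biotype}/{direction}: only {len(pool)} candidates survive the gates "
                f"(requested {n_each})",
                RuntimeWarning,
            )
        out[f"{biotype}:{direction}"] = pool[:n_each]
    return out


def concordance_rate(
    candidates: Sequence[DERecord],
    qpcr: Iterable[QpcrOutcome],
) -> float:
    """Percentage of candidates whose qPCR call matches the microarray direction."""
    outcomes = {o.feature_id: o.qpcr_call for o in qpcr}
    if not candidates:
        raise ValueError("no candidates supplied")
    missing = [r.feature_id for r in candidates if r.feature_id not in outcomes]
    if missing:
        raise ValueError(f"missing qPCR outcome for: {missing}")
    confirmed = sum(1 for r in candidates if outcomes[r.feature_id] == r.direction)
    return 100.0 * confirmed / len(candidates)


def cluster_order(bundle: ExpressionBundle, features: Sequence[str]) -> list[str]:
    """Leaf order of an average-linkage dendrogram under 1 - Pearson distance.

    Constant features cannot be correlated; they are assigned the maximal
    distance (2.0) to every other feature, with a warning.
    """
    if len(features) < 2:
        raise ValueError("need >= 2 features to cluster")
    mat = bundle.values.loc[list(features)].to_numpy(dtype=float)
    n = mat.shape[0]
    sd = mat.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) assigned maximal distance",
            RuntimeWarning,
        )
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if constant[i] or constant[j]:
                d = 2.0
            else:
                r = float(np.corrcoef(mat[i], mat[j])[0, 1])
                d = 1.0 - r
            dist[i, j] = dist[j, i] = d
    linkage = average(squareform(dist, checks=False))
    order = leaves_list(linkage)
    return [features[i] for i in order]
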
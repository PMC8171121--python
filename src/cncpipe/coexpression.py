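"""Coding/non-coding co-expression network: thresholded Pearson edges
between selected lncRNAs and DE mRNAs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import ExpressionBundle

__all__ = [
    "CoexpressionEdge",
    "NetworkSummary",
    "pearson_r",
    "correlation_p",
    "build_cnc",
]


@dataclass(frozen=True)
class CoexpressionEdge:
    lncRNA_id: str
    mRNA_id: str
    r: float
    p_value: float
    sign: str  # 'positive' | 'negative'


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation, clamped to [-1, 1] against rounding."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def correlation_p(r: float, n: int) -> float:
    """Two-sided p for a Pearson coefficient via the t transform on n-2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def build_cnc(
    bundle: ExpressionBundle,
    lnc_ids: Sequence[str],
    mrna_ids: Sequence[str],
    r_min: float = 0.9,
    p_max: float = 0.005,
) -> tuple[list[CoexpressionEdge], NetworkSummary]:
    """All-pairs thresholded correlation between lncRNAs and mRNAs.

    An edge is kept when |r| >= r_min and p <= p_max.  Correlations run on
    the bundle's values across all samples pooled (log2 scale expected).
    """
    overlap = set(lnc_ids) & set(mrna_ids)
    if overlap:
        raise ValueError(f"ids present in both lists: {sorted(overlap)}")
    missing = [f for f in (*lnc_ids, *mrna_ids) if f not in bundle.values.index]
    if missing:
        raise ValueError(f"ids absent from bundle: {missing}")
    n = len(bundle.sample_ids)
    edges: list[CoexpressionEdge] = []
    lnc_mat = bundle.values.loc[list(lnc_ids)].to_numpy(dtype=float)
    mrna_mat = bundle.values.loc[list(mrna_ids)].to_numpy(dtype=float)
    for i, lnc in enumerate(lnc_ids):
        for j, mrna in enumerate(mrna_ids):
            x, y = lnc_mat[i], mrna_mat[j]
            if x.std() == 0 or y.std() == 0:
                continue  # correlation undefined; no edge
            r = pearson_r(x, y)
            if abs(r) < r_min:
                continue
            p = correlation_p(r, n)
            if p > p_max:
                continue
            edges.append(
                CoexpressionEdge(lnc, mrna, r, p, "positive" if r > 0 else "negative")
            )
    nodes = {e.lncRNA_id for e in edges} | {e.mRNA_id for e in edges}
    n_pos = sum(1 for e in edges if e.sign == "positive")
    summary = NetworkSummary(
        n_nodes=len(nodes),
        n_edges=len(edges),
        n_positive=n_pos,
        n_negative=len(edges) - n_pos,
    )
    return edges, summary
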
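"""Fisher-exact over-representation of a study gene list against gene sets."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .io_formats import GeneSet

__all__ = ["EnrichmentRecord", "fisher_enrich", "score_transform", "top_by_category"]

MAX_SCORE = 320.0  # cap for p == 0 after underflow


@dataclass(frozen=True)
class EnrichmentRecord:
    set_id: str
    category: str
    k: int  # study genes in the set
    K: int  # population genes in the set
    n: int  # study size
    N: int  # population size
    p_value: float
    score: float
    capped: bool = False


def score_transform(p: float) -> tuple[float, bool]:
    """-log10(p); p == 0 is capped at MAX_SCORE and flagged."""
    if p < 0 or p > 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p == 0.0:
        return MAX_SCORE, True
    return -math.log10(p), False


def fisher_enrich(
    study: Sequence[str],
    population: Sequence[str],
    sets: Sequence[GeneSet],
    p_max: float = 0.05,
) -> list[EnrichmentRecord]:
    """One-sided (over-representation) Fisher exact test per gene set.

    The 2x2 table is (k, n-k; K-k, N-n-K+k) after intersecting each set
    with the population.  Records come back sorted by p ascending with a
    deterministic set-id tie-break; ``p_max`` is recorded by callers, not
    applied here.
    """
    pop = set(population)
    if len(pop) != len(population):
        raise ValueError("population contains duplicates")
    stud = set(study)
    if len(stud) != len(study):
        raise ValueError("study list contains duplicates")
    offenders = sorted(stud - pop)
    if offenders:
        raise ValueError(f"study genes absent from population: {offenders}")
    if not stud:
        return []
    N, n = len(pop), len(stud)
    records: list[EnrichmentRecord] = []
    for gs in sets:
        members = gs.members & pop
        K = len(members)
        if K == 0:
            continue
        k = len(members & stud)
        # hypergeometric upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(1.0, max(0.0, p))
        score, capped = score_transform(p)
        records.append(EnrichmentRecord(gs.set_id, gs.category, k, K, n, N, p, score, capped))
    records.sort(key=lambda r: (r.p_value, r.set_id))
    return records


def top_by_category(records: Sequence[EnrichmentRecord], top: int = 10) -> dict[str, list[EnrichmentRecord]]:
    """Top ``top`` records per category (records assumed p-sorted)."""
    out: dict[str, list[EnrichmentRecord]] = {}
    for r in records:
        bucket = out.setdefault(r.category, [])
        if len(bucket) < top:
            bucket.append(r)
    return out
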
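"""Cis nearby-gene pairing of lncRNAs and mRNAs within a genomic window,
and intersection with the co-expression network."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from .coexpression import CoexpressionEdge
from .io_formats import FeatureAnnotation

__all__ = ["CisPair", "OverlapPair", "genomic_distance", "find_cis_pairs", "intersect_networks"]


@dataclass(frozen=True)
class CisPair:
    lncRNA_id: str
    mRNA_id: str
    distance: int
    relationship: str  # 'upstream' | 'downstream' | 'overlapping'
    lnc_regulation: str
    mrna_regulation: str


@dataclass(frozen=True)
class OverlapPair:
    lncRNA_id: str
    mRNA_id: str
    r: float
    distance: int


def genomic_distance(a: FeatureAnnotation, b: FeatureAnnotation) -> int | None:
    """Nearest-edge gap between two intervals; 0 if they overlap, None if
    the features sit on different chromosomes."""
    if a.chromosome != b.chromosome:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


def _relationship(lnc: FeatureAnnotation, mrna: FeatureAnnotation) -> str:
    """Position of the mRNA relative to the lncRNA on the lncRNA's strand."""
    if lnc.start < mrna.end and mrna.start < lnc.end:
        return "overlapping"
    mrna_is_right = mrna.start >= lnc.end
    if lnc.strand == "+":
        return "downstream" if mrna_is_right else "upstream"
    return "upstream" if mrna_is_right else "downstream"


def find_cis_pairs(
    lnc_annotations: Mapping[str, FeatureAnnotation],
    mrna_annotations: Mapping[str, FeatureAnnotation],
    regulation: Mapping[str, str],
    window: int = 200_000,
) -> list[CisPair]:
    """Pair every lncRNA with each mRNA within ``window`` bp (inclusive).

    ``regulation`` maps feature_id -> 'up'/'down'; features missing either
    annotation or regulation are skipped with a warning.
    """
    pairs: list[CisPair] = []
    skipped = 0
    for lnc_id, lnc in lnc_annotations.items():
        if lnc_id not in regulation:
            skipped += 1
            continue
        for mrna_id, mrna in mrna_annotations.items():
            if mrna_id not in regulation:
                skipped += 1
                continue
            d = genomic_distance(lnc, mrna)
            if d is None or d > window:
                continue
            pairs.append(
                CisPair(
                    lncRNA_id=lnc_id,
                    mRNA_id=mrna_id,
                    distance=d,
                    relationship=_relationship(lnc, mrna),
                    lnc_regulation=regulation[lnc_id],
                    mrna_regulation=regulation[mrna_id],
                )
            )
    if skipped:
        warnings.warn(f"{skipped} feature pairing(s) skipped for missing regulation labels",
                      RuntimeWarning)
    return pairs


def intersect_networks(
    cnc_edges: Iterable[CoexpressionEdge],
    cis_pairs: Iterable[CisPair],
) -> list[OverlapPair]:
    """Exact (lncRNA, mRNA) key intersection of the two edge collections,
    annotated with the correlation and the genomic distance."""
    by_key_r = {(e.lncRNA_id, e.mRNA_id): e.r for e in cnc_edges}
    out: list[OverlapPair] = []
    seen: set[tuple[str, str]] = set()
    for p in cis_pairs:
        key = (p.lncRNA_id, p.mRNA_id)
        if key in by_key_r and key not in seen:
            seen.add(key)
            out.append(OverlapPair(p.lncRNA_id, p.mRNA_id, by_key_r[key], p.distance))
    out.sort(key=lambda o: (o.lncRNA_id, o.mRNA_id))
    return out
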
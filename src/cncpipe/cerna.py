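"""ceRNA triad inference: canonical miRNA seed-site detection on transcript
sequences, shared-miRNA overlap, and expression-direction concordance.

Site taxonomy follows the canonical grading of seed complementarity.  With
the mature miRNA written 5'->3', the seed core is nucleotides 2-7; a site on
a transcript (also 5'->3') is the reverse complement of that core, with the
position pairing miRNA nt 8 immediately 5' of the core match and the
position opposite miRNA nt 1 immediately 3' of it:

    8mer     core + nt-8 match + A opposite nt 1
    7mer-m8  core + nt-8 match
    7mer-A1  core + A opposite nt 1
    6mer     core only
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GeneSet

__all__ = [
    "MiRNA",
    "SeedSite",
    "CeRNATriad",
    "find_seed_sites",
    "validate_site",
    "filter_mirnas_by_id",
    "build_cerna",
    "pathway_restrict",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


_MIR_NUM = re.compile(r"(?:^|-)miR-(\d+)", re.IGNORECASE)


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA; ``seed`` is nucleotides 2-8 of the 5'->3' sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize(self.sequence))
        if len(self.sequence) < 8:
            raise ValueError(f"{self.name}: mature sequence must be >= 8 nt")

    @property
    def seed(self) -> str:
        return self.sequence[1:8]  # nt 2-8

    @property
    def numeric_id(self) -> int | None:
        m = _MIR_NUM.search(self.name)
        return int(m.group(1)) if m else None


@dataclass(frozen=True)
class SeedSite:
    """A seed match; ``start`` is the 0-based 6mer-core start on the transcript."""

    transcript_id: str
    mirna: str
    start: int
    site_type: str  # '8mer' | '7mer-m8' | '7mer-A1' | '6mer'


def find_seed_sites(transcript_id: str, transcript: str, mirna: MiRNA) -> list[SeedSite]:
    """Scan a transcript for seed matches of one miRNA, maximally classified.

    Windows containing ambiguous bases are skipped.  Flank positions that
    fall off the transcript count as mismatches for their site-type upgrade.
    """
    seq = _normalize(transcript)
    if len(seq) < 6:
        raise ValueError(f"{transcript_id}: transcript shorter than 6 nt")
    core = reverse_complement(mirna.sequence[1:7])  # nt 2-7 complement, 6 nt
    m8 = reverse_complement(mirna.sequence[7])      # pairs immediately 5' of core
    sites: list[SeedSite] = []
    for i in range(len(seq) - 5):
        if seq[i : i + 6] != core:
            continue
        has_m8 = i >= 1 and seq[i - 1] == m8
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if has_m8 and has_a1:
            stype = "8mer"
        elif has_m8:
            stype = "7mer-m8"
        elif has_a1:
            stype = "7mer-A1"
        else:
            stype = "6mer"
        sites.append(SeedSite(transcript_id, mirna.name, i, stype))
    return sites


def validate_site(site: SeedSite, transcript: str, mirna: MiRNA) -> bool:
    """Re-derive the site from sequence alone; True iff type and span agree."""
    seq = _normalize(transcript)
    i = site.start
    core = reverse_complement(mirna.sequence[1:7])
    if seq[i : i + 6] != core:
        return False
    has_m8 = i >= 1 and seq[i - 1] == reverse_complement(mirna.sequence[7])
    has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
    expected = {
        (True, True): "8mer",
        (True, False): "7mer-m8",
        (False, True): "7mer-A1",
        (False, False): "6mer",
    }[(has_m8, has_a1)]
    return expected == site.site_type


def filter_mirnas_by_id(mirnas: Iterable[MiRNA], max_id: int = 1000) -> list[MiRNA]:
    """Keep miRNAs whose parsed miR number is strictly below ``max_id``.

    Names without a parsable miR number (let-family etc.) are retained with
    a warning.
    """
    kept: list[MiRNA] = []
    for m in mirnas:
        nid = m.numeric_id
        if nid is None:
            warnings.warn(f"{m.name}: no parsable miR number; retained", RuntimeWarning)
            kept.append(m)
        elif nid < max_id:
            kept.append(m)
    return kept


@dataclass(frozen=True)
class CeRNATriad:
    lncRNA_id: str
    mirna: str
    mRNA_id: str
    lnc_site_count: int
    mrna_site_count: int
    shared_direction: str  # 'up' | 'down' | 'discordant'

    def __post_init__(self) -> None:
        if self.lnc_site_count < 1 or self.mrna_site_count < 1:
            raise ValueError("triad requires >= 1 site on each transcript")


def build_cerna(
    lnc_sites: Iterable[SeedSite],
    mrna_sites: Iterable[SeedSite],
    directions: Mapping[str, str],
    require_same_direction: bool = True,
    min_shared_mirnas: int = 1,
) -> list[CeRNATriad]:
    """Enumerate (lncRNA, miRNA, mRNA) triads with sites on both transcripts.

    ``directions`` maps every transcript id to its DE direction.  With
    ``require_same_direction`` only direction-concordant triads are kept
    (the ceRNA reading of the construction); ``min_shared_mirnas`` further
    requires that the (lncRNA, mRNA) pair shares at least that many miRNAs.
    """
    lnc_counts: dict[tuple[str, str], int] = {}
    for s in lnc_sites:
        lnc_counts[(s.transcript_id, s.mirna)] = lnc_counts.get((s.transcript_id, s.mirna), 0) + 1
    mrna_counts: dict[tuple[str, str], int] = {}
    for s in mrna_sites:
        mrna_counts[(s.transcript_id, s.mirna)] = mrna_counts.get((s.transcript_id, s.mirna), 0) + 1
    for tid, _ in list(lnc_counts) + list(mrna_counts):
        if tid not in directions:
            raise ValueError(f"transcript {tid!r} absent from the DE direction table")
    triads: list[CeRNATriad] = []
    for (lnc, mir), n_lnc in sorted(lnc_counts.items()):
        for (mrna, mir2), n_mrna in sorted(mrna_counts.items()):
            if mir2 != mir:
                continue
            d_lnc, d_mrna = directions[lnc], directions[mrna]
            same = d_lnc == d_mrna
            if require_same_direction and not same:
                continue
            triads.append(
                CeRNATriad(
                    lncRNA_id=lnc,
                    mirna=mir,
                    mRNA_id=mrna,
                    lnc_site_count=n_lnc,
                    mrna_site_count=n_mrna,
                    shared_direction=d_lnc if same else "discordant",
                )
            )
    if min_shared_mirnas > 1:
        shared: dict[tuple[str, str], int] = {}
        for t in triads:
            shared[(t.lncRNA_id, t.mRNA_id)] = shared.get((t.lncRNA_id, t.mRNA_id), 0) + 1
        triads = [t for t in triads if shared[(t.lncRNA_id, t.mRNA_id)] >= min_shared_mirnas]
    return triads


def pathway_restrict(
    triads: Sequence[CeRNATriad],
    gene_sets: Sequence[GeneSet],
    allowed_set_ids: Sequence[str],
    symbols: Mapping[str, str] | None = None,
) -> list[CeRNATriad]:
    """Keep triads whose mRNA symbol belongs to >= 1 allowed gene set.

    ``symbols`` maps mRNA id -> gene symbol (identity when omitted).
    """
    by_id = {gs.set_id: gs for gs in gene_sets}
    unknown = [sid for sid in allowed_set_ids if sid not in by_id]
    if unknown:
        raise ValueError(f"unknown gene set id(s): {unknown}")
    allowed_members: set[str] = set()
    for sid in allowed_set_ids:
        allowed_members |= by_id[sid].members
    sym = symbols or {}
    return [t for t in triads if sym.get(t.mRNA_id, t.mRNA_id) in allowed_members]
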
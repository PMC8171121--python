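"""Readers, writers and validated domain containers for every external format.

All tabular formats are plain tab-delimited text.  The expression matrix
dialect pairs each sample's intensity column with a detection-flag column
(``<sample>`` / ``<sample>_flag`` by default).  Genomic coordinates are held
0-based half-open internally; 1-based readers convert at the boundary.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionBundle",
    "FeatureAnnotation",
    "GroupDesign",
    "GeneSet",
    "PPIEdgeTable",
    "SchemaError",
    "ParseError",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "read_fasta",
    "write_fasta",
    "read_ppi_table",
    "write_ppi_table",
    "write_edge_table",
]


class SchemaError(ValueError):
    """Structural violation: duplicate ids, bad shapes, invariant breaches."""


class ParseError(ValueError):
    """Cell-level violation: non-numeric intensity, unknown flag token, ..."""


VALID_FLAGS = ("P", "M", "A")

_FLAG_ALIASES = {
    "P": "P", "PRESENT": "P",
    "M": "M", "MARGINAL": "M",
    "A": "A", "ABSENT": "A",
}


def normalize_flag(token: str) -> str:
    """Map vendor flag spellings onto the canonical {P, M, A} alphabet."""
    canon = _FLAG_ALIASES.get(str(token).strip().upper())
    if canon is None:
        raise ParseError(f"unknown detection flag token {token!r}")
    return canon


@dataclass
class ExpressionBundle:
    """Feature x sample intensity matrix with per-cell detection flags.

    ``values`` and ``flags`` are pandas DataFrames sharing index
    (feature ids) and columns (sample ids).  ``scale`` is ``'linear'`` or
    ``'log2'``; linear intensities must be non-negative.
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def validate(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise SchemaError(f"unknown scale {self.scale!r}")
        if self.values.shape != self.flags.shape:
            raise SchemaError(
                f"values shape {self.values.shape} != flags shape {self.flags.shape}"
            )
        if not self.values.index.equals(self.flags.index) or not self.values.columns.equals(
            self.flags.columns
        ):
            raise SchemaError("values and flags must share feature and sample ids")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            raise SchemaError("missing intensity cells are not allowed")
        if self.scale == "linear" and (arr < 0).any():
            raise SchemaError("linear-scale intensities must be non-negative")
        bad = ~self.flags.isin(VALID_FLAGS)
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise SchemaError(
                f"invalid flag {self.flags.iat[r, c]!r} at feature "
                f"{self.flags.index[r]!r}, sample {self.flags.columns[c]!r}"
            )

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionBundle":
        return ExpressionBundle(
            values=self.values.loc[list(feature_ids)].copy(),
            flags=self.flags.loc[list(feature_ids)].copy(),
            scale=self.scale,
        )

    def copy(self) -> "ExpressionBundle":
        return ExpressionBundle(self.values.copy(), self.flags.copy(), self.scale)


@dataclass(frozen=True)
class FeatureAnnotation:
    """Genomic annotation of one array feature (0-based half-open interval)."""

    feature_id: str
    gene_symbol: str
    biotype: str  # 'lncRNA' | 'mRNA'
    chromosome: str
    strand: str  # '+' | '-'
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.biotype not in ("lncRNA", "mRNA"):
            raise SchemaError(f"{self.feature_id}: biotype must be lncRNA or mRNA")
        if self.strand not in ("+", "-"):
            raise SchemaError(f"{self.feature_id}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise SchemaError(
                f"{self.feature_id}: malformed interval [{self.start}, {self.end})"
            )


@dataclass
class GroupDesign:
    """sample_id -> group mapping; exactly two groups, each with >= 2 samples."""

    groups: dict[str, str]
    case_label: str = "case"
    control_label: str = "control"

    def __post_init__(self) -> None:
        labels = set(self.groups.values())
        if labels != {self.case_label, self.control_label}:
            raise SchemaError(
                f"design must contain exactly groups "
                f"{{{self.case_label}, {self.control_label}}}, got {sorted(labels)}"
            )
        for lab in (self.case_label, self.control_label):
            n = sum(1 for g in self.groups.values() if g == lab)
            if n < 2:
                raise SchemaError(f"group {lab!r} has {n} samples; need >= 2")

    def samples(self, label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == label]

    @property
    def case_samples(self) -> list[str]:
        return self.samples(self.case_label)

    @property
    def control_samples(self) -> list[str]:
        return self.samples(self.control_label)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    category: str  # 'BP' | 'CC' | 'MF' | 'pathway'
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise SchemaError(f"gene set {self.set_id!r} has no members")


@dataclass
class PPIEdgeTable:
    """Symmetric protein-protein edges with combined confidence in [0, 1]."""

    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for a, b, s in self.edges:
            if a == b:
                continue  # self-loops dropped at load
            s = float(s)
            if not 0.0 <= s <= 1.0:
                raise SchemaError(f"edge ({a}, {b}) score {s} outside [0, 1]")
            cleaned.append((str(a), str(b), s))
        self.edges = cleaned


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression(
    path: str | os.PathLike,
    flag_suffix: str = "_flag",
    scale: str = "linear",
) -> ExpressionBundle:
    """Read a tab-delimited feature-by-sample matrix with paired flag columns.

    The header row is ``feature_id`` followed by, for every sample ``S``, the
    pair of columns ``S`` and ``S<flag_suffix>``.  Feature order is preserved.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if not header or header[0] != "feature_id":
            raise ParseError(f"{path}: first header column must be 'feature_id'")
        sample_ids = [c for c in header[1:] if not c.endswith(flag_suffix)]
        expected = ["feature_id"]
        for s in sample_ids:
            expected.extend([s, s + flag_suffix])
        if header != expected:
            raise ParseError(
                f"{path}: header must interleave value and flag columns per sample"
            )
        feat_ids: list[str] = []
        values: list[list[float]] = []
        flags: list[list[str]] = []
        seen: set[str] = set()
        for row_no, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ParseError(f"{path}: row {row_no} has {len(row)} fields, expected {len(header)}")
            fid = row[0]
            if fid in seen:
                raise SchemaError(f"{path}: duplicate feature id {fid!r} at row {row_no}")
            seen.add(fid)
            vrow, frow = [], []
            for j, s in enumerate(sample_ids):
                vtok = row[1 + 2 * j]
                ftok = row[2 + 2 * j]
                try:
                    vrow.append(float(vtok))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric intensity {vtok!r} at row {row_no}, sample {s!r}"
                    ) from None
                try:
                    frow.append(normalize_flag(ftok))
                except ParseError:
                    raise ParseError(
                        f"{path}: unknown flag token {ftok!r} at row {row_no}, sample {s!r}"
                    ) from None
            feat_ids.append(fid)
            values.append(vrow)
            flags.append(frow)
    vdf = pd.DataFrame(values, index=feat_ids, columns=sample_ids, dtype=float)
    fdf = pd.DataFrame(flags, index=feat_ids, columns=sample_ids)
    return ExpressionBundle(vdf, fdf, scale=scale)


def write_expression(
    bundle: ExpressionBundle,
    path: str | os.PathLike,
    flag_suffix: str = "_flag",
) -> None:
    """Inverse of :func:`read_expression`; full-precision round trip."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["feature_id"]
        for s in bundle.sample_ids:
            header.extend([s, s + flag_suffix])
        w.writerow(header)
        for fid in bundle.feature_ids:
            row: list[str] = [fid]
            for s in bundle.sample_ids:
                row.append(repr(float(bundle.values.at[fid, s])))
                row.append(bundle.flags.at[fid, s])
            w.writerow(row)


# ---------------------------------------------------------------------------
# feature annotation
# ---------------------------------------------------------------------------

_ANNOT_COLS = ["feature_id", "gene_symbol", "biotype", "chromosome", "strand", "start", "end"]


def read_annotation(path: str | os.PathLike, one_based: bool = False) -> dict[str, FeatureAnnotation]:
    """Read the feature annotation table; ``one_based`` converts closed
    1-based starts to the internal 0-based half-open convention."""
    out: dict[str, FeatureAnnotation] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _ANNOT_COLS:
            raise ParseError(f"{path}: annotation header must be {_ANNOT_COLS}")
        for row_no, row in enumerate(reader, start=2):
            if len(row) != len(_ANNOT_COLS):
                raise ParseError(f"{path}: row {row_no} has {len(row)} fields")
            fid, sym, biotype, chrom, strand, start, end = row
            if fid in out:
                raise SchemaError(f"{path}: duplicate feature id {fid!r}")
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}: non-integer coordinate at row {row_no}") from None
            if one_based:
                s -= 1
            out[fid] = FeatureAnnotation(fid, sym, biotype, chrom, strand, s, e)
    return out


def write_annotation(annotations: Mapping[str, FeatureAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_ANNOT_COLS)
        for fid in annotations:
            a = annotations[fid]
            w.writerow([a.feature_id, a.gene_symbol, a.biotype, a.chromosome, a.strand, a.start, a.end])


# ---------------------------------------------------------------------------
# group design
# ---------------------------------------------------------------------------

def read_design(path: str | os.PathLike) -> GroupDesign:
    """Two-column TSV (sample_id, group) with a header row."""
    groups: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["sample_id", "group"]:
            raise ParseError(f"{path}: design header must be ['sample_id', 'group']")
        for row_no, row in enumerate(reader, start=2):
            if len(row) != 2:
                raise ParseError(f"{path}: row {row_no} has {len(row)} fields")
            sid, grp = row
            if sid in groups:
                raise SchemaError(f"{path}: duplicate sample id {sid!r}")
            groups[sid] = grp
    return GroupDesign(groups)


def write_design(design: GroupDesign, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "group"])
        for sid, grp in design.groups.items():
            w.writerow([sid, grp])


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | os.PathLike, category: str = "pathway") -> list[GeneSet]:
    """Standard GMT: set_id <tab> description <tab> member... per line.

    The description field may carry the category as ``category:name``;
    otherwise ``category`` applies to every set in the file.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {line_no} has {len(fields)} fields; GMT needs >= 3"
                )
            set_id, desc = fields[0], fields[1]
            if set_id in seen:
                raise SchemaError(f"{path}: duplicate gene set id {set_id!r}")
            seen.add(set_id)
            members = [m for m in fields[2:] if m]
            if not members:
                raise ParseError(f"{path}: line {line_no} ({set_id}) has no members")
            cat, name = category, desc
            if ":" in desc:
                prefix, rest = desc.split(":", 1)
                if prefix in ("BP", "CC", "MF", "pathway"):
                    cat, name = prefix, rest
            sets.append(GeneSet(set_id, name, cat, frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.set_id}\t{gs.category}:{gs.name}\t{members}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_NT_OK = set("ACGTN")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read nucleotide FASTA; ids are the first whitespace token, U -> T."""
    out: dict[str, str] = {}
    cur_id: str | None = None
    chunks: list[str] = []

    def _commit() -> None:
        if cur_id is None:
            return
        seq = "".join(chunks).upper().replace("U", "T")
        bad = set(seq) - _NT_OK
        if bad:
            raise ParseError(f"{path}: illegal character(s) {sorted(bad)} in record {cur_id!r}")
        out[cur_id] = seq

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _commit()
                cur_id = line[1:].split()[0] if len(line) > 1 else ""
                if not cur_id:
                    raise ParseError(f"{path}: empty FASTA header")
                if cur_id in out:
                    raise SchemaError(f"{path}: duplicate sequence id {cur_id!r}")
                chunks = []
            else:
                if cur_id is None:
                    raise ParseError(f"{path}: sequence data before first header")
                chunks.append(line)
        _commit()
    return out


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PPI edge table
# ---------------------------------------------------------------------------

def read_ppi_table(path: str | os.PathLike) -> PPIEdgeTable:
    """Three-column TSV (protein_a, protein_b, combined_score) with header."""
    edges: list[tuple[str, str, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["protein_a", "protein_b", "combined_score"]:
            raise ParseError(f"{path}: PPI header must be protein_a/protein_b/combined_score")
        for row_no, row in enumerate(reader, start=2):
            if len(row) != 3:
                raise ParseError(f"{path}: row {row_no} has {len(row)} fields")
            a, b, s = row
            try:
                score = float(s)
            except ValueError:
                raise ParseError(f"{path}: non-numeric score {s!r} at row {row_no}") from None
            edges.append((a, b, score))
    return PPIEdgeTable(edges)


def write_ppi_table(table: PPIEdgeTable, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_a", "protein_b", "combined_score"])
        for a, b, s in table.edges:
            w.writerow([a, b, repr(s)])


# ---------------------------------------------------------------------------
# generic edge output
# ---------------------------------------------------------------------------

def write_edge_table(
    edges: Iterable[tuple],
    path: str | os.PathLike,
    dialect: str = "tsv",
    columns: Sequence[str] = ("source", "target"),
    interaction: str = "interacts",
) -> None:
    """Write edges deterministically sorted by (source, target).

    ``tsv`` writes a header (``columns``) and one row per edge tuple;
    ``sif`` writes ``source <interaction> target`` using the first two
    tuple fields.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = sorted(edges, key=lambda e: (str(e[0]), str(e[1])))
    with open(path, "w", newline="") as fh:
        if dialect == "tsv":
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(list(columns))
            for row in rows:
                w.writerow([_fmt(x) for x in row])
        else:
            for row in rows:
                fh.write(f"{row[0]}\t{interaction}\t{row[1]}\n")


def _fmt(x) -> str:
    if isinstance(x, float):
        return repr(x)
    return str(x)
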
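"""Readers and writers for the genomic file formats used across the package.

All coordinates are held internally as 0-based half-open intervals; conversion
to/from 1-based inclusive conventions (GFF, RepeatMasker ``.out``) happens only
at the file boundary.  Formats covered: BED(3-6), a 9-column GFF subset,
minimap2 PAF, RepeatMasker ``.out``, MACS2 narrowPeak, and generic TSV tables
for any of the package's record dataclasses.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

VALID_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """Raised for malformed input lines; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A located, stranded span on a named sequence (0-based, half-open)."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def oriented_strand(self) -> str:
        """Strand for operations that require an orientation.

        Unstranded intervals are treated as '+' with a warning rather than
        being dropped.
        """
        if self.strand == ".":
            warnings.warn(
                f"unstranded interval {self.seq_id}:{self.start}-{self.end} "
                "treated as '+'",
                stacklevel=2,
            )
            return "+"
        return self.strand


@dataclass(frozen=True)
class RepeatCopy:
    """One transposable-element annotation with its divergence to consensus."""

    interval: GenomicInterval
    family: str
    te_class: str  # LTR, LINE, SINE, DNA, other
    pct_divergence: float

    def __post_init__(self):
        if not self.family:
            raise ValueError("RepeatCopy.family must be nonempty")
        if not (0.0 <= self.pct_divergence <= 100.0):
            raise ValueError(
                f"pct_divergence {self.pct_divergence} outside [0, 100]"
            )


@dataclass(frozen=True)
class PafRecord:
    """One PAF alignment line (columns 1-12; SAM-style tags are ignored)."""

    query: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target: str
    target_len: int
    target_start: int
    target_end: int
    n_match: int
    aln_len: int

    def __post_init__(self):
        if not (self.query_start < self.query_end <= self.query_len):
            raise ValueError(
                f"PAF {self.query}: require query_start < query_end <= query_len"
            )
        if not (self.target_start < self.target_end):
            raise ValueError(f"PAF {self.query}: target_start >= target_end")
        if self.n_match > self.aln_len:
            raise ValueError(f"PAF {self.query}: n_match > aln_len")


@dataclass(frozen=True)
class Peak:
    """A called peak; q_value is stored on the plain (not -log10) scale."""

    interval: GenomicInterval
    summit: int  # offset from interval.start
    q_value: float
    fold_enrichment: float

    def __post_init__(self):
        if not (0 <= self.summit <= len(self.interval)):
            raise ValueError("summit offset outside peak")
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")


@dataclass(frozen=True)
class UnitsRow:
    """One row of a species x KZFP-unit census table."""

    species: str
    unit_id: str
    copy_count: int

    def __post_init__(self):
        if self.copy_count < 1:
            raise ValueError("copy_count must be >= 1")


# ---------------------------------------------------------------------------
# interval formats


def read_intervals(path, fmt: str = "bed"):
    """Read BED or GFF-lite intervals.

    Returns ``(intervals, attributes)`` where ``attributes`` is a list of dicts
    (BED: name/score when present; GFF: parsed column-9 key=value pairs).
    GFF coordinates (1-based inclusive) are converted to 0-based half-open.
    Input order is preserved.
    """
    if fmt not in {"bed", "gff_lite"}:
        raise ValueError(f"unknown interval format {fmt!r}")
    intervals: list[GenomicInterval] = []
    attrs: list[dict] = []
    for lineno, raw in enumerate(_lines(path), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        try:
            if fmt == "bed":
                if len(cols) < 3:
                    raise ValueError("BED requires >= 3 tab-separated columns")
                seq_id, start, end = cols[0], int(cols[1]), int(cols[2])
                strand = cols[5] if len(cols) >= 6 else "."
                iv = GenomicInterval(seq_id, start, end, strand)
                a = {}
                if len(cols) >= 4:
                    a["name"] = cols[3]
                if len(cols) >= 5:
                    a["score"] = cols[4]
            else:  # gff_lite
                if len(cols) != 9:
                    raise ValueError("GFF-lite requires exactly 9 columns")
                seq_id = cols[0]
                start1, end1 = int(cols[3]), int(cols[4])
                strand = cols[6] if cols[6] in VALID_STRANDS else "."
                iv = GenomicInterval(seq_id, start1 - 1, end1, strand)
                a = _parse_gff_attrs(cols[8])
                a.setdefault("feature", cols[2])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        intervals.append(iv)
        attrs.append(a)
    return intervals, attrs


def interval_to_bed_line(iv: GenomicInterval, name: str = ".", score="0") -> str:
    return f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}"


def interval_to_gff_coords(iv: GenomicInterval) -> tuple[int, int]:
    """Back-convert internal coordinates to 1-based inclusive (GFF)."""
    return iv.start + 1, iv.end


def write_bed(intervals: Sequence[GenomicInterval], path, names=None) -> None:
    names = names or ["."] * len(intervals)
    with open(path, "w") as fh:
        for iv, name in zip(intervals, names):
            fh.write(interval_to_bed_line(iv, name) + "\n")


def _parse_gff_attrs(text: str) -> dict:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _lines(path) -> Iterable[str]:
    with open(path) as fh:
        yield from fh


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_CLASSES = {"LTR", "LINE", "SINE", "DNA"}


def read_repeatmasker_out(path) -> list[RepeatCopy]:
    """Parse a RepeatMasker ``.out`` table (3 header lines, whitespace-split).

    Column 2 is the percent divergence to consensus, column 9 the orientation
    ('+' or 'C' for the minus strand), column 10 the repeat (family) name and
    column 11 the 'class/family' string from which the class is taken.
    """
    copies: list[RepeatCopy] = []
    with open(path) as fh:
        rows = fh.readlines()
    for lineno, raw in enumerate(rows, start=1):
        if lineno <= 3 or not raw.strip():
            continue
        cols = raw.split()
        try:
            if len(cols) < 11:
                raise ValueError("expected >= 11 whitespace-separated fields")
            div = float(cols[1])
            seq_id = cols[4]
            start = int(cols[5]) - 1  # 1-based inclusive -> 0-based half-open
            end = int(cols[6])
            strand = "-" if cols[8] == "C" else "+"
            family = cols[9]
            te_class = cols[10].split("/")[0]
            if te_class not in _RM_CLASSES:
                te_class = "other"
            copies.append(
                RepeatCopy(
                    GenomicInterval(seq_id, start, end, strand),
                    family=family,
                    te_class=te_class,
                    pct_divergence=div,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: row {lineno}: {exc}") from exc
    return copies


RM_HEADER = (
    "   SW   perc perc perc  query     position in query         matching"
    "       repeat            position in repeat\n"
    "score   div. del. ins.  sequence  begin  end      (left)    repeat"
    "         class/family      begin  end    (left)  ID\n"
    "\n"
)


def write_repeatmasker_out(copies: Sequence[RepeatCopy], path,
                           seq_len: int | None = None) -> None:
    """Write RepeatCopy records in RepeatMasker ``.out`` layout."""
    with open(path, "w") as fh:
        fh.write(RM_HEADER)
        for i, rc in enumerate(copies, start=1):
            iv = rc.interval
            left = (seq_len - iv.end) if seq_len is not None else 0
            strand = "C" if iv.strand == "-" else "+"
            fh.write(
                f"1000 {rc.pct_divergence:.1f} 0.0 0.0 {iv.seq_id} "
                f"{iv.start + 1} {iv.end} ({left}) {strand} {rc.family} "
                f"{rc.te_class}/{rc.family} 1 {len(iv)} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# PAF


def read_paf(path) -> list[PafRecord]:
    """Read mandatory PAF columns 1-12; optional tag columns are ignored."""
    records: list[PafRecord] = []
    for lineno, raw in enumerate(_lines(path), start=1):
        if not raw.strip():
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 12:
            raise FormatError(
                f"{path}: line {lineno}: PAF requires >= 12 columns, got {len(cols)}"
            )
        try:
            records.append(
                PafRecord(
                    query=cols[0],
                    query_len=int(cols[1]),
                    query_start=int(cols[2]),
                    query_end=int(cols[3]),
                    strand=cols[4],
                    target=cols[5],
                    target_len=int(cols[6]),
                    target_start=int(cols[7]),
                    target_end=int(cols[8]),
                    n_match=int(cols[9]),
                    aln_len=int(cols[10]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# narrowPeak


def read_narrowpeak(path, q_dialect: str = "neglog10") -> list[Peak]:
    """Read a MACS2 narrowPeak file.

    ``q_dialect`` controls how column 9 is interpreted: MACS2 writes -log10(q)
    ('neglog10', the default); 'plain' takes the column at face value.  The
    returned Peak always carries a plain q-value.
    """
    if q_dialect not in {"neglog10", "plain"}:
        raise ValueError(f"unknown q_dialect {q_dialect!r}")
    peaks: list[Peak] = []
    for lineno, raw in enumerate(_lines(path), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 10:
            raise FormatError(
                f"{path}: line {lineno}: narrowPeak requires 10 columns"
            )
        try:
            iv = GenomicInterval(
                cols[0], int(cols[1]), int(cols[2]),
                cols[5] if cols[5] in VALID_STRANDS else ".",
            )
            qcol = float(cols[8])
            q = 10.0 ** (-qcol) if q_dialect == "neglog10" else qcol
            peaks.append(
                Peak(iv, summit=int(cols[9]), q_value=q,
                     fold_enrichment=float(cols[6]))
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return peaks


# ---------------------------------------------------------------------------
# units table


def read_units_table(path) -> list[UnitsRow]:
    """Read a TSV of (species, unit_id, copy_count) with a header line."""
    df = pd.read_csv(path, sep="\t")
    required = {"species", "unit_id", "copy_count"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: units table needs columns {sorted(required)}")
    rows = [
        UnitsRow(str(r.species), str(r.unit_id), int(r.copy_count))
        for r in df.itertuples()
    ]
    seen = set()
    for r in rows:
        key = (r.species, r.unit_id)
        if key in seen:
            raise FormatError(f"{path}: duplicate (species, unit_id) {key}")
        seen.add(key)
    return rows


# ---------------------------------------------------------------------------
# generic TSV round trip for record dataclasses

_FLAT_TYPES = (str, int, float, bool)


def _flatten(record, prefix="") -> dict:
    out = {}
    for f in fields(record):
        v = getattr(record, f.name)
        if dataclasses.is_dataclass(v):
            out.update(_flatten(v, prefix=f"{prefix}{f.name}."))
        else:
            out[f"{prefix}{f.name}"] = v
    return out


def write_table(records: Sequence, path) -> None:
    """Write homogeneous record dataclasses as a TSV with a header.

    Nested dataclass fields are flattened with dotted column names so that
    ``read_table`` can rebuild identical records.  An empty list writes a
    header-only file only when given a record type via ``read_table`` --
    here it writes an empty file with no rows (schema unknown), so callers
    with possibly-empty data should pass the type to :func:`write_empty_table`.
    """
    records = list(records)
    if records:
        t0 = type(records[0])
        if any(type(r) is not t0 for r in records):
            raise ValueError("write_table requires records of a single type")
        df = pd.DataFrame([_flatten(r) for r in records])
    else:
        df = pd.DataFrame()
    df.to_csv(path, sep="\t", index=False)


def write_empty_table(record_type, path) -> None:
    cols = list(_header_for(record_type))
    pd.DataFrame(columns=cols).to_csv(path, sep="\t", index=False)


def _header_for(record_type, prefix=""):
    for f in fields(record_type):
        if dataclasses.is_dataclass(f.type) or f.type in (
            "GenomicInterval",
            GenomicInterval,
        ):
            yield from _header_for(GenomicInterval, prefix=f"{prefix}{f.name}.")
        else:
            yield f"{prefix}{f.name}"


def read_table(path, record_type) -> list:
    """Read back a TSV written by :func:`write_table` into record dataclasses."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(_build(record_type, row, prefix=""))
    return out


def _build(record_type, row, prefix):
    kwargs = {}
    for f in fields(record_type):
        col = f"{prefix}{f.name}"
        if any(c.startswith(col + ".") for c in row.index):
            kwargs[f.name] = _build(GenomicInterval, row, prefix=col + ".")
        else:
            caster = {"int": int, "float": float, "str": str, "bool": bool}.get(
                f.type if isinstance(f.type, str) else f.type.__name__, lambda x: x
            )
            kwargs[f.name] = caster(row[col])
    return record_type(**kwargs)
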
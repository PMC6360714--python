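"""Interval overlap between candidate regions and QTL/gene annotation.

Annotation comes in as BED (0-based half-open) or as a minimal QTL TSV
dialect (1-based inclusive, header ``qtl_id  chrom  start  end  trait
source``).  Everything is normalized to 0-based half-open internally; point
records (start == end on 1-based input) become length-1 intervals.
Intersection is a per-chromosome sweep line; chromosome names are matched
exactly after normalization through a configurable alias map (by default
``chr``/``ECA`` prefixes are stripped, so "1", "chr1" and "ECA1" agree).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Optional, Sequence, Union

from .sweepcall import CandidateRegion

__all__ = [
    "QtlRecord",
    "OverlapHit",
    "read_annotation",
    "intersect",
    "normalize_chrom",
    "overlap_report_tsv",
]


@dataclass(frozen=True)
class QtlRecord:
    """A named trait interval, stored 0-based half-open."""

    qtl_id: str
    chrom: str
    start: int
    end: int
    trait: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start after normalization")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OverlapHit:
    region: CandidateRegion
    annotation: QtlRecord
    overlap_bp: int


def normalize_chrom(name: str, aliases: Optional[dict[str, str]] = None) -> str:
    """Canonical chromosome key: alias map first, then chr/ECA prefix strip."""
    if aliases and name in aliases:
        return aliases[name]
    low = name.lower()
    for prefix in ("chr", "eca"):
        if low.startswith(prefix) and len(name) > len(prefix):
            return name[len(prefix):]
    return name


def _iter_lines(source: Union[str, IO[str], Iterable[str]]):
    if isinstance(source, str):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def read_annotation(
    source: Union[str, IO[str], Iterable[str]], dialect: str = "bed"
) -> list[QtlRecord]:
    """Read annotation intervals; invalid records are rejected with a warning.

    ``bed``: chrom, start, end[, name[, score[, ...]]] — 0-based half-open.
    ``qtl_tsv``: tab-separated with header ``qtl_id chrom start end trait
    source`` — 1-based inclusive; a point (start == end) becomes a length-1
    interval.
    """
    if dialect not in ("bed", "qtl_tsv"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    records: list[QtlRecord] = []
    header_seen = False
    for line_no, line in enumerate(_iter_lines(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("track"):
            continue
        fields = line.split("\t")
        if dialect == "qtl_tsv" and not header_seen:
            header_seen = True
            if fields[0].lower() in ("qtl_id", "qtlid", "id"):
                continue  # header row
        try:
            if dialect == "bed":
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"bed_{line_no}"
                rec = QtlRecord(qtl_id=name, chrom=chrom, start=start, end=end)
            else:
                qtl_id, chrom = fields[0], fields[1]
                start1, end1 = int(fields[2]), int(fields[3])
                trait = fields[4] if len(fields) > 4 else ""
                source_ = fields[5] if len(fields) > 5 else ""
                # 1-based inclusive -> 0-based half-open; a point
                # (start == end) naturally becomes a length-1 interval
                start0, end0 = start1 - 1, end1
                rec = QtlRecord(
                    qtl_id=qtl_id, chrom=chrom, start=start0, end=end0,
                    trait=trait, source=source_,
                )
        except (ValueError, IndexError) as exc:
            warnings.warn(f"annotation line {line_no} rejected: {exc}")
            continue
        records.append(rec)
    return records


def intersect(
    regions: Sequence[CandidateRegion],
    annotations: Sequence[QtlRecord],
    aliases: Optional[dict[str, str]] = None,
    min_overlap_bp: int = 1,
) -> list[OverlapHit]:
    """All (region, annotation) pairs overlapping by >= ``min_overlap_bp``.

    Sweep line over each chromosome's two sorted interval lists; output is
    sorted by (chrom, region start, annotation start).
    """
    by_chrom_r: dict[str, list[CandidateRegion]] = {}
    for r in regions:
        by_chrom_r.setdefault(normalize_chrom(r.chrom, aliases), []).append(r)
    by_chrom_a: dict[str, list[QtlRecord]] = {}
    for a in annotations:
        by_chrom_a.setdefault(normalize_chrom(a.chrom, aliases), []).append(a)
    hits: list[OverlapHit] = []
    for chrom in sorted(set(by_chrom_r) & set(by_chrom_a)):
        rs = sorted(by_chrom_r[chrom], key=lambda r: (r.start, r.end))
        qs = sorted(by_chrom_a[chrom], key=lambda a: (a.start, a.end))
        start_j = 0
        for r in rs:
            # advance past annotations that end before any later region starts
            while start_j < len(qs) and qs[start_j].end <= r.start:
                start_j += 1
            j = start_j
            while j < len(qs) and qs[j].start < r.end:
                ov = min(r.end, qs[j].end) - max(r.start, qs[j].start)
                if ov >= min_overlap_bp:
                    hits.append(OverlapHit(region=r, annotation=qs[j], overlap_bp=ov))
                j += 1
    return hits


def overlap_report_tsv(hits: Sequence[OverlapHit], header: Optional[str] = None) -> str:
    """TSV report: QTL identity/trait columns plus the overlapping region.

    QTL and region coordinates are printed 1-based inclusive (report
    convention); the BED outputs elsewhere stay 0-based.
    """
    lines = []
    if header:
        lines.append(f"# {header}")
    lines.append(
        "qtl_id\tchrom\tqtl_start_1based\tqtl_end_1based\ttrait\tsource"
        "\tregion_start_1based\tregion_end_1based\toverlap_bp"
    )
    for h in hits:
        a, r = h.annotation, h.region
        lines.append(
            f"{a.qtl_id}\t{a.chrom}\t{a.start + 1}\t{a.end}\t{a.trait}\t{a.source}"
            f"\t{r.start + 1}\t{r.end}\t{h.overlap_bp}"
        )
    return "\n".join(lines) + "\n"
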
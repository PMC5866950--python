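"""SAM parsing and CIGAR-aware, base-quality-filtered allele counting.

Reads are aligned (upstream, e.g. with bwa) against capture-probe or
reference-contig sequences and handed to this package as plain-text SAM.
The parser here is deliberately tolerant: malformed records are rejected
with a warning naming the line, while the rest of the file still loads —
a pileup over thousands of probe references should not be lost to one
bad record.  Records referencing a contig with no ``@SQ`` header line
are a hard error, since their coordinates cannot be trusted.

All coordinates are 0-based half-open internally; SAM's 1-based ``POS``
is converted at the parser boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")
_ALIGN_OPS = frozenset("M=X")
COUNTED_BASES = ("A", "C", "G", "T")

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


class SamFormatError(ValueError):
    """Raised for SAM problems that cannot be skipped safely."""


def parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    if cigar == "*":
        return ()
    ops = tuple((m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar))
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR string {cigar!r}")
    return ops


@dataclass(frozen=True)
class AlignedRead:
    """One mapped, primary SAM record."""

    read_id: str
    reference_id: str
    reference_start: int  # 0-based leftmost reference coordinate
    cigar: tuple[tuple[str, int], ...]
    bases: str
    base_qualities: tuple[int, ...]
    mapping_quality: int = 255
    flag: int = 0

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _QUERY_OPS)

    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the reference span."""
        return self.reference_start + sum(n for op, n in self.cigar if op in _REF_OPS)

    def base_at(self, position: int) -> tuple[str, int] | None:
        """Query base and quality aligned to reference ``position``.

        Walks the CIGAR; returns None when the read does not align a
        query base there (outside the span, or a deletion/skip/clip).
        Only M/=/X columns place a query base on the reference.
        """
        ref = self.reference_start
        query = 0
        for op, n in self.cigar:
            consumes_ref = op in _REF_OPS
            consumes_query = op in _QUERY_OPS
            if consumes_ref and ref <= position < ref + n:
                if op in _ALIGN_OPS:
                    qi = query + (position - ref)
                    return self.bases[qi], self.base_qualities[qi]
                return None  # deletion or reference skip covers it
            if consumes_ref:
                ref += n
            if consumes_query:
                query += n
        return None


@dataclass(frozen=True)
class AlleleCounts:
    """Base-quality-filtered read counts at one reference position."""

    reference_id: str
    position: int  # 0-based
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative allele count")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def get(self, base: str) -> int:
        return self.counts.get(base, 0)


def read_sam(path: str | Path) -> dict[str, list[AlignedRead]]:
    """Parse a SAM file into mapped primary reads grouped by reference.

    Unmapped, secondary and supplementary records are dropped silently
    (they are legal SAM); records that are internally inconsistent —
    too few fields, unparseable CIGAR, CIGAR query length disagreeing
    with SEQ, QUAL length disagreeing with SEQ — are rejected with a
    warning that names the line number.  A mapped record whose RNAME has
    no ``@SQ`` header entry raises :class:`SamFormatError`.
    """
    path = Path(path)
    declared: set[str] = set()
    grouped: dict[str, list[AlignedRead]] = {}
    n_kept = n_skipped = 0
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    for tag in line.split("\t")[1:]:
                        if tag.startswith("SN:"):
                            declared.add(tag[3:])
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                log.warning("%s line %d: %d fields (need 11), record skipped",
                            path, line_no, len(fields))
                n_skipped += 1
                continue
            qname, flag_s, rname, pos_s, mapq_s, cigar_s = fields[0:6]
            seq, qual = fields[9], fields[10]
            try:
                flag = int(flag_s)
                pos = int(pos_s)
                mapq = int(mapq_s)
            except ValueError:
                log.warning("%s line %d: non-integer FLAG/POS/MAPQ, record skipped",
                            path, line_no)
                n_skipped += 1
                continue
            if flag & FLAG_UNMAPPED or rname == "*":
                continue
            if flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
                continue
            if rname not in declared:
                raise SamFormatError(
                    f"{path} line {line_no}: reference {rname!r} has no @SQ header line"
                )
            try:
                cigar = parse_cigar(cigar_s)
            except ValueError as exc:
                log.warning("%s line %d: %s, record skipped", path, line_no, exc)
                n_skipped += 1
                continue
            if seq == "*":
                log.warning("%s line %d: mapped record without SEQ, skipped",
                            path, line_no)
                n_skipped += 1
                continue
            if qual == "*":
                qualities = tuple([255] * len(seq))
            else:
                qualities = tuple(ord(c) - 33 for c in qual)
            read = AlignedRead(
                read_id=qname,
                reference_id=rname,
                reference_start=pos - 1,
                cigar=cigar,
                bases=seq.upper(),
                base_qualities=qualities,
                mapping_quality=mapq,
                flag=flag,
            )
            if cigar and read.query_length != len(seq):
                log.warning(
                    "%s line %d: CIGAR query length %d != SEQ length %d, record skipped",
                    path, line_no, read.query_length, len(seq))
                n_skipped += 1
                continue
            if len(qualities) != len(seq):
                log.warning("%s line %d: QUAL length %d != SEQ length %d, record skipped",
                            path, line_no, len(qualities), len(seq))
                n_skipped += 1
                continue
            grouped.setdefault(rname, []).append(read)
            n_kept += 1
    log.debug("%s: kept %d mapped primary records, skipped %d malformed",
              path, n_kept, n_skipped)
    return grouped


def pileup_at(reads: Iterable[AlignedRead], position: int,
              min_base_quality: int = 20, min_mapping_quality: int = 0,
              reference_id: str | None = None) -> AlleleCounts:
    """Allele counts at one 0-based reference position.

    Each read contributes the query base its CIGAR aligns to
    ``position``, counted only when the aligning op is M/=/X, the base is
    a concrete A/C/G/T, and its Phred quality is >= ``min_base_quality``.
    Deletions, skips and clips at the position contribute nothing.  An
    empty pileup is a valid zero-depth result.
    """
    counts = dict.fromkeys(COUNTED_BASES, 0)
    ref_id = reference_id
    for read in reads:
        if ref_id is None:
            ref_id = read.reference_id
        if read.mapping_quality < min_mapping_quality:
            continue
        hit = read.base_at(position)
        if hit is None:
            continue
        base, quality = hit
        if base in counts and quality >= min_base_quality:
            counts[base] += 1
    return AlleleCounts(reference_id=ref_id or "", position=position,
                        counts={b: n for b, n in counts.items() if n})
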
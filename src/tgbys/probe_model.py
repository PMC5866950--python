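"""Capture-probe data model, I/O and probe-level sequence statistics.

Array-validated SNP markers are converted into allele-specific pairs of
120-mer capture probes: for each SNP two probes are designed, one carrying
each allele at the target position, identical elsewhere.  A probe set is
stored as a FASTA of probe sequences plus a tab-separated metadata table
(probe id, locus id, captured allele, 0-based SNP offset, chromosome and
dominance class taken from the array design).

This module loads and round-trips such probe sets, groups probes into
per-SNP loci, and computes the sequence statistics used for probe-design
QC: per-probe GC fraction, probe-set summaries and two-group GC
comparisons (failed vs. total probes, cross-platform vs. total probes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

log = logging.getLogger(__name__)

_PROBE_ALPHABET = frozenset("ACGTN")

METADATA_COLUMNS = ("probe_id", "locus_id", "allele", "snp_offset", "chromosome", "dominance")


class ProbeSetError(ValueError):
    """Raised for unrecoverable problems in a probe FASTA/metadata pair."""


class Dominance(str, Enum):
    """Marker dominance class, taken from the source array design.

    Co-dominant markers distinguish heterozygotes from both homozygotes;
    dominant markers cannot.  The class is metadata, never inferred from
    sequence.
    """

    CO_DOMINANT = "co_dominant"
    DOMINANT = "dominant"
    PARTIAL_CO_DOMINANT = "partial_co_dominant"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ProbeRecord:
    """One allele-specific capture probe (canonically a 120-mer).

    ``snp_offset`` is the 0-based index of the target SNP within
    ``sequence``; ``allele`` is the base this probe captures there.
    """

    probe_id: str
    locus_id: str
    allele: str
    sequence: str
    snp_offset: int
    chromosome: str = "unknown"
    dominance: Dominance = Dominance.UNKNOWN

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ProbeSetError(f"probe {self.probe_id!r}: empty sequence")
        bad = set(self.sequence.upper()) - _PROBE_ALPHABET
        if bad:
            raise ProbeSetError(
                f"probe {self.probe_id!r}: invalid bases {sorted(bad)} in sequence"
            )
        if not 0 <= self.snp_offset < len(self.sequence):
            raise ProbeSetError(
                f"probe {self.probe_id!r}: snp_offset {self.snp_offset} outside "
                f"sequence of length {len(self.sequence)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "allele", self.allele.upper())

    def problems(self) -> list[str]:
        """Soft invariant violations (reported, not fatal)."""
        out = []
        if self.allele != "N" and self.sequence[self.snp_offset] != self.allele:
            out.append(
                f"probe {self.probe_id!r}: sequence has "
                f"{self.sequence[self.snp_offset]!r} at snp_offset "
                f"{self.snp_offset}, metadata allele is {self.allele!r}"
            )
        return out


@dataclass
class ProbeLocus:
    """A SNP target with its one or two allele-specific probes."""

    locus_id: str
    probes: list[ProbeRecord]
    ref_allele: str
    alt_allele: str
    chromosome: str = "unknown"
    flags: list[str] = field(default_factory=list)

    @classmethod
    def from_probes(cls, locus_id: str, probes: Sequence[ProbeRecord]) -> "ProbeLocus":
        probes = sorted(probes, key=lambda p: p.probe_id)
        flags: list[str] = []
        for p in probes:
            flags.extend(p.problems())
        alleles = sorted({p.allele for p in probes})
        if len(probes) == 1:
            flags.append("single_probe")
            ref, alt = probes[0].allele, "N"
        else:
            if len(probes) > 2:
                flags.append(f"extra_probes:{len(probes)}")
            a, b = probes[0], probes[1]
            if len(a.sequence) != len(b.sequence):
                flags.append("pair_length_mismatch")
            else:
                diffs = [i for i, (x, y) in enumerate(zip(a.sequence, b.sequence)) if x != y]
                if diffs != [a.snp_offset] and a.sequence != b.sequence:
                    flags.append(f"pair_mismatch:{len(diffs)}_positions")
                elif a.sequence == b.sequence:
                    flags.append("pair_identical_sequences")
            if a.snp_offset != b.snp_offset:
                flags.append("pair_offset_mismatch")
            if len(alleles) == 2:
                ref, alt = alleles[0], alleles[1]
            else:
                flags.append("pair_allele_mismatch")
                ref = alleles[0]
                alt = alleles[-1] if len(alleles) > 1 else "N"
        chrom = probes[0].chromosome
        return cls(locus_id=locus_id, probes=list(probes), ref_allele=ref,
                   alt_allele=alt, chromosome=chrom, flags=flags)

    @property
    def is_flagged(self) -> bool:
        return bool(self.flags)


@dataclass(frozen=True)
class ProbeSetSummary:
    n_probes: int
    mean_gc: float
    dominance_fractions: Mapping[Dominance, float]


def gc_content(sequence: str) -> float:
    """GC fraction of a probe sequence; ``N`` bases are excluded from the
    denominator so masked probes are not biased toward 0.

    Raises ``ValueError`` for an empty or all-N sequence (the fraction is
    undefined there).
    """
    seq = sequence.upper()
    bad = set(seq) - _PROBE_ALPHABET
    if bad:
        raise ValueError(f"invalid bases {sorted(bad)} in sequence")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("GC content undefined for empty or all-N sequence")
    return (seq.count("G") + seq.count("C")) / denom


def load_probe_set(fasta_path: str | Path, metadata_path: str | Path) -> list[ProbeLocus]:
    """Load a probe set from FASTA + TSV metadata, grouped into loci.

    Every FASTA record must have a metadata row (keyed by ``probe_id``);
    a missing row, or a ``snp_offset`` outside the sequence, is a hard
    error naming the offending probe.  Pair-level inconsistencies (e.g.
    the two probes of a locus differing at more than the SNP position)
    are retained but flagged on the locus; loci with a single surviving
    probe are flagged ``single_probe``.
    """
    fasta_path, metadata_path = Path(fasta_path), Path(metadata_path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ProbeSetError(f"{metadata_path}: missing metadata columns {missing_cols}")
    rows: dict[str, tuple[int, pd.Series]] = {}
    for idx, row in meta.iterrows():
        line_no = int(idx) + 2  # header is line 1
        pid = row["probe_id"]
        if pid in rows:
            log.warning("%s line %d: duplicate probe_id %r (first kept)",
                        metadata_path, line_no, pid)
            continue
        rows[pid] = (line_no, row)

    by_locus: dict[str, list[ProbeRecord]] = {}
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in rows:
            raise ProbeSetError(
                f"FASTA record {rec.id!r} has no metadata row in {metadata_path}"
            )
        line_no, row = rows[rec.id]
        seen.add(rec.id)
        try:
            offset = int(row["snp_offset"])
        except ValueError:
            raise ProbeSetError(
                f"{metadata_path} line {line_no}: non-integer snp_offset "
                f"{row['snp_offset']!r}"
            ) from None
        try:
            dominance = Dominance(row["dominance"]) if row["dominance"] else Dominance.UNKNOWN
        except ValueError:
            log.warning("%s line %d: unknown dominance class %r, using 'unknown'",
                        metadata_path, line_no, row["dominance"])
            dominance = Dominance.UNKNOWN
        try:
            probe = ProbeRecord(
                probe_id=rec.id,
                locus_id=row["locus_id"],
                allele=row["allele"],
                sequence=str(rec.seq),
                snp_offset=offset,
                chromosome=row["chromosome"] or "unknown",
                dominance=dominance,
            )
        except ProbeSetError as exc:
            raise ProbeSetError(f"{metadata_path} line {line_no}: {exc}") from None
        for problem in probe.problems():
            log.warning("%s line %d: %s", metadata_path, line_no, problem)
        by_locus.setdefault(probe.locus_id, []).append(probe)

    for pid, (line_no, _) in rows.items():
        if pid not in seen:
            log.warning("%s line %d: metadata row %r has no FASTA record",
                        metadata_path, line_no, pid)

    loci = [ProbeLocus.from_probes(lid, probes) for lid, probes in sorted(by_locus.items())]
    n_flagged = sum(l.is_flagged for l in loci)
    log.info("loaded %d probes in %d loci (%d flagged) from %s",
             sum(len(l.probes) for l in loci), len(loci), n_flagged, fasta_path)
    return loci


def write_probe_set(loci: Iterable[ProbeLocus], fasta_path: str | Path,
                    metadata_path: str | Path) -> None:
    """Serialize loci back to FASTA + TSV (inverse of :func:`load_probe_set`)."""
    records, rows = [], []
    for locus in loci:
        for p in locus.probes:
            records.append(SeqRecord(Seq(p.sequence), id=p.probe_id, description=""))
            rows.append({
                "probe_id": p.probe_id, "locus_id": p.locus_id, "allele": p.allele,
                "snp_offset": p.snp_offset, "chromosome": p.chromosome,
                "dominance": p.dominance.value,
            })
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
        metadata_path, sep="\t", index=False)


def iter_probes(loci: Iterable[ProbeLocus]) -> Iterable[ProbeRecord]:
    for locus in loci:
        yield from locus.probes


def summarize_probe_set(loci: Sequence[ProbeLocus]) -> ProbeSetSummary:
    """Probe-set summary: mean GC over unique probe sequences and the
    dominance-class composition over classified probes."""
    probes = list(iter_probes(loci))
    if not probes:
        raise ProbeSetError("cannot summarize an empty probe set")
    unique_seqs = sorted({p.sequence for p in probes})
    mean_gc = sum(gc_content(s) for s in unique_seqs) / len(unique_seqs)
    classified = [p for p in probes if p.dominance is not Dominance.UNKNOWN]
    fractions: dict[Dominance, float] = {}
    if classified:
        for dom in Dominance:
            if dom is Dominance.UNKNOWN:
                continue
            n = sum(p.dominance is dom for p in classified)
            if n:
                fractions[dom] = n / len(classified)
    return ProbeSetSummary(n_probes=len(probes), mean_gc=mean_gc,
                           dominance_fractions=fractions)


@dataclass(frozen=True)
class GcComparison:
    mean_a: float
    mean_b: float
    p_value: float


def compare_gc(group_a: Sequence[str], group_b: Sequence[str]) -> GcComparison:
    """Two-sample comparison of per-sequence GC fractions.

    Uses Welch's unequal-variance t-test (two-sided).  When both groups
    are constant the statistic is undefined; the p-value is then reported
    as the limit case: 1 for equal means, 0 otherwise.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 sequences")
    gc_a = [gc_content(s) for s in group_a]
    gc_b = [gc_content(s) for s in group_b]
    mean_a = sum(gc_a) / len(gc_a)
    mean_b = sum(gc_b) / len(gc_b)
    res = stats.ttest_ind(gc_a, gc_b, equal_var=False)
    p = float(res.pvalue)
    if math.isnan(p):
        p = 1.0 if math.isclose(mean_a, mean_b) else 0.0
    return GcComparison(mean_a=mean_a, mean_b=mean_b, p_value=p)
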
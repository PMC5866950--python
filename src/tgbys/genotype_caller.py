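"""Threshold-based genotype calling from allele pileups.

The calling rule is purely frequency-based, with no ploidy model or
heterozygosity prior: a locus/sample cell is called when at least
``min_reads`` quality-filtered reads cover the target position, and the
genotype is the set of every base carried by at least ``min_fraction``
of those reads.  For example a pileup of A(20), T(80) with the default
thresholds (10 reads, 20%) is the heterozygous genotype AT.  Both
threshold comparisons are inclusive (>=): 20 of 100 reads at a 20%
threshold passes — the worked example above fixes that convention.

Because the two probes of a locus capture the same fragment population
(one per allele), their pileups at the target SNP are pooled base-wise
before calling; a marker fails only when the pooled evidence fails.
Hexaploid wheat adds a twist: co-captured homoeologues can put a third
allele over the threshold, so tri-allelic loci are detected both per
call (three alleles in one sample) and per locus (allele union across
samples of size >= 3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment_io import AlleleCounts, COUNTED_BASES, pileup_at, read_sam
from .probe_model import ProbeLocus

log = logging.getLogger(__name__)

#: serialized cell for a zero-coverage call
NO_DATA_TOKEN = "NA"
#: serialized cell for coverage above zero but below the read cutoff
LOW_DEPTH_TOKEN = "LOW"


@dataclass(frozen=True)
class CallingParameters:
    """Depth and allele-fraction cutoffs for genotype calling.

    Defaults are the pipeline's operating point: a minimum of 10 reads
    aligned per contig and a 20% minimum read fraction per allele.
    """

    min_reads: int = 10
    min_fraction: float = 0.20
    min_base_quality: int = 20

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")


class CallStatus(str, Enum):
    CALLED = "called"
    NO_DATA = "no_data"
    BELOW_MIN_READS = "below_min_reads"


class Allelicity(str, Enum):
    MONOMORPHIC = "monomorphic"
    HETEROZYGOUS_BI = "heterozygous_bi"
    TRI_OR_MORE = "tri_or_more"
    NOT_CALLED = "not_called"


def _allelicity(alleles: Sequence[str]) -> Allelicity:
    if not alleles:
        return Allelicity.NOT_CALLED
    if len(alleles) == 1:
        return Allelicity.MONOMORPHIC
    if len(alleles) == 2:
        return Allelicity.HETEROZYGOUS_BI
    return Allelicity.TRI_OR_MORE


@dataclass(frozen=True)
class GenotypeCall:
    """Called allele set and status for one locus in one sample."""

    locus_id: str
    sample_id: str
    alleles: tuple[str, ...]
    status: CallStatus
    allelicity: Allelicity
    depth: int

    @property
    def genotype(self) -> str:
        """Serialized genotype: concatenated sorted alleles, or a status token."""
        if self.status is CallStatus.NO_DATA:
            return NO_DATA_TOKEN
        if self.status is CallStatus.BELOW_MIN_READS:
            return LOW_DEPTH_TOKEN
        return "".join(self.alleles)


def call_genotype(counts: AlleleCounts, params: CallingParameters = CallingParameters(),
                  locus_id: str = "", sample_id: str = "") -> GenotypeCall:
    """Apply the two-threshold rule to one pileup.

    depth == 0 -> ``no_data``; 0 < depth < ``min_reads`` ->
    ``below_min_reads``; otherwise every base with count/depth >=
    ``min_fraction`` enters the genotype, alphabetically sorted.  With a
    fraction threshold above 0.25 it is possible for no base to qualify
    (four alleles each under the bar); such a cell is reported as
    ``no_data`` since it carries no callable genotype.
    """
    locus_id = locus_id or counts.reference_id
    depth = counts.depth
    if depth == 0:
        return GenotypeCall(locus_id, sample_id, (), CallStatus.NO_DATA,
                            Allelicity.NOT_CALLED, 0)
    if depth < params.min_reads:
        return GenotypeCall(locus_id, sample_id, (), CallStatus.BELOW_MIN_READS,
                            Allelicity.NOT_CALLED, depth)
    alleles = tuple(sorted(
        b for b in COUNTED_BASES if counts.get(b) / depth >= params.min_fraction))
    if not alleles:
        return GenotypeCall(locus_id, sample_id, (), CallStatus.NO_DATA,
                            Allelicity.NOT_CALLED, depth)
    return GenotypeCall(locus_id, sample_id, alleles, CallStatus.CALLED,
                        _allelicity(alleles), depth)


class ProbePairError(ValueError):
    """Probes of one locus reported counts at inconsistent positions."""


def pool_counts(per_probe_counts: Sequence[AlleleCounts], locus_id: str = "") -> AlleleCounts:
    """Sum allele counts base-wise across the probes of one locus."""
    if not per_probe_counts:
        return AlleleCounts(reference_id=locus_id, position=0, counts={})
    positions = {c.position for c in per_probe_counts}
    if len(positions) > 1:
        raise ProbePairError(
            f"locus {locus_id!r}: probes report different target positions {sorted(positions)}"
        )
    merged: dict[str, int] = {}
    for c in per_probe_counts:
        for base, n in c.counts.items():
            merged[base] = merged.get(base, 0) + n
    return AlleleCounts(reference_id=locus_id or per_probe_counts[0].reference_id,
                        position=per_probe_counts[0].position, counts=merged)


def call_locus(locus: ProbeLocus, per_probe_counts: Sequence[AlleleCounts],
               params: CallingParameters = CallingParameters(),
               sample_id: str = "") -> GenotypeCall:
    """Pool the allele-specific probe pileups of one locus and call once."""
    pooled = pool_counts(per_probe_counts, locus_id=locus.locus_id)
    return call_genotype(pooled, params, locus_id=locus.locus_id, sample_id=sample_id)


@dataclass
class GenotypeMatrix:
    """Complete locus x sample grid of genotype calls."""

    loci: list[str]
    samples: list[str]
    calls: dict[tuple[str, str], GenotypeCall]

    def __post_init__(self) -> None:
        for locus in self.loci:
            for sample in self.samples:
                if (locus, sample) not in self.calls:
                    raise ValueError(f"incomplete matrix: no call for ({locus}, {sample})")

    def get(self, locus_id: str, sample_id: str) -> GenotypeCall:
        return self.calls[(locus_id, sample_id)]

    def to_frame(self) -> pd.DataFrame:
        """Genotype strings as a locus x sample DataFrame ("AT", "NA", "LOW")."""
        data = {s: [self.calls[(l, s)].genotype for l in self.loci] for s in self.samples}
        return pd.DataFrame(data, index=pd.Index(self.loci, name="locus_id"))

    def to_tsv(self, path: str | Path, collapse_low: bool = False) -> None:
        """Write the matrix as TSV.  ``collapse_low`` folds sub-threshold
        coverage into ``NA``, discarding the zero- vs. low-coverage
        distinction the in-memory matrix preserves."""
        frame = self.to_frame()
        if collapse_low:
            frame = frame.replace(LOW_DEPTH_TOKEN, NO_DATA_TOKEN)
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeMatrix":
        calls = {}
        for locus in frame.index:
            for sample in frame.columns:
                cell = str(frame.loc[locus, sample])
                if cell in (NO_DATA_TOKEN, "", "nan"):
                    call = GenotypeCall(locus, sample, (), CallStatus.NO_DATA,
                                        Allelicity.NOT_CALLED, 0)
                elif cell == LOW_DEPTH_TOKEN:
                    call = GenotypeCall(locus, sample, (), CallStatus.BELOW_MIN_READS,
                                        Allelicity.NOT_CALLED, 0)
                else:
                    alleles = tuple(sorted(cell))
                    call = GenotypeCall(locus, sample, alleles, CallStatus.CALLED,
                                        _allelicity(alleles), 0)
                calls[(locus, sample)] = call
        return cls(loci=list(frame.index), samples=list(frame.columns), calls=calls)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna(NO_DATA_TOKEN)
        frame.index = frame.index.astype(str)
        return cls.from_frame(frame)


def _counts_for_locus(locus: ProbeLocus, by_reference: Mapping[str, list],
                      params: CallingParameters) -> list[AlleleCounts]:
    """Pileups for one locus in one sample's alignments.

    Reads may be aligned per allele-specific probe (references named by
    probe_id) or against one contig per locus (reference named by
    locus_id); probe-level references take precedence so a read is never
    counted twice.
    """
    counts = []
    matched = False
    for probe in locus.probes:
        reads = by_reference.get(probe.probe_id)
        if reads:
            matched = True
            counts.append(pileup_at(reads, probe.snp_offset,
                                    min_base_quality=params.min_base_quality))
    if not matched and locus.locus_id in by_reference:
        offset = locus.probes[0].snp_offset
        counts.append(pileup_at(by_reference[locus.locus_id], offset,
                                min_base_quality=params.min_base_quality))
    return counts


def call_matrix(loci: Sequence[ProbeLocus], alignments: Mapping[str, str | Path],
                params: CallingParameters = CallingParameters()) -> GenotypeMatrix:
    """Call every locus in every sample into a complete genotype matrix.

    ``alignments`` maps sample id -> SAM path.  An unreadable alignment
    file downgrades that sample's whole column to ``no_data`` with a
    warning rather than failing the run.
    """
    locus_ids = [l.locus_id for l in loci]
    samples = list(alignments)
    calls: dict[tuple[str, str], GenotypeCall] = {}
    for sample in samples:
        try:
            by_reference = read_sam(alignments[sample])
        except (OSError, ValueError) as exc:
            log.warning("sample %s: alignment unreadable (%s); column set to no_data",
                        sample, exc)
            by_reference = {}
        n_called = 0
        for locus in loci:
            counts = _counts_for_locus(locus, by_reference, params)
            call = call_locus(locus, counts, params, sample_id=sample)
            calls[(locus.locus_id, sample)] = call
            n_called += call.status is CallStatus.CALLED
        log.info("sample %s: %d/%d loci called (%.1f%%)",
                 sample, n_called, len(loci), 100 * n_called / max(len(loci), 1))
    matrix = GenotypeMatrix(loci=locus_ids, samples=samples, calls=calls)
    for locus_id in locus_ids:
        rate = sum(matrix.get(locus_id, s).status is CallStatus.CALLED
                   for s in samples) / max(len(samples), 1)
        log.debug("locus %s: call rate %.2f", locus_id, rate)
    return matrix


def find_triallelic(matrix: GenotypeMatrix) -> list[str]:
    """Loci showing three or more alleles.

    A locus is flagged when the union of alleles over its called samples
    has size >= 3 (three possible genotype calls across accessions) or
    when any single call is itself tri-allelic.  Output order follows the
    matrix locus order.
    """
    flagged = []
    for locus in matrix.loci:
        union: set[str] = set()
        single_tri = False
        for sample in matrix.samples:
            call = matrix.get(locus, sample)
            if call.status is CallStatus.CALLED:
                union.update(call.alleles)
                if call.allelicity is Allelicity.TRI_OR_MORE:
                    single_tri = True
        if single_tri or len(union) >= 3:
            flagged.append(locus)
    return flagged
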
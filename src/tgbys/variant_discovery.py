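"""Off-target SNP discovery across the full captured sequence.

Capture enriches the whole fragment around the designed SNP, so the
alignments also carry information about *other* polymorphic positions
within the capture probe footprint.  This module scans every reference
position for non-reference bases, applying the same conservative depth
and fraction cutoffs as the genotype caller (>= 10 reads, >= 20% of
reads), keeps only bi-allelic positions, and scores each candidate with
a Phred-scaled binomial likelihood-ratio quality filtered at >= 100.

The quality score is a transparent stand-in for an aligner/caller QUAL
field: Q = 10 * log10 [ P(alt count | binomial at the observed alt
fraction) / P(alt count | binomial at the sequencing error rate) ],
i.e. how much better "a real allele at its observed fraction" explains
the alt reads than "sequencing error alone" does.  It is 0 when no alt
reads exist, grows with both depth and alt fraction, and is capped to
keep downstream arithmetic finite.

Only substitutions are considered; indels are out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .alignment_io import AlignedRead, AlleleCounts, COUNTED_BASES, pileup_at

log = logging.getLogger(__name__)

#: cap on the Phred quality score, to keep scores finite and comparable
MAX_QUALITY = 10_000.0


@dataclass(frozen=True)
class DiscoveryParameters:
    """Cutoffs for off-target SNP discovery.

    ``min_reads``/``min_fraction`` mirror the genotype caller (10 reads,
    20%); ``min_quality`` is the Phred likelihood-ratio threshold (100);
    ``assumed_error_rate`` is the per-base substitution error the null
    model assumes (1%, a typical short-read scale).
    """

    min_reads: int = 10
    min_fraction: float = 0.20
    min_quality: float = 100.0
    assumed_error_rate: float = 0.01
    min_base_quality: int = 20

    def __post_init__(self) -> None:
        if self.min_reads < 1 or self.min_fraction <= 0 or self.min_quality < 0:
            raise ValueError("thresholds must be positive")
        if self.min_fraction > 0.5:
            raise ValueError("min_fraction above 0.5 cannot detect a bi-allelic alt")
        if not 0 < self.assumed_error_rate < 1:
            raise ValueError("assumed_error_rate must be in (0, 1)")


@dataclass
class VariantCandidate:
    """A bi-allelic substitution candidate at one reference position."""

    reference_id: str
    position: int  # 0-based
    ref_allele: str
    alt_allele: str
    quality: float
    per_sample: dict[str, AlleleCounts] = field(default_factory=dict)
    n_samples_supporting: int = 1

    def __post_init__(self) -> None:
        if self.alt_allele == self.ref_allele:
            raise ValueError("alt allele equals ref allele")
        if self.quality < 0:
            raise ValueError("quality must be >= 0")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.reference_id, self.position, self.alt_allele)


def quality_score(counts: AlleleCounts, ref_allele: str, alt_allele: str,
                  error_rate: float, cap: float = MAX_QUALITY) -> float:
    """Phred-scaled binomial likelihood ratio for an alternate allele.

    With n = counted depth and k = alt reads, compares Binom(k; n, k/n)
    against Binom(k; n, error_rate) on the Phred scale.  Zero alt reads
    score 0; the score is clamped to [0, cap].
    """
    if not 0 < error_rate < 1:
        raise ValueError("error_rate must be in (0, 1)")
    n = counts.depth
    k = counts.get(alt_allele)
    if k == 0 or n == 0:
        return 0.0
    ll_alt = stats.binom.logpmf(k, n, k / n)
    ll_err = stats.binom.logpmf(k, n, error_rate)
    q = 10.0 * (ll_alt - ll_err) / math.log(10.0)
    return float(min(max(q, 0.0), cap))


def scan_reference(reads: Sequence[AlignedRead], reference_sequence: str,
                   params: DiscoveryParameters = DiscoveryParameters(),
                   sample_id: str = "", reference_id: str | None = None,
                   ) -> list[VariantCandidate]:
    """Scan one reference for bi-allelic substitution candidates.

    At each position with counted depth >= ``min_reads``, non-reference
    bases at fraction >= ``min_fraction`` are collected; a position with
    exactly one such alternate and quality >= ``min_quality`` becomes a
    candidate, while positions with two or more alternates are excluded
    as non-bi-allelic (in hexaploid material those are better explained
    by co-captured homoeologues than by a clean SNP).
    """
    if not reads:
        return []
    ref_id = reference_id or reads[0].reference_id
    candidates = []
    for position, ref_base in enumerate(reference_sequence.upper()):
        counts = pileup_at(reads, position, min_base_quality=params.min_base_quality,
                           reference_id=ref_id)
        depth = counts.depth
        if depth < params.min_reads:
            continue
        alts = [b for b in COUNTED_BASES
                if b != ref_base and counts.get(b) / depth >= params.min_fraction]
        if len(alts) != 1:
            if len(alts) > 1:
                log.debug("%s:%d excluded, %d alternates (not bi-allelic)",
                          ref_id, position, len(alts))
            continue
        alt = alts[0]
        if ref_base not in COUNTED_BASES:
            continue
        q = quality_score(counts, ref_base, alt, params.assumed_error_rate)
        if q < params.min_quality:
            continue
        candidates.append(VariantCandidate(
            reference_id=ref_id, position=position, ref_allele=ref_base,
            alt_allele=alt, quality=q,
            per_sample={sample_id: counts} if sample_id else {},
        ))
    return candidates


def shared_variants(per_sample_candidates: Mapping[str, Sequence[VariantCandidate]],
                    ) -> list[VariantCandidate]:
    """Merge per-sample candidates into one list keyed by
    (reference, position, alt), counting supporting samples.

    The merged record keeps the maximum per-sample quality and the union
    of per-sample allele counts; output is sorted by reference then
    position then alt.
    """
    if not per_sample_candidates:
        raise ValueError("need at least one sample")
    merged: dict[tuple[str, int, str], VariantCandidate] = {}
    for sample in sorted(per_sample_candidates):
        for cand in per_sample_candidates[sample]:
            existing = merged.get(cand.key)
            counts = cand.per_sample.get(sample) or next(iter(cand.per_sample.values()), None)
            if existing is None:
                merged[cand.key] = VariantCandidate(
                    reference_id=cand.reference_id, position=cand.position,
                    ref_allele=cand.ref_allele, alt_allele=cand.alt_allele,
                    quality=cand.quality,
                    per_sample={sample: counts} if counts else {},
                    n_samples_supporting=1,
                )
            else:
                existing.n_samples_supporting += 1
                existing.quality = max(existing.quality, cand.quality)
                if counts is not None:
                    existing.per_sample[sample] = counts
    return sorted(merged.values(), key=lambda c: c.key)


def inphase_contigs(candidates: Iterable[VariantCandidate], min_snps: int = 3,
                    max_gap: int | None = None) -> list[str]:
    """References carrying at least ``min_snps`` SNP positions, hence
    suitable for read-backed haplotype analysis.

    "Contiguous" defaults to simple per-contig co-occurrence (no maximum
    spacing); pass ``max_gap`` to additionally require a run of
    ``min_snps`` positions each within ``max_gap`` bases of the next.
    """
    positions: dict[str, set[int]] = {}
    for cand in candidates:
        positions.setdefault(cand.reference_id, set()).add(cand.position)
    out = []
    for ref in sorted(positions):
        pos = sorted(positions[ref])
        if len(pos) < min_snps:
            continue
        if max_gap is None:
            out.append(ref)
            continue
        run = 1
        best = 1
        for prev, cur in zip(pos, pos[1:]):
            run = run + 1 if cur - prev <= max_gap else 1
            best = max(best, run)
        if best >= min_snps:
            out.append(ref)
    return out


def _genotype_field(counts: AlleleCounts | None, ref: str, alt: str,
                    min_fraction: float = 0.20) -> tuple[str, str]:
    """Per-sample GT and AD strings for VCF output."""
    if counts is None or counts.depth == 0:
        return "./.", ".,."
    ad = f"{counts.get(ref)},{counts.get(alt)}"
    depth = counts.depth
    has_ref = counts.get(ref) / depth >= min_fraction
    has_alt = counts.get(alt) / depth >= min_fraction
    if has_ref and has_alt:
        return "0/1", ad
    if has_alt:
        return "1/1", ad
    if has_ref:
        return "0/0", ad
    return "./.", ad


def write_vcf(candidates: Sequence[VariantCandidate], samples: Sequence[str],
              path: str | Path) -> None:
    """Write candidates as minimally valid VCF 4.2 (1-based POS)."""
    ordered = sorted(candidates, key=lambda c: c.key)
    if list(ordered) != list(candidates):
        log.info("VCF input was unsorted; records sorted by (reference, position, alt)")
    lines = [
        "##fileformat=VCFv4.2",
        "##source=tgbys",
        '##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples supporting the variant">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele (ref,alt)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for cand in ordered:
        cells = []
        for sample in samples:
            gt, ad = _genotype_field(cand.per_sample.get(sample),
                                     cand.ref_allele, cand.alt_allele)
            cells.append(f"{gt}:{ad}")
        lines.append("\t".join([
            cand.reference_id, str(cand.position + 1), ".", cand.ref_allele,
            cand.alt_allele, f"{cand.quality:.2f}", "PASS",
            f"NS={cand.n_samples_supporting}", "GT:AD", *cells,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[VariantCandidate]:
    """Re-parse a VCF written by :func:`write_vcf` (plain text, 4.2)."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            counts: dict[str, AlleleCounts] = {}
            for sample in rec.samples:
                ad = rec.samples[sample].get("AD")
                if ad is None or any(v is None for v in ad):
                    continue
                counts[sample] = AlleleCounts(
                    reference_id=rec.chrom, position=rec.pos - 1,
                    counts={a: int(n) for a, n in zip((rec.ref, rec.alts[0]), ad) if n})
            ns = rec.info.get("NS", 1)
            out.append(VariantCandidate(
                reference_id=rec.chrom, position=rec.pos - 1, ref_allele=rec.ref,
                alt_allele=rec.alts[0], quality=float(rec.qual),
                per_sample=counts, n_samples_supporting=int(ns)))
    return out


def shared_variants_table(candidates: Sequence[VariantCandidate]):
    """TSV-ready summary of shared variants."""
    import pandas as pd

    rows = [{
        "reference_id": c.reference_id, "position": c.position + 1,
        "ref": c.ref_allele, "alt": c.alt_allele, "quality": round(c.quality, 2),
        "n_samples_supporting": c.n_samples_supporting,
    } for c in sorted(candidates, key=lambda c: c.key)]
    return pd.DataFrame(rows, columns=["reference_id", "position", "ref", "alt",
                                       "quality", "n_samples_supporting"])
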
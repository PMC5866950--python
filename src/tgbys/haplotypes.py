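"""Read-backed haplotype phasing over 3-SNP windows.

Short captured fragments often span several nearby SNPs, so the phase
of their alleles can be read directly off individual reads — no
statistical phasing is needed or attempted.  The procedure:

1. find intravarietal variant sites within one sample's alignments
   (positions where at least two distinct bases each have at least two
   supporting reads of Phred quality above 20 — in hexaploid wheat these
   are typically between-homoeologue differences),
2. optionally merge in known varietal variant positions supplied
   externally, giving the full site list per reference,
3. walk each read and record its allele at every covered site, keeping
   the calls phased per read,
4. split each read's phased allele run into overlapping windows of
   three consecutive sites; runs of two or fewer sites are ignored.

Identical (positions, alleles) windows within a variety are aggregated
with a read-support count; the catalogue keeps one row per
(reference, window, haplotype, variety).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment_io import AlignedRead, COUNTED_BASES, pileup_at

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantSite:
    """One variant position with the alleles observed at it."""

    reference_id: str
    position: int  # 0-based
    alleles: tuple[str, ...]


@dataclass(frozen=True)
class PhasedRead:
    """Alleles one read carries at declared variant sites.

    Only sites the read covers with an aligned base above the quality
    threshold appear in ``allele_at``.
    """

    read_id: str
    reference_id: str
    allele_at: Mapping[int, str]


@dataclass(frozen=True)
class HaplotypeWindow:
    """A phased allele triple over three variant sites in one variety."""

    reference_id: str
    positions: tuple[int, ...]  # strictly increasing, 0-based
    haplotype: tuple[str, ...]
    variety: str
    read_support: int

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("window positions must be strictly increasing")
        if self.read_support < 1:
            raise ValueError("read_support must be >= 1")


def intravarietal_sites(reads: Sequence[AlignedRead], min_allele_reads: int = 2,
                        min_phred: int = 20,
                        reference_length: int | None = None) -> list[VariantSite]:
    """Variant positions within one sample's reads on one reference.

    A position qualifies when at least two distinct bases each have
    >= ``min_allele_reads`` supporting reads of base quality strictly
    above ``min_phred``.
    """
    if not reads:
        return []
    ref_id = reads[0].reference_id
    span_end = reference_length if reference_length is not None else max(
        r.reference_end for r in reads)
    span_start = 0 if reference_length is not None else min(
        r.reference_start for r in reads)
    sites = []
    for position in range(span_start, span_end):
        # strict "> min_phred" on integer Phred scores == ">= min_phred + 1"
        counts = pileup_at(reads, position, min_base_quality=min_phred + 1,
                           reference_id=ref_id)
        alleles = tuple(sorted(b for b in COUNTED_BASES
                               if counts.get(b) >= min_allele_reads))
        if len(alleles) >= 2:
            sites.append(VariantSite(reference_id=ref_id, position=position,
                                     alleles=alleles))
    return sites


def merge_site_positions(intravarietal: Iterable[VariantSite],
                         varietal_positions: Iterable[int] = ()) -> list[int]:
    """Union of intravarietal site positions and externally supplied
    varietal variant positions, sorted."""
    positions = {s.position for s in intravarietal}
    positions.update(varietal_positions)
    return sorted(positions)


def phase_reads(reads: Sequence[AlignedRead], sites: Sequence[int],
                min_phred: int = 20) -> list[PhasedRead]:
    """Extract per-read alleles at the given site positions.

    One :class:`PhasedRead` is produced per input read that covers at
    least one site with an aligned A/C/G/T base of quality strictly
    above ``min_phred``; deletions and low-quality bases leave that site
    out of ``allele_at``.
    """
    site_list = sorted(sites)
    phased = []
    for read in reads:
        allele_at: dict[int, str] = {}
        for position in site_list:
            if position >= read.reference_end:
                break
            hit = read.base_at(position)
            if hit is None:
                continue
            base, quality = hit
            if base in COUNTED_BASES and quality > min_phred:
                allele_at[position] = base
        if allele_at:
            phased.append(PhasedRead(read_id=read.read_id,
                                     reference_id=read.reference_id,
                                     allele_at=allele_at))
    return phased


def _consecutive_runs(indices: Sequence[int]) -> list[list[int]]:
    runs: list[list[int]] = []
    for idx in indices:
        if runs and idx == runs[-1][-1] + 1:
            runs[-1].append(idx)
        else:
            runs.append([idx])
    return runs


def window_haplotypes(phased: Sequence[PhasedRead], sites: Sequence[int],
                      variety: str, window: int = 3,
                      min_support: int = 1) -> list[HaplotypeWindow]:
    """Split per-read phased alleles into overlapping windows of
    ``window`` consecutive sites and aggregate identical windows.

    A read covering m consecutive sites yields max(0, m - window + 1)
    windows; reads phased over fewer than ``window`` sites contribute
    nothing.  "Consecutive" means consecutive in the reference's ordered
    site list: a read missing an interior site (deletion or low-quality
    base) breaks the run, so no window ever phases across an unobserved
    position.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    site_list = sorted(sites)
    site_index = {p: i for i, p in enumerate(site_list)}
    support: dict[tuple[str, tuple[int, ...], tuple[str, ...]], int] = {}
    for read in phased:
        indices = sorted(site_index[p] for p in read.allele_at if p in site_index)
        for run in _consecutive_runs(indices):
            if len(run) < window:
                continue
            for start in range(len(run) - window + 1):
                span = run[start:start + window]
                positions = tuple(site_list[i] for i in span)
                haplotype = tuple(read.allele_at[p] for p in positions)
                key = (read.reference_id, positions, haplotype)
                support[key] = support.get(key, 0) + 1
    out = [HaplotypeWindow(reference_id=ref, positions=positions,
                           haplotype=haplotype, variety=variety, read_support=n)
           for (ref, positions, haplotype), n in support.items()
           if n >= min_support]
    return sorted(out, key=lambda w: (w.reference_id, w.positions, w.haplotype))


def haplotype_catalogue(windows: Iterable[HaplotypeWindow]) -> pd.DataFrame:
    """Catalogue of phased 3-SNP haplotypes per variety.

    One row per (reference, positions, haplotype, variety) with the read
    support; positions are 1-based in the output, sorted
    deterministically.
    """
    rows = [{
        "reference_id": w.reference_id,
        **{f"pos{i + 1}": p + 1 for i, p in enumerate(w.positions)},
        "haplotype": "".join(w.haplotype),
        "variety": w.variety,
        "read_support": w.read_support,
    } for w in windows]
    n_pos = max((len(w.positions) for w in windows), default=3) if rows else 3
    columns = (["reference_id"] + [f"pos{i + 1}" for i in range(n_pos)]
               + ["haplotype", "variety", "read_support"])
    frame = pd.DataFrame(rows, columns=columns)
    if not frame.empty:
        frame = frame.sort_values(
            ["reference_id"] + [f"pos{i + 1}" for i in range(n_pos)]
            + ["haplotype", "variety"]).reset_index(drop=True)
    return frame


def catalogue_sample(reads: Sequence[AlignedRead], variety: str,
                     varietal_positions: Iterable[int] = (),
                     min_allele_reads: int = 2, min_phred: int = 20,
                     window: int = 3, reference_length: int | None = None,
                     ) -> list[HaplotypeWindow]:
    """End-to-end haplotype windows for one sample on one reference:
    site discovery, optional varietal-site merge, per-read phasing and
    windowing."""
    sites = intravarietal_sites(reads, min_allele_reads=min_allele_reads,
                                min_phred=min_phred,
                                reference_length=reference_length)
    positions = merge_site_positions(sites, varietal_positions)
    phased = phase_reads(reads, positions, min_phred=min_phred)
    return window_haplotypes(phased, positions, variety=variety, window=window)
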
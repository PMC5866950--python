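"""Synthetic capture-sequencing data with known ground truth.

Every stage of the pipeline is testable without real wheat data: this
module fabricates probe sets, per-sample true genotypes, error-bearing
reads (emitted both as FASTQ and as pre-aligned SAM with truth-known
coordinates, so no external aligner is ever involved), and paired
platform genotype matrices with planted discordance.

What the generator emulates, and what it does not: reads are uniform
random substrings of a 120-mer probe reference covering the target SNP,
with per-locus/sample depth Poisson-distributed around the scenario
mean, i.i.d. substitution errors at a fixed rate and a single Phred
quality consistent with that rate.  Heterozygous cells emit both
alleles at ~50:50 per read; tri-allelic loci (the homoeologue-capture
signature) emit three alleles at ~1/3 each in every sample.  There is
no capture-efficiency or GC-bias modelling, no indel errors, no
position-dependent quality and no mate pairing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment_io import AlignedRead
from .genotype_caller import GenotypeMatrix, NO_DATA_TOKEN
from .probe_model import Dominance, ProbeLocus, ProbeRecord

BASES = ("A", "C", "G", "T")

#: wheat-style chromosome labels used for simulated probe metadata
_CHROMOSOMES = tuple(f"{n}{g}" for n in range(1, 8) for g in "ABD")

#: dominance-class mix for simulated probes: roughly half co-dominant,
#: just over a quarter dominant, the rest partially co-dominant —
#: the composition typical of array-derived probe sets
_DOMINANCE_PROBS = {
    Dominance.CO_DOMINANT: 0.4974,
    Dominance.DOMINANT: 0.2829,
    Dominance.PARTIAL_CO_DOMINANT: 0.2197,
}


@dataclass(frozen=True)
class SimulationScenario:
    """Study conditions for a simulated capture-sequencing run.

    Defaults describe a desk-scale experiment: 200 loci in 8 samples at
    50x mean coverage with a 0.5% substitution error rate, 10% of
    locus/sample cells heterozygous and 2% of loci tri-allelic.
    """

    n_loci: int = 200
    samples: tuple[str, ...] = tuple(f"S{i + 1:02d}" for i in range(8))
    coverage: float = 50.0
    error_rate: float = 0.005
    het_fraction: float = 0.10
    triallelic_fraction: float = 0.02
    offtarget_fraction: float = 0.0
    read_length: int = 100
    gc_target: float = 0.494
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "het_fraction", "triallelic_fraction",
                     "offtarget_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    @property
    def phred_quality(self) -> int:
        """Single per-base quality consistent with ``error_rate``."""
        if self.error_rate <= 0:
            return 40
        return min(40, int(round(-10 * math.log10(self.error_rate))))


@dataclass
class PlantedVariant:
    reference_id: str
    position: int  # 0-based
    ref_allele: str
    alt_allele: str


@dataclass
class TruthSet:
    """Ground truth emitted alongside the simulated reads."""

    genotypes: dict[tuple[str, str], tuple[str, ...]]  # (locus, sample) -> alleles
    triallelic_loci: list[str]
    variants: list[PlantedVariant]
    read_alleles: dict[str, tuple[str, str]]  # read_id -> (snp allele, off-target allele or "")

    def write(self, out_dir: str | Path) -> None:
        import pandas as pd

        out_dir = Path(out_dir)
        rows = [{"locus_id": l, "sample_id": s, "genotype": "".join(g)}
                for (l, s), g in sorted(self.genotypes.items())]
        pd.DataFrame(rows, columns=["locus_id", "sample_id", "genotype"]).to_csv(
            out_dir / "truth_genotypes.tsv", sep="\t", index=False)
        rows = [{"reference_id": v.reference_id, "position": v.position + 1,
                 "ref": v.ref_allele, "alt": v.alt_allele}
                for v in self.variants]
        pd.DataFrame(rows, columns=["reference_id", "position", "ref", "alt"]).to_csv(
            out_dir / "truth_variants.tsv", sep="\t", index=False)
        pd.DataFrame({"locus_id": sorted(self.triallelic_loci)}).to_csv(
            out_dir / "truth_triallelic.tsv", sep="\t", index=False)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=length, p=probs))


def simulate_probe_set(n_loci: int, gc_target: float = 0.494,
                       seed: int = 0, probe_length: int = 120) -> list[ProbeLocus]:
    """Fabricate a probe set: per locus a random 120-mer with a SNP at a
    recorded offset and a two-probe allele pair differing only there.

    Bases are drawn i.i.d. with GC probability ``gc_target``, so for
    n_loci >= 50 the realized mean GC is within a few thousandths of the
    target.  The SNP offset is drawn uniformly from the middle of the
    probe (positions 30-90) rather than assumed central.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    dom_classes = list(_DOMINANCE_PROBS)
    dom_probs = np.array(list(_DOMINANCE_PROBS.values()))
    dom_probs = dom_probs / dom_probs.sum()
    loci = []
    for i in range(n_loci):
        locus_id = f"L{i + 1:05d}"
        sequence = _random_sequence(rng, probe_length, gc_target)
        offset = int(rng.integers(30, 91))
        ref = sequence[offset]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        sequence = sequence[:offset] + ref + sequence[offset + 1:]
        alt_sequence = sequence[:offset] + alt + sequence[offset + 1:]
        chromosome = str(rng.choice(_CHROMOSOMES))
        dominance = dom_classes[int(rng.choice(len(dom_classes), p=dom_probs))]
        probes = [
            ProbeRecord(probe_id=f"{locus_id}_p1", locus_id=locus_id, allele=ref,
                        sequence=sequence, snp_offset=offset, chromosome=chromosome,
                        dominance=dominance),
            ProbeRecord(probe_id=f"{locus_id}_p2", locus_id=locus_id, allele=alt,
                        sequence=alt_sequence, snp_offset=offset, chromosome=chromosome,
                        dominance=dominance),
        ]
        loci.append(ProbeLocus.from_probes(locus_id, probes))
    return loci


def reference_sequences(loci: Iterable[ProbeLocus]) -> dict[str, str]:
    """Per-locus reference contig: the sequence of the probe carrying the
    locus reference allele."""
    refs = {}
    for locus in loci:
        probe = next((p for p in locus.probes if p.allele == locus.ref_allele),
                     locus.probes[0])
        refs[locus.locus_id] = probe.sequence
    return refs


def write_reference_fasta(loci: Iterable[ProbeLocus], path: str | Path) -> None:
    with open(path, "w") as handle:
        for locus_id, seq in reference_sequences(loci).items():
            handle.write(f">{locus_id}\n{seq}\n")


def _sam_header(refs: Mapping[str, str]) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    lines += [f"@SQ\tSN:{name}\tLN:{len(seq)}" for name, seq in refs.items()]
    return lines


def _true_genotype(rng: np.random.Generator, locus: ProbeLocus,
                   third_allele: str | None, het_fraction: float) -> tuple[str, ...]:
    if third_allele is not None:
        return tuple(sorted({locus.ref_allele, locus.alt_allele, third_allele}))
    if rng.random() < het_fraction:
        return tuple(sorted({locus.ref_allele, locus.alt_allele}))
    return (locus.ref_allele,) if rng.random() < 0.5 else (locus.alt_allele,)


def simulate_reads(scenario: SimulationScenario, loci: Sequence[ProbeLocus],
                   out_dir: str | Path) -> TruthSet:
    """Draw reads per locus x sample and emit per-sample SAM + FASTQ.

    Each read carries one allele of its cell's true genotype (uniform
    choice per read), optionally a planted off-target alternate at 50%
    per-read probability, and i.i.d. substitution errors; SAM records
    carry truth-known coordinates and a full-match CIGAR.  The same
    scenario (seed included) always produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)
    refs = reference_sequences(loci)

    n_tri = int(round(scenario.triallelic_fraction * len(loci)))
    tri_idx = set(map(int, rng.choice(len(loci), size=n_tri, replace=False))) if n_tri else set()
    third_alleles: dict[str, str] = {}
    for i in sorted(tri_idx):
        locus = loci[i]
        candidates = [b for b in BASES if b not in (locus.ref_allele, locus.alt_allele)]
        third_alleles[locus.locus_id] = str(rng.choice(candidates))

    non_tri = [i for i in range(len(loci)) if i not in tri_idx]
    n_off = int(round(scenario.offtarget_fraction * len(loci)))
    n_off = min(n_off, len(non_tri))
    off_idx = sorted(map(int, rng.choice(non_tri, size=n_off, replace=False))) if n_off else []
    variants: list[PlantedVariant] = []
    variant_by_locus: dict[str, PlantedVariant] = {}
    for i in off_idx:
        locus = loci[i]
        ref_seq = refs[locus.locus_id]
        offset = locus.probes[0].snp_offset
        # positions 20..99 are covered by every read of length >= 100
        choices = [p for p in range(20, min(100, len(ref_seq))) if p != offset]
        position = int(rng.choice(choices))
        ref_base = ref_seq[position]
        alt_base = str(rng.choice([b for b in BASES if b != ref_base]))
        v = PlantedVariant(reference_id=locus.locus_id, position=position,
                           ref_allele=ref_base, alt_allele=alt_base)
        variants.append(v)
        variant_by_locus[locus.locus_id] = v

    genotypes: dict[tuple[str, str], tuple[str, ...]] = {}
    read_alleles: dict[str, tuple[str, str]] = {}
    quality = scenario.phred_quality
    qual_char = chr(quality + 33)
    base_idx = {b: i for i, b in enumerate(BASES)}

    for sample in scenario.samples:
        sam_lines = _sam_header(refs)
        fastq_lines: list[str] = []
        for locus in loci:
            ref_seq = refs[locus.locus_id]
            offset = locus.probes[0].snp_offset
            genotype = _true_genotype(rng, locus, third_alleles.get(locus.locus_id),
                                      scenario.het_fraction)
            genotypes[(locus.locus_id, sample)] = genotype
            depth = int(rng.poisson(scenario.coverage))
            read_length = min(scenario.read_length, len(ref_seq))
            lo = max(0, offset - read_length + 1)
            hi = min(offset, len(ref_seq) - read_length)
            variant = variant_by_locus.get(locus.locus_id)
            for j in range(depth):
                start = int(rng.integers(lo, hi + 1)) if hi > lo else lo
                allele = str(rng.choice(genotype))
                template = list(ref_seq)
                template[offset] = allele
                off_allele = ""
                if variant is not None and rng.random() < 0.5:
                    template[variant.position] = variant.alt_allele
                    off_allele = variant.alt_allele
                bases = template[start:start + read_length]
                if scenario.error_rate > 0:
                    err = rng.random(read_length) < scenario.error_rate
                    for k in np.nonzero(err)[0]:
                        shift = int(rng.integers(1, 4))
                        bases[k] = BASES[(base_idx[bases[k]] + shift) % 4]
                seq = "".join(bases)
                read_id = f"{locus.locus_id}:{sample}:{j}"
                read_alleles[read_id] = (allele, off_allele)
                sam_lines.append("\t".join([
                    read_id, "0", locus.locus_id, str(start + 1), "60",
                    f"{read_length}M", "*", "0", "0", seq, qual_char * read_length,
                ]))
                fastq_lines += [f"@{read_id}", seq, "+", qual_char * read_length]
        (out_dir / f"{sample}.sam").write_text("\n".join(sam_lines) + "\n")
        (out_dir / f"{sample}.fastq").write_text("\n".join(fastq_lines) + "\n"
                                                 if fastq_lines else "")

    truth = TruthSet(genotypes=genotypes, triallelic_loci=sorted(third_alleles),
                     variants=variants, read_alleles=read_alleles)
    truth.write(out_dir)
    return truth


def sam_paths(out_dir: str | Path, samples: Iterable[str]) -> dict[str, Path]:
    return {s: Path(out_dir) / f"{s}.sam" for s in samples}


def simulate_genotype_matrix(n_loci: int = 500, n_samples: int = 20,
                             seed: int = 0,
                             major_freq_range: tuple[float, float] = (0.75, 0.95),
                             het_minor_prob: float = 0.3) -> GenotypeMatrix:
    """A bi-allelic genotype matrix for platform-comparison simulations.

    Each locus has a two-genotype vocabulary (major homozygote plus
    either the other homozygote or the heterozygote) with the major
    genotype frequency drawn from ``major_freq_range``; keeping the
    major genotype clearly dominant keeps rank codes stable when a
    corrupted copy of the matrix is re-encoded independently.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    data = {}
    loci = []
    for i in range(n_loci):
        locus_id = f"L{i + 1:05d}"
        loci.append(locus_id)
        ref, alt = map(str, rng.choice(BASES, size=2, replace=False))
        major = ref
        minor = "".join(sorted(ref + alt)) if rng.random() < het_minor_prob else alt
        f = rng.uniform(*major_freq_range)
        data[locus_id] = [major if rng.random() < f else minor for _ in samples]
    frame = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    frame.index.name = "locus_id"
    return GenotypeMatrix.from_frame(frame)


def _different_genotype(current: str, vocabulary: Sequence[str],
                        rng: np.random.Generator) -> str:
    others = [g for g in vocabulary if g != current]
    if others:
        return str(rng.choice(others))
    # degenerate single-genotype locus: perturb the first allele
    alt = str(rng.choice([b for b in BASES if b != current[0]]))
    return "".join(sorted(alt + current[1:]))


def simulate_platform_pair(matrix: GenotypeMatrix, discordance: float,
                           missing: float, seed: int = 0) -> GenotypeMatrix:
    """A second-platform copy of ``matrix`` with planted noise.

    Each cell is independently corrupted to a *different* valid genotype
    (drawn from the other genotypes of its locus) with probability
    ``discordance`` and set missing with probability ``missing``.
    """
    if not 0 <= discordance < 1 or not 0 <= missing <= 1:
        raise ValueError("discordance must be in [0, 1) and missing in [0, 1]")
    rng = np.random.default_rng(seed)
    frame = matrix.to_frame().copy()
    vocab = {locus: sorted({g for g in frame.loc[locus]
                            if g not in (NO_DATA_TOKEN, "LOW")})
             for locus in frame.index}
    for locus in frame.index:
        for sample in frame.columns:
            if rng.random() < missing:
                frame.loc[locus, sample] = NO_DATA_TOKEN
                continue
            current = frame.loc[locus, sample]
            if current in (NO_DATA_TOKEN, "LOW"):
                continue
            if rng.random() < discordance:
                frame.loc[locus, sample] = _different_genotype(
                    current, vocab[locus], rng)
    return GenotypeMatrix.from_frame(frame)


def simulate_phased_reads(site_positions: Sequence[int],
                          haplotypes: Sequence[tuple[str, int]],
                          reference_length: int = 120, seed: int = 0,
                          reference_id: str = "contig1",
                          quality: int = 40) -> tuple[str, list[AlignedRead]]:
    """Error-free full-length reads carrying planted phased haplotypes.

    ``haplotypes`` is a list of (allele string over the sites, number of
    reads).  Returns the background reference sequence and the reads;
    useful as exact ground truth for phasing and windowing.
    """
    rng = np.random.default_rng(seed)
    sites = sorted(site_positions)
    if sites and sites[-1] >= reference_length:
        raise ValueError("site position beyond the reference")
    reference = _random_sequence(rng, reference_length, 0.5)
    reads = []
    counter = 0
    for hap, n_reads in haplotypes:
        if len(hap) != len(sites):
            raise ValueError("haplotype length must match the number of sites")
        template = list(reference)
        for pos, allele in zip(sites, hap):
            template[pos] = allele
        seq = "".join(template)
        for _ in range(n_reads):
            reads.append(AlignedRead(
                read_id=f"hap{counter}", reference_id=reference_id,
                reference_start=0, cigar=(("M", reference_length),),
                bases=seq, base_qualities=tuple([quality] * reference_length),
                mapping_quality=60))
            counter += 1
    return reference, reads
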
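# tgbys — targeted genotyping-by-sequencing toolkit

`tgbys` analyses targeted genotyping-by-sequencing (TGbyS) data: short
sequencing reads enriched with allele-specific capture probes designed
around known SNP markers, as used to bridge array-based genotyping
(Axiom, KASP) and sequencing-based genotyping in hexaploid wheat.  It is
aimed at plant-genotyping groups who have per-sample alignments of
capture-enriched reads against probe (or contig) references and want
genotypes, cross-platform marker harmonization, off-target SNP discovery
and read-backed haplotypes — without the custom one-off scripts this
kind of pipeline usually accretes.

## What it computes

**Genotype calling.**  At each probe's target SNP the quality-filtered
allele pileup `n_b` (depth `N = Σ n_b`) is converted to a genotype by a
pure frequency rule: the call is made only when `N ≥ r_min` (default 10)
and consists of every base with `n_b / N ≥ f_min` (default 0.20), both
comparisons inclusive.  A pileup A(20), T(80) is therefore the
heterozygote AT.  Counts from the two allele-specific probes of a locus
are pooled before calling.  Loci showing three or more alleles across
samples are flagged tri-allelic — in hexaploid wheat usually a
co-captured homoeologue, and invisible to a bi-allelic array.

**Cross-platform harmonization.**  Per probe, genotype calls are ranked
by abundance into numeric codes (0 = most prevalent, 1 = next, …), which
makes calls comparable across platforms with different vocabularies.
Per-probe concordance between two platforms, selection of the
cross-platform probe subset (complete, bi-allelic, ≥ 95% of samples
matching), squared-Euclidean inter-sample distances and principal
co-ordinates (classical MDS: eigendecomposition of the double-centred
matrix −½·J·D·J) are built on the codes.

**Off-target SNP discovery.**  Every reference position is scanned with
the same depth/fraction cutoffs; exactly one qualifying alternate makes
a bi-allelic candidate, scored with a Phred-scaled binomial
likelihood-ratio quality Q = 10·log₁₀[Binom(k; N, k/N) / Binom(k; N, ε)]
and thresholded at Q ≥ 100 (ε = assumed sequencing error rate, default 1%).

**Read-backed haplotypes.**  Variant positions with two alleles each
backed by ≥ 2 reads of Phred > 20 are phased directly along individual
reads; each read's phased run is split into overlapping windows of three
consecutive SNPs (a run of m sites yields m − 2 windows; runs of two or
fewer are ignored) and catalogued per variety with read support.

**Simulator.**  `tgbys.synthetic_data` fabricates probe sets, true
genotypes, error-bearing reads (FASTQ + pre-aligned SAM) and paired
platform matrices with planted discordance, so every stage is testable
against known ground truth.

## Worked example

Library use — the calling rule on the canonical pileup:

```python
from tgbys import AlleleCounts, CallingParameters, call_genotype

call = call_genotype(AlleleCounts("BA00123", 0, {"A": 20, "T": 80}),
                     CallingParameters())
print(call.genotype, call.status.value, call.allelicity.value, call.depth)
```

prints

```
AT called heterozygous_bi 100
```

— 100 reads cover the target, both A (20%) and T (80%) clear the 20%
fraction cutoff, so the sample is heterozygous AT.

Command line — simulate a small run and genotype it:

```
tgbys simulate --out-dir demo --n-loci 50 --n-samples 4 --coverage 50 --seed 11
tgbys call --probes-fasta demo/probes.fasta --probes-tsv demo/probes.tsv \
           --alignments demo --out-dir demo/called
```

```
called 50 loci x 4 samples; 1 tri-allelic loci
```

`demo/called/genotype_matrix.tsv` then begins

```
locus_id  S01  S02  S03  S04
L00001    C    C    C    AC
L00002    T    T    C    C
```

i.e. locus L00001 is homozygous C in three samples and heterozygous AC
in S04 (cells are sorted allele strings; `NA` = no coverage, `LOW` =
coverage below the 10-read cutoff).  `demo/called/triallelic_loci.txt`
lists the one locus whose allele union across samples reached three.
Further subcommands: `tgbys compare` (concordance, cross-platform
selection, PCO), `tgbys discover` (VCF + shared variants + in-phase
contigs) and `tgbys haplotype` (3-SNP haplotype catalogue).

## Layout

- `src/tgbys/probe_model.py` — probe set model, FASTA/TSV I/O, GC statistics
- `src/tgbys/alignment_io.py` — SAM parsing, CIGAR-aware quality-filtered pileups
- `src/tgbys/genotype_caller.py` — threshold calling, pooling, tri-allelic detection
- `src/tgbys/cross_platform.py` — rank encoding, concordance, selection, distances, PCO
- `src/tgbys/variant_discovery.py` — off-target scan, quality score, VCF output
- `src/tgbys/haplotypes.py` — site detection, per-read phasing, 3-SNP windows
- `src/tgbys/synthetic_data.py` — ground-truth simulator
- `src/tgbys/cli.py` — `tgbys` console entry point
- `docs/methods.md` — models, parameters, numerical choices, limitations
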
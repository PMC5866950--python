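# Methods

## The genotyping model

Targeted genotyping by sequencing enriches genomic fragments with
allele-specific capture probes — for every SNP marker a pair of 120-mer
probes, one carrying each allele at a recorded offset and identical
elsewhere — then sequences and aligns the enriched reads back to the
probe (or longer contig) references.  A genotype is read directly off
the allele pileup at the target position.

The caller is deliberately model-free: no ploidy assumption, no
heterozygosity prior, no likelihoods.  With quality-filtered counts
`n_b` over bases b ∈ {A,C,G,T} and depth `N = Σ n_b`:

- `N = 0` → `no_data`;
- `0 < N < r_min` → `below_min_reads`;
- otherwise the genotype is `{b : n_b / N ≥ f_min}`, sorted.

Both comparisons are inclusive: a pileup of A(20), T(80) with
`f_min = 0.20` must call AT, which fixes ≥ rather than > as the
convention.  One consequence worth knowing: for `f_min > 0.25` a deep
pileup can have *no* qualifying base (four alleles each under the bar);
such a cell is reported as `no_data`.  This cannot happen at the default
0.20.

Counts from the two probes of a pair are pooled base-wise before
calling, because both probes capture the same fragment population and
the marker should fail only when the pooled evidence fails; per-probe
pileups remain available for diagnostics.  Pooling requires the probes
to agree on the target position; disagreement is a hard error rather
than a silent mis-sum.

In hexaploid wheat a capture probe frequently pulls down homoeologous
copies from the other two subgenomes, so a third allele can clear the
fraction threshold.  Tri-allelic loci are detected two ways, either of
which flags: a single call containing ≥ 3 alleles, or the union of
called alleles across samples reaching 3.  The union rule matters
because each individual sample may look cleanly bi-allelic while the
locus segregates three alleles across the panel.

### Parameters

| parameter | default | units | why |
|---|---|---|---|
| `min_reads` (`r_min`) | 10 | reads | minimum aligned reads per contig before any call |
| `min_fraction` (`f_min`) | 0.20 | fraction of counted reads | allele admission threshold; 0.20 admits up to 4 alleles but in practice 1–3 |
| `min_base_quality` | 20 | Phred | bases below this are excluded from counts *and* depth, so thresholds act on the evidence actually used |
| `min_mapping_quality` | 0 | Phred | probes are short references; by default no mapping filter |

## Alignment handling

Coordinates are 0-based half-open everywhere internally; SAM's 1-based
`POS` is converted at the parser boundary, and 1-based positions
reappear only in serialized outputs (VCF, haplotype catalogue, truth
tables).  The pileup walks each read's CIGAR: only M/=/X columns place
a query base on the reference; insertions and clips consume query,
deletions and skips consume reference and contribute nothing at the
position.  Secondary and supplementary records are excluded so a read
is never counted twice; unmapped records are ignored.  Overlapping
mate pairs are *not* deduplicated — each record counts independently —
which can double-count the inner span of short fragments; callers
wanting mate-awareness must dedupe upstream.

The SAM reader is tolerant by design: a record with an unparseable
CIGAR, a CIGAR/SEQ length disagreement or too few fields is skipped
with a warning naming the line, so one bad record cannot void a
many-probe pileup.  A mapped record naming a reference with no `@SQ`
line is a hard error, since its coordinates cannot be validated.

## Cross-platform encoding and comparison

Platforms report genotypes in incompatible vocabularies (bases vs
AA/AB/BB cluster calls), so each probe's calls are ranked by relative
abundance into integer codes: 0 for the most prevalent genotype, 1 for
the next, and so on; missing cells stay missing and the genotype→code
map is kept for audit.  Ties in abundance are broken by alphabetical
order of the genotype string.  Determinism was judged more important
than label-invariance here: with ties the code assignment necessarily
depends on the labels, so the relabelling-invariance property of the
encoding holds exactly only for tie-free abundance patterns.

Concordance between two encoded matrices is computed over their locus
and sample intersection, per locus as the fraction of
both-platform-called samples with equal codes.  The "overall"
similarity can be averaged over samples or over loci; both are
reported (`mean_similarity` is the over-samples version).

The cross-platform probe subset requires (1) a call in every sample —
no missing data, so the genotype is unambiguous; (2) not tri-allelic —
an array cannot represent the third allele; (3) at least
`ceil(min_similarity · n_compared)` matching samples.  The ceil rule
reproduces "at least 30 of 31" at the default 0.95 rather than a raw
fractional cutoff.

Inter-sample distances are squared Euclidean over code vectors,
computed pairwise-complete and rescaled by (total loci / shared loci)
so samples with different missingness stay comparable; with no missing
cells this is the plain squared Euclidean distance.  Principal
co-ordinates are classical metric MDS: the matrix is taken element-wise
as squared distances, double-centred (B = −½·J·D·J), eigendecomposed,
and coordinates are eigenvectors scaled by √eigenvalue.  Negative
eigenvalues (non-Euclidean input) are dropped with a warning;
eigenvector sign is fixed by making each axis's largest-magnitude
loading positive, since the sign is otherwise arbitrary and
reproducibility across runs matters more than any particular
orientation.

## Variant quality score

Aligner/caller QUAL fields are tool-specific; this package scores a
candidate with a transparent binomial likelihood ratio instead.  With
depth N, alt count k and assumed per-base error rate ε:

    Q = 10 · log10 [ Binom(k; N, k/N) / Binom(k; N, ε) ]
      = (10 / ln 10) · N · KL( k/N ‖ ε )

i.e. Phred-scaled evidence that the alternate reads reflect a real
allele at its observed fraction rather than sequencing error alone.
Q = 0 when k = 0, is clamped to [0, 10000], and grows roughly linearly
in depth at fixed fraction.  The same ≥ 100 threshold semantics as a
conventional caller QUAL cutoff are applied, per sample; the shared-
variant step then merges per-sample survivors.  ε defaults to 1%, a
conservative short-read error scale — conservative here means *higher*
ε, which lowers Q and admits fewer candidates.  At ε = 1%, Q ≥ 100
needs e.g. ≥ 9/40 or ≥ 13/130 alternate reads, so the 20% fraction
cutoff usually binds first at moderate depth.

Positions with two or more qualifying alternates are excluded as
non-bi-allelic rather than emitted as multi-allelic records: in
hexaploid material they are better explained by co-captured
homoeologues.  "In-phase" contigs are those carrying ≥ 3 variant
positions (no maximum spacing by default; a `max_gap` option exists).

## Haplotype windowing

Intravarietal variant sites are positions where ≥ 2 distinct bases
each have ≥ 2 supporting reads of quality strictly above Phred 20
(implemented as ≥ 21 on the integer scale).  Externally known varietal
variant positions can be merged into the site list.  Alleles are then
extracted per read — phasing is free because the bases sit on one
molecule — and each read's phased run is cut into overlapping windows
of 3 consecutive sites; a run of m sites yields max(0, m − 2) windows.

"Consecutive" means consecutive in the reference's ordered site list:
a read that covers a site but fails to report it (deletion, low
quality) breaks the run, so no window ever phases across an unobserved
position.  Mates are phased independently; identical
(positions, alleles) windows are aggregated per variety with a read
support count, and no support floor is applied by default — the
catalogue reports counts and lets downstream users threshold.

## The simulator

The generator emulates: probe pairs differing only at the SNP (i.i.d.
bases at a target GC of 0.494, matching a typical array-derived probe
set, with the SNP offset drawn uniformly in 30–90 rather than assumed
central); per-cell true genotypes (10% heterozygous by default, both
alleles at ~50:50 per read); tri-allelic loci (2% of loci, three
alleles at ~⅓ each in every sample, the homoeologue signature);
Poisson-distributed depth around a 50× mean; i.i.d. substitution
errors at 0.5% with a single per-base Phred quality consistent with
the rate; planted off-target variants carried by each read with
probability ½; and a second-platform matrix with i.i.d. per-cell
corruption.  Reads are emitted pre-aligned (SAM with truth-known
coordinates and full-match CIGARs) alongside FASTQ so no aligner sits
inside the test loop.

It does *not* model capture-efficiency variation, GC-dependent capture
failure, indels, position-dependent quality, mate pairing, mapping
ambiguity between homoeologues, or linkage between loci.  Passing
tests therefore demonstrate that the *algorithms* recover planted
truth under calibrated noise — not that real wheat capture data will
genotype at the same rates, since real failure modes (capture dropout,
mismapping) are exactly the ones the simulator omits.

For platform-pair simulations the base matrix keeps each locus's major
genotype frequency in 0.75–0.95.  Because the two matrices are
rank-encoded independently, heavy corruption of a closely balanced
locus can swap the abundance order between platforms and turn the
whole locus discordant; keeping the major genotype dominant makes such
rank swaps rare (a fraction of a percent of loci), which is why the
measured mean similarity under 15% planted discordance sits around
84–85% rather than exactly 85%.

## Numerical and design choices

- Threshold comparisons inclusive (≥) throughout the caller; strictly
  greater (>) only where the haplotype filter says "PHRED > 20".
- Fractions are computed against counted depth (post quality filter),
  not raw overlapping reads.
- Zero-coverage and sub-threshold coverage are distinct states
  (`NA` vs `LOW` in serialized matrices); `collapse_low=True` folds
  them at serialization for consumers that do not care.
- Rank-encoding ties break alphabetically; PCO axis signs fixed by
  largest loading; eigenvalue positivity tolerance is relative
  (10⁻¹² of the largest magnitude).
- Degenerate inputs: empty pileups are valid zero-depth counts; an
  all-N or empty sequence has undefined GC (error); constant groups in
  the GC comparison report the limit-case p-value (1 if means equal,
  else 0) instead of NaN; a sample pair sharing zero loci is a hard
  error naming the pair.
- Dominance class is metadata from the array design, never inferred
  from sequence.
- The probe-metadata TSV uses explicit `snp_offset` per probe; the SNP
  is not assumed central in the 120-mer.

## Problem sizes

The test suite and the acceptance script run at desk scale: 200 loci ×
8 samples at 50× for end-to-end genotype recovery (~1600 cells, ~80k
reads), 500 × 20 for platform comparison, 200 loci at 40× for variant
recovery, and an exhaustive caller/oracle sweep over all ~46k count
vectors of depth ≤ 30.  These sizes give the binomial margins the
checks rely on (e.g. a het cell at 50× misses the 20% cutoff with
probability ~10⁻⁵) while the whole suite stays in the tens of seconds.

## Known limitations

- No likelihood-based or ploidy-aware calling; allele fractions near
  the threshold flip calls stochastically at low depth.
- Read pairs are independent observations; overlapping mates can
  double-count.
- The variant quality model ignores quality heterogeneity within a
  pileup (it uses counts, not per-base qualities, beyond the admission
  filter).
- Rank codes are stable only while genotype abundance orders agree
  between platforms; closely balanced loci can rank-swap.
- BAM/CRAM input is not supported; convert to SAM upstream.
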
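"""Cross-platform genotype harmonization, concordance and ordination.

Different genotyping platforms report genotypes in incompatible
vocabularies (sequencing gives bases, arrays give AA/AB/BB cluster
calls).  To compare them, each probe's calls are ranked by relative
abundance into a numerical code: 0 for the most prevalent genotype, 1
for the next, and so on.  Rank codes are platform-agnostic, so two
platforms agree at a cell exactly when they place that sample in the
same abundance rank for that probe.

On top of the encoding this module computes per-probe concordance
between two platforms, selects the cross-platform probe subset
(complete, bi-allelic, >= 95% matching samples by default), builds
squared-Euclidean inter-sample distance matrices, and embeds samples by
principal co-ordinates analysis (classical metric MDS).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_caller import GenotypeMatrix, find_triallelic

log = logging.getLogger(__name__)

#: cell values treated as missing when encoding a genotype frame
MISSING_TOKENS = frozenset({"", "NA", "LOW", "nan", "NoCall", "---"})


@dataclass
class EncodedMatrix:
    """Rank-abundance numeric encoding of a genotype matrix.

    ``codes`` is a locus x sample float DataFrame (NaN = missing); within
    each locus, codes are consecutive integers from 0 assigned in
    non-increasing order of genotype abundance, ties broken by
    alphabetical order of the genotype string.  ``code_map`` records the
    genotype -> code assignment per locus for audit.
    """

    codes: pd.DataFrame
    code_map: dict[str, dict[str, int]]

    @property
    def loci(self) -> list[str]:
        return list(self.codes.index)

    @property
    def samples(self) -> list[str]:
        return list(self.codes.columns)

    def write_code_map(self, path: str | Path) -> None:
        rows = [{"locus_id": locus, "genotype": g, "code": c}
                for locus, mapping in self.code_map.items()
                for g, c in sorted(mapping.items(), key=lambda kv: kv[1])]
        pd.DataFrame(rows, columns=["locus_id", "genotype", "code"]).to_csv(
            path, sep="\t", index=False)


def encode_frame(frame: pd.DataFrame) -> EncodedMatrix:
    """Rank-encode a locus x sample frame of genotype strings."""
    codes = pd.DataFrame(np.nan, index=frame.index, columns=frame.columns, dtype=float)
    code_map: dict[str, dict[str, int]] = {}
    for locus in frame.index:
        row = frame.loc[locus]
        observed = row[~row.astype(str).isin(MISSING_TOKENS)]
        if observed.empty:
            log.warning("locus %s: zero called samples, row left all-missing", locus)
            code_map[str(locus)] = {}
            continue
        counts = observed.astype(str).value_counts()
        # most abundant first; equal abundance broken alphabetically
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        mapping = {genotype: rank for rank, (genotype, _) in enumerate(ranked)}
        code_map[str(locus)] = mapping
        codes.loc[locus, observed.index] = observed.astype(str).map(mapping).astype(float)
    return EncodedMatrix(codes=codes, code_map=code_map)


def encode_numeric(matrix: GenotypeMatrix | pd.DataFrame) -> EncodedMatrix:
    """Rank-encode a genotype matrix (or a genotype-string DataFrame)."""
    frame = matrix.to_frame() if isinstance(matrix, GenotypeMatrix) else matrix
    return encode_frame(frame)


def load_platform_matrix(path: str | Path,
                         vocabulary: Mapping[str, str] | None = None,
                         locus_alleles: Mapping[str, tuple[str, str]] | None = None,
                         ) -> pd.DataFrame:
    """Read a platform genotype TSV (probe x sample) with an explicit,
    auditable normalization of its genotype vocabulary.

    ``vocabulary`` maps platform symbols to templates over the locus
    allele pair: ``"ref"``/``"alt"`` (the matching homozygote),
    ``"refalt"`` (the heterozygote, emitted as the sorted allele pair) or
    ``None``/empty for missing.  Array-style exports (AA/AB/BB) thus
    become base-space genotypes comparable with sequencing calls; rank
    encoding would sidestep the letters anyway, but keeping the
    normalization explicit makes the comparison auditable.  With no
    vocabulary the cells are used verbatim.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("NA")
    frame.index = frame.index.astype(str)
    if vocabulary is None:
        return frame
    if locus_alleles is None:
        raise ValueError("a vocabulary needs locus_alleles to resolve ref/alt templates")
    out = frame.copy()
    for locus in frame.index:
        ref, alt = locus_alleles.get(locus, ("N", "N"))
        resolved = {}
        for symbol, template in vocabulary.items():
            if template in (None, ""):
                resolved[symbol] = "NA"
            elif template == "ref":
                resolved[symbol] = ref
            elif template == "alt":
                resolved[symbol] = alt
            elif template == "refalt":
                resolved[symbol] = "".join(sorted(ref + alt))
            else:
                resolved[symbol] = template
        out.loc[locus] = frame.loc[locus].map(lambda v: resolved.get(v, v))
    return out


@dataclass
class ConcordanceReport:
    """Per-probe and per-sample agreement between two encoded matrices.

    ``per_locus`` has one row per shared locus with ``n_compared``
    (samples non-missing on both platforms), ``n_matching`` and
    ``fraction``.  Whether "overall similarity" should average over
    samples or over probes is a reporting choice, so both are exposed.
    """

    per_locus: pd.DataFrame
    per_sample: pd.Series
    mean_similarity_samples: float
    mean_similarity_loci: float

    @property
    def mean_similarity(self) -> float:
        """Headline similarity: mean over samples (varieties)."""
        return self.mean_similarity_samples

    def to_tsv(self, path: str | Path) -> None:
        self.per_locus.to_csv(path, sep="\t")


def probe_concordance(enc_a: EncodedMatrix, enc_b: EncodedMatrix) -> ConcordanceReport:
    """Fraction of samples with matching rank codes, per shared probe.

    Comparison is restricted to the locus and sample intersection of the
    two matrices; cells missing on either platform are excluded from
    both numerator and denominator.
    """
    shared_loci = [l for l in enc_a.loci if l in set(enc_b.loci)]
    shared_samples = [s for s in enc_a.samples if s in set(enc_b.samples)]
    if not shared_loci:
        raise ValueError("no shared loci between the two matrices")
    if not shared_samples:
        raise ValueError("no shared samples between the two matrices")
    a = enc_a.codes.loc[shared_loci, shared_samples].to_numpy(dtype=float)
    b = enc_b.codes.loc[shared_loci, shared_samples].to_numpy(dtype=float)
    both = ~np.isnan(a) & ~np.isnan(b)
    equal = both & (a == b)
    n_compared = both.sum(axis=1)
    n_matching = equal.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(n_compared > 0, n_matching / np.maximum(n_compared, 1), np.nan)
    per_locus = pd.DataFrame(
        {"n_compared": n_compared, "n_matching": n_matching, "fraction": fraction},
        index=pd.Index(shared_loci, name="locus_id"))
    s_compared = both.sum(axis=0)
    s_matching = equal.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s_fraction = np.where(s_compared > 0, s_matching / np.maximum(s_compared, 1), np.nan)
    per_sample = pd.Series(s_fraction, index=pd.Index(shared_samples, name="sample_id"),
                           name="fraction")
    return ConcordanceReport(
        per_locus=per_locus,
        per_sample=per_sample,
        mean_similarity_samples=float(np.nanmean(s_fraction)),
        mean_similarity_loci=float(np.nanmean(fraction)),
    )


def select_cross_platform(report: ConcordanceReport, matrix: GenotypeMatrix,
                          min_similarity: float = 0.95,
                          triallelic: Sequence[str] | None = None) -> list[str]:
    """Probes reliable enough to bridge platforms.

    A locus is selected when (1) it has a genotype call in every sample
    of ``matrix`` (an unambiguous genotype — no missing data), (2) it is
    not tri-allelic (arrays cannot represent a third allele), and (3) at
    least ``ceil(min_similarity * n_compared)`` of the compared samples
    match between platforms — the >= 95% rule is "at least 30 of the 31
    varieties" rather than a raw fraction cutoff.
    """
    if triallelic is None:
        triallelic = find_triallelic(matrix)
    tri = set(triallelic)
    complete = {
        locus for locus in matrix.loci
        if all(matrix.get(locus, s).alleles for s in matrix.samples)
    }
    selected = []
    for locus, row in report.per_locus.iterrows():
        if locus not in complete or locus in tri:
            continue
        n = int(row["n_compared"])
        if n == 0:
            continue
        if int(row["n_matching"]) >= math.ceil(min_similarity * n):
            selected.append(str(locus))
    return selected


def distance_matrix(enc: EncodedMatrix) -> pd.DataFrame:
    """Squared-Euclidean distances between sample code vectors.

    Distances are computed over the loci where both samples are
    non-missing, then rescaled by (total loci / shared loci) so samples
    with different missingness stay comparable; with no missing cells
    this is exactly the plain squared-Euclidean distance.  A sample pair
    sharing zero loci is a hard error naming the pair.
    """
    samples = enc.samples
    if len(samples) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    codes = enc.codes.to_numpy(dtype=float)
    n_loci = codes.shape[0]
    present = ~np.isnan(codes)
    dist = np.zeros((len(samples), len(samples)))
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            both = present[:, i] & present[:, j]
            n_shared = int(both.sum())
            if n_shared == 0:
                raise ValueError(
                    f"samples {samples[i]!r} and {samples[j]!r} share no called loci")
            diff = codes[both, i] - codes[both, j]
            d = float(diff @ diff) * (n_loci / n_shared)
            dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=samples, columns=samples)


@dataclass
class PcoResult:
    """Principal co-ordinates embedding of a distance matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes, centred
    eigenvalues: np.ndarray  # non-increasing, positive axes only

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=cols)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def pco(dist: pd.DataFrame | np.ndarray, n_axes: int = 2) -> PcoResult:
    """Classical multidimensional scaling of a squared-distance matrix.

    The input (taken element-wise as squared distances, matching the
    squared-Euclidean matrices produced here) is double-centred as
    B = -1/2 J D J with J = I - 11'/n, eigendecomposed, and the top
    ``n_axes`` eigenvectors scaled by the square root of their
    eigenvalues become the co-ordinates.  Negative eigenvalues (a
    non-Euclidean input) are dropped with a warning; if fewer positive
    axes exist than requested, the result is truncated with a warning.
    Eigenvector signs are fixed so each axis's largest-magnitude loading
    is positive.
    """
    if isinstance(dist, pd.DataFrame):
        sample_ids = [str(s) for s in dist.index]
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        sample_ids = [f"s{i}" for i in range(d.shape[0])]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if (d < -1e-12).any():
        raise ValueError("distance matrix must be non-negative")
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    if (eigvals < -tol).any():
        warnings.warn(
            f"{int((eigvals < -tol).sum())} negative eigenvalue(s) dropped: "
            "input is not Euclidean-embeddable", stacklevel=2)
    n_pos = int((eigvals > tol).sum())
    k = min(n_axes, n_pos)
    if k < n_axes:
        warnings.warn(f"only {k} positive axes available, result truncated from "
                      f"{n_axes}", stacklevel=2)
    vals = eigvals[:k]
    coords = eigvecs[:, :k] * np.sqrt(vals)
    for axis in range(k):
        imax = int(np.argmax(np.abs(coords[:, axis])))
        if coords[imax, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    return PcoResult(sample_ids=sample_ids, coordinates=coords, eigenvalues=vals)
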
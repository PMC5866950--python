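"""Threshold genotype calling, probe-pair pooling and tri-allelic detection."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgbys.alignment_io import AlleleCounts
from tgbys.genotype_caller import (Allelicity, CallingParameters, CallStatus,
                                   GenotypeMatrix, ProbePairError, call_genotype,
                                   call_locus, call_matrix, find_triallelic,
                                   pool_counts)

DEFAULTS = CallingParameters()


def counts(**kwargs):
    return AlleleCounts("c1", 0, kwargs)


@pytest.mark.parametrize("pileup, alleles, status, allelicity", [
    ({"A": 20, "T": 80}, ("A", "T"), CallStatus.CALLED, Allelicity.HETEROZYGOUS_BI),
    ({"A": 9}, (), CallStatus.BELOW_MIN_READS, Allelicity.NOT_CALLED),
    ({"A": 10}, ("A",), CallStatus.CALLED, Allelicity.MONOMORPHIC),
    ({"G": 100}, ("G",), CallStatus.CALLED, Allelicity.MONOMORPHIC),
    ({"A": 34, "C": 33, "G": 33}, ("A", "C", "G"), CallStatus.CALLED,
     Allelicity.TRI_OR_MORE),
    ({"A": 19, "T": 81}, ("T",), CallStatus.CALLED, Allelicity.MONOMORPHIC),
    ({}, (), CallStatus.NO_DATA, Allelicity.NOT_CALLED),
])
def test_calling_rule(pileup, alleles, status, allelicity):
    call = call_genotype(counts(**pileup), DEFAULTS)
    assert (call.alleles, call.status, call.allelicity) == (alleles, status, allelicity)


def test_threshold_is_inclusive():
    """Exactly 20% of reads passes the fraction cutoff, exactly 10 reads
    passes the depth cutoff — the A(20)/T(80) -> AT example fixes both."""
    assert call_genotype(counts(A=2, T=8), DEFAULTS).alleles == ("A", "T")
    assert call_genotype(counts(A=10), DEFAULTS).status is CallStatus.CALLED


def test_no_allele_reaches_fraction():
    params = CallingParameters(min_reads=10, min_fraction=0.30)
    call = call_genotype(counts(A=3, C=3, G=3, T=3), params)
    assert call.status is CallStatus.NO_DATA and not call.alleles


def _oracle(pileup, params):
    """Two-threshold rule coded literally, independent of the caller."""
    depth = sum(pileup.values())
    if depth == 0:
        return ("no_data", ())
    if depth < params.min_reads:
        return ("below_min_reads", ())
    alleles = tuple(sorted(b for b, n in pileup.items()
                           if n / depth >= params.min_fraction))
    return ("called", alleles) if alleles else ("no_data", ())


def test_caller_matches_oracle_exhaustively_to_depth_14():
    """Exhaustive equivalence on every 4-base count vector of depth <= 14
    (the full depth <= 30 sweep lives with the end-to-end checks)."""
    for depth in range(15):
        for a, c, g in itertools.product(range(depth + 1), repeat=3):
            t = depth - a - c - g
            if t < 0:
                continue
            pileup = {b: n for b, n in zip("ACGT", (a, c, g, t)) if n}
            call = call_genotype(counts(**pileup), DEFAULTS)
            assert (call.status.value, call.alleles) == _oracle(pileup, DEFAULTS)


@settings(derandomize=True, max_examples=100)
@given(
    pileup=st.fixed_dictionaries({}, optional={
        b: st.integers(min_value=1, max_value=50) for b in "ACGT"}),
    scale=st.integers(min_value=2, max_value=5),
)
def test_fraction_invariance_under_scaling(pileup, scale):
    """Once depth clears the cutoff, multiplying all counts by a positive
    integer never changes the allele set."""
    base = call_genotype(counts(**pileup), DEFAULTS)
    scaled = call_genotype(counts(**{b: n * scale for b, n in pileup.items()}), DEFAULTS)
    if base.status is CallStatus.CALLED:
        assert scaled.alleles == base.alleles


@settings(derandomize=True, max_examples=100)
@given(pileup=st.fixed_dictionaries({}, optional={
    b: st.integers(min_value=1, max_value=60) for b in "ACGT"}))
def test_fraction_above_half_calls_at_most_one_allele(pileup):
    strict = CallingParameters(min_reads=1, min_fraction=0.51)
    assert len(call_genotype(counts(**pileup), strict).alleles) <= 1


@settings(derandomize=True, max_examples=100)
@given(
    pileup=st.fixed_dictionaries({"A": st.integers(10, 60)}, optional={
        b: st.integers(min_value=1, max_value=30) for b in "CGT"}),
    extra=st.integers(min_value=1, max_value=40),
)
def test_monotonicity_adding_reads_of_called_allele(pileup, extra):
    before = call_genotype(counts(**pileup), DEFAULTS)
    for allele in before.alleles:
        boosted = dict(pileup)
        boosted[allele] = boosted.get(allele, 0) + extra
        after = call_genotype(counts(**boosted), DEFAULTS)
        assert allele in after.alleles


def test_pooling_rescues_split_coverage(small_loci):
    """Two probes each below the depth cutoff pool to a confident call."""
    locus = small_loci[0]
    offset = locus.probes[0].snp_offset
    per_probe = [AlleleCounts(p.probe_id, offset, {"A": 6}) for p in locus.probes]
    call = call_locus(locus, per_probe, DEFAULTS)
    assert call.status is CallStatus.CALLED and call.alleles == ("A",)
    assert call.depth == 12


def test_pooling_still_fails_below_cutoff(small_loci):
    locus = small_loci[0]
    offset = locus.probes[0].snp_offset
    per_probe = [AlleleCounts(locus.probes[0].probe_id, offset, {"A": 4}),
                 AlleleCounts(locus.probes[1].probe_id, offset, {"T": 4})]
    assert call_locus(locus, per_probe, DEFAULTS).status is CallStatus.BELOW_MIN_READS


def test_single_probe_locus_degenerates_to_plain_call(small_loci):
    locus = small_loci[1]
    offset = locus.probes[0].snp_offset
    single = [AlleleCounts(locus.probes[0].probe_id, offset, {"A": 20, "T": 80})]
    call = call_locus(locus, single, DEFAULTS)
    direct = call_genotype(single[0], DEFAULTS)
    assert call.alleles == direct.alleles == ("A", "T")


def test_pair_position_mismatch_is_hard_error(small_loci):
    locus = small_loci[0]
    per_probe = [AlleleCounts("p1", 10, {"A": 20}), AlleleCounts("p2", 11, {"A": 20})]
    with pytest.raises(ProbePairError, match=locus.locus_id):
        call_locus(locus, per_probe, DEFAULTS)


def test_pool_counts_sums_basewise():
    pooled = pool_counts([AlleleCounts("p1", 5, {"A": 3, "T": 2}),
                          AlleleCounts("p2", 5, {"A": 1, "G": 4})], "L")
    assert pooled.counts == {"A": 4, "T": 2, "G": 4}


def _matrix(cells):
    """cells: {locus: {sample: 'AT' | 'NA' | 'LOW'}} -> GenotypeMatrix."""
    import pandas as pd

    frame = pd.DataFrame(cells).T
    frame.index.name = "locus_id"
    return GenotypeMatrix.from_frame(frame)


@pytest.mark.parametrize("cells, expected", [
    ({"L1": {"s1": "A", "s2": "AT"}}, []),           # union {A,T}: bi-allelic
    ({"L1": {"s1": "AT", "s2": "C"}}, ["L1"]),       # union {A,C,T}
    ({"L1": {"s1": "ACG", "s2": "NA"}}, ["L1"]),     # single tri call
    ({"L1": {"s1": "NA", "s2": "NA"}}, []),
])
def test_find_triallelic_union_rule(cells, expected):
    assert find_triallelic(_matrix(cells)) == expected


def test_matrix_tsv_round_trip(tmp_path):
    matrix = _matrix({"L1": {"s1": "AT", "s2": "NA"}, "L2": {"s1": "G", "s2": "LOW"}})
    matrix.to_tsv(tmp_path / "m.tsv")
    reloaded = GenotypeMatrix.from_tsv(tmp_path / "m.tsv")
    assert reloaded.to_frame().equals(matrix.to_frame())
    assert reloaded.get("L2", "s2").status is CallStatus.BELOW_MIN_READS


def test_collapse_low_on_serialization(tmp_path):
    matrix = _matrix({"L1": {"s1": "LOW", "s2": "A"}})
    matrix.to_tsv(tmp_path / "m.tsv", collapse_low=True)
    reloaded = GenotypeMatrix.from_tsv(tmp_path / "m.tsv")
    assert reloaded.get("L1", "s1").status is CallStatus.NO_DATA


def test_unreadable_sample_becomes_no_data_column(scenario, tmp_path):
    sc, loci, out_dir, _ = scenario
    alignments = {"S01": out_dir / "S01.sam", "GONE": tmp_path / "missing.sam"}
    matrix = call_matrix(loci[:5], alignments)
    assert all(matrix.get(l.locus_id, "GONE").status is CallStatus.NO_DATA
               for l in loci[:5])
    assert any(matrix.get(l.locus_id, "S01").status is CallStatus.CALLED
               for l in loci[:5])


def test_call_matrix_recovers_simulated_truth(scenario):
    sc, loci, out_dir, truth = scenario
    from tgbys.synthetic_data import sam_paths

    matrix = call_matrix(loci, sam_paths(out_dir, sc.samples))
    cells = [(l, s) for l in matrix.loci for s in matrix.samples]
    matching = sum(matrix.get(l, s).alleles == truth.genotypes[(l, s)]
                   for l, s in cells)
    assert matching / len(cells) >= 0.99
    assert set(truth.triallelic_loci) <= set(find_triallelic(matrix))


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        CallingParameters(min_reads=0)
    with pytest.raises(ValueError):
        CallingParameters(min_fraction=0.0)
    with pytest.raises(ValueError):
        CallingParameters(min_fraction=1.2)
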
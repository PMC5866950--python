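"""Rank encoding, concordance, probe selection, distances and PCO."""

import numpy as np
import pandas as pd
import pytest

from tgbys.cross_platform import (distance_matrix, encode_frame, encode_numeric,
                                  load_platform_matrix, pco, probe_concordance,
                                  select_cross_platform)
from tgbys.genotype_caller import GenotypeMatrix


def frame(cells):
    f = pd.DataFrame(cells).T
    f.index.name = "locus_id"
    return f


def test_encoding_by_abundance():
    enc = encode_frame(frame({"L1": {"s1": "AA", "s2": "AA", "s3": "AT"}}))
    assert list(enc.codes.loc["L1"]) == [0.0, 0.0, 1.0]
    assert enc.code_map["L1"] == {"AA": 0, "AT": 1}


def test_encoding_all_identical():
    enc = encode_frame(frame({"L1": {"s1": "G", "s2": "G", "s3": "G"}}))
    assert list(enc.codes.loc["L1"]) == [0.0, 0.0, 0.0]


def test_encoding_tie_broken_alphabetically():
    enc = encode_frame(frame({"L1": {"s1": "AT", "s2": "AT", "s3": "AC", "s4": "AC"}}))
    # equal abundance: AC (earlier) takes code 0
    assert enc.code_map["L1"] == {"AC": 0, "AT": 1}


def test_encoding_missing_cells_stay_missing():
    enc = encode_frame(frame({"L1": {"s1": "A", "s2": "NA", "s3": "LOW"}}))
    row = enc.codes.loc["L1"]
    assert row["s1"] == 0.0 and np.isnan(row["s2"]) and np.isnan(row["s3"])


def test_encoding_invariant_under_allele_relabelling():
    """With strictly ordered abundances, codes depend only on the
    equivalence classes, not the letters (ties instead break on the
    genotype string, which is deliberately label-dependent)."""
    base = frame({"L1": {"s1": "AA", "s2": "AA", "s3": "AA", "s4": "GG",
                         "s5": "GG", "s6": "AG"}})
    relabelled = base.replace({"AA": "TT", "GG": "CC", "AG": "CT"})
    assert encode_frame(base).codes.equals(encode_frame(relabelled).codes)


def test_concordance_self_is_one():
    enc = encode_frame(frame({"L1": {"s1": "A", "s2": "T"},
                              "L2": {"s1": "G", "s2": "G"}}))
    report = probe_concordance(enc, enc)
    assert (report.per_locus["fraction"] == 1.0).all()
    assert report.mean_similarity == 1.0


def test_concordance_single_flip():
    cells = {f"s{i}": "A" for i in range(10)}
    enc_a = encode_frame(frame({"L1": cells, "L2": cells}))
    flipped = frame({"L1": {**cells, "s0": "T"}, "L2": cells})
    report = probe_concordance(enc_a, encode_frame(flipped))
    assert report.per_locus.loc["L1", "fraction"] == pytest.approx(0.9)
    assert report.per_locus.loc["L2", "fraction"] == 1.0


def test_concordance_requires_shared_loci():
    enc_a = encode_frame(frame({"L1": {"s1": "A", "s2": "T"}}))
    enc_b = encode_frame(frame({"L9": {"s1": "A", "s2": "T"}}))
    with pytest.raises(ValueError, match="shared loci"):
        probe_concordance(enc_a, enc_b)


def _report_and_matrix(cells):
    matrix = GenotypeMatrix.from_frame(frame(cells))
    enc = encode_numeric(matrix)
    return probe_concordance(enc, enc), matrix


def test_selection_requires_completeness():
    report, matrix = _report_and_matrix(
        {"L1": {f"s{i}": "A" for i in range(10)},
         "L2": {**{f"s{i}": "A" for i in range(9)}, "s9": "NA"}})
    assert select_cross_platform(report, matrix) == ["L1"]


def test_selection_excludes_triallelic():
    report, matrix = _report_and_matrix(
        {"L1": {"s1": "AT", "s2": "C", "s3": "AT"},   # union {A,C,T}
         "L2": {"s1": "A", "s2": "A", "s3": "T"}})
    assert select_cross_platform(report, matrix) == ["L2"]


def test_selection_ceil_rule_mirrors_30_of_31():
    """>= 95% over 31 samples means at least ceil(29.45) = 30 matching."""
    cells = {f"s{i:02d}": "A" for i in range(31)}
    matrix = GenotypeMatrix.from_frame(frame({"L1": cells}))
    enc_a = encode_numeric(matrix)
    one_off = frame({"L1": {**cells, "s00": "T"}})
    report = probe_concordance(enc_a, encode_frame(one_off))
    assert report.per_locus.loc["L1", "n_matching"] == 30
    assert select_cross_platform(report, matrix) == ["L1"]
    two_off = frame({"L1": {**cells, "s00": "T", "s01": "T"}})
    report2 = probe_concordance(enc_a, encode_frame(two_off))
    assert select_cross_platform(report2, matrix) == []


def test_selection_monotone_in_threshold():
    rng = np.random.default_rng(5)
    cells = {f"L{i}": {f"s{j}": "A" for j in range(20)} for i in range(30)}
    matrix = GenotypeMatrix.from_frame(frame(cells))
    noisy = matrix.to_frame().copy()
    for locus in noisy.index:
        for sample in noisy.columns:
            if rng.random() < 0.1:
                noisy.loc[locus, sample] = "T"
    report = probe_concordance(encode_numeric(matrix), encode_frame(noisy))
    previous = None
    for threshold in (0.80, 0.90, 0.95, 1.0):
        selected = set(select_cross_platform(report, matrix, min_similarity=threshold))
        if previous is not None:
            assert selected <= previous
        previous = selected


def test_distance_hand_example():
    enc = encode_frame(frame({"L1": {"a": "A", "b": "A"},
                              "L2": {"a": "A", "b": "T"},
                              "L3": {"a": "T", "b": "A"}}))
    # codes per locus: L1 (0,0) tie->alphabetical, L2/L3 majority ties broken
    dist = distance_matrix(enc)
    assert dist.loc["a", "b"] == pytest.approx(2.0)
    assert dist.loc["a", "a"] == 0.0
    assert np.allclose(dist, dist.T)


def test_distance_identical_columns_zero():
    enc = encode_frame(frame({"L1": {"a": "A", "b": "A", "c": "T"}}))
    assert distance_matrix(enc).loc["a", "b"] == 0.0


def test_distance_pairwise_complete_rescaling():
    """A missing cell drops that locus from the pair and rescales by
    total/shared, keeping distances comparable."""
    enc = encode_frame(frame({"L1": {"a": "A", "b": "T"},
                              "L2": {"a": "A", "b": "NA"}}))
    # shared loci = 1 of 2, raw squared distance 1 -> scaled to 2
    assert distance_matrix(enc).loc["a", "b"] == pytest.approx(2.0)


def test_distance_zero_shared_loci_names_pair():
    enc = encode_frame(frame({"L1": {"a": "A", "b": "NA"},
                              "L2": {"a": "NA", "b": "T"}}))
    with pytest.raises(ValueError, match="'a' and 'b'"):
        distance_matrix(enc)


def test_pco_three_collinear_points():
    # points at 0, 1, 2 on a line: squared distances 1, 1, 4
    d = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 1.0], [4.0, 1.0, 0.0]])
    result = pco(d, n_axes=2)
    assert result.coordinates.shape[1] == 1  # second axis is degenerate
    axis1 = result.coordinates[:, 0]
    assert np.allclose(sorted(axis1), [-1, 0, 1], atol=1e-9)


def test_pco_round_trip_on_2d_cloud():
    rng = np.random.default_rng(42)
    points = rng.normal(size=(10, 2))
    sq = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    result = pco(sq, n_axes=2)
    rec = ((result.coordinates[:, None, :] - result.coordinates[None, :, :]) ** 2).sum(axis=2)
    assert np.allclose(rec, sq, atol=1e-8)
    assert np.allclose(result.coordinates.mean(axis=0), 0, atol=1e-9)
    assert result.eigenvalues[0] >= result.eigenvalues[-1]


def test_pco_duplicated_sample_identical_coordinates():
    points = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [3.0, 0.0]])
    sq = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    result = pco(sq, n_axes=2)
    assert np.allclose(result.coordinates[1], result.coordinates[2], atol=1e-9)


def test_pco_warns_on_non_euclidean_input():
    d = np.array([[0.0, 100.0, 1.0], [100.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
    d = d + d.T  # keep symmetric; triangle-violating squared distances
    with pytest.warns(UserWarning, match="negative eigenvalue"):
        pco(d / 2, n_axes=3)


def test_platform_matrix_normalization(tmp_path):
    path = tmp_path / "axiom.tsv"
    path.write_text("probe_id\ts1\ts2\ts3\nL1\tAA\tAB\tNoCall\n")
    normalized = load_platform_matrix(
        path, vocabulary={"AA": "ref", "AB": "refalt", "BB": "alt", "NoCall": None},
        locus_alleles={"L1": ("A", "T")})
    assert list(normalized.loc["L1"]) == ["A", "AT", "NA"]
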
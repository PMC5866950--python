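import pytest

from tgbys.alignment_io import AlignedRead, parse_cigar
from tgbys.synthetic_data import (SimulationScenario, simulate_probe_set,
                                  simulate_reads)


def make_read(bases, start=0, cigar=None, quals=None, read_id="r1",
              reference_id="c1", mapq=60):
    """Construct an AlignedRead with sensible defaults for unit tests."""
    if cigar is None:
        cigar = f"{len(bases)}M"
    if quals is None:
        quals = [30] * len(bases)
    return AlignedRead(read_id=read_id, reference_id=reference_id,
                       reference_start=start, cigar=parse_cigar(cigar),
                       bases=bases, base_qualities=tuple(quals),
                       mapping_quality=mapq)


@pytest.fixture
def read_factory():
    return make_read


@pytest.fixture(scope="session")
def small_loci():
    """A dozen simulated probe loci."""
    return simulate_probe_set(12, seed=11)


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """A small but complete simulated capture run: 40 loci, 4 samples,
    50x coverage, 0.5% errors, 10% het cells, 5% tri-allelic loci."""
    sc = SimulationScenario(
        n_loci=40, samples=tuple(f"S{i + 1:02d}" for i in range(4)),
        coverage=50.0, error_rate=0.005, het_fraction=0.10,
        triallelic_fraction=0.05, seed=7)
    loci = simulate_probe_set(sc.n_loci, seed=sc.seed)
    out_dir = tmp_path_factory.mktemp("scenario")
    truth = simulate_reads(sc, loci, out_dir)
    return sc, loci, out_dir, truth
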
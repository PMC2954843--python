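import numpy as np
import pytest

from popscan.genotypes import GenotypeDataset, Marker, SampleInfo


def make_dataset(calls, positions=None, chrom="1", sample_prefix="s",
                 alleles=("A", "C")):
    """Small literal dataset: calls is (n_samples, n_markers)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = [(j + 1) * 1000 for j in range(m)]
    markers = [Marker(f"m{j + 1}", chrom, int(positions[j]), *alleles)
               for j in range(m)]
    samples = [SampleInfo(id=f"{sample_prefix}{i + 1}") for i in range(n)]
    return GenotypeDataset(markers, samples, calls)


@pytest.fixture
def toy_dataset():
    return make_dataset([[0, 1, 2, 0], [2, 1, 0, 0], [1, 1, 1, -1]])


@pytest.fixture(scope="session")
def balding_nichols_pair():
    """Two cohorts with clear differentiation for structure tests."""
    from popscan.simulate import ChromLayout, SimulationConfig, \
        simulate_structured_cohort
    cfg = SimulationConfig(seed=11, n_pop1=50, n_pop2=50,
                           layout=ChromLayout([("1", 2000)]), fst=0.05,
                           missing_rate=0.0)
    return simulate_structured_cohort(cfg)
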
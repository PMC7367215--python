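import numpy as np
import pytest

from popaf import simulate


@pytest.fixture(scope="session")
def small_spec():
    return simulate.CohortSpec(n_samples=40, n_loci=1200, n_pops=3, fst=0.1,
                               missing_rate=0.02, known_fraction=0.9, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate.simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_sample_vcf(small_cohort, tmp_path_factory):
    _gm, truth = small_cohort
    out = tmp_path_factory.mktemp("vcf") / "s1.vcf"
    return simulate.emit_sample_vcf(truth, 0, out, extra_loci=300, indel_fraction=0.2)


def write_toy_vcf(path, records, sample="S1"):
    """records: iterable of (chrom, pos, ref, alt, gt) with gt in {1,2}."""
    import pandas as pd

    from popaf.vcfio import write_sample_vcf

    df = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt", "gt"])
    write_sample_vcf(df, sample, path)
    return path


@pytest.fixture
def toy_vcf_writer():
    return write_toy_vcf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
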
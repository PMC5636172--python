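import numpy as np
import pytest

from dosagekin.io_formats import DosagePanel, SnpId


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_snp_ids(m):
    return [SnpId("1", i + 1, "A", "C") for i in range(m)]


def random_panel(rng, n=10, m=50, rsq=None):
    """A small random dosage panel with HWE-ish genotype-like dosages."""
    p = rng.uniform(0.1, 0.9, m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(float)
    if rsq is None:
        rsq = np.ones(m)
    return DosagePanel(
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=make_snp_ids(m),
        dosages=dosages,
        rsq=np.asarray(rsq, dtype=float),
    )


@pytest.fixture
def small_panel(rng):
    return random_panel(rng)


def write_vcf_text(path, body, samples=("A", "B", "C")):
    """Write a minimal dosage VCF with the given variant lines."""
    header = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=DR2,Number=1,Type=Float,Description="dosage r2">\n'
        '##INFO=<ID=R2,Number=1,Type=Float,Description="dosage r2">\n'
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="dosage">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    path.write_text(header + body)
    return path
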
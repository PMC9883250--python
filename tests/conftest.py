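import numpy as np
import pytest

from warblerdiv.synthetic import SyntheticConfig, generate_dataset

SAMPLE_MAP = {"S1": "south", "S2": "south", "N1": "north", "N2": "north"}

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1,length=100000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tN1\tN2\n"
)


def write_vcf(path, body_lines):
    path.write_text(VCF_HEADER + "".join(line + "\n" for line in body_lines))
    return str(path)


@pytest.fixture
def sample_map():
    return dict(SAMPLE_MAP)


@pytest.fixture(scope="session")
def synth_dataset(tmp_path_factory):
    """A small synthetic region with equal-size SI truth (T = 7e5)."""
    out = tmp_path_factory.mktemp("synth")
    cfg = SyntheticConfig(region_length=60_000, seed=7)
    ds = generate_dataset(cfg, str(out))
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
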
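import pytest
from hypothesis import settings

from mhscreen.synthetic_data import SimConfig
from mhscreen.synthetic_data import index_family as make_index_family

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def index_family():
    """Deterministic index-family fixture (pedigree, phase, depths)."""
    return make_index_family()


@pytest.fixture()
def sim_config():
    return SimConfig(seed=7)


def write_vcf(path, samples, rows):
    """Write a minimal GT-only VCF for screen tests.

    ``rows`` are (chrom, pos, ref, alt, [genotype strings]).
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for chrom, pos, ref, alt, gts in rows:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")
    return path
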
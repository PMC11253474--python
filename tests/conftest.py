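import io

import pytest

from bulkmap.annotation import GenomeAnnotation
from bulkmap.simulate import simulate_toy_genome
from bulkmap.variant_io import parse_role_assignment


def make_vcf(samples, records, fmt="AD"):
    """Build minimal VCF text.

    records: iterable of (chrom, pos, ref, alt, {sample: "a,b"}) tuples;
    the per-sample value string is written verbatim under FORMAT.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for chrom, pos, ref, alt, per_sample in records:
        vals = "\t".join(per_sample[s] for s in samples)
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t{vals}")
    return "\n".join(lines) + "\n"


@pytest.fixture
def vcf_stream():
    def _make(samples, records, fmt="AD"):
        return io.StringIO(make_vcf(samples, records, fmt))

    return _make


@pytest.fixture(scope="session")
def toy():
    return simulate_toy_genome(5, seed=7)


@pytest.fixture(scope="session")
def toy_ann(toy):
    return GenomeAnnotation.from_gff3(toy.gff3)


@pytest.fixture(scope="session")
def big_toy():
    """50-gene fixture for locate-vs-linear-scan equivalence."""
    return simulate_toy_genome(50, seed=11)


@pytest.fixture
def mbs_roles():
    return parse_role_assignment("R,D,Pr,Pd", "mbs")
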
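import numpy as np
import pysam
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Shared small simulation: 200 kb, 10 deletions + 10 insertions
    sized 1-50, 20x error-free reads."""
    from indelscout import simulate_dataset

    d = tmp_path_factory.mktemp("smallsim")
    return simulate_dataset(
        str(d), seed=5, length=200_000, n_del=10, n_ins=10,
        size_sampler=(1, 50), error_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_callset(small_bundle):
    from indelscout import CallOptions, call_indels

    return call_indels(small_bundle.bam_path, small_bundle.fasta_path, CallOptions())


def make_bam(path, reads, ref_len=100000, chrom="chr1", rg="sim"):
    """Write a tiny BAM from (name, flag, pos, mapq, cigar, seq, mpos, tlen)
    tuples; returns the path."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": ref_len}],
        "RG": [{"ID": rg, "SM": "s"}],
    }
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for name, flag, pos, mapq, cigar, seq, mpos, tlen in reads:
            seg = pysam.AlignedSegment()
            seg.query_name = name
            seg.flag = flag
            seg.reference_id = 0
            seg.reference_start = pos
            seg.mapping_quality = mapq
            if cigar:
                seg.cigarstring = cigar
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            seg.next_reference_id = 0
            seg.next_reference_start = mpos
            seg.template_length = tlen
            seg.set_tag("RG", rg)
            bam.write(seg)
    pysam.index(str(path))
    return str(path)
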
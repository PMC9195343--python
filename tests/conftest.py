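import numpy as np
import pytest

from erodekit.formats import AlignmentRecord, SampleCall, VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_read(
    name="r1", ref="c1", start=100, end=150, strand="+",
    mapq=40, quals=None, merged=True, primary=True,
):
    if quals is None:
        quals = tuple([30] * (end - start))
    return AlignmentRecord(
        query_name=name, ref_name=ref, start=start, end=end, strand=strand,
        mapq=mapq, base_qualities=tuple(quals), is_merged=merged,
        is_primary=primary,
    )


def make_variant(
    chrom="c1", pos=100, ref="A", alts=("G",), qual=60.0, mq=60.0,
    sample="s1", gt=(0, 1), dp=20, ad=(10, 10),
):
    calls = {sample: SampleCall(genotype=gt, dp=dp, ad=ad)}
    return VariantRecord(
        chrom=chrom, pos=pos, ref_allele=ref, alt_alleles=tuple(alts),
        site_qual=qual, map_qual=mq, calls=calls,
    )
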
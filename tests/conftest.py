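import numpy as np
import pytest

from stresslnc.annotation_model import GenomicInterval, TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_tx(tid, chrom, strand, exons, biotype="noncoding", source="de-novo"):
    return TranscriptModel(
        tid,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        biotype=biotype,
        source=source,
    )


@pytest.fixture
def tx_factory():
    return make_tx
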
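import numpy as np
import pytest

import riboqueue as rq


def make_track(counts, library_size=None, tx="tx1", condition=None):
    counts = np.asarray(counts, dtype=np.int64)
    size = int(counts.sum()) if library_size is None else library_size
    track = rq.CoverageTrack(
        transcript_id=tx, counts=counts, library_size=size, condition=condition
    )
    track.rpm = counts * (1e6 / size) if size > 0 else counts.astype(float)
    return track


def make_orf(cds_len=300, utr3_len=90, cds_start=30, tx="tx1", seq=None, pad=20):
    """A minimal ORF whose sequence is AAA-codons ending ...AAA TAA."""
    if seq is None:
        seq = "AAA" * (cds_len // 3 - 1) + "TAA"
    return rq.OrfAnnotation(
        transcript_id=tx,
        cds_start=cds_start,
        cds_end=cds_start + cds_len,
        utr3_len=utr3_len,
        tx_len=cds_start + cds_len + utr3_len + pad,
        cds_seq=seq,
    )


@pytest.fixture
def small_sim_config():
    return rq.SimConfig(n_orfs=30, seed=11)


@pytest.fixture
def flat_track_and_orf():
    """Constant positive RPM everywhere, paired with a fitting ORF."""
    orf = make_orf(cds_len=300)
    track = make_track(np.full(orf.tx_len, 4))
    return track, orf
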
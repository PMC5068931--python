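import pytest

from transeval.io import HitRecord, SequenceSet, SeqEntry


@pytest.fixture
def make_hit():
    """HitRecord factory with sensible defaults; coordinates are 1-based inclusive."""

    def _make(
        query="c1",
        subject="r1",
        qs=1,
        qe=100,
        ss=1,
        se=100,
        identity=100.0,
        bitscore=200.0,
        evalue=0.0,
        length=None,
    ):
        return HitRecord(
            query_id=query,
            subject_id=subject,
            pct_identity=identity,
            aln_length=length if length is not None else abs(qe - qs) + 1,
            mismatches=0,
            gap_opens=0,
            q_start=qs,
            q_end=qe,
            s_start=ss,
            s_end=se,
            evalue=evalue,
            bitscore=bitscore,
        )

    return _make


@pytest.fixture
def make_set():
    """SequenceSet factory from a {id: sequence} mapping."""

    def _make(seqs, alphabet="nucleotide"):
        return SequenceSet(
            records=[SeqEntry(k, v) for k, v in seqs.items()], alphabet=alphabet
        )

    return _make
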
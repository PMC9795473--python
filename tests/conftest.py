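import numpy as np
import pytest

from asmqc.misassembly import AlignmentBlock


def mk_block(contig="c1", qs=0, qe=100, strand="+", rep="r1", ts=0, te=100,
             n_match=None, aln_cols=None):
    span = min(qe - qs, te - ts)
    return AlignmentBlock(
        contig_id=contig, q_start=qs, q_end=qe, strand=strand,
        replicon_id=rep, t_start=ts, t_end=te,
        n_match=span if n_match is None else n_match,
        aln_cols=span if aln_cols is None else aln_cols)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_seq(rng, n, gc=0.5):
    bases = np.array(list("ACGT"))
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(bases[rng.choice(4, size=n, p=p)])
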
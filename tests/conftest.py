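import numpy as np
import pytest

from mirsvm import corpus
from mirsvm.seqdata import MirnaSeq, UtrSeq

COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small deterministic synthetic corpus shared by read-only tests."""
    spec = corpus.SyntheticSpec(n_pos=8, n_neg=8, utr_len=250, seed=7)
    return corpus.generate_synthetic(spec)


def make_perfect_pair(mirna_seq: str = "UGAGGUAGUAGGUUGUAUAGUU",
                      flank: int = 30):
    """A miRNA and a UTR carrying its exact 20-nt complement once, on a
    poly-C background that cannot pair with anything."""
    mirna = MirnaSeq(id="mir", seq=mirna_seq)
    target = revcomp(mirna.seq[:20])
    bg = "C" * flank
    utr = UtrSeq(id="utr", seq=bg + target + bg)
    seed_start = flank + len(target) - 8
    return mirna, utr, seed_start
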
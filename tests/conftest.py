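import random

import pytest

from plexprimer.config import DesignConfig
from plexprimer.genome_index import QualityScore
from plexprimer.primer_search import PrimerCandidate, PrimerPair
from plexprimer.seq import revcomp


@pytest.fixture
def cfg():
    return DesignConfig()


def random_genome(rng: random.Random, n: int, gc: float = 0.5) -> str:
    return "".join(
        rng.choice("GC") if rng.random() < gc else rng.choice("AT") for _ in range(n)
    )


def count_overlapping(hay: str, needle: str) -> int:
    total = 0
    i = hay.find(needle)
    while i != -1:
        total += 1
        i = hay.find(needle, i + 1)
    return total


def brute_kmer_count(seqs: dict, kmer: str) -> int:
    """Independent two-strand occurrence count by plain string scanning."""
    total = 0
    for seq in seqs.values():
        up = seq.upper()
        total += count_overlapping(up, kmer)
        total += count_overlapping(up, revcomp(kmer))
    return total


# Stub primer pairs for pooling tests.  A/C-only primer alphabets are inert:
# their reverse complements are G/T-only, so no complementary run of any
# length can form between two of them, and an all-T amplicon interior admits
# no 3'-word annealing as long as each primer's last 7 bases include a C.
_FWD_DEFAULT = "ACCACAACCACAACCACC"
_REV_DEFAULT = "CACCACCAACACCACCAC"


def make_stub_pair(
    chrom: str = "chr1",
    start: int = 0,
    length: int = 280,
    tm: float = 60.0,
    fwd_seq: str = _FWD_DEFAULT,
    rev_seq: str = _REV_DEFAULT,
    score: float = 1.0,
    pair_id: str | None = None,
    interior_char: str = "T",
) -> PrimerPair:
    end = start + length
    fwd = PrimerCandidate(chrom, start, start + len(fwd_seq), "+", fwd_seq,
                          tm=tm, gc=0.5, score=QualityScore(score, True))
    rev = PrimerCandidate(chrom, end - len(rev_seq), end, "-", rev_seq,
                          tm=tm, gc=0.5, score=QualityScore(score, True))
    interior = interior_char * (length - len(fwd_seq) - len(rev_seq))
    return PrimerPair(
        fwd=fwd, rev=rev, chrom=chrom, start=start, end=end, length=length,
        tm_spread=0.0, combined_score=2 * score,
        amplicon_seq=fwd_seq + interior + revcomp(rev_seq),
        pair_id=pair_id,
    )
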
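"""Hashed-genome k-mer index.

The index counts every k-length window of the genome over both strands
(k-mers are stored canonically — the lexicographic minimum of a k-mer and its
reverse complement — so a query and its reverse complement always return the
same two-strand total).  Windows containing N are excluded.  Soft-masked
(lowercase) runs of the input FASTA are recorded as mask intervals.

The primer *quality score* summarizes how common a primer's constituent
k-mers are in the genome: the arithmetic mean of the k-mer occurrence counts
over every k-length window of the primer, multiplied by a large penalty
factor when the 3'-terminal k-mer is not genome-unique (a repeated 3' end is
the dominant mispriming risk).  A score of 1 means every window occurs
exactly once in the genome.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping

from pyfaidx import Fasta

from .seq import FASTA_ALPHABET, canonical, revcomp

_MASK_RE = re.compile(r"[a-z]+")


@dataclass(frozen=True)
class QualityScore:
    """Genome-commonness score of one primer (lower is better; 1 is the floor)."""

    value: float
    unique3prime: bool


class GenomeIndex:
    """K-mer occurrence counts, soft-mask intervals and sequence access for one genome."""

    def __init__(self, sequences: Mapping[str, str], k: int = 15):
        # tiny k is allowed for in-memory toy genomes; file-level builds enforce 8-16
        if not 2 <= k <= 16:
            raise ValueError(f"k={k} outside supported range 2-16")
        self.k = k
        self._seq: dict[str, str] = {}
        self._upper: dict[str, str] = {}
        self._mask: dict[str, list[tuple[int, int]]] = {}
        self._counts: dict[str, int] = {}
        for name, seq in sequences.items():
            bad = set(seq) - FASTA_ALPHABET
            if bad:
                raise ValueError(f"{name}: invalid characters {sorted(bad)!r}")
            self._seq[name] = seq
            self._upper[name] = seq.upper()
            self._mask[name] = [(m.start(), m.end()) for m in _MASK_RE.finditer(seq)]
        self._build_counts()

    def _build_counts(self) -> None:
        k = self.k
        counts = self._counts
        for up in self._upper.values():
            n_next = -1  # index of next N at or beyond the current window
            for i in range(len(up) - k + 1):
                if n_next < i:
                    n_next = up.find("N", i, i + k)
                if i <= n_next < i + k:
                    continue
                w = up[i:i + k]
                rc = revcomp(w)
                if w == rc:  # palindrome: one genomic window is seen from both strands
                    counts[w] = counts.get(w, 0) + 2
                elif w <= rc:
                    counts[w] = counts.get(w, 0) + 1
                else:
                    counts[rc] = counts.get(rc, 0) + 1

    # --- sequence access -----------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self._seq)

    def chrom_length(self, chrom: str) -> int:
        return len(self._seq[chrom])

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._seq

    def sequence(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Uppercase genomic sequence of [start, end); '-' returns the reverse complement."""
        self._check_range(chrom, start, end)
        s = self._upper[chrom][start:end]
        return s if strand == "+" else revcomp(s)

    def chrom_sequence(self, chrom: str) -> str:
        """The full uppercase sequence of one chromosome."""
        return self._upper[chrom]

    def _check_range(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self._seq:
            raise KeyError(f"unknown sequence {chrom!r}")
        if start < 0 or end > len(self._seq[chrom]) or start > end:
            raise ValueError(
                f"range [{start},{end}) out of bounds for {chrom} "
                f"(length {len(self._seq[chrom])})")

    # --- k-mer counts and scoring --------------------------------------

    def kmer_count(self, kmer: str) -> int:
        """Two-strand occurrence count of a k-mer; 0 if absent from the genome."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        u = kmer.upper()
        if set(u) - set("ACGT"):
            raise ValueError(f"not an ACGT k-mer: {kmer!r}")
        return self._counts.get(canonical(u), 0)

    def quality_score(self, primer: str, three_prime_penalty: float = 100.0) -> QualityScore:
        """Mean k-mer count over the primer's windows, penalized for a non-unique 3' k-mer."""
        p = primer.upper()
        if len(p) < self.k:
            raise ValueError(f"primer length {len(p)} < k={self.k}")
        counts = [self.kmer_count(p[i:i + self.k]) for i in range(len(p) - self.k + 1)]
        value = sum(counts) / len(counts)
        unique3 = counts[-1] == 1
        if not unique3:
            value *= three_prime_penalty
        return QualityScore(value=value, unique3prime=unique3)

    # --- soft-mask queries ---------------------------------------------

    def is_masked(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) intersects any soft-masked (lowercase) run."""
        self._check_range(chrom, start, end)
        if start == end:
            return False
        runs = self._mask[chrom]
        idx = bisect_right(runs, (end,)) - 1  # last run starting before end
        return idx >= 0 and runs[idx][1] > start

    def mask_intervals(self, chrom: str) -> list[tuple[int, int]]:
        return list(self._mask[chrom])


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping (case preserved)."""
    fa = Fasta(str(path), as_raw=True, read_ahead=10_000_000)
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


def build_index(fasta_path, k: int = 15) -> GenomeIndex:
    """Build a :class:`GenomeIndex` from a (soft-masked) FASTA file."""
    if not 8 <= k <= 16:
        raise ValueError(f"k={k} outside supported range 8-16")
    return GenomeIndex(read_fasta(fasta_path), k=k)
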
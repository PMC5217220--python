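"""Small sequence utilities shared across the package."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Characters permitted in input FASTA records (soft-masked reference convention).
FASTA_ALPHABET = frozenset("ACGTNacgtn")


def revcomp(seq: str) -> str:
    """Reverse complement, case-preserving (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def is_dna(seq: str) -> bool:
    """True if *seq* is nonempty and uses only uppercase A/C/G/T."""
    return bool(seq) and not (set(seq) - set("ACGT"))
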
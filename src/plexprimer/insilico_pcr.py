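"""Internal in-silico PCR: predict every product of a primer pair or pool.

Binding model: the 3'-terminal k bases of a primer (k = the index k-mer size)
must match the template exactly — a mismatch near the extending 3' end kills
amplification — while up to ``max_mismatches`` substitutions are tolerated in
the 5' remainder.  A product is any correctly oriented forward/reverse site
combination on one chromosome within the maximum product size; within a pool
this includes cross-pair combinations, which a good design must not produce.

The search seeds on exact occurrences of the 3'-terminal k-mer (found by
plain string scanning over both strands) and verifies each extension by
direct sequence comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .genome_index import GenomeIndex
from .pooling import PrimerPool
from .primer_search import PrimerPair
from .seq import revcomp


class BindingSite(NamedTuple):
    chrom: str
    pos: int       # 0-based start of the binding footprint on the + strand
    strand: str    # '+': primer sequence equals the genome; '-': its revcomp does
    mismatches: int
    length: int


@dataclass(frozen=True)
class PcrProduct:
    chrom: str
    start: int
    end: int
    length: int
    fwd_primer: str  # label, e.g. "P1_F"
    rev_primer: str
    fwd_pos: int
    rev_pos: int
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def cross_pair(self) -> bool:
        """True when the two priming oligos come from different designed pairs."""
        return self.fwd_primer.rsplit("_", 1)[0] != self.rev_primer.rsplit("_", 1)[0]


def _find_all(hay: str, needle: str) -> Iterable[int]:
    i = hay.find(needle)
    while i != -1:
        yield i
        i = hay.find(needle, i + 1)


def _mismatches(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                break
    return mm


def find_binding_sites(index: GenomeIndex, primer: str, max_mismatches: int = 0) -> list[BindingSite]:
    """All genomic sites where *primer* could prime synthesis.

    The 3'-terminal k-mer must match exactly (k = index k-mer size, always
    covering the critical 3'-terminal 5 bases); mismatches up to the limit are
    allowed only in the 5' remainder.
    """
    p = primer.upper()
    k = index.k
    if len(p) < k:
        raise ValueError(f"primer length {len(p)} < k={k}")
    if max_mismatches not in (0, 1, 2):
        raise ValueError("max_mismatches must be 0, 1 or 2")
    seed = p[-k:]
    prefix = p[:-k]
    np = len(prefix)
    sites: list[BindingSite] = []
    for chrom in index.chroms:
        genome = index.chrom_sequence(chrom)
        # + strand: genome reads  prefix + seed
        for s in _find_all(genome, seed):
            start = s - np
            if start < 0:
                continue
            mm = _mismatches(genome[start:s], prefix, max_mismatches)
            if mm <= max_mismatches:
                sites.append(BindingSite(chrom, start, "+", mm, len(p)))
        # - strand: genome reads  revcomp(seed) + revcomp(prefix)
        seed_rc = revcomp(seed)
        prefix_rc = revcomp(prefix)
        for s in _find_all(genome, seed_rc):
            end = s + k + np
            if end > len(genome):
                continue
            mm = _mismatches(genome[s + k:end], prefix_rc, max_mismatches)
            if mm <= max_mismatches:
                sites.append(BindingSite(chrom, s, "-", mm, len(p)))
    sites.sort(key=lambda t: (t.chrom, t.pos, t.strand))
    return sites


def _primer_set(pool_or_pair) -> list[tuple[str, str]]:
    if isinstance(pool_or_pair, PrimerPair):
        pairs: Sequence[PrimerPair] = [pool_or_pair]
    elif isinstance(pool_or_pair, PrimerPool):
        pairs = pool_or_pair.members
    else:
        pairs = list(pool_or_pair)
    labeled = []
    for i, pair in enumerate(pairs):
        pid = pair.pair_id or f"pair{i + 1}"
        labeled.append((f"{pid}_F", pair.fwd.sequence))
        labeled.append((f"{pid}_R", pair.rev.sequence))
    return labeled


def simulate_pcr(
    index: GenomeIndex,
    pool_or_pair,
    max_product: int | None = None,
    max_mismatches: int = 0,
) -> list[PcrProduct]:
    """Enumerate all predicted amplification products of a pair, pool, or pair list.

    Any primer may act as the forward or the reverse oligo of a product; all
    plus-strand x minus-strand site combinations on one chromosome within
    ``max_product`` (default 1200 bp) are reported, sorted by coordinate.
    """
    if max_product is None:
        max_product = 1200
    primers = _primer_set(pool_or_pair)
    site_cache: dict[str, list[BindingSite]] = {}
    labeled_sites: list[tuple[str, BindingSite]] = []
    for label, seq in primers:
        if seq not in site_cache:
            site_cache[seq] = find_binding_sites(index, seq, max_mismatches)
        for site in site_cache[seq]:
            labeled_sites.append((label, site))

    plus = [(lab, s) for lab, s in labeled_sites if s.strand == "+"]
    minus = [(lab, s) for lab, s in labeled_sites if s.strand == "-"]
    products = []
    seen = set()
    for flab, fs in plus:
        for rlab, rs in minus:
            if fs.chrom != rs.chrom:
                continue
            if rs.pos < fs.pos + fs.length:  # reverse site must lie downstream
                continue
            end = rs.pos + rs.length
            length = end - fs.pos
            if length > max_product:
                continue
            key = (fs.chrom, fs.pos, end, flab, rlab)
            if key in seen:
                continue
            seen.add(key)
            products.append(PcrProduct(
                chrom=fs.chrom, start=fs.pos, end=end, length=length,
                fwd_primer=flab, rev_primer=rlab,
                fwd_pos=fs.pos, rev_pos=rs.pos,
                fwd_mismatches=fs.mismatches, rev_mismatches=rs.mismatches,
            ))
    products.sort(key=lambda p: (p.chrom, p.start, p.end, p.fwd_primer, p.rev_primer))
    return products
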
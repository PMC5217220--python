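"""Compatibility matrix over primer pairs and greedy pool assembly.

Two primer pairs may share a multiplex reaction when

1. none of the four cross combinations of their primers can dimerize,
2. all four primer Tm's lie within a 2 °C spread,
3. their amplicons do not overlap genomically, and
4. their amplicon lengths differ by at most 20% of the maximum allowable
   amplicon size (so no one product dominates the reaction kinetics);
5. (optional, default on) neither pair's primers can anneal, via their
   3'-terminal word, within the other pair's amplicon interior — a guard
   against amplicon-amplicon interaction inside a pool.

Pooling seeds a new pool with the unpooled pair of extreme compatibility
degree ("most" or "least" connected) and grows it greedily with pairs
compatible with every current member; closed pools are maximal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .config import DesignConfig
from .primer_search import PrimerPair
from . import thermo


@dataclass
class CompatibilityMatrix:
    ok: list[list[bool]]
    degrees: list[int]

    def compatible(self, i: int, j: int) -> bool:
        return self.ok[i][j]


@dataclass
class PrimerPool:
    pool_id: int
    members: list[PrimerPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def pair_compatible(a: PrimerPair, b: PrimerPair, cfg: DesignConfig) -> bool:
    """All pairwise multiplex-compatibility rules between two primer pairs."""
    sp = cfg.structure
    primers_a = (a.fwd.sequence, a.rev.sequence)
    primers_b = (b.fwd.sequence, b.rev.sequence)
    for pa in primers_a:
        for pb in primers_b:
            if thermo.dimerizes(pa, pb, sp):
                return False
    tms = (a.fwd.tm, a.rev.tm, b.fwd.tm, b.rev.tm)
    if max(tms) - min(tms) > cfg.pool_tm_spread:
        return False
    if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
        return False
    if abs(a.length - b.length) > cfg.pool_size_frac * cfg.amp_max:
        return False
    if cfg.cross_anneal_check:
        word = cfg.self_anneal_word
        for pa in primers_a:
            if thermo.three_prime_anneals_within(pa, b.interior_seq, word):
                return False
        for pb in primers_b:
            if thermo.three_prime_anneals_within(pb, a.interior_seq, word):
                return False
    return True


def build_matrix(pairs: Sequence[PrimerPair], cfg: DesignConfig) -> CompatibilityMatrix:
    """Symmetric boolean compatibility matrix; diagonal true by convention."""
    n = len(pairs)
    ok = [[True] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            c = pair_compatible(pairs[i], pairs[j], cfg)
            ok[i][j] = ok[j][i] = c
    degrees = [sum(row) - 1 for row in ok]
    return CompatibilityMatrix(ok=ok, degrees=degrees)


def _order_key(pair: PrimerPair) -> tuple:
    return (pair.combined_score, pair.chrom, pair.start, pair.end)


def build_pools(
    pairs: Sequence[PrimerPair],
    matrix: CompatibilityMatrix,
    strategy: str = "most",
    cfg: DesignConfig | None = None,
) -> list[PrimerPool]:
    """Greedy pool assembly; every pair ends in exactly one pool (singletons allowed).

    Degrees are static properties of the full matrix unless
    ``cfg.dynamic_degrees`` asks for recomputation among unpooled pairs.
    Ties break on lower combined quality score, then genomic order.
    """
    if strategy not in ("most", "least"):
        raise ValueError(f"unknown pooling strategy {strategy!r}")
    dynamic = bool(cfg and cfg.dynamic_degrees)
    sign = -1 if strategy == "most" else 1

    n = len(pairs)
    unpooled = set(range(n))
    pools: list[PrimerPool] = []

    def degree(i: int) -> int:
        if dynamic:
            return sum(1 for j in unpooled if j != i and matrix.ok[i][j])
        return matrix.degrees[i]

    def pick(candidates) -> int:
        return min(candidates, key=lambda i: (sign * degree(i),) + _order_key(pairs[i]))

    while unpooled:
        seed = pick(unpooled)
        unpooled.remove(seed)
        members = [seed]
        while True:
            admissible = [i for i in unpooled
                          if all(matrix.ok[i][m] for m in members)]
            if not admissible:
                break
            nxt = pick(admissible)
            unpooled.remove(nxt)
            members.append(nxt)
        pools.append(PrimerPool(pool_id=len(pools) + 1,
                                members=[pairs[i] for i in members]))
    return pools


def validate_pool(pool: PrimerPool, cfg: DesignConfig) -> list[str]:
    """Independent full re-check of the compatibility rules over a pool.

    Uses brute-force complementary-run scans (a separate code path from the
    screens used during matrix construction).  Returns a list of violation
    messages; an empty list means the pool is valid.
    """
    violations: list[str] = []
    members = pool.members
    sp = cfg.structure
    word = cfg.self_anneal_word

    # Tm compatibility binds between pairs: for >=2 members the pool-wide
    # spread equals the worst pairwise four-Tm spread; a singleton has no
    # partner to be compatible with.
    all_tms = [t for p in members for t in (p.fwd.tm, p.rev.tm)]
    if len(members) >= 2 and max(all_tms) - min(all_tms) > cfg.pool_tm_spread + 1e-9:
        violations.append(f"pool {pool.pool_id}: Tm spread "
                          f"{max(all_tms) - min(all_tms):.2f} > {cfg.pool_tm_spread}")

    for x in range(len(members)):
        for y in range(x + 1, len(members)):
            a, b = members[x], members[y]
            tag = f"pool {pool.pool_id}: {a.pair_id}/{b.pair_id}"
            for pa in (a.fwd.sequence, a.rev.sequence):
                for pb in (b.fwd.sequence, b.rev.sequence):
                    if thermo.max_complementary_run(pa, pb) >= sp.dimer_min_run:
                        violations.append(f"{tag}: cross-dimer run >= {sp.dimer_min_run}")
                    if (thermo.max_3prime_complementary_run(pa, pb) >= sp.dimer_min_run_3p
                            or thermo.max_3prime_complementary_run(pb, pa) >= sp.dimer_min_run_3p):
                        violations.append(f"{tag}: 3' cross-dimer run >= {sp.dimer_min_run_3p}")
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                violations.append(f"{tag}: overlapping amplicons")
            if abs(a.length - b.length) > cfg.pool_size_frac * cfg.amp_max:
                violations.append(f"{tag}: amplicon size difference "
                                  f"{abs(a.length - b.length)} > "
                                  f"{cfg.pool_size_frac * cfg.amp_max:.0f}")
            if cfg.cross_anneal_check:
                for p, interior, who in (
                    (a.fwd.sequence, b.interior_seq, "a.fwd vs b"),
                    (a.rev.sequence, b.interior_seq, "a.rev vs b"),
                    (b.fwd.sequence, a.interior_seq, "b.fwd vs a"),
                    (b.rev.sequence, a.interior_seq, "b.rev vs a"),
                ):
                    if _word_anneals(p, interior, word):
                        violations.append(f"{tag}: 3' word anneals in partner amplicon ({who})")
    return violations


def _word_anneals(primer: str, interior: str, word: int) -> bool:
    # explicit window comparison, independent of the substring-based screen
    from .seq import revcomp
    suffix = primer.upper()[-word:]
    targets = (suffix, revcomp(suffix))
    interior = interior.upper()
    for i in range(len(interior) - word + 1):
        if interior[i:i + word] in targets:
            return True
    return False
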
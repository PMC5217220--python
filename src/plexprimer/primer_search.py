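"""Candidate enumeration, the exclusion filters, pairing and amplicon tiling.

Every window of every allowed length, on both strands, within the design
flank around a target is examined.  A candidate either passes or carries the
first failing exclusion filter as its rejection code, in the fixed order

    hairpin, self_dimer, tm, gc, masked, snp

(the 3'-anneal-within-product check needs the amplicon and is therefore
applied at pairing time; the "quality" code is attached later when a passing
candidate's genome-commonness score exceeds the acceptance threshold).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Sequence

from .config import DesignConfig
from .genome_index import GenomeIndex, QualityScore
from .io_formats import SnpRecord, TargetRegion
from .seq import revcomp
from . import thermo

REJECT_HAIRPIN = "hairpin"
REJECT_SELF_DIMER = "self_dimer"
REJECT_TM = "tm"
REJECT_GC = "gc"
REJECT_MASKED = "masked"
REJECT_SNP = "snp"
REJECT_QUALITY = "quality"


@dataclass(slots=True)
class PrimerCandidate:
    """One oriented oligo: binding site [start, end) on *chrom*, sequence 5'->3'."""

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    tm: float | None = None
    gc: float | None = None
    score: QualityScore | None = None
    rejection: str | None = None

    @property
    def passed(self) -> bool:
        return self.rejection is None


@dataclass(slots=True)
class PrimerPair:
    """A forward/reverse candidate pair and the amplicon they define."""

    fwd: PrimerCandidate
    rev: PrimerCandidate
    chrom: str
    start: int  # amplicon start == fwd binding-site start
    end: int    # amplicon end == rev binding-site end
    length: int
    tm_spread: float
    combined_score: float
    amplicon_seq: str
    pair_id: str | None = None
    iteration: int = 0

    @property
    def interior_seq(self) -> str:
        """Amplicon sequence excluding the two primer binding sites."""
        return self.amplicon_seq[len(self.fwd.sequence):len(self.amplicon_seq) - len(self.rev.sequence)]


def enumerate_candidates(
    index: GenomeIndex,
    region: TargetRegion,
    cfg: DesignConfig,
    snps: Sequence[SnpRecord] = (),
) -> list[PrimerCandidate]:
    """Examine every primer-sized window around *region* and apply filters 1-6.

    Primers may bind up to ``cfg.effective_flank`` bases outside the target so
    that amplicons can overhang it.  Windows containing N are not viable
    primers and are skipped.  Quality scores are computed for passing
    candidates only.
    """
    chrom = region.chrom
    if not index.has_chrom(chrom) or region.end > index.chrom_length(chrom):
        raise ValueError(f"target {chrom}:{region.start}-{region.end} outside genome")

    up = index.chrom_sequence(chrom)
    flank = cfg.effective_flank
    lo = max(0, region.start - flank)
    hi = min(len(up), region.end + flank)
    sp = cfg.structure
    cond = cfg.thermo
    snp_pos = sorted(s.pos for s in snps if s.chrom == chrom and s.freq >= cfg.snp_freq_cutoff)

    out: list[PrimerCandidate] = []
    for start in range(lo, hi - cfg.len_min + 1):
        max_len = min(cfg.len_max, hi - start)
        window = up[start:start + max_len]
        n_at = window.find("N")
        if n_at != -1:
            max_len = n_at  # lengths beyond the first N are not viable
        # properties shared by both strands of the same window
        for length in range(cfg.len_min, max_len + 1):
            w = window[:length]
            end = start + length
            hairpin = thermo.forms_hairpin(w, sp)  # strand-symmetric
            tm = gc = None
            shared_rejection = None
            if not hairpin:
                tm = thermo.melting_temperature(w, cond)
                gc = thermo.gc_fraction(w)
            for strand in ("+", "-"):
                seq = w if strand == "+" else revcomp(w)
                cand = PrimerCandidate(chrom, start, end, strand, seq, tm=tm, gc=gc)
                if hairpin:
                    cand.rejection = REJECT_HAIRPIN
                elif thermo.dimerizes(seq, seq, sp):
                    cand.rejection = REJECT_SELF_DIMER
                elif shared_rejection is not None:
                    cand.rejection = shared_rejection
                else:
                    if not cfg.tm_min <= tm <= cfg.tm_max:
                        shared_rejection = REJECT_TM
                    elif not cfg.gc_min <= gc <= cfg.gc_max:
                        shared_rejection = REJECT_GC
                    elif index.is_masked(chrom, start, end):
                        shared_rejection = REJECT_MASKED
                    elif _overlaps_snp(snp_pos, start, end):
                        shared_rejection = REJECT_SNP
                    if shared_rejection is not None:
                        cand.rejection = shared_rejection
                    else:
                        cand.score = index.quality_score(seq, cfg.three_prime_penalty)
                out.append(cand)
    return out


def _overlaps_snp(snp_pos: list[int], start: int, end: int) -> bool:
    idx = bisect_left(snp_pos, start)
    return idx < len(snp_pos) and snp_pos[idx] < end


def apply_quality_threshold(cands: Iterable[PrimerCandidate], cfg: DesignConfig) -> list[PrimerCandidate]:
    """Mark passing candidates whose quality score exceeds the threshold as rejected."""
    kept = []
    for c in cands:
        if c.passed and c.score is not None and c.score.value > cfg.quality_threshold:
            c.rejection = REJECT_QUALITY
        if c.passed:
            kept.append(c)
    return kept


def form_pairs(
    cands: Sequence[PrimerCandidate],
    region: TargetRegion,
    index: GenomeIndex,
    cfg: DesignConfig,
) -> list[PrimerPair]:
    """All forward/reverse combinations with an in-range amplicon.

    A pair is rejected when either primer's 3'-terminal word can anneal within
    the amplicon interior (the product excluding the two binding sites).
    """
    fwd = sorted((c for c in cands if c.passed and c.strand == "+"),
                 key=lambda c: (c.start, c.end))
    rev = sorted((c for c in cands if c.passed and c.strand == "-"),
                 key=lambda c: (c.end, c.start))
    rev_ends = [r.end for r in rev]
    up = index.chrom_sequence(region.chrom)
    word = cfg.self_anneal_word

    pairs: list[PrimerPair] = []
    seen: set[tuple[int, int, int, int]] = set()
    for f in fwd:
        lo_i = bisect_left(rev_ends, f.start + cfg.amp_min)
        for i in range(lo_i, len(rev)):
            r = rev[i]
            length = r.end - f.start
            if length > cfg.amp_max:
                break
            if r.start < f.end:  # binding sites must not overlap
                continue
            key = (f.start, f.end, r.start, r.end)
            if key in seen:
                continue
            seen.add(key)
            interior = up[f.end:r.start]
            if thermo.three_prime_anneals_within(f.sequence, interior, word):
                continue
            if thermo.three_prime_anneals_within(r.sequence, interior, word):
                continue
            pairs.append(PrimerPair(
                fwd=f, rev=r, chrom=region.chrom,
                start=f.start, end=r.end, length=length,
                tm_spread=abs(f.tm - r.tm),
                combined_score=f.score.value + r.score.value,
                amplicon_seq=up[f.start:r.end],
            ))
    pairs.sort(key=lambda p: (p.start, p.end, p.combined_score))
    return pairs


def select_tiling(
    pairs: Sequence[PrimerPair],
    region: TargetRegion,
    cfg: DesignConfig,
) -> list[PrimerPair]:
    """Greedy interval cover of the target by amplicons.

    Repeatedly picks the pair covering the leftmost uncovered target base that
    extends coverage furthest right; ties go to the lower combined quality
    score, then the leftmost amplicon start.  Gaps no pair covers are skipped
    (they surface in the coverage report).
    """
    cov = []
    for p in pairs:
        s = max(p.start, region.start)
        e = min(p.end, region.end)
        if s < e:
            cov.append((s, e, p))
    cov.sort(key=lambda t: (t[0], t[1]))

    selected: list[PrimerPair] = []
    chosen: set[int] = set()
    pos = region.start
    while pos < region.end:
        best = None
        next_start = None
        for s, e, p in cov:
            if id(p) in chosen:
                continue
            if s <= pos:
                if e > pos:
                    k = (-e, p.combined_score, p.start)
                    if best is None or k < best[0]:
                        best = (k, p, e)
            elif next_start is None:
                next_start = s
        if best is not None:
            selected.append(best[1])
            chosen.add(id(best[1]))
            pos = best[2]
        elif next_start is not None:
            pos = next_start
        else:
            break
    selected.sort(key=lambda p: (p.start, p.end))
    return selected
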
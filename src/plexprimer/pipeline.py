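"""Full design orchestration: sanitize targets, design, retain, loosen, pool.

Iteration 0 runs at the stringent configuration.  Pairs whose primers pass
all filters and whose quality scores meet the acceptance threshold are
retained and their covered bases removed from the open target set; each
further iteration widens the Tm window by ``tm_step`` (symmetrically) and the
maximum amplicon size by ``amp_step`` and designs only over still-uncovered
bases, so earlier, more stringent designs are never revisited.  Pooling runs
once at the end over all retained pairs so that pairs from different
iterations can share pools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import DesignConfig
from .genome_index import build_index
from .io_formats import (CoverageReport, TargetRegion, read_bed, read_snp_table,
                         sanitize_regions, write_outputs)
from .pooling import PrimerPool, build_matrix, build_pools
from .primer_search import (PrimerPair, apply_quality_threshold,
                            enumerate_candidates, form_pairs, select_tiling)

logger = logging.getLogger(__name__)


@dataclass
class IterationRecord:
    index: int
    tm_window: tuple[float, float]
    amp_window: tuple[int, int]
    new_pairs: int
    covered_bp: int
    target_bp: int


@dataclass
class DesignResult:
    config: DesignConfig
    regions: list[TargetRegion]
    pairs: list[PrimerPair] = field(default_factory=list)
    pools: list[PrimerPool] = field(default_factory=list)
    coverage: list[CoverageReport] = field(default_factory=list)
    iterations: list[IterationRecord] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    @property
    def covered_bp(self) -> int:
        return sum(r.covered_bp for r in self.coverage)

    @property
    def target_bp(self) -> int:
        return sum(len(r.region) for r in self.coverage)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _uncovered(region: TargetRegion, pairs: list[PrimerPair]) -> list[tuple[int, int]]:
    covered = _merge([
        (max(p.start, region.start), min(p.end, region.end))
        for p in pairs
        if p.chrom == region.chrom and p.start < region.end and p.end > region.start
    ])
    gaps = []
    pos = region.start
    for s, e in covered:
        if s > pos:
            gaps.append((pos, s))
        pos = max(pos, e)
    if pos < region.end:
        gaps.append((pos, region.end))
    return gaps


def coverage_report(region: TargetRegion, pairs: list[PrimerPair]) -> CoverageReport:
    covering = [p for p in pairs
                if p.chrom == region.chrom and p.start < region.end and p.end > region.start]
    gaps = _uncovered(region, covering)
    covered_bp = len(region) - sum(e - s for s, e in gaps)
    amplified_bp = sum(e - s for s, e in _merge([(p.start, p.end) for p in covering]))
    return CoverageReport(
        region=region,
        covered_bp=covered_bp,
        fraction=covered_bp / len(region),
        amplified_bp=amplified_bp,
        pair_ids=[p.pair_id or "?" for p in sorted(covering, key=lambda p: (p.start, p.end))],
        uncovered=gaps,
    )


def run_design(
    cfg: DesignConfig,
    bed_path,
    fasta_path,
    snp_path=None,
    strategy: str | None = None,
) -> DesignResult:
    """Design primer pools for every BED target; never raises on undesignable targets."""
    regions = sanitize_regions(read_bed(bed_path))
    index = build_index(fasta_path, cfg.kmer_size)
    for r in regions:
        if not index.has_chrom(r.chrom) or r.end > index.chrom_length(r.chrom):
            raise ValueError(f"target {r.chrom}:{r.start}-{r.end} outside genome")
    snps = read_snp_table(snp_path) if snp_path else []
    strategy = strategy or cfg.pool_strategy

    result = DesignResult(config=cfg, regions=regions)
    retained: list[PrimerPair] = []
    seen_pairs: set[tuple] = set()
    loosest = cfg

    for it in range(cfg.max_iterations + 1):
        cfg_it = cfg.loosened(it)
        open_work = [(r, gaps) for r in regions
                     for gaps in [_uncovered(r, retained)] if gaps]
        if not open_work:
            break
        loosest = cfg_it
        new_here = 0
        for region, gaps in open_work:
            for gs, ge in gaps:
                sub = TargetRegion(region.chrom, gs, ge, region.label)
                cands = enumerate_candidates(index, sub, cfg_it, snps)
                passing = apply_quality_threshold(cands, cfg_it)
                pairs = form_pairs(passing, sub, index, cfg_it)
                for p in select_tiling(pairs, sub, cfg_it):
                    key = (p.chrom, p.start, p.end, p.fwd.sequence, p.rev.sequence)
                    if key in seen_pairs:
                        continue
                    seen_pairs.add(key)
                    p.iteration = it
                    retained.append(p)
                    new_here += 1
        covered = sum(len(r) - sum(e - s for s, e in _uncovered(r, retained))
                      for r in regions)
        total = sum(len(r) for r in regions)
        rec = IterationRecord(
            index=it,
            tm_window=(cfg_it.tm_min, cfg_it.tm_max),
            amp_window=(cfg_it.amp_min, cfg_it.amp_max),
            new_pairs=new_here,
            covered_bp=covered,
            target_bp=total,
        )
        result.iterations.append(rec)
        msg = (f"[iter {it}] Tm {cfg_it.tm_min:.1f}-{cfg_it.tm_max:.1f} "
               f"amp {cfg_it.amp_min}-{cfg_it.amp_max}: {new_here} new pairs, "
               f"coverage {covered}/{total} bp")
        result.log.append(msg)
        logger.info(msg)

    retained.sort(key=lambda p: (p.chrom, p.start, p.end))
    for i, p in enumerate(retained, start=1):
        p.pair_id = f"P{i}"
    result.pairs = retained

    if retained:
        # rule 4 scales with the loosest max_amp actually used, since retained
        # amplicons may be that large
        matrix = build_matrix(retained, loosest)
        result.pools = build_pools(retained, matrix, strategy=strategy, cfg=loosest)
    result.coverage = [coverage_report(r, retained) for r in regions]
    npools = len(result.pools)
    msg = (f"done: {len(retained)} pairs in {npools} pools, "
           f"{result.covered_bp}/{result.target_bp} target bp covered")
    result.log.append(msg)
    logger.info(msg)
    return result


def run_and_write(cfg, bed_path, fasta_path, snp_path, out_dir, strategy=None) -> DesignResult:
    result = run_design(cfg, bed_path, fasta_path, snp_path, strategy=strategy)
    write_outputs(result, out_dir)
    return result
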
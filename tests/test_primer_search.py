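import random

import pytest

from conftest import make_stub_pair, random_genome
from plexprimer.config import DesignConfig
from plexprimer.fixtures import sample_primer_site
from plexprimer.genome_index import GenomeIndex
from plexprimer.io_formats import SnpRecord, TargetRegion
from plexprimer.primer_search import (apply_quality_threshold,
                                      enumerate_candidates, form_pairs,
                                      select_tiling)
from plexprimer.seq import revcomp
from plexprimer import thermo


def planted_site_genome(seed=0, n=3000, site_pos=1000, site=None):
    """Random genome with a known filter-passing primer window planted at site_pos."""
    rng = random.Random(seed)
    genome = random_genome(rng, n)
    site = site or sample_primer_site(rng, 20, (57.5, 62.5))
    genome = genome[:site_pos] + site + genome[site_pos + len(site):]
    return genome, site


def candidate_at(cands, start, end, strand="+"):
    return next(c for c in cands
                if c.start == start and c.end == end and c.strand == strand)


class TestEnumerateFilters:
    def setup_method(self):
        self.cfg = DesignConfig()
        self.genome, self.site = planted_site_genome()
        self.region = TargetRegion("chr1", 1000, 1020)

    def _cands(self, genome=None, snps=()):
        gi = GenomeIndex({"chr1": genome or self.genome}, k=15)
        return enumerate_candidates(gi, self.region, self.cfg, snps)

    def test_planted_clean_site_passes(self):
        cand = candidate_at(self._cands(), 1000, 1020)
        assert cand.rejection is None
        assert self.cfg.tm_min <= cand.tm <= self.cfg.tm_max
        assert cand.score.value >= 1.0

    def test_snp_overlap_rejected_and_flips(self):
        snp = SnpRecord("chr1", 1010, 0.30)
        cand = candidate_at(self._cands(snps=[snp]), 1000, 1020)
        assert cand.rejection == "snp"
        low = SnpRecord("chr1", 1010, 0.005)  # below the 0.01 frequency cutoff
        assert candidate_at(self._cands(snps=[low]), 1000, 1020).rejection is None

    def test_masked_site_rejected_and_flips(self):
        g = self.genome[:1000] + self.site.lower() + self.genome[1020:]
        assert candidate_at(self._cands(genome=g), 1000, 1020).rejection == "masked"
        assert candidate_at(self._cands(), 1000, 1020).rejection is None

    def test_hairpin_site_rejected_and_flips(self):
        hairpin = "GGGCGAAACGCCCAAAATAT"  # 4-bp stem GGGCG/CGCCC-ish with 3-nt loop
        assert thermo.forms_hairpin(hairpin)
        g = self.genome[:1000] + hairpin + self.genome[1020:]
        assert candidate_at(self._cands(genome=g), 1000, 1020).rejection == "hairpin"
        assert candidate_at(self._cands(), 1000, 1020).rejection is None

    def test_multicopy_site_rejected_as_quality_and_flips(self):
        g = self.genome[:2500] + self.site + self.genome[2500 + len(self.site):]
        gi = GenomeIndex({"chr1": g}, k=15)
        cands = enumerate_candidates(gi, self.region, self.cfg)
        apply_quality_threshold(cands, self.cfg)
        cand = candidate_at(cands, 1000, 1020)
        assert cand.rejection == "quality"
        assert not cand.score.unique3prime
        single = self._cands()
        apply_quality_threshold(single, self.cfg)
        assert candidate_at(single, 1000, 1020).rejection is None

    def test_tm_and_gc_rejections(self):
        cands = self._cands()
        at_rich = [c for c in cands if c.rejection == "tm" and c.gc is not None]
        assert at_rich  # a random genome always offers out-of-window Tm candidates
        for c in cands:
            if c.rejection == "gc":
                assert not self.cfg.gc_min <= c.gc <= self.cfg.gc_max

    def test_passing_candidates_satisfy_all_filters_on_recheck(self):
        gi = GenomeIndex({"chr1": self.genome}, k=15)
        cands = enumerate_candidates(gi, self.region, self.cfg)
        passing = [c for c in cands if c.rejection is None]
        assert passing
        sp = self.cfg.structure
        for c in passing[:50]:
            assert not thermo.forms_hairpin(c.sequence, sp)
            assert not thermo.dimerizes(c.sequence, c.sequence, sp)
            assert self.cfg.tm_min <= thermo.melting_temperature(c.sequence) <= self.cfg.tm_max
            assert self.cfg.gc_min <= thermo.gc_fraction(c.sequence) <= self.cfg.gc_max
            assert not gi.is_masked(c.chrom, c.start, c.end)

    def test_region_outside_genome_is_error(self):
        gi = GenomeIndex({"chr1": self.genome}, k=15)
        with pytest.raises(ValueError):
            enumerate_candidates(gi, TargetRegion("chr1", 2990, 3050), self.cfg)
        with pytest.raises(ValueError):
            enumerate_candidates(gi, TargetRegion("chrX", 0, 100), self.cfg)


class TestFormPairs:
    def _mini_setup(self):
        """Genome with one fwd site at 100 and one rev site ending at 380."""
        rng = random.Random(7)
        fwd = sample_primer_site(rng, 20, (57.5, 62.5))
        rev = sample_primer_site(rng, 20, (57.5, 62.5))
        genome = random_genome(rng, 1000)
        genome = genome[:100] + fwd + genome[120:360] + revcomp(rev) + genome[380:]
        return genome, fwd, rev

    def test_coordinate_arithmetic(self, cfg):
        genome, fwd, rev = self._mini_setup()
        gi = GenomeIndex({"chr1": genome}, k=15)
        region = TargetRegion("chr1", 100, 380)
        cands = enumerate_candidates(gi, region, cfg)
        f = candidate_at(cands, 100, 120, "+")
        r = candidate_at(cands, 360, 380, "-")
        assert f.rejection is None and r.rejection is None
        pairs = form_pairs([f, r], region, gi, cfg)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.start, p.end, p.length) == (100, 380, 280)
        # sequence/coordinate consistency
        assert p.amplicon_seq.startswith(p.fwd.sequence)
        assert p.amplicon_seq.endswith(revcomp(p.rev.sequence))
        assert r.sequence == rev

    def test_amplicon_length_bounds(self, cfg):
        genome, fwd, rev = self._mini_setup()
        gi = GenomeIndex({"chr1": genome}, k=15)
        region = TargetRegion("chr1", 100, 380)
        cands = [c for c in enumerate_candidates(gi, region, cfg)
                 if c.rejection is None]
        f = candidate_at(cands, 100, 120, "+")
        r = candidate_at(cands, 360, 380, "-")
        tight = DesignConfig(amp_min=247, amp_max=279)  # amplicon of 280 now too big
        assert form_pairs([f, r], region, gi, tight) == []

    def test_three_prime_anneal_in_interior_rejected(self, cfg):
        genome, fwd, rev = self._mini_setup()
        # plant the reverse primer's 3' word inside the amplicon interior
        word = revcomp(rev[-7:])
        sab = genome[:200] + word + genome[207:]
        gi = GenomeIndex({"chr1": sab}, k=15)
        region = TargetRegion("chr1", 100, 380)
        cands = enumerate_candidates(gi, region, cfg)
        f = candidate_at(cands, 100, 120, "+")
        r = candidate_at(cands, 360, 380, "-")
        assert f.rejection is None and r.rejection is None
        assert form_pairs([f, r], region, gi, cfg) == []


class TestSelectTiling:
    def test_single_spanning_pair(self, cfg):
        region = TargetRegion("chr1", 100, 350)
        p = make_stub_pair(start=80, length=300)
        assert select_tiling([p], region, cfg) == [p]

    def test_disjoint_pairs_both_selected(self, cfg):
        region = TargetRegion("chr1", 0, 600)
        a = make_stub_pair(start=0, length=280)
        b = make_stub_pair(start=300, length=280)
        assert select_tiling([a, b], region, cfg) == [a, b]

    def test_redundant_contained_pair_not_selected(self, cfg):
        region = TargetRegion("chr1", 100, 300)
        big = make_stub_pair(start=50, length=300)
        small = make_stub_pair(start=120, length=280 - 130)
        got = select_tiling([big, small], region, cfg)
        assert got == [big]

    def test_matches_bruteforce_greedy_cover(self, cfg):
        rng = random.Random(13)
        region = TargetRegion("chr1", 0, 1000)
        for _ in range(20):
            pairs = []
            for i in range(rng.randint(1, 15)):
                start = rng.randrange(-200, 950)
                length = rng.randint(250, 330)
                pairs.append(make_stub_pair(start=max(0, start), length=length,
                                            score=rng.choice([1.0, 1.2, 1.5])))
            got = select_tiling(pairs, region, cfg)
            # oracle: literal restatement of the greedy cover rule
            expected = []
            pos, remaining = region.start, list(pairs)
            while pos < region.end:
                covering = [p for p in remaining
                            if max(p.start, region.start) <= pos < min(p.end, region.end)]
                if covering:
                    best = min(covering, key=lambda p: (-min(p.end, region.end),
                                                        p.combined_score, p.start))
                    expected.append(best)
                    remaining.remove(best)
                    pos = min(best.end, region.end)
                else:
                    nxt = [max(p.start, region.start) for p in remaining
                           if max(p.start, region.start) > pos
                           and min(p.end, region.end) > max(p.start, region.start)]
                    if not nxt:
                        break
                    pos = min(nxt)
            assert got == sorted(expected, key=lambda p: (p.start, p.end))
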
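import itertools

import pytest

from conftest import make_stub_pair
from plexprimer.config import DesignConfig
from plexprimer.pooling import (build_matrix, build_pools, pair_compatible,
                                validate_pool)
from plexprimer.seq import revcomp


class TestPairCompatible:
    def test_size_rule_threshold_at_20pct_of_max(self):
        """With a 400 bp maximum amplicon the size-difference threshold is 80 bp."""
        cfg = DesignConfig(amp_min=100, amp_max=400)
        a = make_stub_pair(start=0, length=300)
        ok = make_stub_pair(start=10_000, length=379)   # diff 79 <= 80
        bad = make_stub_pair(start=10_000, length=381)  # diff 81 > 80
        assert pair_compatible(a, ok, cfg)
        assert not pair_compatible(a, bad, cfg)

    def test_overlapping_amplicons_incompatible(self, cfg):
        a = make_stub_pair(start=0, length=280)
        b = make_stub_pair(start=0, length=280)
        assert not pair_compatible(a, b, cfg)

    def test_tm_spread_over_2c_incompatible(self, cfg):
        a = make_stub_pair(start=0, length=280, tm=59.0)
        b = make_stub_pair(start=10_000, length=280, tm=61.5)
        a.rev.tm = 59.5
        b.fwd.tm = 60.0
        assert not pair_compatible(a, b, cfg)  # spread 2.5 across the four Tm's

    def test_cross_dimer_incompatible(self, cfg):
        a = make_stub_pair(start=0, length=280)
        b = make_stub_pair(start=10_000, length=280,
                           fwd_seq=revcomp(a.fwd.sequence))
        assert not pair_compatible(a, b, cfg)

    def test_cross_amplicon_annealing_incompatible(self, cfg):
        a = make_stub_pair(start=0, length=280)
        b = make_stub_pair(start=10_000, length=280)
        word = revcomp(a.fwd.sequence[-7:])
        b.amplicon_seq = (b.fwd.sequence + word
                          + "T" * (280 - len(b.fwd.sequence) - len(b.rev.sequence) - 7)
                          + revcomp(b.rev.sequence))
        assert not pair_compatible(a, b, cfg)
        relaxed = DesignConfig(cross_anneal_check=False)
        assert pair_compatible(a, b, relaxed)

    def test_different_chromosomes_never_overlap(self, cfg):
        a = make_stub_pair(chrom="chr1", start=0, length=280)
        b = make_stub_pair(chrom="chr2", start=0, length=280)
        assert pair_compatible(a, b, cfg)


class TestBuildMatrix:
    def test_symmetric_with_true_diagonal(self, cfg):
        pairs = [make_stub_pair(start=i * 10_000, length=280, pair_id=f"P{i}")
                 for i in range(3)]
        pairs.append(make_stub_pair(start=5_000, length=280, pair_id="P3ovl"))
        pairs[3].start, pairs[3].end = pairs[1].start, pairs[1].end  # overlap P1
        m = build_matrix(pairs, cfg)
        for i in range(4):
            assert m.ok[i][i]
            for j in range(4):
                assert m.ok[i][j] == m.ok[j][i]
        assert not m.ok[1][3]
        assert m.ok[0][2]

    def test_degrees_count_compatible_partners(self, cfg):
        pairs = [make_stub_pair(start=i * 10_000, length=280) for i in range(4)]
        m = build_matrix(pairs, cfg)
        assert m.degrees == [3, 3, 3, 3]


def partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [[first] + block] + part[i + 1:]
        yield [[first]] + part


def clique_partitions(n, matrix):
    for part in partitions(list(range(n))):
        if all(matrix.ok[i][j] for block in part for i, j in itertools.combinations(block, 2)):
            yield part


class TestBuildPools:
    def _instance(self, cfg, tms):
        return [make_stub_pair(start=i * 10_000, length=280, tm=tm, score=1.0 + 0.01 * i,
                               pair_id=f"P{i + 1}")
                for i, tm in enumerate(tms)]

    def test_all_compatible_single_pool(self, cfg):
        pairs = self._instance(cfg, [60, 60, 60, 60])
        pools = build_pools(pairs, build_matrix(pairs, cfg), "most", cfg)
        assert len(pools) == 1
        assert len(pools[0].members) == 4

    def test_all_incompatible_singletons(self, cfg):
        pairs = self._instance(cfg, [50, 55, 60, 65])  # every Tm spread > 2
        pools = build_pools(pairs, build_matrix(pairs, cfg), "most", cfg)
        assert [len(p.members) for p in pools] == [1, 1, 1, 1]

    @pytest.mark.parametrize("strategy", ["most", "least"])
    def test_matches_exhaustive_minimal_partition(self, cfg, strategy):
        # unique optimum: {P1,P2,P3} clique + {P4} isolated by Tm
        pairs = self._instance(cfg, [60, 60, 60, 70])
        matrix = build_matrix(pairs, cfg)
        pools = build_pools(pairs, matrix, strategy, cfg)
        got = sorted(tuple(sorted(m.pair_id for m in p.members)) for p in pools)
        best = min(len(list(p)) for p in clique_partitions(4, matrix))
        optima = [sorted(tuple(sorted(pairs[i].pair_id for i in block)) for block in part)
                  for part in clique_partitions(4, matrix)
                  if len(part) == best]
        assert len(optima) == 1
        assert got == optima[0]

    @pytest.mark.parametrize("strategy", ["most", "least"])
    @pytest.mark.parametrize("tms", [
        [60, 60.5, 61, 62.4, 63.0, 70],
        [60, 60, 64, 64, 68, 68],
        [60, 61.9, 63.8, 65.7, 67.6, 69.5],
    ])
    def test_partition_validity_and_maximality(self, cfg, strategy, tms):
        pairs = self._instance(cfg, tms)
        matrix = build_matrix(pairs, cfg)
        pools = build_pools(pairs, matrix, strategy, cfg)
        # partition property
        seen = [m.pair_id for p in pools for m in p.members]
        assert sorted(seen) == sorted(p.pair_id for p in pairs)
        # every block is a clique (checked through the independent validator)
        for p in pools:
            assert validate_pool(p, cfg) == []
        # maximality at close time: no later-pooled pair was admissible
        idx = {p.pair_id: i for i, p in enumerate(pairs)}
        for k, pool in enumerate(pools):
            members = [idx[m.pair_id] for m in pool.members]
            for later in pools[k + 1:]:
                for cand in later.members:
                    assert not all(matrix.ok[idx[cand.pair_id]][m] for m in members)

    def test_deterministic(self, cfg):
        pairs = self._instance(cfg, [60, 60.5, 61, 62.4, 63.0, 70])
        matrix = build_matrix(pairs, cfg)
        a = build_pools(pairs, matrix, "most", cfg)
        b = build_pools(pairs, matrix, "most", cfg)
        assert [[m.pair_id for m in p.members] for p in a] == \
               [[m.pair_id for m in p.members] for p in b]

    def test_unknown_strategy_rejected(self, cfg):
        pairs = self._instance(cfg, [60])
        with pytest.raises(ValueError):
            build_pools(pairs, build_matrix(pairs, cfg), "random", cfg)


class TestValidatePool:
    def test_flags_planted_violations(self, cfg):
        a = make_stub_pair(start=0, length=280, pair_id="A")
        b = make_stub_pair(start=10_000, length=280, pair_id="B", tm=63.0)
        from plexprimer.pooling import PrimerPool
        pool = PrimerPool(1, [a, b])
        msgs = validate_pool(pool, cfg)
        assert any("Tm spread" in m for m in msgs)
        c = make_stub_pair(start=10_000, length=280, pair_id="C",
                           rev_seq=revcomp(a.fwd.sequence))
        msgs = validate_pool(PrimerPool(2, [a, c]), cfg)
        assert any("dimer" in m for m in msgs)

    def test_clean_pool_validates(self, cfg):
        a = make_stub_pair(start=0, length=280, pair_id="A")
        b = make_stub_pair(start=10_000, length=290, pair_id="B")
        from plexprimer.pooling import PrimerPool
        assert validate_pool(PrimerPool(1, [a, b]), cfg) == []
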
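"""Anchors, chaining, gap alignment and block filtering."""

import itertools

import numpy as np
import pytest

import haplodiff as hd
from haplodiff.alignment import (
    CHAIN_WINDOW,
    align_gap,
    block_stats,
    chain_anchors,
    filter_blocks,
    find_anchors,
    gap_penalty,
)
from haplodiff.models import Anchor, CollinearityBlock, revcomp


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestFindAnchors:
    def test_identical_sequences_single_full_anchor(self):
        s = _random_seq(10_000, 1)
        anchors = find_anchors(s, s)
        full = [a for a in anchors if a.length == len(s)]
        assert len(full) == 1
        assert full[0].strand == "+" and full[0].pos_a == full[0].pos_b == 1

    def test_reverse_complement_minus_anchor(self):
        s = _random_seq(8_000, 2)
        anchors = find_anchors(s, revcomp(s))
        full = [a for a in anchors if a.length == len(s)]
        assert len(full) == 1
        assert full[0].strand == "-"

    def test_single_snp_two_flanking_anchors(self):
        s = _random_seq(10_000, 3)
        pos = 5000  # 0-based
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
        s2 = s[:pos] + alt + s[pos + 1 :]
        anchors = find_anchors(s, s2)
        big = sorted((a for a in anchors if a.length > 1000),
                     key=lambda a: a.pos_a)
        assert len(big) == 2
        # maximal matches end exactly at the mismatched base
        assert big[0].pos_a == 1 and big[0].end_a == pos
        assert big[1].pos_a == pos + 2 and big[1].end_a == 10_000

    def test_anchor_intervals_are_exact_matches(self):
        a = _random_seq(4_000, 4)
        b = a[:1500] + _random_seq(80, 5) + a[1500:]
        for anc in find_anchors(a, b):
            sa = a[anc.pos_a - 1 : anc.end_a]
            sb = b[anc.pos_b - 1 : anc.end_b]
            assert sa == (sb if anc.strand == "+" else revcomp(sb))


def _chain_score(chain, strand):
    total = sum(a.length for a in chain)
    for p, n in zip(chain, chain[1:]):
        ga = n.pos_a - p.end_a - 1
        gb = (n.pos_b - p.end_b - 1) if strand == "+" else (p.pos_b - n.end_b - 1)
        total -= gap_penalty(max(ga, 0), max(gb, 0))
    return total


def _brute_force_best(anchors, strand, max_gap):
    """Exhaustive search over all ordered subsets forming a valid chain."""
    from haplodiff.alignment import _compatible

    anchors = sorted(anchors, key=lambda a: (a.pos_a, a.pos_b))
    best = (0.0, [])
    n = len(anchors)

    def dfs(last_idx, chain, score):
        nonlocal best
        if score > best[0]:
            best = (score, list(chain))
        for j in range(last_idx + 1 if last_idx >= 0 else 0, n):
            if last_idx >= 0:
                g = _compatible(anchors[last_idx], anchors[j], strand, max_gap)
                if g is None:
                    continue
                pen = gap_penalty(*g)
            else:
                pen = 0.0
            chain.append(anchors[j])
            dfs(j, chain, score + anchors[j].length - pen)
            chain.pop()

    dfs(-1, [], 0.0)
    return best


class TestChaining:
    def test_collinear_anchors_single_chain(self):
        anchors = [
            Anchor("a", 1 + i * 200, "b", 1 + i * 200, 100, "+") for i in range(8)
        ]
        chains = chain_anchors(anchors)
        assert len(chains) == 1 and len(chains[0]) == 8

    def test_inverted_segment_two_chains(self):
        plus = [Anchor("a", 1 + i * 300, "b", 1 + i * 300, 100, "+")
                for i in range(4)]
        minus = [Anchor("a", 2001 + i * 300, "b", 3000 - i * 300, 100, "-")
                 for i in range(4)]
        chains = chain_anchors(plus + minus, min_chain_anchors=2)
        strands = sorted({c[0].strand for c in chains})
        assert len(chains) == 2 and strands == ["+", "-"]

    def test_order_breaking_anchor_excluded(self):
        anchors = [Anchor("a", 1 + i * 300, "b", 1 + i * 300, 100, "+")
                   for i in range(6)]
        rogue = Anchor("a", 950, "b", 50_000, 40, "+")
        chains = chain_anchors(anchors + [rogue])
        assert rogue not in chains[0]
        assert len(chains[0]) == 6

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(30):
            n = int(rng.integers(2, 9))
            strand = "+" if rng.random() < 0.7 else "-"
            anchors = []
            for _ in range(n):
                pa = int(rng.integers(1, 5000))
                pb = int(rng.integers(1, 5000))
                anchors.append(Anchor("a", pa, "b", pb, int(rng.integers(20, 400)),
                                      strand))
            best_score, _best = _brute_force_best(anchors, strand, max_gap=3000)
            chains = chain_anchors(anchors, max_gap=3000, window=len(anchors) + 1)
            got = _chain_score(chains[0], strand) if chains else 0.0
            assert got == pytest.approx(best_score, abs=1e-9)


class TestAlignGap:
    def test_identical(self):
        g = align_gap("ACGT", "ACGT")
        assert g.identity == 100.0 and g.cigar == [("=", 4)]

    def test_single_mismatch_column(self):
        g = align_gap("ACGT", "AGGT")
        assert sum(ln for op, ln in g.cigar if op == "X") == 1

    def test_planted_divergence_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
            pos = rng.choice(500, size=25, replace=False)
            t = list(s)
            for p in pos:
                t[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[t[p]]
            g = align_gap(s, "".join(t))
            assert 93.0 <= g.identity <= 97.0

    def test_over_limit_rejected(self):
        with pytest.raises(ValueError, match="limit"):
            align_gap("A" * 10, "C" * 10, limit=5)


def _blk(bid, sa, ea, sb=None, eb=None, identity=99.0, aligned=None):
    sb = sa if sb is None else sb
    eb = ea if eb is None else eb
    return CollinearityBlock(bid, "chr1", sa, ea, "chr1", sb, eb, "+", identity,
                             aligned_length=aligned or (ea - sa + 1))


class TestFilterBlocks:
    def test_length_threshold_edge(self):
        kept = filter_blocks([_blk("b1", 1, 14_999)])
        assert kept == []
        kept = filter_blocks([_blk("b2", 1, 15_000)])
        assert len(kept) == 1

    def test_identity_threshold(self):
        assert filter_blocks([_blk("b", 1, 20_000, identity=79.9)]) == []
        assert len(filter_blocks([_blk("b", 1, 20_000, identity=80.0)])) == 1

    def test_one_to_one_keeps_higher_score(self):
        hi = _blk("hi", 1, 20_000, identity=99.0)
        lo = _blk("lo", 500, 19_500, identity=85.0)
        kept = filter_blocks([lo, hi])
        assert [b.id for b in kept] == ["hi"]

    def test_one_to_one_invariant_on_simulation(self, diploid_blocks):
        from haplodiff.alignment import _overlap_frac

        for b1, b2 in itertools.combinations(diploid_blocks, 2):
            if b1.chrom_a == b2.chrom_a:
                assert _overlap_frac(b1.start_a, b1.end_a,
                                     b2.start_a, b2.end_a) <= 0.80
            if b1.chrom_b == b2.chrom_b:
                assert _overlap_frac(b1.start_b, b1.end_b,
                                     b2.start_b, b2.end_b) <= 0.80


def test_bedpe_export_zero_based(tmp_path):
    from haplodiff.alignment import blocks_to_bedpe

    p = tmp_path / "b.bedpe"
    blocks_to_bedpe([_blk("b1", 101, 200)], p)
    fields = p.read_text().strip().split("\t")
    assert fields[:6] == ["chr1", "100", "200", "chr1", "100", "200"]


class TestBlockStats:
    def test_hand_arithmetic(self):
        blocks = [_blk("a", 1, 10_000), _blk("b", 1, 20_000), _blk("c", 1, 30_000)]
        count, mean, total = block_stats(blocks, min_size=15_000)
        assert (count, mean, total) == (2, 25_000, 50_000)

    def test_single_block(self):
        count, mean, total = block_stats([_blk("a", 1, 20_000)])
        assert (count, mean, total) == (1, 20_000, 20_000)

    def test_empty(self):
        assert block_stats([]) == (0, None, 0)


class TestWholeGenome:
    def test_identical_haplotypes_full_coverage_blocks(self):
        cfg = hd.SimulationConfig(
            seed=9, n_chromosomes=2, chrom_length=60_000, n_genes_per_chrom=0,
            snp_rate=0.0, small_indel_rate=0.0, sv_counts={},
            haplotype_specific_gene_fraction=0.0,
        )
        ga, ann = hd.generate_haplotype_a(cfg)
        gb, _, _ = hd.mutate_to_haplotype_b(ga, ann, cfg)
        blocks = hd.align_haplotypes(ga, gb)
        assert len(blocks) == 2
        for b in blocks:
            assert b.identity == 100.0
            assert b.span_a >= 0.999 * 60_000

    def test_no_sv_diploid_blocks_tile_chromosomes(self, diploid, diploid_blocks):
        cfg, ga, *_ = diploid
        covered = {c: 0 for c in ga.sequences}
        for b in diploid_blocks:
            covered[b.chrom_a] += b.span_a
        for chrom, seq in ga.sequences.items():
            assert covered[chrom] >= 0.99 * len(seq)
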
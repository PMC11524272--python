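"""ASE testing, FDR, blocks, sharing, promoter association, motif scan."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import haplodiff as hd
from haplodiff.ase import (
    ase_experiment,
    ase_test,
    bh_fdr,
    call_ase_blocks,
    iupac_to_regex,
    motif_rankings,
    motif_scan,
    promoter_interval,
    rank_correlation,
    shared_blocks,
    sharing_summary,
)
from haplodiff.models import ASEBlock, ASERecord


class TestAseTest:
    def test_balanced_pair_null(self):
        fc, p = ase_test([100, 100], [100, 100])
        assert fc == 0.0
        assert p > 0.9

    def test_all_zero_untestable(self):
        fc, p = ase_test([0, 0], [0, 0])
        assert (fc, p) == (0.0, 1.0)

    def test_replicates_required(self):
        with pytest.raises(ValueError, match="replicates"):
            ase_test([100], [90])

    def test_strong_imbalance_significant(self):
        fc, p = ase_test([400, 380, 420], [100, 95, 105])
        assert fc > 1.9
        assert p < 1e-10


class TestBhFdr:
    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_hand_computed_stepup(self):
        # p(i) * n / i, enforced monotone from the largest rank down
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 60)))
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                adj[i] = running
            assert np.allclose(bh_fdr(p), adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def _records(dirs, exp="e1"):
    out = []
    for i, d in enumerate(dirs):
        out.append(
            ASERecord(
                pair_id=f"p{i:03d}", experiment=exp, count_a=10, count_b=10,
                log2fc=1.5 if d == "A" else (-1.5 if d == "B" else 0.0),
                p_value=0.001, fdr=0.001 if d != "none" else 0.9,
                is_ase=d != "none", direction=d,
            )
        )
    return out


def _order(n, chrom="chr1"):
    return {chrom: [f"p{i:03d}" for i in range(n)]}


class TestCallAseBlocks:
    def test_run_of_four_is_block(self):
        blocks = call_ase_blocks(_records(["A"] * 4), _order(4))
        assert len(blocks) == 1 and len(blocks[0]) == 4

    def test_three_is_not_enough(self):
        assert call_ase_blocks(_records(["A"] * 3), _order(3)) == []

    def test_hand_traced_run_rule(self):
        dirs = ["A", "A", "B", "A", "A", "A", "A", "none", "B", "B", "B", "B"]
        blocks = call_ase_blocks(_records(dirs), _order(len(dirs)))
        assert [(b.direction, b.member_pairs) for b in blocks] == [
            ("A", ["p003", "p004", "p005", "p006"]),
            ("B", ["p008", "p009", "p010", "p011"]),
        ]

    def test_blocks_disjoint_and_consistent(self, expression, diploid, pair_order):
        _cfg, _ga, _ann_a, _gb, _ann_b, truth = diploid
        mats, _at, _bt = expression
        order, spans = pair_order
        pairs = [hd.AllelePair(a, b, 1.0)
                 for a, b in truth.allele_pair_truth.items()]
        for exp, m in mats.items():
            recs = ase_experiment(m, pairs, exp)
            rec = {r.pair_id: r for r in recs}
            blocks = call_ase_blocks(recs, order, pair_spans=spans)
            seen = set()
            for b in blocks:
                assert len(b) >= 4
                for pid in b.member_pairs:
                    assert pid not in seen
                    seen.add(pid)
                    assert rec[pid].is_ase and rec[pid].direction == b.direction


def test_ase_block_bed_export(tmp_path):
    from haplodiff.ase import ase_blocks_to_bed

    blk = ASEBlock("chr1", ["p1", "p2", "p3", "p4"], "A", span_a=(1001, 5000))
    p = tmp_path / "blocks.bed"
    ase_blocks_to_bed([blk], p)
    assert p.read_text() == "chr1\t1000\t5000\tASE_A_4\n"


class TestSharingSummary:
    def test_printed_fraction_arithmetic(self):
        # construct sets realising the published marginals
        in_all = {f"c{i}" for i in range(8183)}
        singles = [514, 996, 303, 866]
        sets = {f"e{j}": set(in_all) for j in range(4)}
        uid = itertools.count()
        for j, n in enumerate(singles):
            for _ in range(n):
                sets[f"e{j}"].add(f"s{next(uid)}")
        # distribute the remaining >=2-experiment pairs between e0 and e1
        n_rest = 14_829 - 8183 - sum(singles)
        for _ in range(n_rest):
            x = f"d{next(uid)}"
            sets["e0"].add(x)
            sets["e1"].add(x)
        s = sharing_summary(sets)
        assert s["union_size"] == 14_829
        assert s["n_in_all"] == 8183
        assert s["pct_in_all"] == 55.18
        assert s["n_in_ge2"] == 12_150
        assert s["pct_in_ge2"] == 81.93

    def test_identical_sets_fully_shared(self):
        sets = {"a": {"x", "y"}, "b": {"x", "y"}}
        s = sharing_summary(sets)
        assert s["pct_in_all"] == 100.0

    def test_needs_two_experiments(self):
        with pytest.raises(ValueError):
            sharing_summary({"only": {"x"}})


def _blk(members, direction="A", chrom="chr1"):
    return ASEBlock(chrom, list(members), direction)


class TestSharedBlocks:
    def test_identical_lists_all_shared(self):
        blocks = {e: [_blk(["a", "b", "c", "d"]), _blk(["x", "y", "z", "w"], "B")]
                  for e in ("e1", "e2", "e3")}
        assert len(shared_blocks(blocks)) == 2

    def test_two_shared_pairs_insufficient(self):
        blocks = {
            "e1": [_blk(["a", "b", "c", "d"])],
            "e2": [_blk(["c", "d", "e", "f"])],
        }
        assert shared_blocks(blocks, min_shared_pairs=3) == []

    def test_planted_common_blocks_recovered(self):
        rng = np.random.default_rng(3)
        common = [
            _blk([f"c{b}_{i}" for i in range(5)], "A" if b % 2 else "B")
            for b in range(10)
        ]
        blocks = {}
        for e in range(4):
            noise = [
                _blk([f"n{e}_{j}_{i}" for i in range(4)])
                for j in range(int(rng.integers(1, 4)))
            ]
            blocks[f"e{e}"] = common + noise
        shared = shared_blocks(blocks)
        assert len(shared) == 10
        got = {tuple(s["member_union"]) for s in shared}
        assert got == {tuple(sorted(b.member_pairs)) for b in common}


class TestPromoterSvAssociation:
    def test_balanced_table_p_one(self):
        table = np.array([[5, 5], [5, 5]])
        _o, p = sps.fisher_exact(table)
        assert p == 1.0

    def test_published_marginal_table_construction(self):
        # marginals: 5,052 of 14,829 ASE pairs harbor promoter SVs;
        # 10,665 of all 30,892 pairs do
        a = 5052
        b = 14_829 - a
        c = 10_665 - a
        d = (30_892 - 14_829) - c
        assert [a, b, c, d] == [5052, 9777, 5613, 10_450]
        _o, p = sps.fisher_exact([[a, b], [c, d]])
        assert 0.0 < p <= 1.0

    def test_fisher_matches_hypergeometric_enumeration(self):
        # every 2x2 table with all margins <= 9
        def oracle(a, b, c, d):
            n = a + b + c + d
            if n == 0:
                return 1.0
            r1, c1 = a + b, a + c
            lo = max(0, r1 + c1 - n)
            hi = min(r1, c1)
            probs = {x: sps.hypergeom.pmf(x, n, r1, c1) for x in range(lo, hi + 1)}
            p_obs = probs[a]
            return min(1.0, sum(v for v in probs.values() if v <= p_obs * (1 + 1e-9)))

        for a, b, c, d in itertools.product(range(6), repeat=4):
            if max(a + b, c + d, a + c, b + d) > 9:
                continue
            _o, p = sps.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(oracle(a, b, c, d), abs=1e-9)

    def test_pipeline_on_synthetic(self, diploid, diploid_blocks, allele_pairs):
        _cfg, ga, ann_a, gb, ann_b, _truth = diploid
        pairs, _spec = allele_pairs
        svs = hd.call_svs(diploid_blocks, ga, gb)
        ase_ids = {p.pair_id for p in pairs[: len(pairs) // 2]}
        table, p = hd.promoter_sv_association(
            pairs, ase_ids, svs, ann_a, ann_b,
            chrom_lengths_a={c: len(s) for c, s in ga.sequences.items()},
            chrom_lengths_b={c: len(s) for c, s in gb.sequences.items()},
        )
        assert table.sum() == len(pairs)
        assert 0.0 <= p <= 1.0

    def test_promoter_truncated_at_chromosome_start(self):
        from haplodiff.models import GeneModel, Transcript

        t = Transcript("t", 100, 400, exons=[(100, 400)], cds=[(100, 400)])
        g = GeneModel("g", "c", 100, 400, "+", [t])
        s, e = promoter_interval(g, 2000, chrom_len=10_000)
        assert s == 1 and e == 99


class TestMotifScan:
    def test_tata_both_strands(self):
        hits = motif_scan({"p1": "TTATAA"}, {"tata": "TATA"})
        assert hits[0].occurrences == 2  # forward + reverse-complement strand
        assert hits[0].promoters_with_hit == 1

    def test_n_matches_everywhere(self):
        hits = motif_scan({"p": "ACGT"}, {"any": "N"})
        assert hits[0].occurrences == 8  # 4 per strand

    def test_empty_promoter_set(self):
        hits = motif_scan({}, {"m": "TATA"})
        assert hits[0].occurrences == 0 and hits[0].promoters_with_hit == 0

    def test_overlapping_matches_counted(self):
        # forward strand only: positions 0,1,2 (reverse strand is TTTT)
        hits = motif_scan({"p": "AAAA"}, {"aa": "AA"})
        assert hits[0].occurrences == 3

    def test_invalid_iupac_named(self):
        with pytest.raises(ValueError, match="motifX"):
            iupac_to_regex("TAZA", "motifX")

    def test_exhaustive_window_oracle(self):
        rng = np.random.default_rng(9)
        from haplodiff.models import revcomp

        iupac_sets = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG",
                      "Y": "CT", "N": "ACGT", "W": "AT"}
        for _ in range(20):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
            motif = "".join(
                np.array(list("ACGTRYNW"))[rng.integers(0, 8, 4)]
            )

            def count(s):
                c = 0
                for i in range(len(s) - len(motif) + 1):
                    if all(s[i + j] in iupac_sets[m]
                           for j, m in enumerate(motif)):
                        c += 1
                return c

            hits = motif_scan({"p": seq}, {"m": motif})
            assert hits[0].occurrences == count(seq) + count(revcomp(seq))

    def test_rankings_and_correlation(self):
        hits = motif_scan(
            {"p1": "TATATATA", "p2": "GGGGCCCC"},
            {"tata": "TATA", "gc": "GGCC", "rare": "AAATTT"},
        )
        ranks = motif_rankings(hits)
        assert ranks["by_occurrences"]["tata"] == 1
        rho = rank_correlation(ranks["by_occurrences"], ranks["by_promoters"])
        assert -1.0 <= rho <= 1.0


class TestPipelineCalibration:
    def test_is_ase_criterion_consistency(self, expression, diploid):
        _cfg, _ga, _ann_a, _gb, _ann_b, truth = diploid
        mats, _a, _b = expression
        pairs = [hd.AllelePair(a, b, 1.0)
                 for a, b in truth.allele_pair_truth.items()]
        for exp, m in mats.items():
            for r in ase_experiment(m, pairs, exp):
                assert r.is_ase == (abs(r.log2fc) > 1.0 and r.fdr < 0.01)
                if r.is_ase:
                    assert r.direction == ("A" if r.log2fc > 0 else "B")

    def test_planted_ase_detected(self, expression, diploid):
        _cfg, _ga, _ann_a, _gb, _ann_b, truth = diploid
        mats, ase_truth, _bt = expression
        pairs = [hd.AllelePair(a, b, 1.0)
                 for a, b in truth.allele_pair_truth.items()]
        for exp, m in mats.items():
            called = {r.pair_id: r.direction
                      for r in ase_experiment(m, pairs, exp) if r.is_ase}
            planted = ase_truth[exp]
            tp = sum(1 for pid, d in called.items() if planted.get(pid) == d)
            assert tp / len(planted) >= 0.8
            fp = sum(1 for pid in called if pid not in planted)
            assert fp <= max(2, 0.05 * len(called))
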
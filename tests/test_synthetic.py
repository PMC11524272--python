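"""Synthetic diploid generator: contracts, determinism, planted truth."""

import numpy as np
import pytest

import haplodiff as hd
from haplodiff.models import gene_protein
from haplodiff.synthetic import simulate_kmer_histogram


def _small_cfg(**kw):
    base = dict(
        seed=1, n_chromosomes=1, chrom_length=100_000, n_genes_per_chrom=10,
        snp_rate=0.0, small_indel_rate=0.0, sv_counts={},
        haplotype_specific_gene_fraction=0.0,
    )
    base.update(kw)
    return hd.SimulationConfig(**base)


class TestGenerateHaplotypeA:
    def test_basic_contract(self):
        cfg = _small_cfg()
        genome, ann = hd.generate_haplotype_a(cfg)
        assert set(genome.sequences) == {"chr1"}
        assert len(genome.sequences["chr1"]) == 100_000
        assert len(ann) == 10
        strands = {g.strand for g in ann}
        assert strands <= {"+", "-"}
        for g in ann:
            t = g.longest_transcript()
            assert t.exons and t.cds
            cds_len = sum(e - s + 1 for s, e in t.cds)
            assert cds_len % 3 == 0
            prot = gene_protein(g, genome.sequences[g.chrom])
            assert prot.startswith("M")

    def test_genes_non_overlapping(self):
        _genome, ann = hd.generate_haplotype_a(_small_cfg())
        spans = sorted((g.start, g.end) for g in ann)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2

    def test_determinism_byte_identical(self, tmp_path):
        files = []
        for run in range(2):
            genome, ann = hd.generate_haplotype_a(_small_cfg())
            fa = tmp_path / f"a{run}.fasta"
            gff = tmp_path / f"a{run}.gff3"
            genome.to_fasta(fa)
            ann.to_gff3(gff)
            files.append((fa.read_bytes(), gff.read_bytes()))
        assert files[0] == files[1]

    def test_gc_content_within_binomial_band(self):
        cfg = _small_cfg(chrom_length=1_000_000, n_genes_per_chrom=0, gc_content=0.5)
        genome, _ = hd.generate_haplotype_a(cfg)
        s = genome.sequences["chr1"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert 0.49 <= gc <= 0.51

    def test_infeasible_gene_count_raises(self):
        with pytest.raises(ValueError, match="genes"):
            hd.generate_haplotype_a(_small_cfg(chrom_length=40_000,
                                               n_genes_per_chrom=50))

    def test_invalid_rate_raises(self):
        with pytest.raises(ValueError):
            hd.SimulationConfig(snp_rate=1.5).validate()


class TestMutateToHaplotypeB:
    def test_identity_when_no_events(self):
        cfg = _small_cfg()
        ga, ann = hd.generate_haplotype_a(cfg)
        gb, ann_b, truth = hd.mutate_to_haplotype_b(ga, ann, cfg)
        assert gb.sequences == ga.sequences
        assert not truth.planted_snps and not truth.planted_indels
        assert not truth.planted_svs and not truth.haplotype_specific_truth
        assert len(ann_b) == len(ann)

    def test_snp_count_within_poisson_band(self):
        cfg = _small_cfg(chrom_length=1_000_000, n_genes_per_chrom=0, snp_rate=0.01)
        ga, ann = hd.generate_haplotype_a(cfg)
        _gb, _ann_b, truth = hd.mutate_to_haplotype_b(ga, ann, cfg)
        expect = 0.01 * 1_000_000
        band = 2.576 * np.sqrt(expect)  # 99%
        assert abs(len(truth.planted_snps) - expect) <= band

    def test_snps_are_real_differences(self):
        cfg = _small_cfg(snp_rate=0.005)
        ga, ann = hd.generate_haplotype_a(cfg)
        gb, _ann_b, truth = hd.mutate_to_haplotype_b(ga, ann, cfg)
        for chrom, pos, ref, alt in truth.planted_snps[:50]:
            assert ga.sequences[chrom][pos - 1] == ref
            assert ref != alt

    def test_deletion_through_gene_makes_it_haplotype_specific(self):
        # a deletion-heavy config: genes overlapped by planted deletions must
        # drop from the lifted B annotation and enter the specific truth
        cfg = hd.SimulationConfig(
            seed=7, n_chromosomes=1, chrom_length=300_000, n_genes_per_chrom=30,
            snp_rate=0.0, small_indel_rate=0.0,
            sv_counts={"deletion": 6}, sv_length_range=(500, 2000),
            haplotype_specific_gene_fraction=0.0,
        )
        ga, ann = hd.generate_haplotype_a(cfg)
        _gb, ann_b, truth = hd.mutate_to_haplotype_b(ga, ann, cfg)
        dels = [(s["start_a"], s["end_a"]) for s in truth.planted_svs]
        overlapped = {
            g.gene_id for g in ann
            if any(s <= g.end and g.start <= e for s, e in dels)
        }
        assert overlapped == set(truth.haplotype_specific_truth)
        for gid in overlapped:
            assert gid[:-2] + "_B" not in ann_b.genes

    def test_gene_conservation_invariant(self, diploid):
        _cfg, _ga, ann_a, _gb, _ann_b, truth = diploid
        assert len(ann_a) == len(truth.allele_pair_truth) + len(
            truth.haplotype_specific_truth
        )

    def test_lifted_coordinates_preserve_gene_sequence(self):
        cfg = _small_cfg(snp_rate=0.0, small_indel_rate=0.002,
                         chrom_length=200_000, n_genes_per_chrom=10)
        ga, ann = hd.generate_haplotype_a(cfg)
        gb, ann_b, truth = hd.mutate_to_haplotype_b(ga, ann, cfg)
        # indels never fall in CDS, so the B protein equals the A protein
        for a_id, b_id in truth.allele_pair_truth.items():
            pa = gene_protein(ann.genes[a_id], ga.sequences[ann.genes[a_id].chrom])
            pb = gene_protein(ann_b.genes[b_id], gb.sequences[ann_b.genes[b_id].chrom])
            assert pa == pb

    def test_overcrowded_svs_raise(self):
        cfg = hd.SimulationConfig(
            seed=1, n_chromosomes=1, chrom_length=60_000, n_genes_per_chrom=0,
            sv_counts={"deletion": 40}, sv_length_range=(2000, 4000),
        )
        with pytest.raises(ValueError, match="retries|chrom_length"):
            hd.generate_haplotype_a(cfg)


class TestSimulateExpression:
    def test_no_ase_means_equal_means(self):
        cfg = _small_cfg(n_genes_per_chrom=10, ase_pair_fraction=0.0,
                         n_experiments=1, replicates_per_experiment=200,
                         dispersion=0.05)
        ga, ann = hd.generate_haplotype_a(cfg)
        _gb, _ann_b, truth = hd.mutate_to_haplotype_b(ga, ann, cfg)
        mats, ase_truth, _ = hd.simulate_expression(truth.allele_pair_truth, cfg,
                                                    annotation_a=ann)
        assert ase_truth == {"exp1": {}}
        m = mats["exp1"]
        for a, b in truth.allele_pair_truth.items():
            ma, mb = m.loc[a].mean(), m.loc[b].mean()
            if ma + mb > 50:  # enough signal to compare
                assert abs(np.log2((ma + 1) / (mb + 1))) < 0.5

    def test_planted_fold_change_realized(self):
        cfg = _small_cfg(n_genes_per_chrom=10, ase_pair_fraction=1.0,
                         ase_log2fc=1.0, n_experiments=1,
                         replicates_per_experiment=1000, mean_expression=500)
        ga, ann = hd.generate_haplotype_a(cfg)
        _gb, _ann_b, truth = hd.mutate_to_haplotype_b(ga, ann, cfg)
        mats, ase_truth, _ = hd.simulate_expression(truth.allele_pair_truth, cfg,
                                                    annotation_a=ann)
        m = mats["exp1"]
        pid, direction = next(iter(ase_truth["exp1"].items()))
        a, b = pid, truth.allele_pair_truth[pid]
        fc = np.log2(m.loc[a].mean() / m.loc[b].mean())
        expected = 1.0 if direction == "A" else -1.0
        assert abs(fc - expected) < 0.25

    def test_block_members_share_direction(self, expression, diploid):
        _cfg, _ga, _ann_a, _gb, _ann_b, truth = diploid
        mats, ase_truth, block_truth = expression
        assert block_truth, "config plants two blocks"
        for blk in block_truth:
            for exp, m in mats.items():
                for pid in blk["members"]:
                    assert ase_truth[exp][pid] == blk["direction"]
                    b = truth.allele_pair_truth[pid]
                    ma, mb = m.loc[pid].mean(), m.loc[b].mean()
                    if blk["direction"] == "A":
                        assert ma > mb
                    else:
                        assert mb > ma

    def test_single_replicate_rejected(self):
        cfg = _small_cfg(replicates_per_experiment=1)
        with pytest.raises(ValueError, match="replicate"):
            hd.simulate_expression({"a_A": "a_B"}, cfg)


class TestSimulateKmerHistogram:
    def test_homozygous_single_peak(self):
        cfg = _small_cfg(chrom_length=200_000, n_genes_per_chrom=0)
        ga, ann = hd.generate_haplotype_a(cfg)
        gb, _, _ = hd.mutate_to_haplotype_b(ga, ann, cfg)
        hist = simulate_kmer_histogram(ga, gb, coverage=50, error_rate=0.0,
                                       k=17, seed=3)
        mode = max(hist.bins, key=hist.bins.get)
        assert 90 <= mode <= 110  # both haplotypes contribute

    def test_heterozygous_bimodal(self):
        cfg = _small_cfg(chrom_length=500_000, n_genes_per_chrom=0, snp_rate=0.02)
        ga, ann = hd.generate_haplotype_a(cfg)
        gb, _, _ = hd.mutate_to_haplotype_b(ga, ann, cfg)
        hist = simulate_kmer_histogram(ga, gb, coverage=50, error_rate=0.0,
                                       k=17, seed=3)
        counts = np.zeros(200)
        for m, c in hist.bins.items():
            if m < 200:
                counts[m] = c
        het_mass = counts[35:65].sum()
        hom_mass = counts[85:115].sum()
        assert het_mass > 0 and hom_mass > 0
        assert counts[65:85].sum() < min(het_mass, hom_mass)

    def test_no_error_kmers_when_error_rate_zero(self):
        cfg = _small_cfg(chrom_length=100_000, n_genes_per_chrom=0)
        ga, ann = hd.generate_haplotype_a(cfg)
        gb, _, _ = hd.mutate_to_haplotype_b(ga, ann, cfg)
        hist = simulate_kmer_histogram(ga, gb, coverage=30, error_rate=0.0,
                                       k=17, seed=5)
        # with no errors the low-multiplicity error shoulder is absent
        low = sum(c for m, c in hist.bins.items() if m <= 5)
        assert low < 0.01 * sum(hist.bins.values())

    def test_invalid_coverage(self):
        cfg = _small_cfg(chrom_length=60_000, n_genes_per_chrom=0)
        ga, ann = hd.generate_haplotype_a(cfg)
        with pytest.raises(ValueError, match="coverage"):
            simulate_kmer_histogram(ga, ga, coverage=0, error_rate=0, k=17, seed=1)
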
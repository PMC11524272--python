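"""Shared fixtures: one moderately sized synthetic diploid reused across
modules (expensive stages are computed once per session)."""

import pytest

import haplodiff as hd
from haplodiff.alleles import genome_similarity_fn


@pytest.fixture(scope="session")
def default_config():
    return hd.SimulationConfig(
        seed=1,
        ase_block_spec=[("chr1", 5, 5, "A"), ("chr2", 10, 6, "B")],
    )


@pytest.fixture(scope="session")
def diploid(default_config):
    """(config, genome_a, ann_a, genome_b, ann_b, truth)."""
    cfg = default_config
    genome_a, ann_a = hd.generate_haplotype_a(cfg)
    genome_b, ann_b, truth = hd.mutate_to_haplotype_b(genome_a, ann_a, cfg)
    return cfg, genome_a, ann_a, genome_b, ann_b, truth


@pytest.fixture(scope="session")
def diploid_blocks(diploid):
    _cfg, genome_a, _ann_a, genome_b, _ann_b, _truth = diploid
    return hd.align_haplotypes(genome_a, genome_b)


@pytest.fixture(scope="session")
def allele_pairs(diploid, diploid_blocks):
    _cfg, genome_a, ann_a, genome_b, ann_b, _truth = diploid
    sim = genome_similarity_fn(ann_a, ann_b, genome_a, genome_b)
    return hd.assign_alleles(ann_a, ann_b, diploid_blocks, similarity=sim)


@pytest.fixture(scope="session")
def expression(diploid):
    cfg, _ga, ann_a, _gb, _ann_b, truth = diploid
    return hd.simulate_expression(
        truth.allele_pair_truth, cfg, annotation_a=ann_a,
        specific_genes=truth.haplotype_specific_truth,
    )


@pytest.fixture(scope="session")
def pair_order(diploid):
    """Pair ids per chromosome in A-coordinate order, plus spans."""
    _cfg, _ga, ann_a, _gb, _ann_b, truth = diploid
    pos = {g.gene_id: (g.chrom, g.start, g.end) for g in ann_a}
    order, spans = {}, {}
    for p in sorted(truth.allele_pair_truth, key=lambda x: (pos[x][0], pos[x][1])):
        order.setdefault(pos[p][0], []).append(p)
        spans[p] = (pos[p][1], pos[p][2])
    return order, spans
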
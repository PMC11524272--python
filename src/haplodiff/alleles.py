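"""Allele-pair identification and comparative gene-feature statistics.

Two genes, one per haplotype, are alleles when they are each other's top
protein similarity and both lie within the same one-to-one collinearity
block (choosing for each gene the largest block containing it). Genes left
over after that stage are paired by reciprocal top similarity alone when at
least one of the two sits on an unplaced scaffold; everything still unpaired
is haplotype-specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .models import AllelePair, GeneAnnotation, gene_protein

GENE_IN_BLOCK_FRACTION = 0.90
MIN_PAIR_SIMILARITY = 0.2

_BLOSUM = substitution_matrices.load("BLOSUM62")
_VALID_RESIDUES = set(str(_BLOSUM.alphabet))


def _protein_aligner():
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _BLOSUM
    al.open_gap_score = -11
    al.extend_gap_score = -1
    return al


_PALIGNER = _protein_aligner()


def protein_similarity(prot_a: str, prot_b: str) -> float:
    """Normalized global-alignment similarity in [0, 1] (BLOSUM62; score
    divided by the self-score of the longer protein). Symmetric."""
    for name, p in (("prot_a", prot_a), ("prot_b", prot_b)):
        if not p:
            raise ValueError(f"{name} is empty")
        bad = sorted(set(p) - _VALID_RESIDUES)
        if bad:
            raise ValueError(f"invalid residues in {name}: {','.join(bad)}")
    longer = prot_a if len(prot_a) >= len(prot_b) else prot_b
    self_score = _PALIGNER.score(longer, longer)
    score = _PALIGNER.score(prot_a, prot_b)
    return float(min(max(score / self_score, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Allele assignment
# ---------------------------------------------------------------------------


def _gene_in_interval(gene, start, end, frac=GENE_IN_BLOCK_FRACTION) -> bool:
    ov = min(gene.end, end) - max(gene.start, start) + 1
    return ov >= frac * gene.length


def assign_alleles(genes_a: GeneAnnotation, genes_b: GeneAnnotation, blocks,
                   placed: dict | None = None,
                   similarity: "callable | dict" = None,
                   min_similarity: float = MIN_PAIR_SIMILARITY):
    """Two-stage allele pairing.

    `similarity` is either a callable (gene_a_id, gene_b_id) -> score or a
    precomputed {(a, b): score} dict. `placed` maps gene id to its
    chromosome or scaffold name; names absent from the block chromosomes are
    treated as unplaced scaffolds (stage-2 candidates).

    Returns (pairs, haplotype_specific_ids); every gene appears in exactly
    one pair or in the specific set. Deterministic: ties broken by higher
    similarity then lexicographically smaller id pair.
    """
    if placed is None:
        placed = {g.gene_id: g.chrom for g in list(genes_a) + list(genes_b)}
    sim_cache: dict[tuple, float] = {}

    def sim(a_id, b_id):
        key = (a_id, b_id)
        if key not in sim_cache:
            if callable(similarity):
                sim_cache[key] = similarity(a_id, b_id)
            else:
                sim_cache[key] = similarity.get(key, 0.0)
        return sim_cache[key]

    # stage 1: largest shared one-to-one block
    block_of_a: dict[str, object] = {}
    block_of_b: dict[str, object] = {}
    for blk in sorted(blocks, key=lambda b: -(b.end_a - b.start_a)):
        for g in genes_a:
            if g.gene_id not in block_of_a and g.chrom == blk.chrom_a and \
                    _gene_in_interval(g, blk.start_a, blk.end_a):
                block_of_a[g.gene_id] = blk
        for g in genes_b:
            if g.gene_id not in block_of_b and g.chrom == blk.chrom_b and \
                    _gene_in_interval(g, blk.start_b, blk.end_b):
                block_of_b[g.gene_id] = blk

    members_a: dict[str, list[str]] = {}
    members_b: dict[str, list[str]] = {}
    for gid, blk in block_of_a.items():
        members_a.setdefault(blk.id, []).append(gid)
    for gid, blk in block_of_b.items():
        members_b.setdefault(blk.id, []).append(gid)

    pairs: list[AllelePair] = []
    paired_a: set = set()
    paired_b: set = set()
    for blk_id in sorted(set(members_a) & set(members_b)):
        cand_a = sorted(members_a[blk_id])
        cand_b = sorted(members_b[blk_id])
        scores = {
            (a, b): sim(a, b) for a in cand_a for b in cand_b
        }
        best_for_a = {
            a: max(cand_b, key=lambda b: (scores[(a, b)], b)) for a in cand_a
        }
        best_for_b = {
            b: max(cand_a, key=lambda a: (scores[(a, b)], a)) for b in cand_b
        }
        for a in cand_a:
            b = best_for_a[a]
            if best_for_b[b] == a and scores[(a, b)] >= min_similarity:
                pairs.append(
                    AllelePair(a, b, scores[(a, b)], block_id=blk_id,
                               evidence="collinear_rbh")
                )
                paired_a.add(a)
                paired_b.add(b)

    # stage 2: reciprocal best hit when a scaffold gene is involved
    chrom_names = {b.chrom_a for b in blocks} | {b.chrom_b for b in blocks}
    rest_a = [g.gene_id for g in genes_a if g.gene_id not in paired_a]
    rest_b = [g.gene_id for g in genes_b if g.gene_id not in paired_b]
    stage2_a = sorted(rest_a)
    stage2_b = sorted(rest_b)
    if stage2_a and stage2_b:
        scores2 = {}
        for a in stage2_a:
            for b in stage2_b:
                if placed.get(a) in chrom_names and placed.get(b) in chrom_names:
                    continue  # both placed: stage 2 does not apply
                scores2[(a, b)] = sim(a, b)
        cand_a2 = sorted({a for a, _ in scores2})
        cand_b2 = sorted({b for _, b in scores2})
        best_a2 = {
            a: max((b for b in cand_b2 if (a, b) in scores2),
                   key=lambda b: (scores2[(a, b)], b), default=None)
            for a in cand_a2
        }
        best_b2 = {
            b: max((a for a in cand_a2 if (a, b) in scores2),
                   key=lambda a: (scores2[(a, b)], a), default=None)
            for b in cand_b2
        }
        for a in cand_a2:
            b = best_a2[a]
            if b is not None and best_b2[b] == a and scores2[(a, b)] >= min_similarity:
                pairs.append(
                    AllelePair(a, b, scores2[(a, b)], evidence="scaffold_rbh")
                )
                paired_a.add(a)
                paired_b.add(b)

    specific = sorted(
        [g.gene_id for g in genes_a if g.gene_id not in paired_a]
        + [g.gene_id for g in genes_b if g.gene_id not in paired_b]
    )
    pairs.sort(key=lambda p: (p.gene_a_id, p.gene_b_id))
    return pairs, specific


def genome_similarity_fn(genes_a: GeneAnnotation, genes_b: GeneAnnotation,
                         genome_a, genome_b):
    """Protein-similarity callable over the longest isoform of each gene."""
    prots: dict[str, str] = {}

    def prot(gid, ann, genome):
        if gid not in prots:
            g = ann.genes[gid]
            prots[gid] = gene_protein(g, genome.sequences[g.chrom])
        return prots[gid]

    def fn(a_id, b_id):
        pa = prot(a_id, genes_a, genome_a)
        pb = prot(b_id, genes_b, genome_b)
        if not pa or not pb:
            return 0.0
        return protein_similarity(pa, pb)

    return fn


# ---------------------------------------------------------------------------
# Feature statistics
# ---------------------------------------------------------------------------


@dataclass
class GeneFeatureStats:
    gene_class: str  # haplotype_specific | allelic | all
    n: int
    gene_length: tuple = (float("nan"), float("nan"))  # (mean, sd)
    cds_length: tuple = (float("nan"), float("nan"))
    exon_length: tuple = (float("nan"), float("nan"))
    intron_length: tuple = (float("nan"), float("nan"))
    mean_rpkm: float = float("nan")
    rpkm_cv: float = float("nan")
    letters: dict = field(default_factory=dict)  # feature -> group letter(s)


def rpkm_matrix(counts: pd.DataFrame, gene_lengths: dict) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads; the per-sample total over
    all gene copies is the million-scaling denominator."""
    lens = pd.Series({g: gene_lengths[g] for g in counts.index}, dtype=float)
    totals = counts.sum(axis=0) / 1e6
    return counts.div(totals, axis=1).div(lens / 1e3, axis=0)


def _mean_sd(values) -> tuple:
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return (float(v.mean()) if v.size else float("nan"), float("nan"))
    return float(v.mean()), float(v.std(ddof=1))


def _compact_letters(classes, means, sig_pairs) -> dict:
    """Compact letter display: classes not significantly different share a
    letter (insert-and-absorb on the sorted means)."""
    order = sorted(range(len(classes)), key=lambda i: -means[i])
    letters = {c: "" for c in classes}
    groups: list[set] = []
    for i in order:
        placed_any = False
        for grp in groups:
            if all((classes[i], classes[j]) not in sig_pairs and
                   (classes[j], classes[i]) not in sig_pairs for j in grp):
                grp.add(i)
                placed_any = True
        if not placed_any:
            groups.append({i})
    # absorb subsets
    groups = [g for g in groups if not any(g < h for h in groups)]
    for li, grp in enumerate(groups):
        for i in grp:
            letters[classes[i]] += chr(ord("a") + li)
    return {c: "".join(sorted(s)) for c, s in letters.items()}


def tukey_letters(values_by_class: dict, alpha: float = 0.05) -> dict:
    """Tukey HSD multiple comparison -> compact letter display per class."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    classes = sorted(values_by_class)
    data = np.concatenate([np.asarray(values_by_class[c], float) for c in classes])
    labels = np.concatenate(
        [np.full(len(values_by_class[c]), c, dtype=object) for c in classes]
    )
    if len(classes) < 2 or any(len(values_by_class[c]) < 2 for c in classes):
        return {c: "a" for c in classes}
    res = pairwise_tukeyhsd(data, labels, alpha=alpha)
    sig_pairs = set()
    for row, reject in zip(res.summary().data[1:], res.reject):
        if reject:
            sig_pairs.add((str(row[0]), str(row[1])))
    means = [float(np.mean(values_by_class[c])) for c in classes]
    return _compact_letters(classes, means, sig_pairs)


def feature_stats(pairs, specific, annotation_all: GeneAnnotation,
                  counts: pd.DataFrame | None = None) -> list[GeneFeatureStats]:
    """Per-class (haplotype-specific / allelic / all) gene feature summaries
    with Tukey HSD group letters at alpha = 0.05."""
    allelic_ids = sorted({p.gene_a_id for p in pairs} | {p.gene_b_id for p in pairs})
    specific_ids = sorted(specific)
    classes = {
        "haplotype_specific": specific_ids,
        "allelic": allelic_ids,
        "all": sorted(set(allelic_ids) | set(specific_ids)),
    }

    def feats(gid):
        g = annotation_all.genes[gid]
        t = g.longest_transcript()
        exon = sum(e - s + 1 for s, e in t.exons)
        return {
            "gene_length": g.length,
            "cds_length": sum(e - s + 1 for s, e in t.cds),
            "exon_length": exon,
            "intron_length": g.length - exon,
        }

    per_gene = {gid: feats(gid) for gid in classes["all"] if gid in annotation_all.genes}

    rpkm = None
    if counts is not None:
        lengths = {gid: annotation_all.genes[gid].length
                   for gid in counts.index if gid in annotation_all.genes}
        usable = [g for g in counts.index if g in lengths]
        rpkm = rpkm_matrix(counts.loc[usable], lengths)

    out = []
    letter_data: dict[str, dict] = {}
    for feat in ("gene_length", "cds_length", "exon_length", "intron_length"):
        letter_data[feat] = {
            c: [per_gene[g][feat] for g in ids if g in per_gene]
            for c, ids in classes.items()
            if c != "all"
        }
    feat_letters = {
        feat: tukey_letters(vals) if all(len(v) >= 2 for v in vals.values()) else {}
        for feat, vals in letter_data.items()
    }

    for cname, ids in classes.items():
        ids_here = [g for g in ids if g in per_gene]
        if len(ids_here) < 2:
            warnings.warn(f"class {cname!r} has < 2 members; statistics suppressed")
            out.append(GeneFeatureStats(cname, len(ids_here)))
            continue
        st = GeneFeatureStats(cname, len(ids_here))
        for feat in ("gene_length", "cds_length", "exon_length", "intron_length"):
            setattr(st, feat, _mean_sd([per_gene[g][feat] for g in ids_here]))
        if rpkm is not None:
            sub = rpkm.loc[[g for g in ids_here if g in rpkm.index]]
            if len(sub):
                pooled = sub.to_numpy().ravel()
                st.mean_rpkm = float(pooled.mean())
                st.rpkm_cv = (
                    100.0 * float(pooled.std(ddof=1)) / st.mean_rpkm
                    if st.mean_rpkm > 0
                    else float("nan")
                )
        st.letters = {
            feat: feat_letters[feat].get(cname, "") for feat in feat_letters
        }
        out.append(st)
    return out
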
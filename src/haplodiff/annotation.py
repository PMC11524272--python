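"""Genic-location and functional-impact annotation of variants.

Each variant receives exactly one of twelve location groups (downstream,
exon, gene, intergenic, intron, splice site acceptor/donor/region,
transcript, upstream, 3'/5' UTR) under a fixed precedence, and variants
touching coding sequence or splice sites receive an effect and an impact
class (HIGH / MODERATE / LOW / MODIFIER) from the coding consequence.
"""

from __future__ import annotations

import warnings

from Bio.Seq import Seq

from .models import (
    AnnotatedVariant,
    GeneAnnotation,
    GeneModel,
    VariantCall,
    percent,
    revcomp,
)

UP_DOWN_WINDOW = 5000

# most specific first; a variant's location is the highest-precedence
# category achieved by any base it touches, over any overlapping gene
LOCATION_PRECEDENCE = (
    "splice_site_acceptor",
    "splice_site_donor",
    "splice_site_region",
    "utr_5_prime",
    "utr_3_prime",
    "exon",
    "intron",
    "transcript",
    "gene",
    "upstream",
    "downstream",
    "intergenic",
)
_RANK = {loc: i for i, loc in enumerate(LOCATION_PRECEDENCE)}


def _variant_interval(variant: VariantCall) -> tuple[int, int]:
    return variant.span_a


def _position_categories(pos: int, gene: GeneModel,
                         window: int = UP_DOWN_WINDOW) -> list[str]:
    """All location categories position `pos` attains within `gene`."""
    cats: list[str] = []
    plus = gene.strand == "+"
    for t in gene.transcripts:
        in_tx = t.start <= pos <= t.end
        exons = sorted(t.exons)
        cds = sorted(t.cds)
        in_exon = any(s <= pos <= e for s, e in exons)
        in_cds = any(s <= pos <= e for s, e in cds)
        if in_tx:
            cats.append("transcript")
        introns = t.introns()
        for s, e in introns:
            if not s <= pos <= e:
                continue
            cats.append("intron")
            # donor = first 2 intronic bases at the 5' end of the intron
            d_off = pos - s if plus else e - pos
            a_off = e - pos if plus else pos - s
            if d_off < 2:
                cats.append("splice_site_donor")
            if a_off < 2:
                cats.append("splice_site_acceptor")
            if 2 <= d_off <= 7 or 2 <= a_off <= 7:  # intronic 3-8 bp
                cats.append("splice_site_region")
        if in_exon:
            # exonic 1-3 bp from an exon/intron junction
            if any(1 <= js - pos <= 3 or 1 <= pos - je <= 3 for js, je in introns):
                cats.append("splice_site_region")
            if in_cds:
                cats.append("exon")
            else:
                first_cds = cds[0][0] if cds else None
                if first_cds is None:
                    cats.append("exon")
                elif (pos < first_cds) == plus:
                    cats.append("utr_5_prime")
                else:
                    cats.append("utr_3_prime")
    if gene.start <= pos <= gene.end:
        cats.append("gene")
    if plus:
        if gene.start - window <= pos < gene.start:
            cats.append("upstream")
        if gene.end < pos <= gene.end + window:
            cats.append("downstream")
    else:
        if gene.end < pos <= gene.end + window:
            cats.append("upstream")
        if gene.start - window <= pos < gene.start:
            cats.append("downstream")
    return cats


def classify_location(variant: VariantCall, annotation: GeneAnnotation,
                      chrom_lengths: dict | None = None,
                      up_down_window: int = UP_DOWN_WINDOW) -> str:
    """Assign the variant its single location group."""
    lo, hi = _variant_interval(variant)
    if chrom_lengths is not None:
        L = chrom_lengths.get(variant.chrom_a)
        if L is not None and (hi > L or lo < 1):
            raise ValueError(f"variant at {variant.chrom_a}:{lo}-{hi} beyond bounds")
    best = "intergenic"
    for gene in annotation:
        if gene.chrom != variant.chrom_a:
            continue
        if hi < gene.start - up_down_window or lo > gene.end + up_down_window:
            continue
        for pos in range(lo, hi + 1):
            for cat in _position_categories(pos, gene, up_down_window):
                if _RANK[cat] < _RANK[best]:
                    best = cat
    return best


# ---------------------------------------------------------------------------
# Coding effect
# ---------------------------------------------------------------------------


def _cds_map(gene: GeneModel):
    """(ordered genomic CDS positions 5'->3', spliced CDS coordinates)."""
    t = gene.longest_transcript()
    spans = sorted(t.cds)
    positions: list[int] = []
    for s, e in spans:
        positions.extend(range(s, e + 1))
    if gene.strand == "-":
        positions.reverse()
    return positions


def _splice_site_hit(variant: VariantCall, gene: GeneModel):
    lo, hi = _variant_interval(variant)
    plus = gene.strand == "+"
    for t in gene.transcripts:
        for s, e in t.introns():
            donor = (s, s + 1) if plus else (e - 1, e)
            acceptor = (e - 1, e) if plus else (s, s + 1)
            if lo <= donor[1] and donor[0] <= hi:
                return "splice_donor_variant"
            if lo <= acceptor[1] and acceptor[0] <= hi:
                return "splice_acceptor_variant"
    return None


def classify_effect(variant: VariantCall, gene: GeneModel,
                    chrom_seq: str) -> tuple[str, str]:
    """(effect, impact) of a variant on a gene's coding sequence.

    Variants outside CDS and splice sites are MODIFIER. CDS lengths not
    divisible by 3 raise a warning and the effect is computed on the frame
    anchored at the start codon.
    """
    splice = _splice_site_hit(variant, gene)
    if splice:
        return splice, "HIGH"

    positions = _cds_map(gene)
    if not positions:
        return "non_coding", "MODIFIER"
    if len(positions) % 3 != 0:
        warnings.warn(f"CDS length of {gene.gene_id} not divisible by 3")
    pos_index = {p: i for i, p in enumerate(positions)}
    lo, hi = _variant_interval(variant)
    touched = [pos_index[p] for p in range(lo, hi + 1) if p in pos_index]
    if not touched:
        return "non_coding", "MODIFIER"

    if variant.vtype in ("INS", "DEL"):
        if variant.vtype == "INS":
            # insertion is coding only if strictly inside the CDS span
            indel_len = len(variant.alt)
        else:
            indel_len = len(touched)  # deleted coding bases
        if indel_len % 3 != 0:
            return "frameshift", "HIGH"
        return (
            ("inframe_insertion", "MODERATE")
            if variant.vtype == "INS"
            else ("inframe_deletion", "MODERATE")
        )

    # SNP
    i = touched[0]
    codon_i = i // 3
    codon_pos = [positions[3 * codon_i + j] for j in range(3)]
    ref_codon = "".join(chrom_seq[p - 1] for p in sorted(codon_pos))
    alt_base = variant.alt
    new_seq = {p: chrom_seq[p - 1] for p in sorted(codon_pos)}
    new_seq[variant.pos_a] = alt_base
    alt_codon = "".join(new_seq[p] for p in sorted(codon_pos))
    if gene.strand == "-":
        ref_codon, alt_codon = revcomp(ref_codon), revcomp(alt_codon)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if codon_i == 0 and ref_aa == "M" and alt_aa != "M":
        return "start_lost", "HIGH"
    if ref_aa != "*" and alt_aa == "*":
        return "stop_gained", "HIGH"
    if ref_aa == "*" and alt_aa != "*":
        return "stop_lost", "HIGH"
    if ref_aa == alt_aa:
        return "synonymous", "LOW"
    return "missense", "MODERATE"


def annotate_variants(variants, annotation: GeneAnnotation, genome_a,
                      up_down_window: int = UP_DOWN_WINDOW) -> list[AnnotatedVariant]:
    """Location + effect annotation for a variant list.

    The most severe effect over all overlapping genes is reported; the
    location is the single highest-precedence category.
    """
    by_chrom = annotation.by_chrom()
    impact_rank = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3}
    out = []
    for v in variants:
        loc = classify_location(v, annotation, up_down_window=up_down_window)
        lo, hi = _variant_interval(v)
        effect, impact, gene_id = "intergenic_or_regulatory", "MODIFIER", None
        for g in by_chrom.get(v.chrom_a, []):
            if hi < g.start or lo > g.end:
                continue
            seq = genome_a.sequences[g.chrom]
            e, im = classify_effect(v, g, seq)
            if impact_rank[im] < impact_rank[impact]:
                effect, impact, gene_id = e, im, g.gene_id
        out.append(AnnotatedVariant(v, loc, effect, impact, gene_id))
    return out


def high_impact_gene_fraction(n_high_genes: int, n_genes: int) -> float:
    """Percent of genes carrying at least one HIGH-impact variant (2 dp)."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return percent(n_high_genes, n_genes, 2)


def high_impact_genes(annotated) -> set:
    return {a.gene_id for a in annotated if a.impact == "HIGH" and a.gene_id}
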
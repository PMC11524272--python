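"""Variant calling between haplotypes inside collinearity blocks.

Small variants (SNPs and indels < 50 bp) come from base-level alignment of
inter-anchor gaps, reported in haplotype-A coordinates with indels
left-aligned. Events of >= 50 bp are classified into the five structural
classes: deletion, insertion, duplication (extra tandem copy in B of an A
unit), contraction (copy loss in B) and translocation (a block out of place
relative to its neighbours or on another chromosome).
"""

from __future__ import annotations

import numpy as np

from .alignment import GAP_ALIGN_LIMIT, align_gap
from .models import CollinearityBlock, SVCall, VariantCall, percent, revcomp

SV_MIN_SIZE = 50
_COPY_IDENTITY = 85.0  # % identity for the extra/lost unit to count as a copy


# ---------------------------------------------------------------------------
# Small variants
# ---------------------------------------------------------------------------


def _left_align(chrom_seq: str, pos: int, seq: str, vtype: str, floor: int):
    """Left-normalize an indel (1-based pos; DEL pos = first deleted base,
    INS pos = base after which insertion occurs)."""
    if vtype == "DEL":
        L = len(seq)
        while pos > floor and chrom_seq[pos - 2] == chrom_seq[pos + L - 2]:
            pos -= 1
        return pos, chrom_seq[pos - 1 : pos + L - 1]
    while pos >= floor and pos >= 1 and chrom_seq[pos - 1] == seq[-1]:
        seq = seq[-1] + seq[:-1]
        pos -= 1
    return pos, seq


def _gap_segments(block: CollinearityBlock, seq_a: str, seq_b: str):
    """Yield (a_start_1based, seg_a, seg_b) per inter-anchor gap, with seg_b
    in A-orientation."""
    chain = block.anchors
    for prev, nxt in zip(chain, chain[1:]):
        a_start = prev.end_a + 1
        seg_a = seq_a[prev.end_a : nxt.pos_a - 1]
        if block.strand == "+":
            seg_b = seq_b[prev.end_b : nxt.pos_b - 1]
        else:
            seg_b = revcomp(seq_b[nxt.end_b : prev.pos_b - 1])
        yield a_start, seg_a, seg_b


def call_small_variants(blocks, genome_a, genome_b,
                        sv_min_size: int = SV_MIN_SIZE) -> list[VariantCall]:
    """SNPs and < 50 bp indels inside collinearity blocks, A as reference."""
    calls: list[VariantCall] = []
    for block in blocks:
        seq_a = genome_a.sequences[block.chrom_a]
        seq_b = genome_b.sequences[block.chrom_b]
        for a_start, seg_a, seg_b in _gap_segments(block, seq_a, seq_b):
            if len(seg_a) > GAP_ALIGN_LIMIT or len(seg_b) > GAP_ALIGN_LIMIT:
                continue
            if not seg_a and not seg_b:
                continue
            g = align_gap(seg_a, seg_b)
            a_pos = a_start  # 1-based position of next unconsumed A base
            b_off = 0
            for op, ln in g.cigar:
                if op == "=":
                    a_pos += ln
                    b_off += ln
                elif op == "X":
                    for i in range(ln):
                        calls.append(
                            VariantCall(
                                block.chrom_a,
                                a_pos + i,
                                seg_a[a_pos + i - a_start],
                                seg_b[b_off + i],
                                "SNP",
                                block.id,
                            )
                        )
                    a_pos += ln
                    b_off += ln
                elif op == "D":  # extra bases in A -> deletion in B
                    if ln < sv_min_size:
                        pos, ref = _left_align(
                            seq_a, a_pos, seq_a[a_pos - 1 : a_pos + ln - 1],
                            "DEL", block.start_a,
                        )
                        calls.append(
                            VariantCall(block.chrom_a, pos, ref, "", "DEL", block.id)
                        )
                    a_pos += ln
                else:  # I: extra bases in B -> insertion
                    if ln < sv_min_size:
                        ins = seg_b[b_off : b_off + ln]
                        pos, alt = _left_align(seq_a, a_pos - 1, ins, "INS",
                                               block.start_a)
                        calls.append(
                            VariantCall(block.chrom_a, pos, "", alt, "INS", block.id)
                        )
                    b_off += ln
    calls.sort(key=lambda v: (v.chrom_a, v.pos_a, v.vtype))
    return calls


def heterozygosity_rate(n_variants: int, genome_size: int) -> float:
    """Heterozygous variants per haplotype-A base, as a percent (2 decimals,
    rounded half away from zero)."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return percent(n_variants, genome_size, 2)


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------


def _unit_matches(unit: str, context: str, min_identity: float = _COPY_IDENTITY) -> bool:
    """Does `unit` occur (approximately) within `context`?"""
    import edlib

    if not unit or not context:
        return False
    res = edlib.align(unit, context, mode="HW", task="distance")
    dist = res["editDistance"]
    if dist < 0:
        return False
    return 100.0 * (1.0 - dist / len(unit)) >= min_identity


_TRANS_SEARCH_MIN = 5000  # bp: search displaced copies only for large events


def _find_elsewhere(segment: str, genome, max_err: float = 0.10):
    """Locate `segment` in another genome; (chrom, start_1based, end) or None."""
    import edlib

    k = int(max_err * len(segment))
    for chrom, seq in genome.sequences.items():
        res = edlib.align(segment, seq, mode="HW", task="locations", k=k)
        if res["editDistance"] >= 0 and res["locations"]:
            s, e = res["locations"][0]
            return chrom, s + 1, e + 1
    return None


def _classify_indel_gap(seq_a, seg_a, seg_b, a_start, block, min_size,
                        genome_a=None, genome_b=None):
    """Classify one >= 50 bp inter-anchor size difference (or None when the
    event is the receiving end of a translocation, reported from its source).
    """
    ga, gb = len(seg_a), len(seg_b)
    size = abs(ga - gb)
    a_end = a_start + ga - 1
    chrom_b, start_b, end_b = block.chrom_b, 0, 0
    if ga > gb:  # missing sequence in B
        # contraction: the lost material duplicates the adjacent A sequence
        unit = seg_a
        left_ctx = seq_a[max(a_start - 1 - ga - 100, 0) : a_start - 1]
        right_ctx = seq_a[a_end : a_end + ga + 100]
        if size >= min_size and (
            _unit_matches(unit[:size], left_ctx) or _unit_matches(unit[-size:], right_ctx)
            or _unit_matches(unit, left_ctx) or _unit_matches(unit, right_ctx)
        ):
            svtype = "contraction"
        elif size >= _TRANS_SEARCH_MIN and genome_b is not None and (
            hit := _find_elsewhere(seg_a, genome_b)
        ):
            svtype = "translocation"
            chrom_b, start_b, end_b = hit
        else:
            svtype = "deletion"
    else:  # extra sequence in B
        extra = seg_b
        left_ctx = seq_a[max(a_start - 1 - gb - 100, 0) : a_start - 1]
        right_ctx = seq_a[a_end : a_end + gb + 100]
        if size >= min_size and (
            _unit_matches(extra[:size], left_ctx) or _unit_matches(extra[-size:], right_ctx)
            or _unit_matches(extra, left_ctx) or _unit_matches(extra, right_ctx)
        ):
            svtype = "duplication"
        elif size >= _TRANS_SEARCH_MIN and genome_a is not None and \
                _find_elsewhere(seg_b, genome_a):
            return None  # receiving end of a translocation
        else:
            svtype = "insertion"
    return SVCall(
        svtype=svtype,
        chrom_a=block.chrom_a,
        start_a=a_start,
        end_a=max(a_end, a_start),
        chrom_b=chrom_b,
        start_b=start_b,
        end_b=end_b,
        size=size,
    )


def _translocated_blocks(blocks, k_neighbors: int = 5) -> set:
    """Block ids breaking the dominant A/B order of their neighbourhood, or
    paired with a different chromosome than their A-chromosome's dominant
    partner."""
    out = set()
    by_chrom: dict[str, list] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom_a, []).append(b)
    for chrom, lst in by_chrom.items():
        lst.sort(key=lambda b: b.start_a)
        # dominant B chromosome by aligned length
        tally: dict[str, float] = {}
        for b in lst:
            tally[b.chrom_b] = tally.get(b.chrom_b, 0.0) + b.aligned_length
        dominant = max(tally, key=tally.get)
        same = [b for b in lst if b.chrom_b == dominant]
        for b in lst:
            if b.chrom_b != dominant:
                out.add(b.id)
        for i, b in enumerate(same):
            nb = [x for j, x in enumerate(same) if j != i]
            nb.sort(key=lambda x: abs(x.start_a - b.start_a))
            nb = nb[:k_neighbors]
            if not nb:
                continue
            # expected B position from the median neighbour offset
            offsets = sorted(x.start_b - x.start_a for x in nb)
            med = offsets[len(offsets) // 2]
            if abs((b.start_b - b.start_a) - med) > max(b.span_a, 20_000):
                out.add(b.id)
    return out


def call_svs(blocks, genome_a, genome_b, min_size: int = SV_MIN_SIZE) -> list[SVCall]:
    """Classify >= 50 bp events into the five structural classes.

    Translocations are called at block level; indel-scale calls whose A
    interval is explained by a translocated block are suppressed (the
    sequence is present elsewhere in B, not lost).
    """
    trans_ids = _translocated_blocks(blocks)
    trans_blocks = [b for b in blocks if b.id in trans_ids]
    svs: list[SVCall] = []
    for b in trans_blocks:
        svs.append(
            SVCall(
                "translocation", b.chrom_a, b.start_a, b.end_a,
                b.chrom_b, b.start_b, b.end_b, b.span_a,
            )
        )
    for block in blocks:
        if block.id in trans_ids:
            continue
        seq_a = genome_a.sequences[block.chrom_a]
        seq_b = genome_b.sequences[block.chrom_b]
        for a_start, seg_a, seg_b in _gap_segments(block, seq_a, seq_b):
            if abs(len(seg_a) - len(seg_b)) < min_size:
                continue
            call = _classify_indel_gap(
                seq_a, seg_a, seg_b, a_start, block, min_size,
                genome_a=genome_a, genome_b=genome_b,
            )
            if call is None:
                continue
            covered = any(
                t.chrom_a == call.chrom_a
                and min(t.end_a, call.end_a) - max(t.start_a, call.start_a) + 1
                >= 0.8 * (call.end_a - call.start_a + 1)
                for t in trans_blocks
            )
            if not covered:
                svs.append(call)
    svs.sort(key=lambda s: (s.chrom_a, s.start_a))
    return svs


# ---------------------------------------------------------------------------
# VCF utilities
# ---------------------------------------------------------------------------


def write_vcf(calls, genome_a, path) -> None:
    """Minimal VCF 4.2 of the small-variant calls, haplotype A as reference."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in genome_a.sequences.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in calls:
            seq = genome_a.sequences[v.chrom_a]
            if v.vtype == "SNP":
                pos, ref, alt = v.pos_a, v.ref, v.alt
            elif v.vtype == "DEL":
                pos = max(v.pos_a - 1, 1)
                anchor = seq[pos - 1]
                ref, alt = anchor + v.ref, anchor
            else:  # INS: pos_a is the base left of the insertion
                pos = max(v.pos_a, 1)
                anchor = seq[pos - 1]
                ref, alt = anchor, anchor + v.alt
            fh.write(
                f"{v.chrom_a}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                f"TYPE={v.vtype};BLOCK={v.block_id}\n"
            )


def count_het_per_sample(vcf_path) -> list[tuple[str, int]]:
    """Per-sample heterozygous-genotype counts from a multi-sample VCF,
    ranked descending. Genotypes with any missing allele are excluded."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"no genotype (GT) samples in {vcf_path}")
    counts = np.zeros(len(samples), dtype=np.int64)
    for var in vcf:
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if len(alleles) >= 2 and min(alleles) >= 0 and len(set(alleles)) > 1:
                counts[i] += 1
    ranked = sorted(zip(samples, counts.tolist()), key=lambda x: (-x[1], x[0]))
    return ranked


def svs_to_bedpe(svs, path) -> None:
    """SV calls as BEDPE (0-based half-open; B side may be 0/0 when the
    event has no resolved B interval)."""
    with open(path, "w") as fh:
        for s in svs:
            b_start = max(s.start_b - 1, 0)
            fh.write(
                f"{s.chrom_a}\t{s.start_a - 1}\t{s.end_a}\t"
                f"{s.chrom_b}\t{b_start}\t{max(s.end_b, b_start)}\t"
                f"{s.svtype}\t{s.size}\n"
            )


def svs_to_tsv(svs, path) -> None:
    with open(path, "w") as fh:
        fh.write("svtype\tchrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\tsize\n")
        for s in svs:
            fh.write(
                f"{s.svtype}\t{s.chrom_a}\t{s.start_a}\t{s.end_a}\t{s.chrom_b}\t"
                f"{s.start_b}\t{s.end_b}\t{s.size}\n"
            )
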
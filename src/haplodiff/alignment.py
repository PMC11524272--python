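"""Collinearity-block detection between two haplotypes.

The pipeline mirrors a nucmer + delta-filter workflow: maximal exact matches
seeded by k-mers that are unique in at least one sequence (anchors), weighted
collinear chaining per strand, base-level alignment of inter-anchor gaps to
obtain identity, then filtering to one-to-one blocks of span >= 15 kb and
identity >= 80% with mutual overlap above 80% resolved in favour of the
higher-scoring block (score = aligned length x identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from Bio import Align

from .models import Anchor, CollinearityBlock, revcomp
from .kmer import encode_sequence

DEFAULT_SEED_K = 21
REPEAT_GUARD = 10  # seeds occurring more often than this in both sequences are dropped
DEFAULT_MAX_GAP = 100_000
GAP_DIAG_PENALTY = 0.05  # per base of |gapA - gapB|
GAP_MIN_PENALTY = 0.01  # per base of min(gapA, gapB)
CHAIN_WINDOW = 80  # DP predecessor window
MIN_BLOCK_LEN = 15_000
MIN_BLOCK_IDENTITY = 80.0
MAX_BLOCK_OVERLAP = 0.80
GAP_ALIGN_LIMIT = 100_000
_AFFINE_LIMIT = 4_000  # above this (either side), edlib replaces the affine DP


# ---------------------------------------------------------------------------
# Anchors
# ---------------------------------------------------------------------------


def _kmer_codes(seq: str, k: int):
    """(forward codes, rc codes, validity) for every window of `seq`."""
    codes = encode_sequence(seq)
    n = len(codes) - k + 1
    if n <= 0:
        z = np.empty(0, dtype=np.uint64)
        return z, z, np.empty(0, dtype=bool)
    valid = codes != 255
    c = np.where(valid, codes, 0).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd |= c[j : j + n] << np.uint64(2 * (k - 1 - j))
        rev |= (np.uint64(3) - c[j : j + n]) << np.uint64(2 * j)
    cs = np.concatenate(([0], np.cumsum(~valid)))
    ok = (cs[k:] - cs[:-k]) == 0
    return fwd, rev, ok


def _seed_matches(codes_a, codes_b, max_occ: int):
    """(posA, posB) pairs for seed codes unique in A or in B (and not
    occurring more than max_occ times in either)."""
    order_a = np.argsort(codes_a, kind="stable")
    order_b = np.argsort(codes_b, kind="stable")
    sa, sb = codes_a[order_a], codes_b[order_b]
    ua, starts_a = np.unique(sa, return_index=True)
    ub, starts_b = np.unique(sb, return_index=True)
    counts_a = np.diff(np.append(starts_a, sa.size))
    counts_b = np.diff(np.append(starts_b, sb.size))
    common, ia, ib = np.intersect1d(ua, ub, return_indices=True)
    ca, cb = counts_a[ia], counts_b[ib]
    keep = ((ca == 1) | (cb == 1)) & (ca <= max_occ) & (cb <= max_occ)
    out_a, out_b = [], []
    for idx in np.flatnonzero(keep):
        pa = order_a[starts_a[ia[idx]] : starts_a[ia[idx]] + ca[idx]]
        pb = order_b[starts_b[ib[idx]] : starts_b[ib[idx]] + cb[idx]]
        for x in pa:
            for y in pb:
                out_a.append(int(x))
                out_b.append(int(y))
    return np.array(out_a, dtype=np.int64), np.array(out_b, dtype=np.int64)


def _merge_diagonal_runs(pa, pb, k, antidiag: bool):
    """Merge seed matches on the same (anti)diagonal into runs.

    Returns (a_start, b_start, length) triples, 0-based, where for the minus
    strand b_start is the leftmost base of the matched B interval.
    """
    if pa.size == 0:
        return []
    diag = pa + pb if antidiag else pa - pb
    order = np.lexsort((pa, diag))
    runs = []
    cur_a = cur_b = cur_end = None
    cur_d = None
    for i in order:
        a, b, d = int(pa[i]), int(pb[i]), int(diag[i])
        if cur_d == d and a <= cur_end:
            cur_end = max(cur_end, a + k)
        else:
            if cur_d is not None:
                runs.append((cur_a, cur_b, cur_end - cur_a, cur_d))
            cur_a, cur_b, cur_end, cur_d = a, b, a + k, d
    runs.append((cur_a, cur_b, cur_end - cur_a, cur_d))
    out = []
    for a, b, length, _d in runs:
        if antidiag:
            # seeds advance left on B as A advances; the run's leftmost B base
            b_left = b - (length - k)
            out.append((a, b_left, length))
        else:
            out.append((a, b, length))
    return out


def _extend_run(seq_a, seq_b, a, b_left, length, minus: bool):
    """Maximally extend an exact-match run in both directions."""
    la, lb = len(seq_a), len(seq_b)
    if not minus:
        while a > 0 and b_left > 0 and seq_a[a - 1] == seq_b[b_left - 1]:
            a -= 1
            b_left -= 1
            length += 1
        while a + length < la and b_left + length < lb and \
                seq_a[a + length] == seq_b[b_left + length]:
            length += 1
    else:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        # extending A rightwards consumes B leftwards
        while a + length < la and b_left > 0 and \
                seq_a[a + length] == comp.get(seq_b[b_left - 1], "?"):
            b_left -= 1
            length += 1
        while a > 0 and b_left + length < lb and \
                seq_a[a - 1] == comp.get(seq_b[b_left + length], "?"):
            a -= 1
            length += 1
    return a, b_left, length


def find_anchors(seq_a: str, seq_b: str, seed_k: int = DEFAULT_SEED_K,
                 chrom_a: str = "A", chrom_b: str = "B") -> list[Anchor]:
    """Maximal exact matches between seq_a and seq_b on both strands,
    seeded by k-mers unique in at least one sequence."""
    if not 15 <= seed_k <= 31:
        raise ValueError("seed_k must be in [15, 31]")
    fa, _ra, oka = _kmer_codes(seq_a, seed_k)
    fb, rb, okb = _kmer_codes(seq_b, seed_k)
    fa_idx = np.flatnonzero(oka)
    fb_idx = np.flatnonzero(okb)
    anchors: list[Anchor] = []
    seen = set()
    for strand, codes_b_eff in (("+", fb), ("-", rb)):
        pa, pb = _seed_matches(fa[fa_idx], codes_b_eff[fb_idx], REPEAT_GUARD)
        pa = fa_idx[pa]
        pb = fb_idx[pb]
        runs = _merge_diagonal_runs(pa, pb, seed_k, antidiag=(strand == "-"))
        for a, b_left, length in runs:
            a, b_left, length = _extend_run(seq_a, seq_b, a, b_left, length,
                                            minus=(strand == "-"))
            key = (strand, a, b_left, length)
            if key in seen:
                continue
            seen.add(key)
            anchors.append(
                Anchor(chrom_a, a + 1, chrom_b, b_left + 1, length, strand)
            )
    anchors.sort(key=lambda x: (x.pos_a, x.pos_b, x.strand))
    return anchors


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------


def gap_penalty(gap_a: int, gap_b: int) -> float:
    return GAP_DIAG_PENALTY * abs(gap_a - gap_b) + GAP_MIN_PENALTY * min(gap_a, gap_b)


MAX_ANCHOR_TRIM = 50  # maximal-match overlap tolerated (trimmed) at junctions


def _compatible(prev: Anchor, nxt: Anchor, strand: str, max_gap: int):
    """Gap sizes if `nxt` may follow `prev` in a chain, else None.

    Small overlaps (chance-matching bases flanking an indel make maximal
    matches overlap) are tolerated and later trimmed.
    """
    if nxt.pos_a <= prev.pos_a:
        return None
    gap_a = nxt.pos_a - prev.end_a - 1
    if gap_a < -MAX_ANCHOR_TRIM or gap_a > max_gap:
        return None
    if strand == "+":
        if nxt.pos_b <= prev.pos_b:
            return None
        gap_b = nxt.pos_b - prev.end_b - 1
    else:
        if nxt.pos_b >= prev.pos_b:
            return None
        gap_b = prev.pos_b - nxt.end_b - 1
    if gap_b < -MAX_ANCHOR_TRIM or gap_b > max_gap:
        return None
    return max(gap_a, 0), max(gap_b, 0)


def _trim_chain(chain: list[Anchor]) -> list[Anchor]:
    """Trim anchor left-ends so consecutive anchors never overlap on A or B.

    Trimming an exact match keeps it exact; the trimmed copy replaces the
    original (anchors are not mutated in place).
    """
    out = [chain[0]]
    for nxt in chain[1:]:
        prev = out[-1]
        ov_a = prev.end_a - nxt.pos_a + 1
        if nxt.strand == "+":
            ov_b = prev.end_b - nxt.pos_b + 1
        else:
            ov_b = nxt.end_b - prev.pos_b + 1
        o = max(ov_a, ov_b, 0)
        if o > 0:
            if o >= nxt.length:
                continue
            nxt = Anchor(
                nxt.chrom_a,
                nxt.pos_a + o,
                nxt.chrom_b,
                nxt.pos_b + o if nxt.strand == "+" else nxt.pos_b,
                nxt.length - o,
                nxt.strand,
            )
        out.append(nxt)
    return out


def chain_anchors(anchors: list[Anchor], max_gap: int = DEFAULT_MAX_GAP,
                  min_chain_anchors: int = 1,
                  window: int = CHAIN_WINDOW) -> list[list[Anchor]]:
    """Weighted collinear chaining (sparse DP on A-order with B-order
    consistency per strand), maximizing anchored length minus gap penalties.

    Returns chains (anchor lists) in decreasing score order; each anchor is
    used in at most one chain. With `window >= len(anchors)` the DP is exact.
    """
    chains: list[list[Anchor]] = []
    remaining = list(anchors)
    while remaining:
        best_chain = None
        best_score = 0.0
        for strand in ("+", "-"):
            sub = [a for a in remaining if a.strand == strand]
            sub.sort(key=lambda a: (a.pos_a, a.pos_b))
            n = len(sub)
            if not n:
                continue
            score = [float(a.length) for a in sub]
            prev = [-1] * n
            for i in range(n):
                lo = max(0, i - window)
                for j in range(lo, i):
                    g = _compatible(sub[j], sub[i], strand, max_gap)
                    if g is None:
                        continue
                    cand = score[j] + sub[i].length - gap_penalty(*g)
                    if cand > score[i]:
                        score[i] = cand
                        prev[i] = j
            top = int(np.argmax(score))
            if score[top] > best_score:
                chain = []
                i = top
                while i != -1:
                    chain.append(sub[i])
                    i = prev[i]
                chain.reverse()
                best_chain, best_score = chain, score[top]
        if best_chain is None or len(best_chain) < min_chain_anchors:
            break
        chains.append(best_chain)
        used = set(id(a) for a in best_chain)
        remaining = [a for a in remaining if id(a) not in used]
        if len(best_chain) == 1 and len(chains) > 5000:  # degenerate guard
            break
    return chains


# ---------------------------------------------------------------------------
# Gap alignment (shared with the variant caller)
# ---------------------------------------------------------------------------


@dataclass
class GapAlignment:
    """Base-level alignment of an inter-anchor segment pair.

    cigar: list of (op, length) with op in {'=', 'X', 'I', 'D'};
    'I' = extra bases in B, 'D' = extra bases in A.
    """

    cigar: list
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 100.0


def _affine_aligner():
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -5  # -4 open plus the first -1 extension
    al.extend_gap_score = -1
    return al


_ALIGNER = _affine_aligner()


def _cigar_from_pairwise(aln, seg_a, seg_b):
    cig = []
    a_blocks, b_blocks = aln.aligned
    pa = pb = 0
    for (as_, ae), (bs, be) in zip(a_blocks, b_blocks):
        if as_ > pa and bs > pb:
            # simultaneous gap: order D then I (arbitrary but fixed)
            cig.append(["D", as_ - pa])
            cig.append(["I", bs - pb])
        elif as_ > pa:
            cig.append(["D", as_ - pa])
        elif bs > pb:
            cig.append(["I", bs - pb])
        run_op = None
        run = 0
        for i in range(ae - as_):
            op = "=" if seg_a[as_ + i] == seg_b[bs + i] else "X"
            if op == run_op:
                run += 1
            else:
                if run:
                    cig.append([run_op, run])
                run_op, run = op, 1
        if run:
            cig.append([run_op, run])
        pa, pb = ae, be
    if len(seg_a) > pa:
        cig.append(["D", len(seg_a) - pa])
    if len(seg_b) > pb:
        cig.append(["I", len(seg_b) - pb])
    return [(op, ln) for op, ln in cig]


def _cigar_from_edlib(seg_a, seg_b):
    res = edlib.align(seg_b, seg_a, mode="NW", task="path")
    cig = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            ln = int(num)
            num = ""
            op = {"=": "=", "X": "X", "I": "I", "D": "D"}[ch]
            cig.append((op, ln))
    return cig


def align_gap(seg_a: str, seg_b: str, limit: int = GAP_ALIGN_LIMIT) -> GapAlignment:
    """Globally align two inter-anchor segments.

    Affine-gap DP (match +1, mismatch -2, gap open -4, extend -1) for small
    segments; edit-distance alignment with an extended CIGAR for large ones.
    Raises ValueError when either side exceeds `limit` (such gaps belong to
    the SV caller).
    """
    la, lb = len(seg_a), len(seg_b)
    if la > limit or lb > limit:
        raise ValueError("segment exceeds gap alignment limit")
    if la == 0 and lb == 0:
        return GapAlignment([], 0, 0)
    if la == 0:
        return GapAlignment([("I", lb)], 0, lb)
    if lb == 0:
        return GapAlignment([("D", la)], 0, la)
    if max(la, lb) <= _AFFINE_LIMIT:
        aln = _ALIGNER.align(seg_a, seg_b)[0]
        cig = _cigar_from_pairwise(aln, seg_a, seg_b)
    else:
        cig = _cigar_from_edlib(seg_a, seg_b)
    matches = sum(ln for op, ln in cig if op == "=")
    columns = sum(ln for _op, ln in cig)
    return GapAlignment(cig, matches, columns)


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------


def chains_to_blocks(chains, seq_a: str, seq_b: str,
                     gap_limit: int = GAP_ALIGN_LIMIT,
                     id_prefix: str = "blk") -> list[CollinearityBlock]:
    """Convert chains to blocks with identity from inter-anchor gap alignment.

    Gaps beyond `gap_limit` on either side are excluded from identity (they
    are handled by the SV caller but do not break the block).
    """
    blocks = []
    for ci, chain in enumerate(chains):
        chain = _trim_chain(chain)
        strand = chain[0].strand
        matches = columns = 0
        for a in chain:
            matches += a.length
            columns += a.length
        for prev, nxt in zip(chain, chain[1:]):
            seg_a = seq_a[prev.end_a : nxt.pos_a - 1]
            if strand == "+":
                seg_b = seq_b[prev.end_b : nxt.pos_b - 1]
            else:
                seg_b = revcomp(seq_b[nxt.end_b : prev.pos_b - 1])
            if len(seg_a) > gap_limit or len(seg_b) > gap_limit:
                continue
            g = align_gap(seg_a, seg_b, gap_limit)
            matches += g.matches
            columns += g.columns
        start_a, end_a = chain[0].pos_a, chain[-1].end_a
        b_positions = [a.pos_b for a in chain] + [a.end_b for a in chain]
        start_b, end_b = min(b_positions), max(b_positions)
        blocks.append(
            CollinearityBlock(
                id=f"{id_prefix}{ci + 1}",
                chrom_a=chain[0].chrom_a,
                start_a=start_a,
                end_a=end_a,
                chrom_b=chain[0].chrom_b,
                start_b=start_b,
                end_b=end_b,
                strand=strand,
                identity=100.0 * matches / columns if columns else 100.0,
                anchors=list(chain),
                aligned_length=columns,
            )
        )
    return blocks


def _overlap_frac(s1, e1, s2, e2) -> float:
    inter = min(e1, e2) - max(s1, s2) + 1
    if inter <= 0:
        return 0.0
    return inter / min(e1 - s1 + 1, e2 - s2 + 1)


def filter_blocks(blocks, min_len: int = MIN_BLOCK_LEN,
                  min_identity: float = MIN_BLOCK_IDENTITY,
                  max_overlap: float = MAX_BLOCK_OVERLAP) -> list[CollinearityBlock]:
    """Length/identity filter plus one-to-one best-alignment selection."""
    cand = [b for b in blocks if b.span_a >= min_len and b.identity >= min_identity]
    cand.sort(key=lambda b: (-b.score, b.chrom_a, b.start_a))
    kept: list[CollinearityBlock] = []
    for b in cand:
        clash = False
        for k in kept:
            if b.chrom_a == k.chrom_a and _overlap_frac(
                b.start_a, b.end_a, k.start_a, k.end_a
            ) > max_overlap:
                clash = True
                break
            if b.chrom_b == k.chrom_b and _overlap_frac(
                b.start_b, b.end_b, k.start_b, k.end_b
            ) > max_overlap:
                clash = True
                break
        if not clash:
            kept.append(b)
    kept.sort(key=lambda b: (b.chrom_a, b.start_a))
    return kept


def block_stats(blocks, min_size: int = MIN_BLOCK_LEN):
    """(count, mean A-span, total A-span) over blocks of span >= min_size."""
    spans = [b.span_a for b in blocks if b.span_a >= min_size]
    if not spans:
        return 0, None, 0
    return len(spans), sum(spans) / len(spans), sum(spans)


def align_haplotypes(genome_a, genome_b, seed_k: int = DEFAULT_SEED_K,
                     max_gap: int = DEFAULT_MAX_GAP, min_len: int = MIN_BLOCK_LEN,
                     min_identity: float = MIN_BLOCK_IDENTITY):
    """Whole-genome convenience pipeline: anchors -> chains -> filtered blocks.

    Homonymous chromosomes are aligned pairwise (the haplotypes of one
    individual share chromosome names).
    """
    all_blocks = []
    for chrom in genome_a.sequences:
        if chrom not in genome_b.sequences:
            continue
        seq_a = genome_a.sequences[chrom]
        seq_b = genome_b.sequences[chrom]
        anchors = find_anchors(seq_a, seq_b, seed_k, chrom_a=chrom, chrom_b=chrom)
        chains = chain_anchors(anchors, max_gap=max_gap)
        all_blocks.extend(
            chains_to_blocks(chains, seq_a, seq_b, id_prefix=f"{chrom}.blk")
        )
    return filter_blocks(all_blocks, min_len=min_len, min_identity=min_identity)


def blocks_to_bedpe(blocks, path) -> None:
    """Block intervals as BEDPE (0-based half-open, A then B side)."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                f"{b.chrom_a}\t{b.start_a - 1}\t{b.end_a}\t"
                f"{b.chrom_b}\t{b.start_b - 1}\t{b.end_b}\t"
                f"{b.id}\t{b.identity:.2f}\t+\t{b.strand}\n"
            )


def blocks_to_tsv(blocks, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "block_id\tchrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\t"
            "strand\tidentity\taligned_length\tn_anchors\n"
        )
        for b in blocks:
            fh.write(
                f"{b.id}\t{b.chrom_a}\t{b.start_a}\t{b.end_a}\t{b.chrom_b}\t"
                f"{b.start_b}\t{b.end_b}\t{b.strand}\t{b.identity:.2f}\t"
                f"{b.aligned_length}\t{len(b.anchors)}\n"
            )
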
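"""Allele-specific expression: per-pair testing, blocks, sharing, promoters.

A pair is ASE when |log2FC| > 1 and BH-adjusted FDR < 0.01. The test is an
exact conditional test of the haplotype-A read sum given the pair total,
under a symmetric beta-binomial null whose overdispersion is estimated by
method of moments across all pairs of the experiment (binomial when the
moment estimate is non-positive). An ASE block is a maximal run of at least
four consecutive allele pairs biased toward the same haplotype.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import ASEBlock, ASERecord, percent, revcomp

LOG2FC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.01
MIN_BLOCK_PAIRS = 4
PROMOTER_SV_LEN = 2000
PROMOTER_MOTIF_LEN = 1500


# ---------------------------------------------------------------------------
# Exact conditional test
# ---------------------------------------------------------------------------


_MEDIAN_Z = stats.norm.ppf(0.75)
_EST_MIN_TOTAL = 20  # pairs with fewer reads carry no dispersion information


def estimate_overdispersion(sums_a, sums_b) -> float:
    """Intra-pair correlation rho of the allele fraction under the null.

    Moment matching on the median: under a symmetric beta-binomial,
    sd(x/n) = sqrt((1 + (n-1) rho) / (4n)), so the median of the
    standardized deviations |x/n - 1/2| / sd equals the normal quartile
    0.6745. Solving for rho by bisection gives an estimate that is robust
    to a minority of genuinely imbalanced (ASE) pairs, unlike the plain
    second-moment average which they would dominate.
    """
    a = np.asarray(sums_a, dtype=float)
    n = a + np.asarray(sums_b, dtype=float)
    ok = n >= _EST_MIN_TOTAL
    a, n = a[ok], n[ok]
    if a.size < 10:
        return 0.0
    dev = np.abs(a / n - 0.5)

    def median_std(rho):
        sig = np.sqrt((1.0 + (n - 1.0) * rho) / (4.0 * n))
        return np.median(dev / sig)

    if median_std(0.0) <= _MEDIAN_Z:
        return 0.0
    lo, hi = 0.0, 0.5
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if median_std(mid) > _MEDIAN_Z:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def betabinom_test(x, n, rho: float):
    """Vectorized two-sided (equal-tail) exact test of x successes in n
    trials against a symmetric beta-binomial(n, alpha, alpha) null with
    intra-class correlation rho; rho <= 0 falls back to binomial."""
    x = np.atleast_1d(np.asarray(x, dtype=np.int64))
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    p = np.ones(x.shape, dtype=float)
    pos = n > 0
    if rho > 0:
        alpha = 0.5 * (1.0 / rho - 1.0)
        lo = stats.betabinom.cdf(x[pos], n[pos], alpha, alpha)
        hi = stats.betabinom.sf(x[pos] - 1, n[pos], alpha, alpha)
    else:
        lo = stats.binom.cdf(x[pos], n[pos], 0.5)
        hi = stats.binom.sf(x[pos] - 1, n[pos], 0.5)
    p[pos] = np.minimum(1.0, 2.0 * np.minimum(lo, hi))
    return p


def ase_test(counts_a, counts_b, rho: float | None = None,
             lib_sizes=None) -> tuple[float, float]:
    """(log2fc, p_value) for one allele pair from per-replicate counts.

    log2fc uses library-size-normalized counts with a 0.5 pseudocount; the
    p-value conditions the summed A count on the pair total. With rho=None
    a plain binomial null is used (single-pair call; the experiment-level
    pipeline estimates rho across pairs). All-zero pairs give (0.0, 1.0).
    """
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)
    if ca.size < 2 or cb.size < 2:
        raise ValueError("the ASE test requires at least 2 replicates")
    if lib_sizes is None:
        lib = np.ones(ca.size)
    else:
        lib = np.asarray(lib_sizes, dtype=float)
        lib = lib / lib.mean()
    na = float(np.sum(ca / lib))
    nb = float(np.sum(cb / lib))
    log2fc = float(np.log2((na + 0.5) / (nb + 0.5)))
    total = int(round(ca.sum() + cb.sum()))
    if total == 0:
        return 0.0, 1.0
    pval = float(betabinom_test(int(round(ca.sum())), total, rho or 0.0)[0])
    return log2fc, pval


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ase_experiment(counts, pairs, experiment: str,
                   log2fc_threshold: float = LOG2FC_THRESHOLD,
                   fdr_threshold: float = FDR_THRESHOLD) -> list[ASERecord]:
    """Full per-experiment ASE calling over a counts DataFrame whose rows are
    gene copies and whose columns are this experiment's replicates."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    lib = lib / lib.mean()
    sums_a, sums_b, fcs = [], [], []
    usable = []
    for p in pairs:
        if p.gene_a_id not in counts.index or p.gene_b_id not in counts.index:
            continue
        ca = counts.loc[p.gene_a_id].to_numpy(dtype=float)
        cb = counts.loc[p.gene_b_id].to_numpy(dtype=float)
        usable.append(p)
        sums_a.append(ca.sum())
        sums_b.append(cb.sum())
        na = float(np.sum(ca / lib))
        nb = float(np.sum(cb / lib))
        fcs.append(np.log2((na + 0.5) / (nb + 0.5)))
    sums_a = np.asarray(sums_a)
    sums_b = np.asarray(sums_b)
    totals = (sums_a + sums_b).astype(np.int64)
    xs = np.round(sums_a).astype(np.int64)
    fcs = np.asarray(fcs)
    # two-pass dispersion: exclude pairs already significant at a loose
    # criterion, then re-estimate on the remainder (null-like) pairs
    rho = estimate_overdispersion(sums_a, sums_b)
    q1 = bh_fdr(betabinom_test(xs, totals, rho))
    flagged = (np.abs(fcs) > 1.0) & (q1 < 0.05)
    if flagged.any() and (~flagged).sum() >= 10:
        rho = estimate_overdispersion(sums_a[~flagged], sums_b[~flagged])
    pvals = betabinom_test(xs, totals, rho)
    fdrs = bh_fdr(pvals)
    records = []
    for p, sa, sb, fc, pv, q in zip(usable, sums_a, sums_b, fcs, pvals, fdrs):
        testable = (sa + sb) > 0
        is_ase = bool(testable and abs(fc) > log2fc_threshold and q < fdr_threshold)
        direction = "none"
        if is_ase:
            direction = "A" if fc > 0 else "B"
        records.append(
            ASERecord(
                pair_id=p.pair_id,
                experiment=experiment,
                count_a=float(sa),
                count_b=float(sb),
                log2fc=float(fc),
                p_value=float(pv),
                fdr=float(q),
                is_ase=is_ase,
                direction=direction,
                testable=bool(testable),
            )
        )
    return records


# ---------------------------------------------------------------------------
# ASE blocks
# ---------------------------------------------------------------------------


def call_ase_blocks(ase_records, pair_order_on_chrom: dict,
                    min_pairs: int = MIN_BLOCK_PAIRS,
                    pair_spans: dict | None = None) -> list[ASEBlock]:
    """Maximal runs of >= `min_pairs` consecutive allele pairs, all ASE with
    the same direction; a non-ASE or opposite-direction pair breaks the run.

    `pair_order_on_chrom` maps chromosome -> pair ids in A-coordinate order;
    `pair_spans` (optional) maps pair id -> (start_a, end_a) for block spans.
    """
    rec = {r.pair_id: r for r in ase_records}
    blocks = []
    for chrom in sorted(pair_order_on_chrom):
        order = pair_order_on_chrom[chrom]
        run: list[str] = []
        run_dir = "none"

        def flush():
            if len(run) >= min_pairs:
                span = (0, 0)
                if pair_spans:
                    coords = [pair_spans[p] for p in run if p in pair_spans]
                    if coords:
                        span = (min(c[0] for c in coords), max(c[1] for c in coords))
                blocks.append(ASEBlock(chrom, list(run), run_dir, span))

        for pid in order:
            r = rec.get(pid)
            d = r.direction if (r is not None and r.is_ase) else "none"
            if d == run_dir and d != "none":
                run.append(pid)
            else:
                flush()
                run, run_dir = ([pid], d) if d != "none" else ([], "none")
        flush()
    return blocks


def ase_blocks_to_bed(blocks, path) -> None:
    """ASE blocks as BED (A coordinates, 0-based half-open; name is the
    direction plus member count)."""
    with open(path, "w") as fh:
        for b in blocks:
            s, e = b.span_a
            fh.write(
                f"{b.chrom_pair}\t{max(s - 1, 0)}\t{max(e, s)}\t"
                f"ASE_{b.direction}_{len(b)}\n"
            )


def sharing_summary(per_experiment_ase_sets: dict) -> dict:
    """Venn-style sharing of ASE pair ids across experiments.

    Returns union size, per-membership-pattern counts, the in-all and
    in->=2 counts, and their percentages of the union (2 decimals).
    """
    exps = sorted(per_experiment_ase_sets)
    if len(exps) < 2:
        raise ValueError("sharing requires at least 2 experiments")
    union = set().union(*per_experiment_ase_sets.values())
    pattern_counts: dict[str, int] = {}
    n_all = n_ge2 = 0
    for pid in union:
        member = tuple(e for e in exps if pid in per_experiment_ase_sets[e])
        key = "&".join(member)
        pattern_counts[key] = pattern_counts.get(key, 0) + 1
        if len(member) == len(exps):
            n_all += 1
        if len(member) >= 2:
            n_ge2 += 1
    return {
        "experiments": exps,
        "union_size": len(union),
        "pattern_counts": dict(sorted(pattern_counts.items())),
        "n_in_all": n_all,
        "n_in_ge2": n_ge2,
        "pct_in_all": percent(n_all, len(union)) if union else 0.0,
        "pct_in_ge2": percent(n_ge2, len(union)) if union else 0.0,
    }


def shared_blocks(blocks_per_experiment: dict, min_shared_pairs: int = 3) -> list[dict]:
    """Blocks conserved across all experiments.

    A shared block is a set of same-direction blocks, one per experiment,
    pairwise sharing >= `min_shared_pairs` member pairs (greedy maximal
    matching seeded from the first experiment's blocks). Reports the member
    union per shared block.
    """
    exps = sorted(blocks_per_experiment)
    if not exps:
        return []
    first, rest = exps[0], exps[1:]
    used: dict[str, set] = {e: set() for e in exps}
    shared = []
    for bi, blk in enumerate(blocks_per_experiment[first]):
        members = set(blk.member_pairs)
        chosen = [(first, bi, blk)]
        ok = True
        for e in rest:
            best = None
            for bj, other in enumerate(blocks_per_experiment[e]):
                if bj in used[e] or other.direction != blk.direction:
                    continue
                if all(
                    len(set(other.member_pairs) & set(c[2].member_pairs))
                    >= min_shared_pairs
                    for c in chosen
                ):
                    ov = len(set(other.member_pairs) & members)
                    if best is None or ov > best[1]:
                        best = (bj, ov, other)
            if best is None:
                ok = False
                break
            chosen.append((e, best[0], best[2]))
        if not ok:
            continue
        for e, bj, _b in chosen:
            used[e].add(bj)
        union_members = sorted(set().union(*(set(c[2].member_pairs) for c in chosen)))
        shared.append(
            {
                "direction": blk.direction,
                "chrom_pair": blk.chrom_pair,
                "member_union": union_members,
                "blocks": {e: list(c.member_pairs) for e, _j, c in chosen},
            }
        )
    return shared


# ---------------------------------------------------------------------------
# Promoters: SV association and motif scanning
# ---------------------------------------------------------------------------


def promoter_interval(gene, length: int, chrom_len: int | None = None):
    """Strand-aware upstream interval anchored at the translation start
    (first CDS base). Truncated at the chromosome edge."""
    t = gene.longest_transcript()
    cds = sorted(t.cds)
    if not cds:
        anchor = gene.start if gene.strand == "+" else gene.end
    else:
        anchor = cds[0][0] if gene.strand == "+" else cds[-1][1]
    if gene.strand == "+":
        start, end = anchor - length, anchor - 1
    else:
        start, end = anchor + 1, anchor + length
    start = max(start, 1)
    if chrom_len is not None:
        end = min(end, chrom_len)
    return start, max(end, start)


def promoter_sequence(gene, chrom_seq: str, length: int) -> str:
    s, e = promoter_interval(gene, length, chrom_len=len(chrom_seq))
    seq = chrom_seq[s - 1 : e]
    return revcomp(seq) if gene.strand == "-" else seq


def promoter_sv_association(pairs, ase_pair_ids, sv_calls,
                            annotation_a, annotation_b,
                            chrom_lengths_a: dict | None = None,
                            chrom_lengths_b: dict | None = None,
                            promoter_len: int = PROMOTER_SV_LEN):
    """2x2 Fisher exact test of {ASE, non-ASE} x {promoter SV, none}.

    A pair harbors an SV when at least one insertion or deletion (the two
    presence/absence classes) overlaps the strand-aware upstream interval of
    either allele, each tested in its own haplotype's coordinates.
    """
    indels = [s for s in sv_calls if s.svtype in ("insertion", "deletion")]
    iv_a = [(s.chrom_a, s.start_a, s.end_a) for s in indels]
    iv_b = [
        (s.chrom_b, s.start_b, s.end_b)
        for s in indels
        if s.end_b >= s.start_b and s.end_b > 0
    ]

    def overlaps(ivs, chrom, s, e):
        return any(c == chrom and s <= ie and is_ <= e for c, is_, ie in ivs)

    ase_set = set(ase_pair_ids)
    table = np.zeros((2, 2), dtype=np.int64)
    for p in pairs:
        ga = annotation_a.genes[p.gene_a_id]
        gb = annotation_b.genes[p.gene_b_id]
        la = (chrom_lengths_a or {}).get(ga.chrom)
        lb = (chrom_lengths_b or {}).get(gb.chrom)
        sa, ea = promoter_interval(ga, promoter_len, la)
        sb, eb = promoter_interval(gb, promoter_len, lb)
        has_sv = overlaps(iv_a, ga.chrom, sa, ea) or overlaps(iv_b, gb.chrom, sb, eb)
        i = 0 if p.pair_id in ase_set else 1
        j = 0 if has_sv else 1
        table[i, j] += 1
    _odds, pval = stats.fisher_exact(table, alternative="two-sided")
    return table, float(pval)


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def iupac_to_regex(motif: str, name: str = "") -> re.Pattern:
    try:
        pattern = "".join(IUPAC[c] for c in motif.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc.args[0]!r} in motif {name or motif!r}")
    return re.compile(f"(?=({pattern}))")  # overlapping matches


@dataclass
class MotifHits:
    name: str
    occurrences: int  # both strands, overlapping allowed
    promoters_with_hit: int


def motif_scan(promoters: dict, motifs: dict) -> list[MotifHits]:
    """Count IUPAC motif occurrences in promoter sequences on both strands.

    `promoters` maps id -> sequence (5'->3'); `motifs` maps name -> IUPAC
    string. Returns per-motif totals; rank them with :func:`motif_rankings`.
    """
    compiled = {name: iupac_to_regex(m, name) for name, m in motifs.items()}
    hits = []
    for name, rx in compiled.items():
        occ = 0
        n_prom = 0
        for seq in promoters.values():
            fwd = len(rx.findall(seq.upper()))
            rev = len(rx.findall(revcomp(seq.upper())))
            occ += fwd + rev
            if fwd + rev:
                n_prom += 1
        hits.append(MotifHits(name, occ, n_prom))
    return hits


def motif_rankings(hits) -> dict:
    """Two rank tables (1 = most) by total occurrences and by promoter count."""
    by_occ = sorted(hits, key=lambda h: (-h.occurrences, h.name))
    by_prom = sorted(hits, key=lambda h: (-h.promoters_with_hit, h.name))
    return {
        "by_occurrences": {h.name: i + 1 for i, h in enumerate(by_occ)},
        "by_promoters": {h.name: i + 1 for i, h in enumerate(by_prom)},
    }


def rank_correlation(ranks_x: dict, ranks_y: dict) -> float:
    """Spearman correlation between two rank tables over shared motifs."""
    common = sorted(set(ranks_x) & set(ranks_y))
    if len(common) < 3:
        return float("nan")
    rho, _p = stats.spearmanr(
        [ranks_x[m] for m in common], [ranks_y[m] for m in common]
    )
    return float(rho)
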
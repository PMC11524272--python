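"""Synthetic diploid genome, annotation and expression data with planted truth.

Haplotype A is generated de novo; haplotype B is derived from A by planting
SNPs, small indels and structural variants (deletion, insertion, duplication,
contraction, translocation), with every planted event recorded in a
:class:`DiploidTruth` object so that downstream callers can be scored against
a known answer. Expression matrices emulate replicated RNA-seq experiments
with allele-specific effects of configurable size, including runs of
co-biased neighbouring allele pairs (ASE blocks).

All randomness flows from ``SimulationConfig.seed``; identical configs give
byte-identical outputs. The structural-variant placement plan is a pure
function of the config, which lets haplotype A embed the tandem unit that a
contraction event later collapses in B without any shared state between the
two generation steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .models import (
    GeneAnnotation,
    GeneModel,
    HaplotypeGenome,
    KmerHistogram,
    Transcript,
    revcomp,
)

SV_TYPES = ("deletion", "insertion", "duplication", "contraction", "translocation")
_GUARD = 1000  # bp kept clear around every planted SV
_EDGE = 5000  # bp kept clear at chromosome ends
_STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# Configuration & truth containers
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    gc_content: float = 0.34  # poplar-like
    n_genes_per_chrom: int = 40
    snp_rate: float = 0.02
    small_indel_rate: float = 0.004
    indel_length_max: int = 10
    sv_counts: dict = field(
        default_factory=lambda: {
            "deletion": 3,
            "insertion": 3,
            "duplication": 1,
            "contraction": 1,
            "translocation": 0,
        }
    )
    sv_length_range: tuple = (200, 2000)
    translocation_length: int = 20_000
    haplotype_specific_gene_fraction: float = 0.05
    n_experiments: int = 4
    replicates_per_experiment: int = 3
    ase_pair_fraction: float = 0.2
    ase_shared_fraction: float = 0.6
    ase_log2fc: float = 2.0
    ase_block_spec: list = field(default_factory=list)  # (chrom, start_idx, n, dir)
    dispersion: float = 0.1
    mean_expression: float = 200.0

    def validate(self) -> None:
        for name in ("snp_rate", "small_indel_rate", "gc_content",
                     "haplotype_specific_gene_fraction", "ase_pair_fraction",
                     "ase_shared_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.indel_length_max >= 50:
            raise ValueError("small indels must be < 50 bp")
        if self.sv_length_range[0] < 50:
            raise ValueError("SV lengths must be >= 50 bp")
        for t in self.sv_counts:
            if t not in SV_TYPES:
                raise ValueError(f"unknown SV type {t!r}")
        longest_sv = max(
            self.sv_length_range[1],
            self.translocation_length if self.sv_counts.get("translocation") else 0,
            2 * self.sv_length_range[1] if self.sv_counts.get("contraction") else 0,
        )
        if longest_sv and self.chrom_length < 10 * longest_sv:
            raise ValueError("chrom_length must be >= 10 x longest SV")
        for spec in self.ase_block_spec:
            if spec[2] < 4:
                raise ValueError("ASE blocks need at least 4 member pairs")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class DiploidTruth:
    planted_snps: list = field(default_factory=list)  # (chrom, pos_a, ref, alt)
    planted_indels: list = field(default_factory=list)  # (chrom, pos_a, vtype, seq)
    planted_svs: list = field(default_factory=list)  # dicts
    allele_pair_truth: dict = field(default_factory=dict)  # geneA -> geneB
    haplotype_specific_truth: list = field(default_factory=list)
    ase_truth: dict = field(default_factory=dict)  # experiment -> {pair: dir}
    ase_block_truth: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DiploidTruth":
        with open(path) as fh:
            d = json.load(fh)
        t = cls(**d)
        t.planted_snps = [tuple(x) for x in t.planted_snps]
        t.planted_indels = [tuple(x) for x in t.planted_indels]
        return t


# ---------------------------------------------------------------------------
# SV placement plan (deterministic in config)
# ---------------------------------------------------------------------------


@dataclass
class _PlannedSV:
    svtype: str
    chrom: str
    start: int  # 0-based on A
    length: int  # unit length
    target_chrom: str = ""
    target_pos: int = 0  # 0-based insertion point for translocations

    def occupied(self) -> list[tuple[str, int, int]]:
        """(chrom, start, end) A-intervals this event reserves (0-based, excl)."""
        s, L = self.start, self.length
        if self.svtype == "deletion":
            iv = [(self.chrom, s, s + L)]
        elif self.svtype == "insertion":
            iv = [(self.chrom, s, s + 1)]
        elif self.svtype == "duplication":
            iv = [(self.chrom, s, s + L)]
        elif self.svtype == "contraction":
            iv = [(self.chrom, s, s + 2 * L)]
        else:  # translocation
            iv = [(self.chrom, s, s + L), (self.target_chrom, self.target_pos, self.target_pos + 1)]
        return iv


def plan_svs(config: SimulationConfig, max_retries: int = 200) -> list[_PlannedSV]:
    """Draw the SV placement plan. Pure function of the config."""
    rng = np.random.default_rng([config.seed, 1])
    chroms = config.chrom_names()
    occupied: list[tuple[str, int, int]] = []

    def clashes(ivs) -> bool:
        for c, s, e in ivs:
            if s < _EDGE or e > config.chrom_length - _EDGE:
                return True
            for oc, os_, oe in occupied:
                if c == oc and s - _GUARD < oe and os_ < e + _GUARD:
                    return True
        return False

    plan: list[_PlannedSV] = []
    lo, hi = config.sv_length_range
    for svtype in SV_TYPES:
        for _ in range(int(config.sv_counts.get(svtype, 0))):
            for attempt in range(max_retries):
                if svtype == "translocation":
                    L = config.translocation_length
                else:
                    L = int(rng.integers(lo, hi + 1))
                chrom = chroms[int(rng.integers(len(chroms)))]
                span = 2 * L if svtype == "contraction" else L
                start = int(rng.integers(_EDGE, config.chrom_length - _EDGE - span))
                ev = _PlannedSV(svtype, chrom, start, L)
                if svtype == "translocation":
                    ev.target_chrom = chroms[int(rng.integers(len(chroms)))]
                    ev.target_pos = int(rng.integers(_EDGE, config.chrom_length - _EDGE))
                if not clashes(ev.occupied()):
                    occupied.extend(ev.occupied())
                    plan.append(ev)
                    break
            else:
                raise ValueError(
                    f"could not place {svtype} after {max_retries} retries; "
                    "reduce SV counts/lengths or increase chrom_length"
                )
    return plan


# ---------------------------------------------------------------------------
# Haplotype A
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _random_cds(rng, n_codons: int) -> str:
    """ATG + random non-stop codons + TAA."""
    bases = "ACGT"
    codons = []
    while len(codons) < n_codons - 2:
        c = "".join(bases[i] for i in rng.integers(0, 4, 3))
        if c not in _STOP_CODONS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def _spliced_to_genomic(exons, lo: int, hi: int) -> list[tuple[int, int]]:
    """Map spliced interval [lo, hi) (0-based over concatenated exons, in
    genomic left-to-right order) to genomic (start, end) 1-based spans."""
    spans = []
    off = 0
    for s, e in exons:
        elen = e - s + 1
        a, b = max(lo - off, 0), min(hi - off, elen)
        if a < b:
            spans.append((s + a, s + b - 1))
        off += elen
    return spans


def _draw_gene_geometry(rng):
    """(exon_lens, intron_lens, strand) for one gene."""
    n_exons = int(rng.integers(1, 6))
    if n_exons == 1:
        exon_lens = [int(rng.integers(400, 1600))]
    else:
        exon_lens = [int(rng.integers(150, 600)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(60, 800)) for _ in range(n_exons - 1)]
    strand = "+" if rng.random() < 0.5 else "-"
    return exon_lens, intron_lens, strand


def _build_gene(rng, chrom: str, gid: str, pos: int, seq: np.ndarray,
                geometry) -> GeneModel:
    """Materialise a gene at 0-based position `pos`, writing its CDS content
    into `seq`. Returns the GeneModel (1-based coordinates)."""
    exon_lens, intron_lens, strand = geometry
    n_exons = len(exon_lens)
    exons = []
    cur = pos + 1  # 1-based
    for i, el in enumerate(exon_lens):
        exons.append((cur, cur + el - 1))
        cur += el
        if i < n_exons - 1:
            cur += intron_lens[i]
    start, end = exons[0][0], exons[-1][1]

    spliced = sum(exon_lens)
    u5, u3 = 90, 90
    cds_len = spliced - u5 - u3
    cds_len -= cds_len % 3
    if cds_len < 90:
        raise ValueError("gene too short for a CDS")
    if strand == "+":
        lo = u5
    else:  # 5' UTR is at the genomic right for minus-strand genes
        lo = spliced - u5 - cds_len
    cds_spans = _spliced_to_genomic(exons, lo, lo + cds_len)

    cds_seq = _random_cds(rng, cds_len // 3)
    genomic_cds = cds_seq if strand == "+" else revcomp(cds_seq)
    off = 0
    for s, e in cds_spans:
        seg = genomic_cds[off : off + (e - s + 1)]
        seq[s - 1 : e] = np.frombuffer(seg.encode(), dtype=np.uint8)
        off += e - s + 1

    t = Transcript(f"{gid}.t1", start, end, exons=exons, cds=cds_spans)
    return GeneModel(gid, chrom, start, end, strand, transcripts=[t])


def generate_haplotype_a(config: SimulationConfig):
    """Generate haplotype A and its gene annotation.

    Raises ValueError when the requested gene count cannot be placed on a
    chromosome of the configured length.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    plan = plan_svs(config)

    # genes may overlap planted deletions (those become haplotype-specific)
    # but stay clear of the other event classes to keep annotation lifting exact
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_names()}
    for ev in plan:
        if ev.svtype != "deletion":
            for c, s, e in ev.occupied():
                blocked[c].append((s - _GUARD, e + _GUARD))

    sequences: dict[str, str] = {}
    ann = GeneAnnotation()
    if config.n_genes_per_chrom * 2500 > config.chrom_length - 2 * _EDGE:
        raise ValueError(
            f"cannot place {config.n_genes_per_chrom} genes on a "
            f"{config.chrom_length} bp chromosome"
        )
    for chrom in config.chrom_names():
        seq = _random_sequence(rng, config.chrom_length, config.gc_content)
        for ev in plan:  # embed tandem pairs that contractions will collapse
            if ev.svtype == "contraction" and ev.chrom == chrom:
                s, L = ev.start, ev.length
                seq[s + L : s + 2 * L] = seq[s : s + L]
        taken = list(blocked[chrom])
        for i in range(config.n_genes_per_chrom):
            gid = f"{chrom}g{i + 1:04d}_A"
            geometry = _draw_gene_geometry(rng)
            gene_len = sum(geometry[0]) + sum(geometry[1])
            for _ in range(500):
                pos = int(rng.integers(_EDGE, config.chrom_length - _EDGE - gene_len))
                span = (pos - 200, pos + gene_len + 200)
                if any(s < span[1] and span[0] < e for s, e in taken):
                    continue
                g = _build_gene(rng, chrom, gid, pos, seq, geometry)
                taken.append((g.start - 1 - 200, g.end + 200))
                ann.add(g)
                break
            else:
                raise ValueError(f"could not place gene {gid}; chromosome too crowded")
        sequences[chrom] = seq.tobytes().decode("ascii")
    return HaplotypeGenome("A", sequences), ann


# ---------------------------------------------------------------------------
# Haplotype B: edits, offset maps, lifted annotation
# ---------------------------------------------------------------------------


@dataclass
class _Edit:
    a_pos: int  # 0-based
    a_len: int
    b_seq: str
    tag: str  # snp | ins | del | sv:<type>
    ref: object = None  # planned SV, if any


class _OffsetMap:
    """Piecewise A->B coordinate shift after applying a sorted edit list."""

    def __init__(self):
        self.a_after: list[int] = []
        self.offsets: list[int] = []
        self.removed: list[tuple[int, int]] = []  # 0-based [s, e)

    def finalize(self):
        self.a_after = np.array(self.a_after, dtype=np.int64)
        self.offsets = np.array(self.offsets, dtype=np.int64)

    def lift(self, pos1: int, clamp: str = "left"):
        """Lift a 1-based A position to B; positions inside a removed
        interval clamp to the nearest surviving base (or None if dropped)."""
        i = pos1 - 1
        for s, e in self.removed:
            if s <= i < e:
                if clamp == "drop":
                    return None
                i = s - 1 if clamp == "left" else e
                break
        idx = int(np.searchsorted(self.a_after, i, side="right"))
        off = int(self.offsets[idx - 1]) if idx > 0 else 0
        return i + off + 1

    def in_removed(self, start1: int, end1: int) -> bool:
        return any(s < end1 and start1 - 1 < e for s, e in self.removed)


def left_align_indel(chrom_seq: str, pos: int, seq: str, vtype: str, floor: int = 1):
    """Left-normalize an indel against haplotype A.

    pos is 1-based: for DEL the first deleted base, for INS the base after
    which the insertion occurs. Returns (pos, seq).
    """
    if vtype == "DEL":
        L = len(seq)
        while pos > floor and chrom_seq[pos - 2] == chrom_seq[pos + L - 2]:
            pos -= 1
        return pos, chrom_seq[pos - 1 : pos + L - 1]
    # INS: rotate while the base left of the site equals the last inserted base
    while pos >= floor and pos >= 1 and chrom_seq[pos - 1] == seq[-1]:
        seq = seq[-1] + seq[:-1]
        pos -= 1
    return pos, seq


def _draw_site_positions(rng, allowed: np.ndarray, rate: float) -> np.ndarray:
    hits = rng.random(allowed.size) < rate
    return allowed[hits]


def mutate_to_haplotype_b(genome_a: HaplotypeGenome, annotation_a: GeneAnnotation,
                          config: SimulationConfig):
    """Derive haplotype B from A by planting SNPs, indels and SVs.

    `genome_a`/`annotation_a` must come from :func:`generate_haplotype_a`
    with the same config (the SV plan is re-derived from the config).
    Returns (genome_b, annotation_b, truth).
    """
    config.validate()
    plan = plan_svs(config)
    rng = np.random.default_rng([config.seed, 2])
    rng_novel = np.random.default_rng([config.seed, 3])
    truth = DiploidTruth()

    edits: dict[str, list[_Edit]] = {c: [] for c in genome_a.sequences}

    # --- structural events --------------------------------------------------
    for ev in plan:
        A = genome_a.sequences[ev.chrom]
        s, L = ev.start, ev.length
        if ev.svtype == "deletion":
            edits[ev.chrom].append(_Edit(s, L, "", "sv:deletion", ev))
        elif ev.svtype == "insertion":
            novel = _random_sequence(rng_novel, L, config.gc_content).tobytes().decode()
            edits[ev.chrom].append(_Edit(s, 0, novel, "sv:insertion", ev))
        elif ev.svtype == "duplication":
            edits[ev.chrom].append(_Edit(s + L, 0, A[s : s + L], "sv:duplication", ev))
        elif ev.svtype == "contraction":
            edits[ev.chrom].append(_Edit(s + L, L, "", "sv:contraction", ev))
        else:  # translocation: excise at source, insert at target
            seg = A[s : s + L]
            edits[ev.chrom].append(_Edit(s, L, "", "sv:trans_src", ev))
            edits[ev.target_chrom].append(_Edit(ev.target_pos, 0, seg, "sv:trans_tgt", ev))

    # A-intervals barred to small events (every SV footprint + guard)
    sv_zones: dict[str, list[tuple[int, int]]] = {c: [] for c in genome_a.sequences}
    for ev in plan:
        for c, s, e in ev.occupied():
            sv_zones[c].append((s - _GUARD, e + _GUARD))

    # coding bases are shielded from small indels (purifying selection keeps
    # frameshifts out of real coding sequence); SNPs are planted everywhere
    cds_zones: dict[str, list[tuple[int, int]]] = {c: [] for c in genome_a.sequences}
    for g in annotation_a:
        for t in g.transcripts:
            for s, e in t.cds:
                cds_zones[g.chrom].append((s - 3, e + 2))  # 0-based, splice margin

    # --- small variants -----------------------------------------------------
    min_sep = 2 * config.indel_length_max + 20
    for chrom, A in genome_a.sequences.items():
        Lc = len(A)
        mask = np.ones(Lc, dtype=bool)
        mask[: _EDGE // 2] = mask[-_EDGE // 2 :] = False
        for s, e in sv_zones[chrom]:
            mask[max(s, 0) : min(e, Lc)] = False
        snp_extra_mask = mask.copy()
        for s, e in cds_zones[chrom]:
            mask[max(s - config.indel_length_max, 0) : min(e, Lc)] = False
        allowed = np.flatnonzero(mask)

        indel_pos = _draw_site_positions(rng, allowed, config.small_indel_rate)
        kept = []
        last = -(10 ** 9)
        for p in indel_pos:
            if p - last >= min_sep:
                kept.append(int(p))
                last = int(p)
        for p in kept:
            L = int(rng.integers(1, config.indel_length_max + 1))
            if rng.random() < 0.5:  # deletion of A[p : p+L]
                edits[chrom].append(_Edit(p, L, "", "del"))
                npos, nseq = left_align_indel(A, p + 1, A[p : p + L], "DEL")
                truth.planted_indels.append((chrom, npos, "DEL", nseq))
            else:  # insertion after base p (0-based p => 1-based site p+1)
                ins = _random_sequence(rng, L, config.gc_content).tobytes().decode()
                edits[chrom].append(_Edit(p + 1, 0, ins, "ins"))
                npos, nseq = left_align_indel(A, p + 1, ins, "INS")
                truth.planted_indels.append((chrom, npos, "INS", nseq))

        mask = snp_extra_mask  # SNPs may fall in coding sequence
        for p in kept:  # keep SNPs clear of indel ambiguity
            mask[max(p - 25, 0) : p + config.indel_length_max + 25] = False
        allowed = np.flatnonzero(mask)
        snp_pos = _draw_site_positions(rng, allowed, config.snp_rate)
        if snp_pos.size:
            refs = np.frombuffer(A.encode(), dtype=np.uint8)[snp_pos]
            shifts = rng.integers(1, 4, size=snp_pos.size)
            base_idx = np.searchsorted(_BASES, refs)
            alts = _BASES[(base_idx + shifts) % 4]
            for p, r, a in zip(snp_pos, refs, alts):
                edits[chrom].append(_Edit(int(p), 1, chr(a), "snp"))
                truth.planted_snps.append((chrom, int(p) + 1, chr(r), chr(a)))

    # --- apply edits --------------------------------------------------------
    sequences_b: dict[str, str] = {}
    maps: dict[str, _OffsetMap] = {}
    sv_b_intervals: dict[int, tuple[str, int, int]] = {}
    for chrom, A in genome_a.sequences.items():
        evs = sorted(edits[chrom], key=lambda e: (e.a_pos, e.a_len))
        parts: list[str] = []
        omap = _OffsetMap()
        cur_a = 0
        cur_b = 0
        for e in evs:
            if e.a_pos < cur_a:
                raise RuntimeError("overlapping edits")  # pragma: no cover
            parts.append(A[cur_a : e.a_pos])
            cur_b += e.a_pos - cur_a
            b_start = cur_b
            parts.append(e.b_seq)
            cur_b += len(e.b_seq)
            cur_a = e.a_pos + e.a_len
            if e.a_len > 0 and len(e.b_seq) == 0:
                omap.removed.append((e.a_pos, cur_a))
            omap.a_after.append(cur_a)
            omap.offsets.append(cur_b - cur_a)
            if e.tag.startswith("sv:"):
                key = id(e.ref) if e.tag != "sv:trans_tgt" else -id(e.ref)
                sv_b_intervals[key] = (chrom, b_start + 1, max(cur_b, b_start + 1))
        parts.append(A[cur_a:])
        omap.finalize()
        sequences_b[chrom] = "".join(parts)
        maps[chrom] = omap

    # --- SV truth records ---------------------------------------------------
    for ev in plan:
        s, L = ev.start, ev.length
        if ev.svtype == "deletion":
            a_iv = (s + 1, s + L)
            b = sv_b_intervals[id(ev)]
        elif ev.svtype == "insertion":
            a_iv = (s, s)
            b = sv_b_intervals[id(ev)]
        elif ev.svtype == "duplication":
            a_iv = (s + 1, s + L)
            bc, bs, be = sv_b_intervals[id(ev)]
            b = (bc, bs - L, be)  # both tandem copies in B
        elif ev.svtype == "contraction":
            a_iv = (s + 1, s + 2 * L)
            bc, bs, be = sv_b_intervals[id(ev)]
            b = (bc, bs - L, bs - 1)  # the single surviving copy
        else:
            a_iv = (s + 1, s + L)
            b = sv_b_intervals[-id(ev)]
        truth.planted_svs.append(
            {
                "type": ev.svtype,
                "chrom_a": ev.chrom,
                "start_a": a_iv[0],
                "end_a": a_iv[1],
                "chrom_b": b[0],
                "start_b": b[1],
                "end_b": b[2],
                "size": L,
            }
        )

    # --- lift annotation ----------------------------------------------------
    sv_removed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome_a.sequences}
    for ev in plan:
        if ev.svtype == "deletion":
            sv_removed[ev.chrom].append((ev.start, ev.start + ev.length))
        elif ev.svtype == "contraction":
            sv_removed[ev.chrom].append((ev.start + ev.length, ev.start + 2 * ev.length))
        elif ev.svtype == "translocation":
            sv_removed[ev.chrom].append((ev.start, ev.start + ev.length))

    rng_spec = np.random.default_rng([config.seed, 4])
    annotation_b = GeneAnnotation()
    survivors = []
    for g in annotation_a:
        hit = any(
            s < g.end and g.start - 1 < e for s, e in sv_removed[g.chrom]
        )
        if hit:
            truth.haplotype_specific_truth.append(g.gene_id)
        else:
            survivors.append(g)
    n_extra = int(round(config.haplotype_specific_gene_fraction * len(survivors)))
    extra_idx = set(
        rng_spec.choice(len(survivors), size=n_extra, replace=False).tolist()
    ) if n_extra else set()
    for i, g in enumerate(survivors):
        if i in extra_idx:
            truth.haplotype_specific_truth.append(g.gene_id)
            continue
        omap = maps[g.chrom]
        gb_id = g.gene_id[:-2] + "_B"
        tb_list = []
        for t in g.transcripts:
            tb = Transcript(
                t.transcript_id.replace("_A.", "_B."),
                omap.lift(t.start, "right"),
                omap.lift(t.end, "left"),
                exons=[(omap.lift(s, "right"), omap.lift(e, "left")) for s, e in t.exons],
                cds=[(omap.lift(s, "right"), omap.lift(e, "left")) for s, e in t.cds],
            )
            tb.exons = [(s, e) for s, e in tb.exons if s <= e]
            tb.cds = [(s, e) for s, e in tb.cds if s <= e]
            tb_list.append(tb)
        gb = GeneModel(
            gb_id,
            g.chrom,
            omap.lift(g.start, "right"),
            omap.lift(g.end, "left"),
            g.strand,
            transcripts=tb_list,
        )
        annotation_b.add(gb)
        truth.allele_pair_truth[g.gene_id] = gb_id

    truth.haplotype_specific_truth.sort()
    return HaplotypeGenome("B", sequences_b), annotation_b, truth


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(allele_pair_truth: dict, config: SimulationConfig,
                        annotation_a: GeneAnnotation | None = None,
                        specific_genes: list[str] | None = None):
    """Simulate per-allele count matrices for the configured experiments.

    Negative-binomial counts per allele copy per replicate; non-ASE pairs
    share a mean, ASE pairs differ by ``ase_log2fc`` in the planted direction,
    with every member of a planted block sharing the block's direction.
    A log-normal library-size factor (sd 0.1) is shared by all genes of a
    replicate. Returns ({experiment: DataFrame}, ase_truth, ase_block_truth).
    """
    import pandas as pd

    if not allele_pair_truth:
        raise ValueError("no allele pairs to simulate")
    if config.replicates_per_experiment < 2:
        raise ValueError("at least 2 replicates are required for the ASE test")

    # order pairs along the genome (by annotation if given, else by id)
    pair_ids = list(allele_pair_truth)
    if annotation_a is not None:
        pos = {g.gene_id: (g.chrom, g.start) for g in annotation_a}
        pair_ids.sort(key=lambda p: pos.get(p, (p, 0)))
    else:
        pair_ids.sort()
    chrom_of = {p: p.split("g")[0] for p in pair_ids}
    by_chrom: dict[str, list[str]] = {}
    for p in pair_ids:
        by_chrom.setdefault(chrom_of[p], []).append(p)

    rng = np.random.default_rng([config.seed, 5])
    n_pairs = len(pair_ids)

    # planted blocks
    block_members: dict[str, str] = {}  # pair -> direction
    block_truth = []
    for chrom, start_idx, n, direction in config.ase_block_spec:
        members = by_chrom[chrom][start_idx : start_idx + n]
        if len(members) < n:
            raise ValueError("ASE block spec exceeds pairs on chromosome")
        for p in members:
            block_members[p] = direction
        block_truth.append({"chrom": chrom, "members": members, "direction": direction})

    n_ase = int(round(config.ase_pair_fraction * n_pairs))
    n_ase = max(n_ase, len(block_members))
    free = [p for p in pair_ids if p not in block_members]
    n_shared = max(int(round(config.ase_shared_fraction * n_ase)) - len(block_members), 0)
    shared_extra = list(rng.choice(free, size=min(n_shared, len(free)), replace=False))
    shared_dir = {p: ("A" if rng.random() < 0.5 else "B") for p in shared_extra}
    shared_dir.update(block_members)

    base = np.exp(rng.normal(np.log(config.mean_expression), 1.0, size=n_pairs))
    base_by_pair = dict(zip(pair_ids, base))
    # planted-block members are guaranteed quantifiable expression so block
    # recovery exercises the run rule, not detection power at trace levels
    for p in block_members:
        base_by_pair[p] = max(base_by_pair[p], config.mean_expression)

    specific_genes = list(specific_genes or [])
    spec_base = np.exp(
        rng.normal(np.log(config.mean_expression * 0.35), 1.2, size=len(specific_genes))
    )

    disp = config.dispersion
    nb_n = 1.0 / disp

    def nb(rng_e, mu):
        mu = np.maximum(mu, 1e-8)
        return rng_e.negative_binomial(nb_n, nb_n / (nb_n + mu))

    matrices: dict[str, "pd.DataFrame"] = {}
    ase_truth: dict[str, dict] = {}
    experiments = [f"exp{i + 1}" for i in range(config.n_experiments)]
    for ei, exp in enumerate(experiments):
        rng_e = np.random.default_rng([config.seed, 6, ei])
        dirs = dict(shared_dir)
        remaining = [p for p in free if p not in shared_dir]
        n_extra = max(n_ase - len(dirs), 0)
        extra = list(rng_e.choice(remaining, size=min(n_extra, len(remaining)), replace=False))
        for p in extra:
            dirs[p] = "A" if rng_e.random() < 0.5 else "B"
        ase_truth[exp] = dict(sorted(dirs.items()))

        nrep = config.replicates_per_experiment
        lib = np.exp(rng_e.normal(0.0, 0.1, size=nrep))
        cols = [f"{exp}_r{r + 1}" for r in range(nrep)]
        rows = {}
        half = config.ase_log2fc / 2.0
        for p in pair_ids:
            mu = base_by_pair[p]
            d = dirs.get(p)
            fa = 2.0 ** half if d == "A" else (2.0 ** -half if d == "B" else 1.0)
            mu_a, mu_b = mu * fa, mu / fa
            rows[p] = nb(rng_e, mu_a * lib)
            rows[allele_pair_truth[p]] = nb(rng_e, mu_b * lib)
        for g, mu in zip(specific_genes, spec_base):
            rows[g] = rng_e.negative_binomial(
                1.0 / (3 * disp), (1.0 / (3 * disp)) / (1.0 / (3 * disp) + mu * lib)
            )
        matrices[exp] = pd.DataFrame.from_dict(rows, orient="index", columns=cols)

    return matrices, ase_truth, block_truth


# ---------------------------------------------------------------------------
# k-mer histogram simulation
# ---------------------------------------------------------------------------


def simulate_kmer_histogram(genome_a: HaplotypeGenome, genome_b: HaplotypeGenome,
                            coverage: float, error_rate: float, k: int,
                            seed: int) -> KmerHistogram:
    """Simulate the canonical k-mer multiplicity spectrum of uniform-coverage
    sequencing of the diploid (A + B).

    Each distinct genomic k-mer with diploid multiplicity m is observed
    Poisson(m * coverage * (1-error_rate)^k) times (coverage is the per-
    haplotype k-mer depth); substitution errors remove occurrences from true
    k-mers and contribute multiplicity-1 error k-mers.
    """
    from .kmer import genome_kmer_multiplicities

    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError("k must be odd and in [11, 31]")
    rng = np.random.default_rng(seed)
    seqs = list(genome_a.sequences.values()) + list(genome_b.sequences.values())
    _, mult = genome_kmer_multiplicities(seqs, k)
    p_clean = (1.0 - error_rate) ** k
    obs = rng.poisson(mult * coverage * p_clean)
    obs = obs[obs > 0]
    bins_counts = np.bincount(obs)
    bins = {int(m): int(c) for m, c in enumerate(bins_counts) if m >= 1 and c > 0}
    if error_rate > 0:
        total_sampled = float(mult.sum()) * coverage
        n_err = int(rng.poisson(total_sampled * (1.0 - p_clean)))
        if n_err:
            bins[1] = bins.get(1, 0) + n_err
    return KmerHistogram(k=k, bins=bins)
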
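"""Core containers shared across the pipeline.

Coordinates are 1-based inclusive (GFF3 convention) everywhere in memory;
BED exports are 0-based half-open. Haplotypes are referred to as "A" and
"B", with A acting as the reference for variant coordinates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention used for all printed ratios)."""
    import decimal

    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator, rounded half away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_away(100.0 * numerator / denominator, ndigits)


# ---------------------------------------------------------------------------
# Genome & annotation
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeGenome:
    """Named sequences for one haplotype."""

    name: str
    sequences: dict[str, str]

    def __len__(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=c, description="") for c, s in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path, name: str = "") -> "HaplotypeGenome":
        seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
        return cls(name=name or str(path), sequences=seqs)


@dataclass
class Transcript:
    transcript_id: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(ex[i][1] + 1, ex[i + 1][0] - 1) for i in range(len(ex) - 1)]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def longest_transcript(self) -> Transcript:
        return max(self.transcripts, key=lambda t: sum(e - s + 1 for s, e in t.cds) or t.end - t.start)


@dataclass
class GeneAnnotation:
    """Gene models for one haplotype, ordered by (chrom, start)."""

    genes: dict[str, GeneModel] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def add(self, gene: GeneModel) -> None:
        self.genes[gene.gene_id] = gene

    def by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            out.setdefault(g.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: (g.start, g.gene_id))
        return out

    # --- GFF3 serialization -------------------------------------------------

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sorted(self.genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id)):
                fh.write(
                    f"{g.chrom}\thaplodiff\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
                )
                for t in g.transcripts:
                    fh.write(
                        f"{g.chrom}\thaplodiff\tmRNA\t{t.start}\t{t.end}\t.\t{g.strand}\t.\t"
                        f"ID={t.transcript_id};Parent={g.gene_id}\n"
                    )
                    for s, e in sorted(t.exons):
                        fh.write(
                            f"{g.chrom}\thaplodiff\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={t.transcript_id}\n"
                        )
                    phase = 0
                    cds = sorted(t.cds, reverse=(g.strand == "-"))
                    for s, e in cds:
                        fh.write(
                            f"{g.chrom}\thaplodiff\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\tParent={t.transcript_id}\n"
                        )
                        phase = (3 - ((e - s + 1 - phase) % 3)) % 3

    @classmethod
    def from_gff3(cls, path) -> "GeneAnnotation":
        ann = cls()
        tx_parent: dict[str, str] = {}
        tx: dict[str, Transcript] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, _src, ftype, start, end, _score, strand, _phase, attrs = line.rstrip(
                    "\n"
                ).split("\t")
                a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
                start, end = int(start), int(end)
                if ftype == "gene":
                    ann.add(GeneModel(a["ID"], chrom, start, end, strand))
                elif ftype == "mRNA":
                    t = Transcript(a["ID"], start, end)
                    tx[a["ID"]] = t
                    tx_parent[a["ID"]] = a["Parent"]
                    ann.genes[a["Parent"]].transcripts.append(t)
                elif ftype == "exon":
                    tx[a["Parent"]].exons.append((start, end))
                elif ftype == "CDS":
                    tx[a["Parent"]].cds.append((start, end))
        for t in tx.values():
            t.exons.sort()
            t.cds.sort()
        return ann


def gene_cds_sequence(gene: GeneModel, chrom_seq: str) -> str:
    """Spliced CDS of the longest isoform, strand-aware (5'->3')."""
    t = gene.longest_transcript()
    parts = [chrom_seq[s - 1 : e] for s, e in sorted(t.cds)]
    cds = "".join(parts)
    return revcomp(cds) if gene.strand == "-" else cds


def gene_protein(gene: GeneModel, chrom_seq: str) -> str:
    cds = gene_cds_sequence(gene, chrom_seq)
    cds = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(cds).translate())
    return prot.rstrip("*")


# ---------------------------------------------------------------------------
# Alignment containers
# ---------------------------------------------------------------------------


@dataclass
class Anchor:
    chrom_a: str
    pos_a: int  # 1-based start on A
    chrom_b: str
    pos_b: int  # 1-based start on B (leftmost base of the B interval)
    length: int
    strand: str  # "+" or "-"

    @property
    def end_a(self) -> int:
        return self.pos_a + self.length - 1

    @property
    def end_b(self) -> int:
        return self.pos_b + self.length - 1


@dataclass
class CollinearityBlock:
    id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    strand: str
    identity: float  # percent
    anchors: list[Anchor] = field(default_factory=list)
    aligned_length: int = 0

    @property
    def span_a(self) -> int:
        return self.end_a - self.start_a + 1

    @property
    def span_b(self) -> int:
        return self.end_b - self.start_b + 1

    @property
    def score(self) -> float:
        return self.aligned_length * self.identity


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


@dataclass
class VariantCall:
    chrom_a: str
    pos_a: int
    ref: str  # A allele ("" for INS)
    alt: str  # B allele ("" for DEL)
    vtype: str  # SNP | INS | DEL
    block_id: str = ""

    def __post_init__(self):
        if self.vtype == "SNP" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("SNP must have single-base ref and alt")

    @property
    def span_a(self) -> tuple[int, int]:
        """A-interval touched by the variant (1-based inclusive)."""
        if self.vtype == "DEL":
            return (self.pos_a, self.pos_a + len(self.ref) - 1)
        return (self.pos_a, self.pos_a)


@dataclass
class SVCall:
    svtype: str  # deletion | insertion | duplication | contraction | translocation
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    size: int


@dataclass
class AnnotatedVariant:
    variant: VariantCall
    location: str
    effect: str
    impact: str  # HIGH | MODERATE | LOW | MODIFIER
    gene_id: Optional[str] = None


LOCATION_GROUPS = (
    "downstream",
    "exon",
    "gene",
    "intergenic",
    "intron",
    "splice_site_acceptor",
    "splice_site_donor",
    "splice_site_region",
    "transcript",
    "upstream",
    "utr_3_prime",
    "utr_5_prime",
)

HIGH_IMPACT_EFFECTS = frozenset(
    {
        "frameshift",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "transcript_ablation",
    }
)


# ---------------------------------------------------------------------------
# Alleles & expression
# ---------------------------------------------------------------------------


@dataclass
class AllelePair:
    gene_a_id: str
    gene_b_id: str
    similarity: float
    block_id: Optional[str] = None
    evidence: str = "collinear_rbh"  # or "scaffold_rbh"

    @property
    def pair_id(self) -> str:
        return self.gene_a_id


@dataclass
class ASERecord:
    pair_id: str
    experiment: str
    count_a: float
    count_b: float
    log2fc: float
    p_value: float
    fdr: float = 1.0
    is_ase: bool = False
    direction: str = "none"  # A | B | none
    testable: bool = True


@dataclass
class ASEBlock:
    chrom_pair: str
    member_pairs: list[str]
    direction: str  # A | B
    span_a: tuple[int, int] = (0, 0)

    def __len__(self) -> int:
        return len(self.member_pairs)


# ---------------------------------------------------------------------------
# Summary containers
# ---------------------------------------------------------------------------


@dataclass
class KmerHistogram:
    k: int
    bins: dict[int, int]  # multiplicity -> distinct k-mer count

    def total_kmers(self) -> int:
        """Total k-mer occurrences (sum multiplicity * count)."""
        return sum(m * c for m, c in self.bins.items())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for m in sorted(self.bins):
                fh.write(f"{m}\t{self.bins[m]}\n")

    @classmethod
    def from_tsv(cls, path, k: int) -> "KmerHistogram":
        bins: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                m, c = line.split()[:2]
                bins[int(m)] = int(c)
        return cls(k=k, bins=bins)


@dataclass
class SpectrumFit:
    lambda_het: float
    lambda_hom: float
    error_cutoff: int
    genome_size_mono: float
    het_rate: float
    mixture_weights: tuple[float, float]
    unimodal: bool = False  # "no heterozygous peak" flag


@dataclass
class AssemblyStats:
    total_length: int
    n_sequences: int
    n50: int
    longest: int
    shortest: int
    gc_percent: float


@dataclass
class BuscoCounts:
    single: int
    duplicated: int
    fragmented: int
    missing: int
    total: int

    def validate(self) -> None:
        if self.single + self.duplicated + self.fragmented + self.missing != self.total:
            raise ValueError("BUSCO counts do not sum to total")
        if self.total <= 0:
            raise ValueError("BUSCO total must be positive")


def asdict(obj):
    return dataclasses.asdict(obj)
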
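"""Assembly summary statistics, BUSCO-count arithmetic and run reports.

Percentages follow the printed-ratio conventions used throughout the
pipeline: half-away-from-zero rounding, two decimals for rates and
fractions, one decimal for BUSCO-style completeness percentages.
"""

from __future__ import annotations

import json
from pathlib import Path

from .models import AssemblyStats, BuscoCounts, round_half_away


def assembly_stats(sequences) -> AssemblyStats:
    """Standard assembly summary (N50, GC over unambiguous bases)."""
    if isinstance(sequences, dict):
        seqs = list(sequences.values())
    else:
        seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences")
    lengths = sorted((len(s) for s in seqs), reverse=True)
    total = sum(lengths)
    half = total / 2.0
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc >= half:
            n50 = L
            break
    gc = at = 0
    for s in seqs:
        u = s.upper()
        gc += u.count("G") + u.count("C")
        at += u.count("A") + u.count("T")
    gc_pct = round_half_away(100.0 * gc / (gc + at), 2) if gc + at else 0.0
    return AssemblyStats(
        total_length=total,
        n_sequences=len(lengths),
        n50=n50,
        longest=lengths[0],
        shortest=lengths[-1],
        gc_percent=gc_pct,
    )


def busco_percentages(counts: BuscoCounts) -> dict:
    """Completeness percentages (1 decimal); complete = single + duplicated
    before division."""
    counts.validate()
    t = counts.total

    def pct(x):
        return round_half_away(100.0 * x / t, 1)

    return {
        "complete": pct(counts.single + counts.duplicated),
        "single": pct(counts.single),
        "duplicated": pct(counts.duplicated),
        "fragmented": pct(counts.fragmented),
        "missing": pct(counts.missing),
    }


# ---------------------------------------------------------------------------
# Run report
# ---------------------------------------------------------------------------

_STAGE_FILES = {
    "simulation": "truth.json",
    "kmer": "kmer_fit.json",
    "blocks": "blocks.tsv",
    "variants": "variants.vcf",
    "svs": "svs.tsv",
    "alleles": "alleles.tsv",
    "ase": "ase_summary.json",
}


def report(run_dir, strict: bool = False) -> dict:
    """Aggregate the stage outputs found in `run_dir` into one summary.

    Totals are recomputed from the stage files; missing stages are marked
    absent (and raise in strict mode).
    """
    run_dir = Path(run_dir)
    rep: dict = {"run_dir": str(run_dir), "sections": {}}
    missing = []

    def stage(name):
        path = run_dir / _STAGE_FILES[name]
        if not path.exists():
            missing.append(name)
            return None
        return path

    p = stage("variants")
    if p:
        counts = {"SNP": 0, "INS": 0, "DEL": 0}
        with open(p) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                info = line.rstrip("\n").split("\t")[7]
                for kv in info.split(";"):
                    if kv.startswith("TYPE="):
                        counts[kv[5:]] = counts.get(kv[5:], 0) + 1
        counts["total"] = sum(v for k, v in counts.items() if k != "total")
        rep["sections"]["variants"] = counts

    p = stage("svs")
    if p:
        sv_counts: dict[str, int] = {}
        with open(p) as fh:
            next(fh)
            for line in fh:
                t = line.split("\t")[0]
                sv_counts[t] = sv_counts.get(t, 0) + 1
        sv_counts["total"] = sum(sv_counts.values())
        rep["sections"]["svs"] = sv_counts

    p = stage("blocks")
    if p:
        spans = []
        with open(p) as fh:
            next(fh)
            for line in fh:
                f = line.split("\t")
                spans.append(int(f[3]) - int(f[2]) + 1)
        rep["sections"]["blocks"] = {
            "count": len(spans),
            "total_span_a": sum(spans),
            "mean_span_a": (sum(spans) / len(spans)) if spans else None,
        }

    p = stage("alleles")
    if p:
        n_pairs = 0
        with open(p) as fh:
            next(fh)
            for _line in fh:
                n_pairs += 1
        rep["sections"]["alleles"] = {"pairs": n_pairs}

    p = stage("ase")
    if p:
        with open(p) as fh:
            rep["sections"]["ase"] = json.load(fh)

    p = stage("kmer")
    if p:
        with open(p) as fh:
            rep["sections"]["kmer"] = json.load(fh)

    p = stage("simulation")
    if p:
        with open(p) as fh:
            truth = json.load(fh)
        rep["sections"]["simulation"] = {
            "planted_snps": len(truth.get("planted_snps", [])),
            "planted_indels": len(truth.get("planted_indels", [])),
            "planted_svs": len(truth.get("planted_svs", [])),
            "allele_pairs": len(truth.get("allele_pair_truth", {})),
            "haplotype_specific": len(truth.get("haplotype_specific_truth", [])),
        }

    rep["missing_sections"] = missing
    if strict and missing:
        raise FileNotFoundError(f"missing stage outputs: {', '.join(missing)}")
    return rep


def format_report(rep: dict) -> str:
    lines = [f"haplodiff report for {rep['run_dir']}"]
    for name, sec in rep["sections"].items():
        lines.append(f"[{name}]")
        for k, v in sec.items():
            lines.append(f"  {k}: {v}")
    if rep["missing_sections"]:
        lines.append("absent sections: " + ", ".join(rep["missing_sections"]))
    return "\n".join(lines)
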
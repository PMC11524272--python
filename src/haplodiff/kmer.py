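"""k-mer spectrum analysis: counting, and genome-size / heterozygosity estimation.

A diploid sequenced at depth c per haplotype produces a bimodal canonical
k-mer multiplicity spectrum: k-mers private to one haplotype (spanning a
heterozygous site) peak near c, shared k-mers near 2c. A two-component
Poisson mixture with tied means (lambda, 2*lambda) is fitted by EM above the
error valley; with D_het and D_hom the distinct k-mers assigned to the two
components, the monoploid genome size is G = D_hom + D_het/2 and the fraction
of heterozygous k-mers a = (D_het/2)/G converts to a per-base heterozygosity
rate via het = 1 - (1 - a)^(1/k), which inverts the fact that an isolated
SNP makes k overlapping k-mers heterozygous.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln, logsumexp

from .models import KmerHistogram, SpectrumFit

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
for i, b in enumerate(b"acgt"):
    _CODE[b] = i

EM_MAX_ITER = 200
EM_TOL = 1e-8


def encode_sequence(seq: str) -> np.ndarray:
    """2-bit codes per base; 255 marks ambiguous bases."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical (min of forward / reverse-complement) k-mer codes.

    Windows containing an ambiguous base are dropped. Returns a uint64 array
    with one entry per valid window, in sequence order.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if 2 * k > 64:
        raise ValueError("k too large for 64-bit packing")
    codes = encode_sequence(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid = codes != 255
    c = np.where(valid, codes, 0).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd |= c[j : j + n] << np.uint64(2 * (k - 1 - j))
        rev |= (np.uint64(3) - c[j : j + n]) << np.uint64(2 * j)
    ok = np.ones(n, dtype=bool)
    bad = ~valid
    # window is valid iff no ambiguous base among its k positions
    cs = np.concatenate(([0], np.cumsum(bad)))
    ok = (cs[k:] - cs[:-k]) == 0
    canon = np.minimum(fwd, rev)
    return canon[ok]


def genome_kmer_multiplicities(sequences, k: int):
    """(distinct canonical k-mer codes, multiplicities) over a set of sequences."""
    parts = [canonical_kmer_codes(s, k) for s in sequences]
    parts = [p for p in parts if p.size]
    if not parts:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    allc = np.concatenate(parts)
    uniq, counts = np.unique(allc, return_counts=True)
    return uniq, counts.astype(np.int64)


def count_kmers(sequences, k: int) -> KmerHistogram:
    """Histogram canonical k-mer multiplicities over `sequences`.

    Sequences shorter than k contribute nothing; if no sequence is usable an
    empty histogram is returned with a warning rather than an error.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    _, counts = genome_kmer_multiplicities(sequences, k)
    if counts.size == 0:
        warnings.warn("no sequence long enough for k; empty histogram")
        return KmerHistogram(k=k, bins={})
    mult, nkmers = np.unique(counts, return_counts=True)
    return KmerHistogram(k=k, bins={int(m): int(c) for m, c in zip(mult, nkmers)})


# ---------------------------------------------------------------------------
# Spectrum fitting
# ---------------------------------------------------------------------------


def _error_cutoff(m: np.ndarray, c: np.ndarray) -> int:
    """Multiplicity of the first local minimum (start of the signal region)."""
    if len(m) < 3:
        return int(m[0])
    # walk down the initial descending error slope; the first upturn is the valley
    for i in range(len(m) - 1):
        if c[i + 1] > c[i]:
            return int(m[i])
    return int(m[0])


def _local_maxima(m: np.ndarray, c: np.ndarray, min_sep_ratio: float = 1.6) -> list[float]:
    """Modes of the smoothed histogram, used only to flag unimodal spectra."""
    if len(c) < 5:
        return [float(m[np.argmax(c)])] if len(c) else []
    kernel = np.ones(5) / 5.0
    s = np.convolve(c.astype(float), kernel, mode="same")
    floor = 0.05 * s.max()  # prominence guard against tail ripples
    peaks = [
        float(m[i])
        for i in range(1, len(s) - 1)
        if s[i] >= s[i - 1] and s[i] > s[i + 1] and s[i] > floor
    ]
    # merge peaks closer than min_sep_ratio (plateau artifacts)
    merged: list[float] = []
    for p in peaks:
        if merged and p < merged[-1] * min_sep_ratio:
            continue
        merged.append(p)
    return merged


def _poisson_mixture_em(m, c, lam0, max_iter=EM_MAX_ITER, tol=EM_TOL):
    """EM for w1*Pois(lam) + w2*Pois(2*lam) on histogram data; returns
    (lam, weights, loglik, responsibilities-for-component-1)."""
    lam = float(lam0)
    w = np.array([0.5, 0.5])
    m = m.astype(float)
    c = c.astype(float)
    ll_old = -np.inf
    r1 = np.full(len(m), 0.5)
    for _ in range(max_iter):
        logp1 = np.log(w[0] + 1e-300) + m * np.log(lam) - lam - gammaln(m + 1)
        logp2 = np.log(w[1] + 1e-300) + m * np.log(2 * lam) - 2 * lam - gammaln(m + 1)
        norm = np.logaddexp(logp1, logp2)
        ll = float(np.sum(c * norm))
        r1 = np.exp(logp1 - norm)
        r2 = 1.0 - r1
        w = np.array([np.sum(c * r1), np.sum(c * r2)])
        w = w / w.sum()
        lam = float(np.sum(c * m) / np.sum(c * (r1 + 2 * r2)))
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            break
        ll_old = ll
    return lam, w, ll, r1


def fit_spectrum(hist: KmerHistogram, lambda_hom_hint: float | None = None) -> SpectrumFit:
    """Estimate monoploid genome size and heterozygosity from a k-mer histogram.

    Raises ValueError on an empty histogram. A spectrum with no detectable
    heterozygous peak is not an error: it returns het_rate 0 with the
    ``unimodal`` flag set.
    """
    if not hist.bins:
        raise ValueError("empty k-mer histogram")
    m = np.array(sorted(hist.bins), dtype=np.int64)
    c = np.array([hist.bins[int(x)] for x in m], dtype=np.int64)
    cutoff = _error_cutoff(m, c)
    sel = m >= cutoff
    ms, cs = m[sel], c[sel]
    if ms.size == 0:
        raise ValueError("no k-mers above the error cutoff")
    mode = float(ms[np.argmax(cs)])
    total_mass = float(np.sum(ms * cs))
    total_distinct = float(np.sum(cs))

    peaks = _local_maxima(ms, cs)
    if lambda_hom_hint is None and len(peaks) < 2:
        lam_hom = mode
        return SpectrumFit(
            lambda_het=lam_hom / 2.0,
            lambda_hom=lam_hom,
            error_cutoff=cutoff,
            genome_size_mono=total_mass / lam_hom,
            het_rate=0.0,
            mixture_weights=(0.0, 1.0),
            unimodal=True,
        )

    inits = [mode / 2.0] if lambda_hom_hint is None else [lambda_hom_hint / 2.0]
    if lambda_hom_hint is None:
        inits.append(mode)  # het peak may dominate the mode at high heterozygosity
    best = None
    for lam0 in inits:
        lam, w, ll, r1 = _poisson_mixture_em(ms, cs, lam0)
        if best is None or ll > best[2]:
            best = (lam, w, ll, r1)
    lam, w, _, r1 = best
    lam_hom = 2.0 * lam
    d_het = float(np.sum(cs * r1))
    d_hom = total_distinct - d_het
    g = d_hom + d_het / 2.0
    a = (d_het / 2.0) / g if g > 0 else 0.0
    a = min(max(a, 0.0), 1.0 - 1e-12)
    het = 1.0 - (1.0 - a) ** (1.0 / hist.k)
    return SpectrumFit(
        lambda_het=lam,
        lambda_hom=lam_hom,
        error_cutoff=cutoff,
        genome_size_mono=total_mass / lam_hom,
        het_rate=het,
        mixture_weights=(float(w[0]), float(w[1])),
        unimodal=False,
    )
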
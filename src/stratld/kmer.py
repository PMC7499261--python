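"""Weighted k-mer enrichment of annotation-weighted SNP windows.

For a probabilistic annotation D over SNPs and a canonical k-mer i with
per-window counts kappa_s, the weighted k-mer enrichment is

    WKE = (sum_s D_s kappa_s) / (Dbar * sum_s kappa_s),

the annotation-weighted mean count relative to the unweighted mean (the
denominator is the same weighted sum with D replaced by its constant mean).
Significance comes from permuting D across SNPs and fitting a Gaussian to
the permuted WKE values.

K-mers are merged with their reverse complements into canonical classes
(the lexicographically smaller member names the class); counting on the
given strand over both members is equivalent to counting the k-mer on both
strands.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotations import Annotation, encode_sequence, snp_window_interval
from .panel import SnpPanel

_COMP = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class CanonicalKmer:
    """Equivalence class of a k-mer and its reverse complement."""

    sequence: str                 # lexicographically smaller member
    members: tuple                # (kmer,) for palindromes, else both

    @property
    def k(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_string(cls, kmer: str) -> "CanonicalKmer":
        kmer = kmer.upper()
        if set(kmer) - set("ACGT"):
            raise ValueError(f"k-mer {kmer!r} has non-ACGT characters")
        rc = reverse_complement(kmer)
        canon = min(kmer, rc)
        members = (canon,) if kmer == rc else (canon, max(kmer, rc))
        return cls(canon, members)


def enumerate_canonical_kmers(k_max: int) -> list[CanonicalKmer]:
    """All canonical reverse-complement classes for 1 <= k <= k_max, in
    order of k then lexicographic by class representative."""
    if not 1 <= k_max <= 12:
        raise ValueError("k_max must be in 1..12")
    out = []
    for k in range(1, k_max + 1):
        seen = set()
        for tup in itertools.product("ACGT", repeat=k):
            kmer = "".join(tup)
            ck = CanonicalKmer.from_string(kmer)
            if ck.sequence not in seen:
                seen.add(ck.sequence)
                out.append(ck)
    return out


@dataclass
class KmerCountTable:
    """Per-SNP, per-canonical-class occurrence counts in SNP windows."""

    snp_id: np.ndarray
    kmers: list                  # list[CanonicalKmer]
    counts: np.ndarray           # (S, n_kmers) int64
    window_bp: int | None = None

    def column(self, kmer) -> np.ndarray:
        key = kmer.sequence if isinstance(kmer, CanonicalKmer) else \
            CanonicalKmer.from_string(kmer).sequence
        for i, ck in enumerate(self.kmers):
            if ck.sequence == key:
                return self.counts[:, i]
        raise KeyError(key)


def _kmer_ids(codes: np.ndarray, k: int):
    """Sliding-window base-4 ids over a coded sequence; positions touching
    an ambiguous base are invalid.  Returns (ids, valid_mask)."""
    n = len(codes)
    if n < k:
        return np.empty(0, np.int64), np.empty(0, bool)
    valid1 = codes < 4
    c = np.where(valid1, codes, 0).astype(np.int64)
    ids = np.zeros(n - k + 1, dtype=np.int64)
    valid = np.ones(n - k + 1, dtype=bool)
    for i in range(k):
        ids = ids * 4 + c[i:n - k + 1 + i]
        valid &= valid1[i:n - k + 1 + i]
    return ids, valid


def _string_id(kmer: str) -> int:
    return int("".join(str("ACGT".index(ch)) for ch in kmer), 4) if kmer else 0


def count_kmers_in_windows(windows, kmers) -> KmerCountTable:
    """Count canonical-class occurrences in explicit window sequences.

    ``windows`` is a mapping name -> sequence string.  Overlapping
    occurrences count; a class's count is the occurrences of either member
    on the given strand; k-mers overlapping an N contribute 0.
    """
    names = list(windows)
    ks = sorted({ck.k for ck in kmers})
    counts = np.zeros((len(names), len(kmers)), dtype=np.int64)
    # class-member ids per k
    member_ids = {}
    for j, ck in enumerate(kmers):
        for mem in ck.members:
            member_ids.setdefault(ck.k, []).append((_string_id(mem), j))
    for s, name in enumerate(names):
        codes = encode_sequence(str(windows[name]))
        for k in ks:
            ids, valid = _kmer_ids(codes, k)
            if len(ids) == 0:
                continue
            bc = np.bincount(ids[valid], minlength=4 ** k)
            for mid, j in member_ids[k]:
                counts[s, j] += int(bc[mid])
    return KmerCountTable(np.asarray(names, dtype=object), list(kmers), counts)


def extract_windows(sequence_source, panel: SnpPanel, window_bp: int) -> dict:
    """SNP-id -> window sequence, using the shared +/-window_bp convention."""
    out = {}
    for chrom, sl in panel.chrom_slices().items():
        try:
            seq = str(sequence_source[chrom][:])
        except KeyError:
            raise ValueError(f"chromosome {chrom} missing from sequence source")
        for i in range(sl.start, sl.stop):
            start, end = snp_window_interval(panel.pos[i], window_bp, len(seq))
            out[panel.snp_id[i]] = seq[start:end]
    return out


def count_kmers(sequence_source, panel: SnpPanel, kmers,
                window_bp: int = 500) -> KmerCountTable:
    """Count canonical k-mers in the windows around every panel SNP."""
    table = count_kmers_in_windows(
        extract_windows(sequence_source, panel, window_bp), kmers)
    table.window_bp = window_bp
    return table


# ---------------------------------------------------------------------------
# the enrichment statistic
# ---------------------------------------------------------------------------

def weighted_kmer_enrichment(d: Annotation | np.ndarray,
                             counts: KmerCountTable | np.ndarray,
                             kmer=None) -> float:
    """WKE = weighted mean count over unweighted mean count (see module
    docstring).  Equals 1 exactly for a constant annotation."""
    dv = d.values if isinstance(d, Annotation) else np.asarray(d, float)
    kappa = counts.column(kmer) if isinstance(counts, KmerCountTable) \
        else np.asarray(counts, float)
    if len(dv) != len(kappa):
        raise ValueError("annotation and count vector lengths differ")
    total = float(kappa.sum())
    if total == 0:
        raise ValueError("k-mer absent from all windows; enrichment undefined")
    dbar = float(dv.mean())
    if dbar == 0:
        raise ValueError("annotation mean is 0; enrichment undefined")
    return float(dv @ kappa) / (dbar * total)


@dataclass
class KmerEnrichmentResult:
    kmer: str
    wke: float
    perm_mean: float
    perm_sd: float
    z: float
    p: float                      # Gaussian-fit p at the requested sidedness
    p_empirical: float
    n_perm: int
    seed: int
    sided: str = "upper"


def permutation_test(d: Annotation | np.ndarray,
                     counts: KmerCountTable | np.ndarray, kmer=None,
                     n_perm: int = 10000, seed: int = 0,
                     sided: str = "upper") -> KmerEnrichmentResult:
    """Permutation null for WKE: permute annotation values across SNPs,
    recompute WKE each time, fit a Gaussian to the permuted values and
    report z = (WKE_obs - mean)/sd with a one-sided upper (default) or
    two-sided p; an empirical rank p is included for diagnostics.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if sided not in ("upper", "two"):
        raise ValueError(f"unknown sidedness {sided!r}")
    dv = d.values if isinstance(d, Annotation) else np.asarray(d, float)
    kappa = counts.column(kmer) if isinstance(counts, KmerCountTable) \
        else np.asarray(counts, float)
    kappa = kappa.astype(float)
    if dv.max() == dv.min():
        raise ValueError("annotation is constant; permutation test undefined")
    obs = weighted_kmer_enrichment(dv, kappa)
    rng = np.random.default_rng(seed)
    denom = dv.mean() * kappa.sum()
    perm = rng.permuted(np.broadcast_to(dv, (n_perm, len(dv))), axis=1)
    wke_perm = (perm @ kappa) / denom
    mu = float(wke_perm.mean())
    sd = float(wke_perm.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mu)):
        raise ValueError(
            "permutation distribution is degenerate (sd = 0): the counts "
            "are constant across windows, so every permutation gives the "
            "same WKE")
    z = (obs - mu) / sd
    if sided == "upper":
        p = float(stats.norm.sf(z))
        p_emp = float((1 + np.sum(wke_perm >= obs)) / (n_perm + 1))
    else:
        p = float(2 * stats.norm.sf(abs(z)))
        p_emp = float(
            (1 + np.sum(np.abs(wke_perm - mu) >= abs(obs - mu))) / (n_perm + 1))
    name = kmer.sequence if isinstance(kmer, CanonicalKmer) else str(kmer)
    return KmerEnrichmentResult(name, obs, mu, sd, float(z), p, p_emp,
                                n_perm, seed, sided)
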
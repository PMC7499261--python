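"""Per-SNP annotation containers and constructions.

An annotation assigns a numeric value to every SNP of a panel: binary (0/1
membership), probabilistic (continuous in [0, 1], e.g. a predicted chromatin
mark probability or an allelic-effect score), or unrestricted continuous.
This module builds and transforms such annotations: aggregation of
tissue-specific columns, quantile matching onto a reference distribution,
allelic-effect (|ref - alt|) scores, restriction to genomic regions, local
sequence content, and gene-score windows.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import SnpPanel

KINDS = ("binary", "probabilistic", "continuous")


class AnnotationError(ValueError):
    pass


@dataclass
class Annotation:
    """A named per-SNP value vector of one of the three kinds.

    ``meta`` is free-form provenance (source model, chromatin mark, tissue
    set, aggregation method, variant-level vs allelic-effect, ...).
    """

    name: str
    values: np.ndarray
    kind: str = "continuous"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KINDS:
            raise AnnotationError(f"unknown annotation kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise AnnotationError(f"annotation {self.name!r} has non-finite values")
        if self.kind == "probabilistic" and (
                self.values.min() < 0 or self.values.max() > 1):
            raise AnnotationError(
                f"probabilistic annotation {self.name!r} has values outside [0,1]")
        if self.kind == "binary" and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise AnnotationError(
                f"binary annotation {self.name!r} has values outside {{0,1}}")

    @property
    def size(self) -> float:
        """Annotation size: the mean value across SNPs."""
        return float(self.values.mean())

    def sd(self) -> float:
        """Population standard deviation across SNPs (ddof=0)."""
        return float(self.values.std())

    def with_values(self, values, *, name=None, kind=None, **meta) -> "Annotation":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Annotation(name or self.name, values, kind or self.kind, new_meta)


class AnnotationMatrix:
    """Ordered collection of annotations sharing one panel."""

    def __init__(self, panel: SnpPanel, annotations=()):
        self.panel = panel
        self.annotations: list[Annotation] = []
        for a in annotations:
            self.add(a)

    def add(self, ann: Annotation) -> None:
        if len(ann.values) != self.panel.m:
            raise AnnotationError(
                f"annotation {ann.name!r} has {len(ann.values)} values, "
                f"panel has {self.panel.m} SNPs")
        if ann.name in self.names:
            raise AnnotationError(f"duplicate annotation name {ann.name!r}")
        self.annotations.append(ann)

    @property
    def names(self) -> list:
        return [a.name for a in self.annotations]

    @property
    def kinds(self) -> list:
        return [a.kind for a in self.annotations]

    @property
    def c(self) -> int:
        return len(self.annotations)

    def values(self) -> np.ndarray:
        """(M, C) value matrix in column order."""
        if not self.annotations:
            return np.empty((self.panel.m, 0))
        return np.column_stack([a.values for a in self.annotations])

    def __getitem__(self, name: str) -> Annotation:
        for a in self.annotations:
            if a.name == name:
                return a
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def subset(self, names) -> "AnnotationMatrix":
        return AnnotationMatrix(self.panel, [self[n] for n in names])

    def merged(self, other: "AnnotationMatrix") -> "AnnotationMatrix":
        if not self.panel.equals(other.panel):
            raise AnnotationError("cannot merge annotation matrices on different panels")
        return AnnotationMatrix(self.panel, self.annotations + other.annotations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({a.name: a.values for a in self.annotations})


@dataclass
class RegionSet:
    """Genomic intervals in 0-based half-open (BED) coordinates.

    Intervals are sorted and merged on construction, so containment tests
    reduce to a searchsorted against non-overlapping starts.
    """

    intervals: pd.DataFrame  # columns chrom, start, end
    label: str = ""

    def __post_init__(self):
        df = pd.DataFrame(self.intervals, columns=["chrom", "start", "end"])
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["end"] < df["start"]).any():
            raise AnnotationError("region with negative length")
        if (df["start"] < 0).any():
            raise AnnotationError("region with negative start")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort",
                            ignore_index=True)
        # merge overlapping / touching intervals per chromosome
        merged = []
        for chrom, g in df.groupby("chrom", sort=True):
            cur_s = cur_e = None
            for s, e in zip(g["start"], g["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                merged.append((chrom, cur_s, cur_e))
        self.intervals = pd.DataFrame(merged, columns=["chrom", "start", "end"])

    def contains(self, chrom, pos_1based) -> np.ndarray:
        """Vectorized membership of 1-based positions in the region set.

        A 1-based position p lies in [start, end) iff start <= p-1 < end.
        """
        chrom = np.asarray(chrom, dtype=object)
        p0 = np.asarray(pos_1based, dtype=np.int64) - 1
        out = np.zeros(len(p0), dtype=bool)
        for c, g in self.intervals.groupby("chrom", sort=False):
            mask = chrom == c
            if not mask.any():
                continue
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            idx = np.searchsorted(starts, p0[mask], side="right") - 1
            ok = idx >= 0
            ok[ok] = p0[mask][ok] < ends[idx[ok]]
            out[mask] = ok
        return out

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# constructions
# ---------------------------------------------------------------------------

def aggregate_across_tissues(per_tissue: AnnotationMatrix, method: str,
                             name: str | None = None) -> Annotation:
    """Collapse tissue-specific probabilistic columns into one annotation.

    ``method`` is ``"avg"`` (mean across tissues at each SNP) or ``"max"``.
    """
    if per_tissue.c == 0:
        raise AnnotationError("cannot aggregate an empty annotation matrix")
    for a in per_tissue.annotations:
        if a.kind != "probabilistic":
            raise AnnotationError(
                f"aggregation expects probabilistic columns; {a.name!r} is {a.kind}")
    vals = per_tissue.values()
    if method == "avg":
        out = vals.mean(axis=1)
    elif method == "max":
        out = vals.max(axis=1)
    else:
        raise AnnotationError(f"unknown aggregation method {method!r}")
    name = name or f"agg_{method}"
    return Annotation(name, out, "probabilistic",
                      {"aggregation": method, "n_tissues": per_tissue.c})


def quantile_match(source: Annotation, reference: Annotation) -> Annotation:
    """Monotone rank-preserving remap of ``source`` onto the empirical
    distribution of ``reference``.

    With equal lengths and no ties the sorted output equals the sorted
    reference exactly; ties take average ranks and unequal lengths fall back
    to linear interpolation of the reference quantile function.
    """
    src = source.values
    ref = np.sort(reference.values)
    n, nref = len(src), len(ref)
    if src.max() == src.min():
        raise AnnotationError(
            f"annotation {source.name!r} is constant; quantile matching undefined")
    ranks = stats.rankdata(src, method="average")  # in [1, n]
    if n == nref:
        # grid of reference order statistics at ranks 1..n
        out = np.interp(ranks, np.arange(1, n + 1), ref)
    else:
        q = (ranks - 0.5) / n
        qref = (np.arange(nref) + 0.5) / nref
        out = np.interp(q, qref, ref)
    kind = reference.kind if reference.kind in ("probabilistic", "binary") \
        else "continuous"
    if kind == "binary":
        kind = "continuous"  # interpolation can leave non-0/1 values
    return source.with_values(out, kind=kind,
                              quantile_matched_to=reference.name)


def allelic_effect(ref_pred: Annotation, alt_pred: Annotation,
                   name: str | None = None) -> Annotation:
    """Allelic-effect score |ref - alt| of two probabilistic predictions."""
    for a in (ref_pred, alt_pred):
        if a.kind != "probabilistic":
            raise AnnotationError(
                f"allelic_effect expects probabilistic inputs; {a.name!r} is {a.kind}")
    if len(ref_pred.values) != len(alt_pred.values):
        raise AnnotationError("ref and alt predictions are on different panels")
    out = np.abs(ref_pred.values - alt_pred.values)
    return Annotation(name or f"{ref_pred.name}_delta", out, "probabilistic",
                      {"type": "allelic_effect", "ref": ref_pred.name,
                       "alt": alt_pred.name})


def restrict_to_regions(ann: Annotation, regions: RegionSet,
                        panel: SnpPanel) -> Annotation:
    """Zero the annotation outside the given regions."""
    if len(ann.values) != panel.m:
        raise AnnotationError("annotation and panel lengths differ")
    if len(regions) == 0:
        inside = np.zeros(panel.m, dtype=bool)
    else:
        inside = regions.contains(panel.chrom, panel.pos)
    out = np.where(inside, ann.values, 0.0)
    return ann.with_values(out, name=f"{ann.name}_{regions.label or 'restricted'}",
                           restricted_to=regions.label)


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_sequence(seq: str) -> np.ndarray:
    """Uppercase DNA -> uint8 codes (A,C,G,T -> 0..3; anything else 255)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def snp_window_interval(pos_1based: int, window_bp: int,
                        chrom_len: int | None = None) -> tuple[int, int]:
    """0-based half-open interval of the +/-window_bp region around a SNP.

    Covers window_bp bases either side of the SNP base itself, so an
    untruncated window has 2*window_bp + 1 bases.
    """
    p0 = pos_1based - 1
    start = max(0, p0 - window_bp)
    end = p0 + window_bp + 1
    if chrom_len is not None:
        end = min(end, chrom_len)
    return start, end


def local_content(sequence_source, panel: SnpPanel, window_bp: int,
                  content: str) -> Annotation:
    """Local sequence composition around each SNP.

    ``content="gc"``: proportion of G+C bases among non-ambiguous bases in
    the window.  ``content="cpg"``: proportion of CG dinucleotides among
    dinucleotide positions with both bases non-ambiguous.  N bases are
    excluded from denominators.  ``sequence_source`` is any mapping
    chromosome -> sequence string (a pyfaidx.Fasta works).
    """
    if window_bp <= 0:
        raise AnnotationError("window_bp must be positive")
    if content not in ("gc", "cpg"):
        raise AnnotationError(f"unknown content type {content!r}")
    out = np.zeros(panel.m)
    for chrom, sl in panel.chrom_slices().items():
        try:
            seq = str(sequence_source[chrom][:])
        except KeyError:
            raise AnnotationError(f"chromosome {chrom} missing from sequence source")
        codes = encode_sequence(seq)
        for i in range(sl.start, sl.stop):
            start, end = snp_window_interval(panel.pos[i], window_bp, len(codes))
            w = codes[start:end]
            valid = w < 4
            if content == "gc":
                denom = int(valid.sum())
                num = int(np.sum((w == 1) | (w == 2)))
            else:
                both = valid[:-1] & valid[1:]
                denom = int(both.sum())
                num = int(np.sum((w[:-1] == 1) & (w[1:] == 2) & both))
            out[i] = num / denom if denom > 0 else 0.0
    return Annotation(f"local_{content}_content", out, "probabilistic",
                      {"window_bp": window_bp, "content": content})


def gene_score_to_snp_annotation(gene_table: pd.DataFrame, panel: SnpPanel,
                                 window_bp: int, name: str = "gene_score",
                                 combine: str = "max") -> Annotation:
    """Propagate per-gene scores to SNPs within window_bp of the gene body.

    ``gene_table`` has columns (chrom, start, end, score) with gene bodies in
    0-based half-open coordinates.  SNPs in overlapping windows take the
    maximum score by default; SNPs in no window get 0.
    """
    if window_bp < 0:
        raise AnnotationError("window_bp must be non-negative")
    df = pd.DataFrame(gene_table, columns=["chrom", "start", "end", "score"])
    if not np.all(np.isfinite(df["score"])):
        raise AnnotationError("gene scores must be finite")
    if combine not in ("max", "sum"):
        raise AnnotationError(f"unknown combine rule {combine!r}")
    out = np.zeros(panel.m)
    p0 = panel.pos - 1
    for _, row in df.iterrows():
        start = max(0, int(row["start"]) - window_bp)
        end = int(row["end"]) + window_bp
        mask = (panel.chrom == row["chrom"]) & (p0 >= start) & (p0 < end)
        if combine == "max":
            out[mask] = np.maximum(out[mask], row["score"])
        else:
            out[mask] += row["score"]
    return Annotation(name, out, "continuous",
                      {"window_bp": window_bp, "combine": combine})
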
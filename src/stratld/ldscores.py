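"""Stratified LD scores.

The stratified LD score of SNP j with respect to annotation c is
``l(j,c) = sum_k a_ck * r2_jk`` over SNPs k in a window around j (k = j
included), where r2_jk is the squared genotypic correlation estimated from a
reference panel.  The default estimator applies the small-sample bias
adjustment ``r2_adj = r2 - (1 - r2)/(N_ref - 2)``, so that for independent
SNPs the expected contribution of a neighbour is ~0 rather than ~1/N_ref.

Computation streams over SNP chunks so memory is O(window), and the result
is independent of the chunk size.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationMatrix
from .panel import GenotypePanel, PanelError, SnpPanel


@dataclass
class WindowSpec:
    """LD window definition: ``kind`` is "kb", "cm" or "snp"; ``size`` is the
    half-width in that unit (symmetric around the focal SNP)."""
    kind: str = "kb"
    size: float = 1000.0

    def __post_init__(self):
        if self.kind not in ("kb", "cm", "snp"):
            raise ValueError(f"unknown window kind {self.kind!r}")
        if self.size <= 0:
            raise ValueError("window size must be positive")


@dataclass
class StratifiedLDScores:
    """Per-SNP, per-annotation LD scores plus the settings that produced
    them and full-panel annotation summaries (sums, sds, gram matrix) needed
    downstream for heritability, enrichment and tau* denominators."""

    panel: SnpPanel
    names: list
    values: np.ndarray          # (M, C)
    annot_sums: np.ndarray      # sum_j a_cj over the full panel
    annot_sds: np.ndarray       # population sd of each annotation
    kinds: list
    m_total: int
    settings: dict = field(default_factory=dict)
    gram: np.ndarray | None = None   # (C, C) full-panel A'A, for enrichment

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("LD scores contain non-finite values")
        if self.values.shape != (self.panel.m, len(self.names)):
            raise ValueError("LD score matrix shape does not match panel/names")

    @property
    def c(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def subset_annotations(self, names) -> "StratifiedLDScores":
        idx = [self.names.index(n) for n in names]
        return StratifiedLDScores(
            panel=self.panel, names=list(names),
            values=self.values[:, idx],
            annot_sums=self.annot_sums[idx], annot_sds=self.annot_sds[idx],
            kinds=[self.kinds[i] for i in idx], m_total=self.m_total,
            settings=dict(self.settings),
            gram=None if self.gram is None else self.gram[np.ix_(idx, idx)])


def pairwise_r2(genotypes: GenotypePanel, j: int, k: int,
                adjusted: bool = False) -> float:
    """Squared Pearson correlation between standardized dosage columns j, k,
    optionally with the (N_ref - 2) bias adjustment."""
    x = genotypes.standardized([j, k])
    n = genotypes.n_samples
    r2 = float((x[:, 0] @ x[:, 1]) / n) ** 2
    if adjusted:
        r2 = r2 - (1.0 - r2) / (n - 2)
    return r2


def _window_bounds(panel: SnpPanel, sl: slice, window: WindowSpec,
                   cm: np.ndarray | None):
    """Per-SNP [lo, hi) neighbour index ranges within one chromosome slice."""
    idx = np.arange(sl.start, sl.stop)
    if window.kind == "snp":
        w = int(window.size)
        lo = np.maximum(idx - w, sl.start)
        hi = np.minimum(idx + w + 1, sl.stop)
        return lo, hi
    if window.kind == "kb":
        coord = panel.pos[sl].astype(float)
        half = window.size * 1000.0
    else:
        if cm is None:
            raise PanelError("cM window requested but genotype panel has no "
                             "genetic map")
        coord = cm[sl]
        half = window.size
    lo = sl.start + np.searchsorted(coord, coord - half, side="left")
    hi = sl.start + np.searchsorted(coord, coord + half, side="right")
    return lo, hi


def stratified_ld_scores(genotypes: GenotypePanel,
                         annotations: AnnotationMatrix,
                         window: WindowSpec | None = None,
                         adjusted: bool = True,
                         chunk_size: int = 512) -> StratifiedLDScores:
    """Compute l(j,c) for every panel SNP j and annotation column c."""
    panel = genotypes.panel
    if not panel.equals(annotations.panel):
        raise ValueError("genotypes and annotations are on different panels")
    window = window or WindowSpec()
    a = annotations.values()
    m, c = a.shape
    n = genotypes.n_samples
    out = np.zeros((m, c))
    for chrom, sl in panel.chrom_slices().items():
        lo, hi = _window_bounds(panel, sl, window, genotypes.cm)
        x = genotypes.standardized(np.arange(sl.start, sl.stop))  # (n, mc)
        for start in range(sl.start, sl.stop, chunk_size):
            stop = min(start + chunk_size, sl.stop)
            rel = slice(start - sl.start, stop - sl.start)
            klo = int(lo[rel][0])
            khi = int(hi[rel][-1])
            r = (x[:, rel].T @ x[:, klo - sl.start:khi - sl.start]) / n
            r2 = r ** 2
            if adjusted:
                r2 = r2 - (1.0 - r2) / (n - 2)
            # mask neighbours outside each focal SNP's own window
            kk = np.arange(klo, khi)
            mask = (kk[None, :] >= lo[rel][:, None]) & \
                   (kk[None, :] < hi[rel][:, None])
            out[start:stop] = (r2 * mask) @ a[klo:khi]
    return StratifiedLDScores(
        panel=panel, names=list(annotations.names), values=out,
        annot_sums=a.sum(axis=0), annot_sds=a.std(axis=0),
        kinds=list(annotations.kinds), m_total=m,
        settings={"window_kind": window.kind, "window_size": window.size,
                  "adjusted_r2": bool(adjusted), "n_ref": int(n)},
        gram=a.T @ a)


class LDScoreEngine:
    """Caches per-annotation LD score columns for repeated conditional fits.

    LD scores are linear in the annotation, so a fit over any subset of
    annotations reuses previously computed columns (keyed by annotation name
    and a digest of its values).
    """

    def __init__(self, genotypes: GenotypePanel,
                 window: WindowSpec | None = None, adjusted: bool = True):
        self.genotypes = genotypes
        self.window = window or WindowSpec()
        self.adjusted = adjusted
        self._cache: dict = {}

    def _key(self, ann):
        import hashlib
        return (ann.name, hashlib.sha1(ann.values.tobytes()).hexdigest())

    def scores_for(self, annotations: AnnotationMatrix) -> StratifiedLDScores:
        missing = [ann for ann in annotations.annotations
                   if self._key(ann) not in self._cache]
        if missing:
            sub = AnnotationMatrix(annotations.panel, missing)
            scores = stratified_ld_scores(self.genotypes, sub, self.window,
                                          self.adjusted)
            for i, ann in enumerate(missing):
                self._cache[self._key(ann)] = scores.values[:, i]
        vals = np.column_stack([self._cache[self._key(ann)]
                                for ann in annotations.annotations])
        a = annotations.values()
        return StratifiedLDScores(
            panel=annotations.panel, names=list(annotations.names),
            values=vals, annot_sums=a.sum(axis=0), annot_sds=a.std(axis=0),
            kinds=list(annotations.kinds), m_total=annotations.panel.m,
            settings={"window_kind": self.window.kind,
                      "window_size": self.window.size,
                      "adjusted_r2": bool(self.adjusted),
                      "n_ref": int(self.genotypes.n_samples)},
            gram=a.T @ a)
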
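"""SNP panels and reference genotype containers.

The :class:`SnpPanel` is the coordinate frame of the whole package: every
annotation vector, LD score column and summary-statistic record indexes into
its SNP order (grouped by chromosome, positions strictly increasing within a
chromosome).
"""
from __future__ import annotations

import numpy as np
import pandas as pd


class PanelError(ValueError):
    """Raised when a panel or genotype container violates its invariants."""


MIN_MINOR_ALLELE_COUNT = 5


class SnpPanel:
    """Ordered table of SNPs: identifier, chromosome, 1-based position,
    alleles and minor allele frequency.

    Parameters
    ----------
    snp_id, chrom, pos, a1, a2, maf : array-like, one entry per SNP
    minor_allele_count : array-like of int, optional
        When given, every SNP must have a minor allele count of at least
        ``MIN_MINOR_ALLELE_COUNT`` (panel-inclusion rule).
    """

    def __init__(self, snp_id, chrom, pos, a1, a2, maf,
                 minor_allele_count=None, *, validate: bool = True):
        self.snp_id = np.asarray(snp_id, dtype=object)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.a1 = np.asarray(a1, dtype=object)
        self.a2 = np.asarray(a2, dtype=object)
        self.maf = np.asarray(maf, dtype=float)
        self.minor_allele_count = (
            None if minor_allele_count is None
            else np.asarray(minor_allele_count, dtype=np.int64))
        if validate:
            self._validate()

    # -- invariants -------------------------------------------------------
    def _validate(self) -> None:
        m = len(self.snp_id)
        for name in ("chrom", "pos", "a1", "a2", "maf"):
            if len(getattr(self, name)) != m:
                raise PanelError(f"field {name!r} has length "
                                 f"{len(getattr(self, name))}, expected {m}")
        if len(set(self.snp_id)) != m:
            raise PanelError("snp_id values are not unique")
        if np.any(~np.isfinite(self.maf)) or np.any(self.maf <= 0) \
                or np.any(self.maf > 0.5):
            raise PanelError("maf must lie in (0, 0.5]")
        # positions strictly increasing within each chromosome; chromosomes
        # must form contiguous runs so genome order equals panel order
        seen = set()
        for c, sl in self.chrom_slices().items():
            if c in seen:
                raise PanelError(f"chromosome {c} is not contiguous in panel")
            seen.add(c)
            p = self.pos[sl]
            if np.any(np.diff(p) <= 0):
                raise PanelError(
                    f"positions not strictly increasing on chromosome {c}")
        if self.minor_allele_count is not None and \
                np.any(self.minor_allele_count < MIN_MINOR_ALLELE_COUNT):
            bad = int(np.sum(self.minor_allele_count < MIN_MINOR_ALLELE_COUNT))
            raise PanelError(
                f"{bad} SNPs have minor allele count < {MIN_MINOR_ALLELE_COUNT}")

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def m(self) -> int:
        """Number of panel SNPs (the M of heritability denominators)."""
        return len(self.snp_id)

    def chrom_slices(self) -> dict:
        """Mapping chromosome -> slice of panel indices (contiguous runs)."""
        out = {}
        chroms = self.chrom
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def index_of(self, snp_ids) -> np.ndarray:
        """Panel indices of the given SNP ids (raises on unknown ids)."""
        lookup = {s: i for i, s in enumerate(self.snp_id)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=np.int64)
        except KeyError as exc:
            raise PanelError(f"SNP id {exc.args[0]!r} not in panel") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "snp_id": self.snp_id, "chrom": self.chrom, "pos": self.pos,
            "a1": self.a1, "a2": self.a2, "maf": self.maf})
        if self.minor_allele_count is not None:
            df["minor_allele_count"] = self.minor_allele_count
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, validate: bool = True) -> "SnpPanel":
        mac = df["minor_allele_count"] if "minor_allele_count" in df else None
        return cls(df["snp_id"], df["chrom"], df["pos"], df["a1"], df["a2"],
                   df["maf"], mac, validate=validate)

    def equals(self, other: "SnpPanel") -> bool:
        return (len(self) == len(other)
                and np.array_equal(self.snp_id, other.snp_id)
                and np.array_equal(self.chrom, other.chrom)
                and np.array_equal(self.pos, other.pos))


class GenotypePanel:
    """Reference dosage matrix over the SNPs of a panel.

    ``dosages`` is (n_samples, M) with entries in {0, 1, 2} counting copies
    of the panel's a1 allele; ``-1`` marks a missing call.  An optional
    genetic-map position (cM) per SNP enables cM-based LD windows.
    """

    MISSING = -1

    def __init__(self, panel: SnpPanel, dosages, cm=None, *, validate=True):
        self.panel = panel
        self.dosages = np.asarray(dosages, dtype=np.int8)
        self.cm = None if cm is None else np.asarray(cm, dtype=float)
        if validate:
            if self.dosages.ndim != 2 or self.dosages.shape[1] != panel.m:
                raise PanelError(
                    f"dosage matrix shape {self.dosages.shape} does not match "
                    f"panel of {panel.m} SNPs")
            valid = np.isin(self.dosages, (-1, 0, 1, 2))
            if not valid.all():
                raise PanelError("dosages must be in {0,1,2} or -1 (missing)")
            if self.cm is not None and len(self.cm) != panel.m:
                raise PanelError("genetic map length does not match panel")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the coded (a1) allele, missing calls excluded."""
        d = self.dosages.astype(float)
        mask = d >= 0
        with np.errstate(invalid="ignore"):
            return np.where(mask, d, np.nan).sum(axis=0, where=mask) / \
                (2.0 * mask.sum(axis=0))

    def standardized(self, idx=None) -> np.ndarray:
        """Mean-imputed, mean-centred, unit-variance dosage columns.

        Missing calls are replaced by the per-SNP mean before
        standardization.  Monomorphic columns raise ``PanelError``.
        """
        d = self.dosages if idx is None else self.dosages[:, idx]
        x = d.astype(np.float64)
        miss = x < 0
        if miss.any():
            x = np.where(miss, np.nan, x)
            col_mean = np.nanmean(x, axis=0)
            x = np.where(np.isnan(x), col_mean[None, :], x)
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        if np.any(sd == 0):
            j = int(np.flatnonzero(sd == 0)[0])
            raise PanelError(f"monomorphic SNP at column {j}: cannot standardize")
        return (x - mu) / sd
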
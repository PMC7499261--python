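"""File formats: PLINK bed/bim/fam, ldsc-style .annot / .sumstats /
.l2.ldscore tables, BED region files and FASTA access.

All tabular formats transparently handle gzip via pandas; values are
serialized with 6 significant digits.
"""
from __future__ import annotations

import gzip
import json
import warnings

import numpy as np
import pandas as pd

from .annotations import Annotation, AnnotationMatrix, AnnotationError, RegionSet
from .panel import GenotypePanel, PanelError, SnpPanel

_FLOAT_FMT = "%.6g"


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# PLINK 1 binary genotypes
# ---------------------------------------------------------------------------
# 2-bit codes per sample, SNP-major: 0b00 hom a1 (dosage 2), 0b01 missing,
# 0b10 het, 0b11 hom a2 (dosage 0).

_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)
_BYTE_TABLE = np.array(
    [[_DECODE[(b >> (2 * i)) & 3] for i in range(4)] for b in range(256)],
    dtype=np.int8)
_ENCODE = {2: 0, -1: 1, 1: 2, 0: 3}


def read_plink(prefix) -> tuple[SnpPanel, GenotypePanel]:
    """Read a PLINK 1 bed/bim/fam fileset into panel + genotype containers.

    The bim a1 allele is the coded allele: dosages count a1 copies.  MAF and
    minor allele counts are computed from the genotypes.
    """
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str})
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        raw = fh.read()
    if raw[:3] != b"\x6c\x1b\x01":
        raise PanelError(f"{prefix}.bed is not a SNP-major PLINK 1 bed file")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if len(body) != bytes_per_snp * m:
        raise PanelError(f"{prefix}.bed has {len(body)} data bytes, expected "
                         f"{bytes_per_snp * m}")
    dec = _BYTE_TABLE[body.reshape(m, bytes_per_snp)]  # (m, bytes, 4)
    dosages = dec.reshape(m, bytes_per_snp * 4)[:, :n].T.copy()  # (n, m)

    d = dosages.astype(float)
    miss = d < 0
    called = (~miss).sum(axis=0)
    a1_count = np.where(miss, 0, d).sum(axis=0)
    freq = a1_count / (2 * called)
    maf = np.minimum(freq, 1 - freq)
    mac = np.minimum(a1_count, 2 * called - a1_count).astype(np.int64)
    panel = SnpPanel(bim["snp_id"], bim["chrom"], bim["pos"], bim["a1"],
                     bim["a2"], np.clip(maf, 1e-12, 0.5), None)
    cm = bim["cm"].to_numpy(float)
    cm = cm if np.any(cm != 0) else None
    panel.minor_allele_count = mac
    return panel, GenotypePanel(panel, dosages, cm)


def write_plink(prefix, panel: SnpPanel, genotypes: GenotypePanel) -> None:
    bim = pd.DataFrame({
        "chrom": panel.chrom,
        "snp_id": panel.snp_id,
        "cm": genotypes.cm if genotypes.cm is not None else np.zeros(panel.m),
        "pos": panel.pos, "a1": panel.a1, "a2": panel.a2})
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    n = genotypes.n_samples
    fam = pd.DataFrame({
        "fid": [f"F{i}" for i in range(n)], "iid": [f"I{i}" for i in range(n)],
        "pat": 0, "mat": 0, "sex": 0, "pheno": -9})
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)
    bytes_per_snp = (n + 3) // 4
    codes = np.empty((panel.m, bytes_per_snp * 4), dtype=np.uint8)
    code_map = np.zeros(256, dtype=np.uint8)
    for dosage, code in _ENCODE.items():
        code_map[np.int16(dosage) & 0xFF] = code
    d = genotypes.dosages.T  # (m, n)
    codes[:, :n] = code_map[d.astype(np.int16) & 0xFF]
    codes[:, n:] = 0
    packed = (codes[:, 0::4] | (codes[:, 1::4] << 2)
              | (codes[:, 2::4] << 4) | (codes[:, 3::4] << 6)).astype(np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(b"\x6c\x1b\x01")
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# .annot
# ---------------------------------------------------------------------------

def write_annot(matrix: AnnotationMatrix, path) -> None:
    """ldsc-style .annot(.gz): CHR BP SNP CM then one column per annotation,
    one row per panel SNP in panel order."""
    panel = matrix.panel
    df = pd.DataFrame({"CHR": panel.chrom, "BP": panel.pos,
                       "SNP": panel.snp_id, "CM": 0.0})
    for a in matrix.annotations:
        df[a.name] = a.values
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    # kinds sidecar so binary/probabilistic/continuous survives a round trip
    with _open_text(str(path) + ".kinds.json", "wt") as fh:
        json.dump({a.name: a.kind for a in matrix.annotations}, fh)


def _infer_kind(values: np.ndarray) -> str:
    if np.all(np.isin(values, (0.0, 1.0))):
        return "binary"
    if values.min() >= 0 and values.max() <= 1:
        return "probabilistic"
    return "continuous"


def read_annot(path, panel: SnpPanel) -> AnnotationMatrix:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise AnnotationError(f"malformed .annot file {path}: {exc}") from None
    if len(df) != panel.m:
        raise AnnotationError(
            f".annot file {path} has {len(df)} rows, panel has {panel.m} SNPs")
    if not np.array_equal(df["SNP"].to_numpy(object), panel.snp_id):
        raise AnnotationError(f".annot file {path} SNP order differs from panel")
    kinds = {}
    try:
        with _open_text(str(path) + ".kinds.json") as fh:
            kinds = json.load(fh)
    except OSError:
        pass
    mat = AnnotationMatrix(panel)
    for col in df.columns:
        if col in ("CHR", "BP", "SNP", "CM"):
            continue
        vals = df[col].to_numpy(float)
        mat.add(Annotation(col, vals, kinds.get(col, _infer_kind(vals))))
    return mat


# ---------------------------------------------------------------------------
# BED regions
# ---------------------------------------------------------------------------

def read_bed_regions(path, label: str = "") -> RegionSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    return RegionSet(df, label=label or str(path))


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

class SummaryStats:
    """Per-SNP GWAS chi-square statistics for one trait.

    Holds snp_id, chi2 (= Z^2) and per-SNP sample size N; records are a
    subset of a panel and are aligned to it at fit time.
    """

    def __init__(self, snp_id, chi2, n, trait: str = "trait"):
        self.snp_id = np.asarray(snp_id, dtype=object)
        self.chi2 = np.asarray(chi2, dtype=float)
        self.n = np.broadcast_to(np.asarray(n, dtype=float),
                                 self.chi2.shape).copy()
        self.trait = trait
        if np.any(self.chi2 < 0):
            raise ValueError("chi2 statistics must be non-negative")
        if np.any(self.n <= 1):
            raise ValueError("sample size N must exceed 1")

    def __len__(self):
        return len(self.snp_id)


def read_sumstats(path, trait: str | None = None,
                  panel: SnpPanel | None = None) -> SummaryStats:
    """Read an ldsc-style .sumstats file (SNP A1 A2 Z N; chi2 = Z^2).

    When a panel is given, records are matched by snp_id and records whose
    alleles do not match the panel's {a1, a2} (in either order) are dropped
    with a warning giving the count.
    """
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.upper() for c in df.columns]
    ss = SummaryStats(df["SNP"], df["Z"].to_numpy(float) ** 2, df["N"],
                      trait or str(path))
    if panel is not None:
        in_panel = pd.Series(ss.snp_id).isin(panel.snp_id).to_numpy()
        idx = panel.index_of(ss.snp_id[in_panel])
        pa1 = panel.a1[idx]
        pa2 = panel.a2[idx]
        a1 = df["A1"].to_numpy(object)[in_panel]
        a2 = df["A2"].to_numpy(object)[in_panel]
        ok = ((a1 == pa1) & (a2 == pa2)) | ((a1 == pa2) & (a2 == pa1))
        dropped = int(len(ss) - ok.sum())
        if dropped:
            warnings.warn(f"{path}: dropped {dropped} records not matching "
                          "panel SNPs/alleles")
        keep = np.flatnonzero(in_panel)[ok]
        ss = SummaryStats(ss.snp_id[keep], ss.chi2[keep], ss.n[keep], ss.trait)
    return ss


def write_sumstats(ss: SummaryStats, path, panel: SnpPanel | None = None) -> None:
    if panel is not None:
        idx = panel.index_of(ss.snp_id)
        a1, a2 = panel.a1[idx], panel.a2[idx]
    else:
        a1 = np.full(len(ss), "A", dtype=object)
        a2 = np.full(len(ss), "G", dtype=object)
    df = pd.DataFrame({"SNP": ss.snp_id, "A1": a1, "A2": a2,
                       "Z": np.sqrt(ss.chi2), "N": ss.n})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# LD score tables
# ---------------------------------------------------------------------------

def write_ldscores(scores, prefix) -> None:
    """Write .l2.ldscore.gz (CHR SNP BP + one column per annotation) plus
    .l2.M (per-annotation value sums over the full panel) and a JSON sidecar
    with panel size, annotation sds/kinds and estimator settings."""
    panel = scores.panel
    df = pd.DataFrame({"CHR": panel.chrom, "SNP": panel.snp_id, "BP": panel.pos})
    for i, name in enumerate(scores.names):
        df[name] = scores.values[:, i]
    df.to_csv(f"{prefix}.l2.ldscore.gz", sep="\t", index=False,
              float_format=_FLOAT_FMT)
    with open(f"{prefix}.l2.M", "w") as fh:
        fh.write("\t".join(_FLOAT_FMT % s for s in scores.annot_sums) + "\n")
    meta = {"m_total": int(scores.m_total),
            "annot_sums": [float(s) for s in scores.annot_sums],
            "annot_sds": [float(s) for s in scores.annot_sds],
            "kinds": list(scores.kinds),
            "settings": scores.settings}
    with open(f"{prefix}.l2.meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_ldscores(prefix, panel: SnpPanel | None = None):
    from .ldscores import StratifiedLDScores
    df = pd.read_csv(f"{prefix}.l2.ldscore.gz", sep="\t")
    names = [c for c in df.columns if c not in ("CHR", "SNP", "BP")]
    with open(f"{prefix}.l2.meta.json") as fh:
        meta = json.load(fh)
    if panel is None:
        panel = SnpPanel(df["SNP"].astype(str), df["CHR"].astype(str),
                         df["BP"], ["A"] * len(df), ["G"] * len(df),
                         np.full(len(df), 0.25))
    return StratifiedLDScores(
        panel=panel, names=names,
        values=df[names].to_numpy(float),
        annot_sums=np.asarray(meta["annot_sums"], float),
        annot_sds=np.asarray(meta["annot_sds"], float),
        kinds=list(meta["kinds"]), m_total=int(meta["m_total"]),
        settings=meta.get("settings", {}))


def open_fasta(path):
    """Indexed FASTA accessor (chrom -> subscriptable sequence)."""
    from pyfaidx import Fasta
    return Fasta(str(path))


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
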
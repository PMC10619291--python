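"""PLINK 1 binary genotype I/O and genotype normalization.

Genotypes are hard-call minor-allele dosages in {0, 1, 2}; missing calls are
stored as -1. The BED codec implements the standard SNP-major 2-bit layout
(magic bytes 0x6C 0x1B, mode 0x01): within each variant record, sample ``i``
occupies bits ``2*(i % 4)`` of byte ``i // 4`` with codes 00 = homozygous A1
(dosage 2), 10 = heterozygous (1), 11 = homozygous A2 (0), 01 = missing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

# 2-bit code -> dosage of allele1 (minor allele); 01 is the missing sentinel
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised when a BED/BIM/FAM file violates the PLINK 1 binary format."""


@dataclass
class GenotypeMatrix:
    """m samples x n SNPs matrix of minor-allele counts, with metadata.

    ``dosages`` is int8 with entries in {0, 1, 2} or ``MISSING`` (-1).
    ``variants`` rows are (chrom, id, pos, allele1, allele2).
    """

    dosages: np.ndarray
    samples: list[str]
    variants: list[tuple[str, str, int, str, str]]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        m, n = self.dosages.shape
        if m < 2 or n < 1:
            raise ValueError(f"need m >= 2 samples and n >= 1 variants, got {m}x{n}")
        if len(self.samples) != m:
            raise ValueError("sample metadata length does not match matrix rows")
        if len(self.variants) != n:
            raise ValueError("variant metadata length does not match matrix columns")
        valid = np.isin(self.dosages, [0, 1, 2, MISSING])
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"dosages must be 0/1/2 or missing (-1); found {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape


@dataclass
class NormalizedGenotypes:
    """Column-standardized genotype matrix: each column mean 0, variance 1.

    Variance uses the population (1/m) convention so the unit-variance
    invariant holds exactly; the (m-1) factor of the Mahalanobis/leverage
    identity is carried explicitly by the distance formulas instead.
    """

    X: np.ndarray
    kept_variants: np.ndarray

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]


@dataclass
class Phenotype:
    """Trait vector; binary traits are 0 = control, 1 = case; NaN = missing."""

    y: np.ndarray
    trait_kind: str  # "binary" | "quantitative"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.trait_kind not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")
        if self.trait_kind == "binary":
            obs = self.y[~np.isnan(self.y)]
            if obs.size and not np.isin(obs, [0.0, 1.0]).all():
                raise ValueError("binary trait must contain only 0/1")

    @property
    def all_missing(self) -> bool:
        return bool(np.isnan(self.y).all())


def _decode_bed_payload(payload: bytes, m: int, n: int) -> np.ndarray:
    bytes_per_variant = (m + 3) // 4
    expected = bytes_per_variant * n
    if len(payload) != expected:
        raise PlinkFormatError(
            f"BED payload is {len(payload)} bytes; expected {expected} "
            f"for {m} samples x {n} variants"
        )
    raw = np.frombuffer(payload, dtype=np.uint8).reshape(n, bytes_per_variant)
    # unpack 4 samples per byte, low bits first
    codes = np.empty((n, bytes_per_variant * 4), dtype=np.uint8)
    for s in range(4):
        codes[:, s::4] = (raw >> (2 * s)) & 0b11
    return _CODE_TO_DOSAGE[codes[:, :m]].T.copy()  # -> m x n


def _encode_bed_payload(dosages: np.ndarray) -> bytes:
    m, n = dosages.shape
    codes = np.empty((n, m), dtype=np.uint8)
    dt = dosages.T
    codes[dt == 2] = 0b00
    codes[dt == 1] = 0b10
    codes[dt == 0] = 0b11
    codes[dt == MISSING] = 0b01
    bytes_per_variant = (m + 3) // 4
    padded = np.zeros((n, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :m] = codes
    out = np.zeros((n, bytes_per_variant), dtype=np.uint8)
    for s in range(4):
        out |= padded[:, s::4] << (2 * s)
    return out.tobytes()


def _map_fam_phenotype(raw: np.ndarray) -> Phenotype:
    """FAM column 6: 1 -> control, 2 -> case, -9/0 -> missing; else quantitative."""
    vals = raw.astype(float)
    missing = np.isin(vals, (-9.0, 0.0))
    obs = vals[~missing]
    if obs.size == 0:
        return Phenotype(np.full(vals.shape, np.nan), "binary")
    if np.isin(obs, (1.0, 2.0)).all():
        y = np.where(missing, np.nan, vals - 1.0)
        return Phenotype(y, "binary")
    y = np.where(missing, np.nan, vals)
    return Phenotype(y, "quantitative")


def read_plink(prefix: str | Path) -> tuple[GenotypeMatrix, Phenotype]:
    """Read a PLINK 1 binary fileset ``prefix``.bed/.bim/.fam.

    Returns the genotype matrix plus the FAM-column-6 phenotype (1->0, 2->1,
    -9/0 -> missing). If every FAM phenotype is missing the returned
    ``Phenotype.all_missing`` is True and a separate phenotype file must be
    supplied by the caller.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(f"missing PLINK file: {prefix.with_suffix(ext)}")

    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    m, n = len(fam), len(bim)

    with open(prefix.with_suffix(".bed"), "rb") as fh:
        header = fh.read(3)
        if len(header) < 3 or header[0] != 0x6C or header[1] != 0x1B:
            raise PlinkFormatError(f"{prefix.with_suffix('.bed')}: bad magic bytes")
        if header[2] != 0x01:
            raise PlinkFormatError(
                f"{prefix.with_suffix('.bed')}: only SNP-major mode (0x01) supported"
            )
        dosages = _decode_bed_payload(fh.read(), m, n)

    samples = list(fam["iid"].astype(str))
    variants = [
        (str(r.chrom), str(r.id), int(r.pos), str(r.a1), str(r.a2))
        for r in bim.itertuples()
    ]
    g = GenotypeMatrix(dosages, samples, variants)
    return g, _map_fam_phenotype(fam["pheno"].to_numpy())


def write_plink(g: GenotypeMatrix, y: Phenotype | None, prefix: str | Path) -> None:
    """Write ``g`` (and optional phenotype) as a PLINK 1 binary fileset."""
    if len(g.variants) == 0:
        raise ValueError("refusing to write a fileset with no variants")
    prefix = Path(prefix)
    os.makedirs(prefix.parent, exist_ok=True)

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        fh.write(_encode_bed_payload(g.dosages))

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for chrom, vid, pos, a1, a2 in g.variants:
            fh.write(f"{chrom}\t{vid}\t0\t{pos}\t{a1}\t{a2}\n")

    m = g.dosages.shape[0]
    if y is None:
        pheno = ["-9"] * m
    elif y.trait_kind == "binary":
        pheno = ["-9" if np.isnan(v) else str(int(v) + 1) for v in y.y]
    else:
        pheno = ["-9" if np.isnan(v) else repr(float(v)) for v in y.y]
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid, ph in zip(g.samples, pheno):
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t{ph}\n")


def read_phenotype_file(path: str | Path, samples: list[str]) -> Phenotype:
    """Read a tab-delimited FID IID PHENO file (header optional) aligned to
    ``samples`` by IID; samples absent from the file get a missing phenotype."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError("phenotype file needs at least 3 columns: FID IID PHENO")
    first = df.iloc[0, 2]
    try:
        float(first)
    except ValueError:  # header row
        df = df.iloc[1:]
    lookup = dict(zip(df.iloc[:, 1], df.iloc[:, 2].astype(float)))
    raw = np.array([lookup.get(s, -9.0) for s in samples])
    return _map_fam_phenotype(raw)


def impute_and_normalize(
    g: GenotypeMatrix,
    drop_monomorphic: bool = True,
    max_missing: float = 0.1,
    min_maf: float = 0.0,
) -> NormalizedGenotypes:
    """Mean-impute missing calls, then standardize columns to mean 0, var 1.

    Columns exceeding ``max_missing`` missingness are dropped, as are
    monomorphic (zero-variance) columns when ``drop_monomorphic`` and columns
    below the ``min_maf`` minor-allele-frequency floor (0 = keep all,
    standard QC uses 0.01-0.05); surviving column indices are recorded in
    ``kept_variants``. Standardization uses the empirical per-column mean and
    population (1/m) standard deviation.
    """
    D = g.dosages.astype(float)
    D[g.dosages == MISSING] = np.nan
    m, n = D.shape

    miss_frac = np.isnan(D).mean(axis=0)
    keep = miss_frac <= max_missing
    all_missing = miss_frac == 1.0
    keep &= ~all_missing
    with np.errstate(invalid="ignore"):
        col_mean = np.where(all_missing, 0.0, np.nanmean(D, axis=0))
    X = np.where(np.isnan(D), col_mean, D)

    var = X.var(axis=0)  # population variance
    if drop_monomorphic:
        keep &= var > 0
    if min_maf > 0:
        freq = X.mean(axis=0) / 2.0
        keep &= np.minimum(freq, 1.0 - freq) >= min_maf
    kept = np.flatnonzero(keep)
    if kept.size == 0 or (var[kept] > 0).sum() == 0:
        raise ValueError("no informative variants: all columns monomorphic or too missing")
    X = X[:, kept]
    sd = np.sqrt(var[kept])
    sd_safe = np.where(sd > 0, sd, 1.0)  # monomorphic kept only when not dropping
    X = (X - col_mean[kept]) / sd_safe
    return NormalizedGenotypes(X, kept)
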
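"""Genotype input/output and standardization.

Readers for PLINK 1 binary genotypes (BED/BIM/FAM, SNP-major) and VCF
per-sample dosages (FORMAT/DS), the variant-level quality filter, and
column standardization into the block representation consumed by the
implicit GRM operator.

Conventions: the ALT allele (BIM A2 / VCF ALT) is the counted and effect
allele throughout; coordinates are 1-based as in BIM/VCF; missing hard
calls are mean-imputed per column before standardization.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    EmptyBlockError,
    FormatError,
    TruncationError,
)

log = logging.getLogger(__name__)

BED_MAGIC = b"\x6c\x1b"
BED_SNP_MAJOR = 0x01

# 2-bit PLINK codes -> ALT(A2) dosage: 00 hom-A1 -> 0, 01 missing, 10 het -> 1,
# 11 hom-A2 -> 2
_CODE_TO_DOSAGE = np.array([0.0, np.nan, 1.0, 2.0])
_DOSAGE_TO_CODE = {0.0: 0, 1.0: 2, 2.0: 3}


@dataclass
class VariantRecord:
    """Variant-level metadata and the quantities the quality filter uses.

    ``mac`` is the minor allele count min(alt, 2*n_nonmissing - alt); it may
    be fractional for dosage data.  ``info_score`` is the imputation quality
    in [0, 1], or None when the source carries no such key.
    """

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str
    alt_freq: float
    mac: float
    info_score: float | None = None
    n_nonmissing: int = 0


@dataclass
class RawGenotypeBlock:
    """N x m genotype/dosage matrix in [0, 2] with NaN as the missing marker."""

    values: np.ndarray
    variants: list[VariantRecord]
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]


@dataclass
class StandardizedBlock:
    """One column partition A[:, s:e] of the standardized genotype matrix."""

    values: np.ndarray
    start_index: int
    end_index: int

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


@dataclass
class FilterTally:
    """Per-rule rejection counts from :func:`filter_variants`."""

    n_input: int = 0
    n_retained: int = 0
    low_mac: int = 0
    low_info: int = 0


def _variant_stats(col: np.ndarray) -> tuple[float, float, int]:
    """(alt_freq, mac, n_nonmissing) from a dosage column with NaN missing."""
    finite = np.isfinite(col)
    n = int(finite.sum())
    if n == 0:
        return 0.0, 0.0, 0
    alt = float(col[finite].sum())
    freq = alt / (2.0 * n)
    mac = min(alt, 2.0 * n - alt)
    return freq, mac, n


def read_bed(bed_path, bim_path, fam_path) -> RawGenotypeBlock:
    """Read a PLINK 1 SNP-major BED/BIM/FAM triple into a raw block.

    Genotype values are ALT(A2)-allele counts; missing hard calls become NaN.
    """
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(bed_path).read_bytes()
    if len(raw) < 3 or raw[:2] != BED_MAGIC:
        raise FormatError(f"{bed_path}: missing PLINK BED magic bytes 0x6C 0x1B")
    if raw[2] != BED_SNP_MAJOR:
        raise FormatError(
            f"{bed_path}: unsupported mode byte 0x{raw[2]:02X} (only SNP-major 0x01)"
        )
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * m
    if len(raw) != expected:
        raise TruncationError(
            f"{bed_path}: payload is {len(raw)} bytes, expected {expected} "
            f"for {n} samples x {m} variants"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_variant)
    # unpack 2-bit codes, samples packed LSB-first within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0x03
    codes = codes.reshape(m, bytes_per_variant * 4)[:, :n]
    values = _CODE_TO_DOSAGE[codes].T.copy()  # N x m

    variants = []
    for j in range(m):
        freq, mac, nn = _variant_stats(values[:, j])
        row = bim.iloc[j]
        variants.append(VariantRecord(
            chrom=str(row["chrom"]), pos=int(row["pos"]), id=str(row["id"]),
            ref_allele=str(row["a1"]), alt_allele=str(row["a2"]),
            alt_freq=freq, mac=mac, info_score=None, n_nonmissing=nn,
        ))
    return RawGenotypeBlock(values=values, variants=variants,
                            sample_ids=fam["iid"].tolist())


def write_bed(block: RawGenotypeBlock, prefix) -> None:
    """Write a raw block as PLINK 1 SNP-major BED/BIM/FAM.

    Values must be hard calls in {0, 1, 2, NaN}; the counted allele is
    written as A2.
    """
    prefix = Path(prefix)
    values = block.values
    n, m = values.shape
    if not np.all(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))):
        raise DomainError("write_bed requires hard calls in {0, 1, 2, NaN}")
    codes = np.ones((m, n), dtype=np.uint8)  # 01 = missing
    vt = values.T
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[vt == dosage] = code
    bytes_per_variant = (n + 3) // 4
    padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(BED_MAGIC + bytes([BED_SNP_MAJOR]))
        fh.write(packed.tobytes())
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in block.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in block.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")


class VcfDosageReader:
    """Stream (VariantRecord, dosage_vector) pairs from a VCF with FORMAT/DS.

    Multi-allelic sites are decomposed into one record per ALT allele.  Sites
    lacking a DS field are skipped with a logged warning and counted in
    ``n_skipped``.  ``info_key`` names the imputation-quality INFO entry
    (R2 by default; INFO/DR2 dialects are configurable).
    """

    def __init__(self, vcf_path, info_key: str = "R2"):
        import cyvcf2

        self._vcf = cyvcf2.VCF(str(vcf_path))
        self.samples: list[str] = list(self._vcf.samples)
        self.info_key = info_key
        self.n_skipped = 0

    def __iter__(self) -> Iterator[tuple[VariantRecord, np.ndarray]]:
        for site in self._vcf:
            try:
                ds = site.format("DS")
            except KeyError:
                ds = None
            if ds is None:
                self.n_skipped += 1
                log.warning("site %s:%s lacks FORMAT/DS; skipped",
                            site.CHROM, site.POS)
                continue
            ds = np.asarray(ds, dtype=np.float64)
            if ds.ndim == 1:
                ds = ds[:, None]
            info_val = site.INFO.get(self.info_key)
            alts = site.ALT if site.ALT else ["."]
            for j, alt in enumerate(alts):
                col = ds[:, j] if ds.shape[1] > j else ds[:, 0]
                col = col.copy()
                col[~np.isfinite(col) | (col < 0.0) | (col > 2.0)] = np.nan
                if isinstance(info_val, (tuple, list)):
                    info_j = float(info_val[j]) if j < len(info_val) else None
                elif info_val is None:
                    info_j = None
                else:
                    info_j = float(info_val)
                freq, mac, nn = _variant_stats(col)
                rec = VariantRecord(
                    chrom=str(site.CHROM), pos=int(site.POS),
                    id=site.ID or f"{site.CHROM}:{site.POS}",
                    ref_allele=str(site.REF), alt_allele=str(alt),
                    alt_freq=freq, mac=mac, info_score=info_j, n_nonmissing=nn,
                )
                yield rec, col


def read_vcf_dosages(vcf_path, info_key: str = "R2") -> VcfDosageReader:
    """Open a dosage VCF for streaming; see :class:`VcfDosageReader`."""
    return VcfDosageReader(vcf_path, info_key=info_key)


def write_vcf_dosages(path, variants: Sequence[VariantRecord],
                      dosages: np.ndarray, sample_ids: Sequence[str],
                      info_key: str = "R2") -> None:
    """Write an uncompressed dosage VCF (FORMAT/DS, one ALT per line)."""
    dosages = np.asarray(dosages, dtype=np.float64)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f'##INFO=<ID={info_key},Number=1,Type=Float,'
                 'Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=DS,Number=A,Type=Float,'
                 'Description="Alternate allele dosage">\n')
        chroms = []
        for v in variants:
            if v.chrom not in chroms:
                chroms.append(v.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in sample_ids) + "\n")
        for j, v in enumerate(variants):
            info = "." if v.info_score is None else f"{info_key}={v.info_score:.4f}"
            fields = [v.chrom, str(v.pos), v.id, v.ref_allele, v.alt_allele,
                      ".", "PASS", info, "DS"]
            col = dosages[:, j]
            fields.extend("." if not np.isfinite(x) else f"{x:.6f}" for x in col)
            fh.write("\t".join(fields) + "\n")


def filter_variants(records: Sequence[VariantRecord], mac_min: float = 40.0,
                    info_min: float = 0.3) -> tuple[list[VariantRecord], FilterTally]:
    """Apply the step-two inclusion rule: MAC >= mac_min and info > info_min.

    The MAC bound is inclusive, the imputation-quality bound strict; records
    with no info score pass the quality rule.  Order is preserved.
    """
    if mac_min < 0:
        raise DomainError("mac_min must be >= 0")
    if not 0.0 <= info_min <= 1.0:
        raise DomainError("info_min must lie in [0, 1]")
    tally = FilterTally(n_input=len(records))
    kept: list[VariantRecord] = []
    for rec in records:
        ok = True
        if rec.mac < mac_min:
            tally.low_mac += 1
            ok = False
        if rec.info_score is not None and rec.info_score <= info_min:
            tally.low_info += 1
            ok = False
        if ok:
            kept.append(rec)
    tally.n_retained = len(kept)
    return kept, tally


Scheme = Literal["hwe", "unit", "raw"]


def standardize_block(
    raw: RawGenotypeBlock | np.ndarray,
    scheme: Scheme = "hwe",
    start_index: int = 0,
) -> tuple[StandardizedBlock, list[int]]:
    """Center (and scale) genotype columns; returns the block and the indices
    of dropped monomorphic columns (relative to the input block).

    Missing entries are replaced by the column mean before centering.  The
    default "hwe" scheme divides the centered column by sqrt(2*p*(1-p)) with
    p the observed ALT frequency; "unit" divides by the empirical standard
    deviation; "raw" only centers.
    """
    values = raw.values if isinstance(raw, RawGenotypeBlock) else np.asarray(raw)
    values = np.array(values, dtype=np.float64, copy=True)
    n, m = values.shape
    col_mean = np.nanmean(np.where(np.isfinite(values), values, np.nan), axis=0)
    miss = ~np.isfinite(values)
    if miss.any():
        values[miss] = np.take(col_mean, np.nonzero(miss)[1])
    p_hat = col_mean / 2.0
    sd = values.std(axis=0, ddof=0)
    poly = (p_hat > 0.0) & (p_hat < 1.0) & (sd > 0.0)
    dropped = [int(j) for j in np.nonzero(~poly)[0]]
    if not poly.any():
        raise EmptyBlockError("all columns are monomorphic after imputation")
    if dropped:
        log.info("standardize_block: dropped %d monomorphic columns", len(dropped))
    values = values[:, poly]
    values -= col_mean[poly]
    if scheme == "hwe":
        values /= np.sqrt(2.0 * p_hat[poly] * (1.0 - p_hat[poly]))
    elif scheme == "unit":
        values /= sd[poly]
    elif scheme != "raw":
        raise DomainError(f"unknown standardization scheme {scheme!r}")
    block = StandardizedBlock(values=values, start_index=start_index,
                              end_index=start_index + values.shape[1])
    return block, dropped


def load_phenotypes(path, sample_ids: Sequence[str], trait: str,
                    covariates: Sequence[str]) -> tuple[np.ndarray, np.ndarray, dict]:
    """Join a header TSV of phenotypes/covariates to genotype sample order.

    Returns (y, X-with-intercept, join report).  Samples absent from the
    table are dropped from the report's ``matched_ids``; callers decide how
    to subset genotypes.
    """
    tab = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = tab.columns[0]
    tab = tab.set_index(id_col)
    matched = [s for s in sample_ids if s in tab.index]
    report = {
        "n_genotyped": len(sample_ids),
        "n_table": len(tab),
        "n_matched": len(matched),
        "matched_ids": matched,
    }
    log.info("phenotype join: %d genotyped, %d in table, %d matched",
             len(sample_ids), len(tab), len(matched))
    sub = tab.loc[matched]
    y = sub[trait].to_numpy(dtype=np.float64)
    cols = [np.ones(len(matched))]
    cols.extend(sub[c].to_numpy(dtype=np.float64) for c in covariates)
    X = np.column_stack(cols)
    return y, X, report
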
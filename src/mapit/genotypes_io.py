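"""Genotype and phenotype input/output.

Reads genotype panels from PLINK binary triplets (.bed/.bim/.fam,
SNP-major v1.00) or plain TSV allele-count matrices, applies the standard
GWAS hygiene steps (minor-allele-frequency floor, monomorphic-variant
removal, mean imputation of missing calls), and standardizes every variant
to mean 0 and standard deviation 1.  Standardization uses the population
(divide-by-n) standard deviation so that each standardized column ``x``
satisfies ``x.T @ x == n`` exactly -- an identity the kernel algebra
downstream relies on.
"""

from __future__ import annotations

import dataclasses
import logging
import pathlib

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FormatError",
    "EmptyPanelError",
    "GenotypeMatrix",
    "Phenotype",
    "standardize",
    "quantile_normalize",
    "load_genotypes",
    "load_phenotype",
    "write_plink",
    "write_results",
]

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel for a missing allele count

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 2-bit codes (SNP-major): 00 hom A1, 01 missing, 10 het, 11 hom A2.
# We count A1 alleles, so 00 -> 2, 10 -> 1, 11 -> 0, 01 -> MISSING.
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class FormatError(ValueError):
    """A genotype or phenotype file does not parse in the declared format."""


class EmptyPanelError(ValueError):
    """Every variant was removed by quality-control filtering."""


@dataclasses.dataclass(frozen=True)
class GenotypeMatrix:
    """An n x p genotype panel with standardized dosages.

    Attributes
    ----------
    counts:
        Integer allele counts in {0, 1, 2} (``MISSING`` marks an imputed
        entry of ``standardized``).
    standardized:
        Real matrix whose columns each have mean 0 and population standard
        deviation 1.
    variant_ids, chrom, pos:
        Per-variant metadata, parallel to the columns.
    sample_ids:
        Per-sample labels, parallel to the rows.
    maf:
        Per-variant minor allele frequency computed from observed counts.
    """

    counts: np.ndarray
    standardized: np.ndarray
    variant_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: np.ndarray
    maf: np.ndarray

    @property
    def n(self) -> int:
        return self.standardized.shape[0]

    @property
    def p(self) -> int:
        return self.standardized.shape[1]

    def __post_init__(self):
        n, p = self.standardized.shape
        if n < 3 or p < 2:
            raise ValueError(f"panel too small: n={n}, p={p} (need n>=3, p>=2)")

    def variants(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.variant_ids, "chr": self.chrom, "pos": self.pos,
             "maf": self.maf}
        )


@dataclasses.dataclass(frozen=True)
class Phenotype:
    """A quantitative trait vector aligned to a genotype panel."""

    y: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        if self.y.ndim != 1:
            raise ValueError("phenotype must be a vector")
        if len(self.sample_ids) != self.y.size:
            raise ValueError("sample_ids length does not match phenotype")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("phenotype contains missing/non-finite values")

    @property
    def n(self) -> int:
        return self.y.size


def standardize(counts: np.ndarray) -> np.ndarray:
    """Center and scale each column to mean 0 and population s.d. 1.

    Raises on constant columns; those must be filtered at load time.
    """
    x = np.asarray(counts, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected an n x p matrix")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population (divide-by-n) convention
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"constant column(s) at indices {bad.tolist()}; "
            "drop zero-variance variants at load time (see load_genotypes)"
        )
    return (x - mu) / sd


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Map a vector onto standard-normal quantiles of its ranks.

    Uses average ranks for ties (tied entries receive identical output) and
    the quantile points rank / (n + 1), so [10, 20, 30] maps to
    Phi^-1([0.25, 0.5, 0.75]).  Invariant to strictly monotone transforms
    of the input.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a vector of length >= 2")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf(ranks / (v.size + 1))


def _filter_and_build(counts, variant_ids, chrom, pos, sample_ids,
                      maf_floor, missing_policy) -> GenotypeMatrix:
    counts = np.asarray(counts, dtype=np.int8)
    n, p = counts.shape
    observed = counts != MISSING
    if missing_policy not in ("mean-impute", "drop-variant"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    n_obs = observed.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_obs > 0,
                        np.where(observed, counts, 0).sum(axis=0) / (2 * np.maximum(n_obs, 1)),
                        np.nan)
    maf = np.minimum(freq, 1.0 - freq)

    keep = n_obs > 0
    if missing_policy == "drop-variant":
        keep &= n_obs == n
    keep &= maf >= maf_floor
    # zero observed variance -> drop
    filled = np.where(observed, counts, 0).astype(np.float64)
    mean = np.where(n_obs > 0, filled.sum(axis=0) / np.maximum(n_obs, 1), 0.0)
    ssq = np.where(observed, (counts - mean) ** 2, 0.0).sum(axis=0)
    keep &= ssq > 0

    dropped = int(p - keep.sum())
    if dropped:
        logger.info("dropped %d of %d variants (MAF < %g, zero variance, or missingness)",
                    dropped, p, maf_floor)
    if not keep.any() or keep.sum() < 2:
        raise EmptyPanelError(
            f"fewer than 2 variants remain after filtering ({int(keep.sum())} of {p})"
        )

    counts = counts[:, keep]
    observed = observed[:, keep]
    imputed = np.asarray(counts, dtype=np.float64)
    if missing_policy == "mean-impute":
        col_mean = np.where(observed, imputed, 0.0).sum(axis=0) / observed.sum(axis=0)
        imputed = np.where(observed, imputed, col_mean)
    return GenotypeMatrix(
        counts=counts,
        standardized=standardize(imputed),
        variant_ids=np.asarray(variant_ids)[keep],
        chrom=np.asarray(chrom)[keep],
        pos=np.asarray(pos)[keep],
        sample_ids=np.asarray(sample_ids),
        maf=maf[keep],
    )


def _read_bed(prefix: pathlib.Path, n: int, p: int) -> np.ndarray:
    path = prefix.with_suffix(".bed")
    raw = path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{path}: bad magic bytes {raw[:3]!r}; expected SNP-major v1.00")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_variant * p:
        raise FormatError(
            f"{path}: expected {bytes_per_variant * p} data bytes for "
            f"n={n}, p={p}; found {body.size}"
        )
    blocks = body.reshape(p, bytes_per_variant)
    # expand each byte into four 2-bit codes (sample-minor within the byte)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(p, -1)[:, :n]
    return _BED_DECODE[codes].T.copy()  # n x p


def write_plink(counts: np.ndarray, prefix, variant_ids=None, chrom=None,
                pos=None, sample_ids=None) -> None:
    """Write an allele-count matrix as a PLINK .bed/.bim/.fam triplet.

    Intended for fixture generation and interoperability round-trips;
    alleles are written as A (counted) / B.
    """
    counts = np.asarray(counts, dtype=np.int8)
    n, p = counts.shape
    prefix = pathlib.Path(prefix)
    variant_ids = variant_ids if variant_ids is not None else [f"snp{j}" for j in range(p)]
    chrom = chrom if chrom is not None else np.ones(p, dtype=int)
    pos = pos if pos is not None else np.arange(1, p + 1)
    sample_ids = sample_ids if sample_ids is not None else [f"sample{i}" for i in range(n)]

    bytes_per_variant = (n + 3) // 4
    padded = np.zeros((p, bytes_per_variant * 4), dtype=np.uint8)
    code_lut = np.zeros(256, dtype=np.uint8)
    for count, code in _BED_ENCODE.items():
        code_lut[np.int8(count).view(np.uint8)] = code
    padded[:, :n] = code_lut[counts.T.view(np.uint8)]
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded.reshape(p, bytes_per_variant, 4) << shifts).sum(axis=2).astype(np.uint8)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(p):
            fh.write(f"{chrom[j]}\t{variant_ids[j]}\t0\t{pos[j]}\tA\tB\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")


def _load_plink(prefix: pathlib.Path):
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for required in (prefix.with_suffix(".bed"), bim_path, fam_path):
        if not required.exists():
            raise FormatError(f"incomplete PLINK triplet: missing {required}")
    try:
        bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                          names=["chr", "id", "cm", "pos", "a1", "a2"])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{bim_path}: {exc}") from exc
    try:
        fam = pd.read_csv(fam_path, sep=r"\s+", header=None)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"{fam_path}: {exc}") from exc
    counts = _read_bed(prefix, n=len(fam), p=len(bim))
    return counts, bim["id"].to_numpy(), bim["chr"].to_numpy(), \
        bim["pos"].to_numpy(), fam.iloc[:, 1].astype(str).to_numpy()


def _load_tsv(path: pathlib.Path):
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no columns parsed")
    first = df.columns[0]
    if df[first].dtype == object or first.lower() in ("sample", "sample_id", "iid", "id"):
        sample_ids = df[first].astype(str).to_numpy()
        df = df.drop(columns=[first])
    else:
        sample_ids = np.array([f"sample{i}" for i in range(len(df))])
    values = df.to_numpy()
    counts = np.where(np.isnan(values.astype(float)), MISSING, values).astype(np.int8)
    ok = (counts >= 0) & (counts <= 2) | (counts == MISSING)
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise FormatError(
            f"{path}: allele count {values[i, j]!r} out of range at sample "
            f"{sample_ids[i]}, variant {df.columns[j]}"
        )
    p = df.shape[1]
    return counts, df.columns.to_numpy(), np.zeros(p, dtype=int), \
        np.arange(1, p + 1), sample_ids


def load_genotypes(path, format: str = "tsv", maf_floor: float = 0.05,
                   missing_policy: str = "mean-impute") -> GenotypeMatrix:
    """Load, filter, and standardize a genotype panel.

    Parameters
    ----------
    path:
        TSV file (samples x variants, header of variant ids) or PLINK
        prefix/.bed path.
    maf_floor:
        Variants with minor allele frequency below this are dropped
        (default 0.05, the usual GWAS filter).
    missing_policy:
        ``mean-impute`` replaces missing calls by the variant mean before
        standardization; ``drop-variant`` removes any variant with a
        missing call.
    """
    path = pathlib.Path(path)
    if format == "plink":
        prefix = path.with_suffix("") if path.suffix in (".bed", ".bim", ".fam") else path
        counts, vids, chrom, pos, sids = _load_plink(prefix)
    elif format == "tsv":
        counts, vids, chrom, pos, sids = _load_tsv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return _filter_and_build(counts, vids, chrom, pos, sids, maf_floor, missing_policy)


def load_phenotype(path, sample_ids=None) -> Phenotype:
    """Read a phenotype from a 1-column file or FID/IID/value TSV.

    When ``sample_ids`` is given, rows are aligned to that order.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FormatError(f"phenotype file not found: {path}")
    df = pd.read_csv(path, sep=r"\s+", header=None)
    if df.shape[1] == 1:
        y = df.iloc[:, 0].to_numpy(dtype=float)
        sids = np.asarray(sample_ids) if sample_ids is not None \
            else np.array([f"sample{i}" for i in range(y.size)])
        if y.size != len(sids):
            raise FormatError(f"{path}: {y.size} phenotypes for {len(sids)} samples")
        return Phenotype(y=y, sample_ids=sids)
    if df.shape[1] >= 3:
        iid = df.iloc[:, 1].astype(str).to_numpy()
        y = df.iloc[:, 2].to_numpy(dtype=float)
        if sample_ids is not None:
            lut = dict(zip(iid, y))
            missing = [s for s in sample_ids if s not in lut]
            if missing:
                raise FormatError(f"{path}: no phenotype for sample(s) {missing[:5]}")
            y = np.array([lut[s] for s in sample_ids])
            iid = np.asarray(sample_ids)
        return Phenotype(y=y, sample_ids=iid)
    raise FormatError(f"{path}: expected 1 column or FID/IID/value layout")


def write_results(records, geno: GenotypeMatrix, path, seed=None) -> None:
    """Write per-variant test records as a TSV.

    Columns: id, chr, pos, sigma2_hat, se, p_normal, p_davies, p_hybrid,
    method.  ``seed`` (if given) is recorded in a comment header line.
    """
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("id\tchr\tpos\tsigma2_hat\tse\tp_normal\tp_davies\tp_hybrid\tmethod\n")
        for r in records:
            k = r.k
            davies = "" if r.p_davies is None else f"{r.p_davies:.6g}"
            fh.write(
                f"{geno.variant_ids[k]}\t{geno.chrom[k]}\t{geno.pos[k]}\t"
                f"{r.sigma2_hat:.6g}\t{r.se:.6g}\t{r.p_normal:.6g}\t"
                f"{davies}\t{r.p_final:.6g}\t{r.method}\n"
            )
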
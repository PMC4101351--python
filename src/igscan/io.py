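"""Genotype/phenotype input-output, quality control, and result serialisation.

Supported inputs are the PLINK v1 binary trio (``.bed``/``.bim``/``.fam``,
SNP-major) and a plain TSV genotype dialect (header of SNP ids; one row per
sample: ``sample_id  phenotype  code...`` with codes 0/1/2 or NA).  Genotypes
are held as minor-allele dosage; the minor allele is re-derived from observed
frequencies rather than trusted from file metadata.

Quality control mirrors standard case-control GWAS practice: SNPs are dropped
for call rate below 95%, Hardy-Weinberg disequilibrium in controls at
p < 5.7e-7, and minor allele frequency below 5% — in that order, each SNP
attributed to the first filter that removes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _spstats

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "QCReport",
    "read_plink",
    "write_plink",
    "read_tsv_genotypes",
    "write_tsv_genotypes",
    "hwe_test",
    "qc_filter",
    "write_results",
    "read_results",
    "write_edges",
]

logger = logging.getLogger(__name__)

#: genotype code marking a missing call
MISSING = -1

_BED_MAGIC = b"\x6c\x1b"
_SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "allele1", "allele2"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix with a binary phenotype.

    Attributes
    ----------
    genotypes : ndarray of int8, shape (n_samples, n_snps)
        Codes 0/1/2 (minor-allele dosage) with :data:`MISSING` for no-calls.
    phenotype : ndarray of int8, shape (n_samples,)
        1 = case, 0 = control.
    snp_meta : DataFrame
        One row per SNP: snp_id, chrom, pos (1-based), allele1, allele2.
    sample_ids : list of str
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_meta: pd.DataFrame = None
    sample_ids: list = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D samples x SNPs matrix")
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        valid = np.isin(self.genotypes, [0, 1, 2, MISSING])
        if not valid.all():
            bad = np.unique(self.genotypes[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        if not np.isin(self.phenotype, [0, 1]).all():
            raise ValueError("phenotype must be binary (1=case, 0=control)")
        if self.phenotype.shape[0] != self.genotypes.shape[0]:
            raise ValueError("phenotype length does not match sample count")
        if self.snp_meta is None:
            self.snp_meta = default_snp_meta(self.genotypes.shape[1])
        if len(self.snp_meta) != self.genotypes.shape[1]:
            raise ValueError("snp_meta length does not match SNP count")
        if self.sample_ids is None:
            self.sample_ids = [f"S{i + 1}" for i in range(self.genotypes.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing genotype calls."""
        return (self.genotypes != MISSING).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls, in [0, 0.5].

        The allele frequency is folded (``min(f, 1-f)``), so orientation of
        the stored dosage never pushes the value above one half.
        """
        called = self.genotypes != MISSING
        dosage = np.where(called, self.genotypes, 0).sum(axis=0, dtype=float)
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = dosage / (2.0 * n_called)
        f = np.where(n_called > 0, f, np.nan)
        return np.minimum(f, 1.0 - f)

    def take_snps(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the given SNP columns."""
        index = np.asarray(index)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, index],
            phenotype=self.phenotype.copy(),
            snp_meta=self.snp_meta.iloc[index].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )


def default_snp_meta(n_snps: int, prefix: str = "snp") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [f"{prefix}{i + 1}" for i in range(n_snps)],
            "chrom": ["1"] * n_snps,
            "pos": np.arange(1, n_snps + 1, dtype=np.int64),
            "allele1": ["A"] * n_snps,
            "allele2": ["B"] * n_snps,
        }
    )


@dataclass
class QCReport:
    """Tally of SNPs removed by each quality-control filter, in filter order."""

    n_snps_in: int
    n_snps_out: int
    removed_by_call_rate: int
    removed_by_hwe: int
    removed_by_maf: int
    call_rate_min: float
    hwe_alpha: float
    maf_min: float

    def __post_init__(self) -> None:
        removed = self.removed_by_call_rate + self.removed_by_hwe + self.removed_by_maf
        if self.n_snps_out != self.n_snps_in - removed:
            raise ValueError("QC report counts are inconsistent")


# ---------------------------------------------------------------------------
# PLINK v1 binary trio


def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK v1 binary trio into a :class:`GenotypeMatrix`.

    ``bed_path`` may be a prefix (``data`` for ``data.bed/.bim/.fam``) or the
    ``.bed`` path with the companions given explicitly.  Only the SNP-major
    layout (mode byte 0x01) is supported.  Two-bit codes are decoded as
    00 = homozygous allele1, 01 = missing, 10 = heterozygous,
    11 = homozygous allele2, then re-oriented to minor-allele dosage using
    the observed allele frequencies (metadata alleles are swapped to match).
    Phenotype comes from ``.fam`` column 6 (2 = case, 1 = control); samples
    with any other phenotype code are dropped with a logged count.
    """
    bed_path = str(bed_path)
    if bim_path is None or fam_path is None:
        prefix = bed_path[:-4] if bed_path.endswith(".bed") else bed_path
        bed_path = prefix + ".bed"
        bim_path = prefix + ".bim"
        fam_path = prefix + ".fam"
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "snp_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n_samples, n_snps = len(fam), len(bim)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise ValueError(f"{bed_path}: not a PLINK v1 .bed file (bad magic bytes)")
    if raw[2] == 0x00:
        raise ValueError(f"{bed_path}: individual-major .bed files are not supported")
    if raw[2] != 0x01:
        raise ValueError(f"{bed_path}: unknown .bed mode byte {raw[2]:#04x}")
    bytes_per_snp = (n_samples + 3) // 4
    payload = raw[3:]
    if payload.size != bytes_per_snp * n_snps:
        raise ValueError(
            f"{bed_path}: payload of {payload.size} bytes does not match "
            f"{n_snps} SNPs x {n_samples} samples from .bim/.fam"
        )
    blocks = payload.reshape(n_snps, bytes_per_snp)
    # unpack the four 2-bit fields of every byte, little end first
    codes = np.stack(
        [(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(n_snps, -1)[:, :n_samples]
    # 2-bit code -> dosage of allele1 (00->2, 10->1, 11->0, 01->missing)
    lut = np.array([2, MISSING, 1, 0], dtype=np.int8)
    geno = lut[codes].T.copy()  # samples x SNPs

    pheno_raw = fam["pheno"].to_numpy()
    keep = np.isin(pheno_raw, [1, 2])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d samples with missing phenotype", n_dropped)
    geno = geno[keep]
    phenotype = (pheno_raw[keep] == 2).astype(np.int8)
    sample_ids = fam.loc[keep, "iid"].tolist()

    meta = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(np.int64),
            "allele1": bim["allele1"],
            "allele2": bim["allele2"],
        }
    )
    _orient_to_minor(geno, meta)
    return GenotypeMatrix(geno, phenotype, meta, sample_ids)


def _orient_to_minor(geno: np.ndarray, meta: pd.DataFrame) -> None:
    """Flip dosage columns in place so the counted allele is the minor one."""
    called = geno != MISSING
    n_called = called.sum(axis=0)
    dosage = np.where(called, geno, 0).sum(axis=0, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = dosage / (2.0 * n_called)
    flip = np.where(np.nan_to_num(freq) > 0.5)[0]
    for j in flip:
        col = geno[:, j]
        col[col != MISSING] = 2 - col[col != MISSING]
        a1 = meta.at[j, "allele1"]
        meta.at[j, "allele1"] = meta.at[j, "allele2"]
        meta.at[j, "allele2"] = a1


def write_plink(g: GenotypeMatrix, prefix) -> None:
    """Write a :class:`GenotypeMatrix` as a PLINK v1 SNP-major trio."""
    prefix = str(prefix)
    n = g.n_samples
    # dosage of allele1 -> 2-bit code (2->00, 1->10, 0->11, missing->01)
    code_of = np.zeros(4, dtype=np.uint8)
    code_of[[2, 1, 0]] = [0b00, 0b10, 0b11]
    codes = np.where(g.genotypes == MISSING, 0b01, code_of[g.genotypes.clip(0)]).astype(
        np.uint8
    )
    pad = (-n) % 4
    if pad:
        codes = np.vstack([codes, np.zeros((pad, g.n_snps), dtype=np.uint8)])
    codes = codes.T.reshape(g.n_snps, -1, 4)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        packed.tofile(fh)
    meta = g.snp_meta
    with open(prefix + ".bim", "w") as fh:
        for _, row in meta.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['snp_id']}\t0\t{row['pos']}"
                f"\t{row['allele1']}\t{row['allele2']}\n"
            )
    with open(prefix + ".fam", "w") as fh:
        for sid, y in zip(g.sample_ids, g.phenotype):
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t{2 if y == 1 else 1}\n")


# ---------------------------------------------------------------------------
# TSV genotype dialect


def read_tsv_genotypes(path) -> GenotypeMatrix:
    """Read the TSV genotype dialect.

    Header: ``sample_id<TAB>phenotype<TAB><snp ids...>``; one row per sample
    with genotype codes 0/1/2 or NA.  Any other token is a parse error naming
    the offending row and column.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "sample_id" or header[1] != "phenotype":
            raise ValueError(
                f"{path}: expected header 'sample_id\\tphenotype\\t<snp ids>'"
            )
        snp_ids = header[2:]
        sample_ids, phenos, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            sample_ids.append(parts[0])
            if parts[1] not in ("0", "1"):
                raise ValueError(
                    f"{path}:{lineno}: phenotype must be 0 or 1, got {parts[1]!r}"
                )
            phenos.append(int(parts[1]))
            row = np.empty(len(snp_ids), dtype=np.int8)
            for j, tok in enumerate(parts[2:]):
                if tok == "NA":
                    row[j] = MISSING
                elif tok in ("0", "1", "2"):
                    row[j] = int(tok)
                else:
                    raise ValueError(
                        f"{path}:{lineno}: column {snp_ids[j]!r}: "
                        f"invalid genotype code {tok!r}"
                    )
            rows.append(row)
    geno = np.vstack(rows) if rows else np.empty((0, len(snp_ids)), dtype=np.int8)
    meta = default_snp_meta(len(snp_ids))
    meta["snp_id"] = snp_ids
    return GenotypeMatrix(geno, np.asarray(phenos, dtype=np.int8), meta, sample_ids)


def write_tsv_genotypes(g: GenotypeMatrix, path) -> None:
    """Write the TSV genotype dialect (inverse of :func:`read_tsv_genotypes`)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tphenotype\t" + "\t".join(g.snp_meta["snp_id"]) + "\n")
        for i, sid in enumerate(g.sample_ids):
            codes = [
                "NA" if c == MISSING else str(int(c)) for c in g.genotypes[i]
            ]
            fh.write(f"{sid}\t{int(g.phenotype[i])}\t" + "\t".join(codes) + "\n")


# ---------------------------------------------------------------------------
# Quality control


def hwe_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value against Hardy-Weinberg.

    Observed genotype counts are compared with the ``p^2, 2pq, q^2``
    expectations at the observed allele frequency.  A monomorphic SNP (one
    allele absent) is in trivial equilibrium and returns 1.
    """
    counts = np.array([n_hom1, n_het, n_hom2], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be nonnegative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("no genotype calls")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return 1.0
    q = 1.0 - p
    expected = n * np.array([p * p, 2 * p * q, q * q])
    stat = ((counts - expected) ** 2 / expected).sum()
    return float(_spstats.chi2.sf(stat, df=1))


def qc_filter(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    hwe_alpha: float = 5.7e-7,
    maf_min: float = 0.05,
):
    """Apply the standard SNP quality-control filters in order.

    A SNP is removed by the first failing filter: call rate below
    ``call_rate_min``, HWE p-value below ``hwe_alpha`` (computed in controls
    only), then MAF below ``maf_min``.  Returns the filtered matrix and a
    :class:`QCReport`.  The operation is idempotent.
    """
    for name, thr in (
        ("call_rate_min", call_rate_min),
        ("hwe_alpha", hwe_alpha),
        ("maf_min", maf_min),
    ):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {thr}")

    fail_cr = g.call_rate() < call_rate_min

    controls = g.genotypes[g.phenotype == 0]
    hwe_p = np.ones(g.n_snps)
    for j in range(g.n_snps):
        col = controls[:, j]
        col = col[col != MISSING]
        if col.size:
            hwe_p[j] = hwe_test(
                int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())
            )
    fail_hwe = (hwe_p < hwe_alpha) & ~fail_cr

    maf = g.maf()
    fail_maf = (np.nan_to_num(maf) < maf_min) & ~fail_cr & ~fail_hwe

    keep = ~(fail_cr | fail_hwe | fail_maf)
    report = QCReport(
        n_snps_in=g.n_snps,
        n_snps_out=int(keep.sum()),
        removed_by_call_rate=int(fail_cr.sum()),
        removed_by_hwe=int(fail_hwe.sum()),
        removed_by_maf=int(fail_maf.sum()),
        call_rate_min=call_rate_min,
        hwe_alpha=hwe_alpha,
        maf_min=maf_min,
    )
    if report.n_snps_out < report.n_snps_in:
        logger.info(
            "QC removed %d/%d SNPs (call rate %d, HWE %d, MAF %d)",
            report.n_snps_in - report.n_snps_out,
            report.n_snps_in,
            report.removed_by_call_rate,
            report.removed_by_hwe,
            report.removed_by_maf,
        )
    return g.take_snps(np.where(keep)[0]), report


# ---------------------------------------------------------------------------
# Result serialisation

_RESULT_COLUMNS = [
    "rank",
    "snp_ids",
    "order",
    "ig_bits",
    "levels_x",
    "n_complete",
    "p_raw",
    "p_bonferroni",
]


def write_results(results, path, snp_ids=None) -> None:
    """Write ranked interaction results as TSV.

    ``snp_ids`` maps column indices to identifiers; indices are used when it
    is omitted.  Columns: rank, snp_ids (semicolon-joined), order, ig_bits,
    levels_x, n_complete, p_raw, p_bonferroni.
    """
    def label(idx):
        return ";".join(snp_ids[i] if snp_ids is not None else str(i) for i in idx)

    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(results) + 1),
            "snp_ids": [label(r.snp_indices) for r in results],
            "order": [r.order_k for r in results],
            "ig_bits": [r.ig_bits for r in results],
            "levels_x": [r.levels_x for r in results],
            "n_complete": [r.n_complete for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_bonferroni": [r.p_adjusted for r in results],
        },
        columns=_RESULT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame."""
    return pd.read_csv(path, sep="\t")


def write_edges(results, path, snp_ids=None) -> None:
    """Write pairwise results as a network edge list (snp_a, snp_b, p_bonferroni)."""
    with open(path, "w") as fh:
        fh.write("snp_a\tsnp_b\tp_bonferroni\n")
        for r in results:
            if r.order_k != 2:
                continue
            a, b = r.snp_indices
            if snp_ids is not None:
                a, b = snp_ids[a], snp_ids[b]
            fh.write(f"{a}\t{b}\t{r.p_adjusted:.6g}\n")
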
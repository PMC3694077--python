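"""Genotype, map, pedigree and phenotype file handling plus SNP quality control.

The on-disk dialect is text PLINK PED/MAP (whitespace-delimited, missing
allele ``0``).  Genotypes are held in memory as an individuals x SNPs matrix
of minor-allele counts {0, 1, 2} with ``-1`` marking missing calls, and can
be converted to the centred -10/0/10 covariate coding used by the
whole-genome regression model.

Quality control mirrors a standard SNP-chip pipeline: per-SNP call rate,
a per-SNP quality score in [0, 1] (a generic stand-in for an array GC
score, which needs raw intensities to compute), and a Hardy-Weinberg
equilibrium test.  All three thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1

__all__ = [
    "MISSING",
    "MarkerMap",
    "GenotypeMatrix",
    "SnpQuality",
    "QcReport",
    "PedMapFormatError",
    "read_ped_map",
    "write_ped_map",
    "hwe_test",
    "qc_filter",
    "allele_frequency",
    "encode_centered",
    "read_pedigree",
    "write_pedigree",
]


class PedMapFormatError(ValueError):
    """Raised when a PED/MAP pair is internally inconsistent."""


def _chrom_sort_key(label: str):
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


@dataclass
class MarkerMap:
    """Physical SNP map: one row per marker, sorted by (chrom, pos_bp).

    ``chrom`` labels are strings ("1".."18", "X", "Y", "U" for unassigned);
    positions are 1-based base pairs.  ``allele_a``/``allele_b`` fix the
    counted allele: genotype codes count copies of ``allele_b``.
    """

    table: pd.DataFrame  # columns: snp_id, chrom, pos_bp, allele_a, allele_b

    def __post_init__(self) -> None:
        t = self.table
        required = {"snp_id", "chrom", "pos_bp", "allele_a", "allele_b"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        if t["snp_id"].duplicated().any():
            dup = t.loc[t["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r}")
        if (t["pos_bp"] < 1).any():
            raise ValueError("pos_bp must be >= 1")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy()

    def sort_order(self) -> np.ndarray:
        keys = [_chrom_sort_key(c) for c in self.table["chrom"].astype(str)]
        return np.lexsort(
            (
                self.table["pos_bp"].to_numpy(),
                np.array([k[2] for k in keys]),
                np.array([k[1] for k in keys]),
                np.array([k[0] for k in keys]),
            )
        )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosage codes; -1 = missing."""

    codes: np.ndarray  # int8, shape (n_individuals, n_snps)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x SNPs)")
        if not self.sample_ids:
            self.sample_ids = [f"ind{i+1}" for i in range(self.codes.shape[0])]
        if len(self.sample_ids) != self.codes.shape[0]:
            raise ValueError("sample_ids length does not match codes rows")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def missing_fraction(self) -> np.ndarray:
        return (self.codes == MISSING).mean(axis=0)

    def subset(self, rows: np.ndarray | None = None, cols: np.ndarray | None = None) -> "GenotypeMatrix":
        codes = self.codes
        ids = self.sample_ids
        if rows is not None:
            codes = codes[rows]
            ids = [s for s, keep in zip(self.sample_ids, np.asarray(rows)) if keep] if np.asarray(rows).dtype == bool else [self.sample_ids[i] for i in rows]
        if cols is not None:
            codes = codes[:, cols]
        return GenotypeMatrix(codes.copy(), list(ids))


@dataclass
class SnpQuality:
    """Per-SNP QC inputs, every field a fraction/probability in [0, 1]."""

    call_rate: np.ndarray
    quality_score: np.ndarray
    hwe_p: np.ndarray

    def __post_init__(self) -> None:
        for name in ("call_rate", "quality_score", "hwe_p"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} outside [0, 1]")


@dataclass
class QcReport:
    n_input: int
    n_kept: int
    n_fail_call_rate: int
    n_fail_quality: int
    n_fail_hwe: int
    kept_mask: np.ndarray


# ---------------------------------------------------------------------------
# PED / MAP

def read_ped_map(ped_source, map_source) -> tuple[GenotypeMatrix, MarkerMap, list[str]]:
    """Read a text PLINK PED/MAP pair.

    Codes count the dataset minor allele (ties broken lexicographically, the
    later-sorting allele becomes allele_b); "0 0" is missing.  Markers are
    returned sorted by (chromosome, position); genotype columns are permuted
    to match.
    """
    map_rows = []
    for ln, line in enumerate(_iter_lines(map_source), start=1):
        parts = line.split()
        if len(parts) < 4:
            raise PedMapFormatError(f"MAP line {ln}: expected 4 fields, got {len(parts)}")
        chrom, snp_id, _cm, pos = parts[:4]
        map_rows.append((snp_id, chrom, int(pos)))
    n_snps = len(map_rows)

    sample_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    for ln, line in enumerate(_iter_lines(ped_source), start=1):
        parts = line.split()
        if len(parts) != 6 + 2 * n_snps:
            raise PedMapFormatError(
                f"PED line {ln}: expected {6 + 2 * n_snps} fields for {n_snps} MAP rows, got {len(parts)}"
            )
        sample_ids.append(parts[1])
        allele_rows.append(np.array(parts[6:], dtype="U8"))
    if not allele_rows:
        raise PedMapFormatError("empty PED file")

    alleles = np.stack(allele_rows)  # (n, 2k)
    a1 = alleles[:, 0::2]
    a2 = alleles[:, 1::2]
    n = len(sample_ids)

    codes = np.full((n, n_snps), MISSING, dtype=np.int8)
    allele_a = np.empty(n_snps, dtype="U8")
    allele_b = np.empty(n_snps, dtype="U8")
    for j in range(n_snps):
        col = np.concatenate([a1[:, j], a2[:, j]])
        obs = col[col != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if uniq.size == 0:
            allele_a[j], allele_b[j] = "0", "0"
            continue
        if uniq.size == 1:
            allele_a[j] = allele_b[j] = uniq[0]
            # monomorphic: count copies of the single observed allele
        elif uniq.size == 2:
            # minor allele becomes allele_b; lexicographic tie-break
            order = np.argsort(counts, kind="stable")
            if counts[order[0]] == counts[order[1]]:
                minor = max(uniq)
            else:
                minor = uniq[order[0]]
            major = uniq[uniq != minor][0]
            allele_a[j], allele_b[j] = major, minor
        else:
            raise PedMapFormatError(f"SNP {map_rows[j][0]}: more than two alleles {list(uniq)}")
        miss = (a1[:, j] == "0") | (a2[:, j] == "0")
        cnt = (a1[:, j] == allele_b[j]).astype(np.int8) + (a2[:, j] == allele_b[j]).astype(np.int8)
        if uniq.size == 1:
            cnt = np.where(miss, MISSING, 2).astype(np.int8)
        codes[:, j] = np.where(miss, MISSING, cnt)

    table = pd.DataFrame(
        {
            "snp_id": [r[0] for r in map_rows],
            "chrom": [r[1] for r in map_rows],
            "pos_bp": [r[2] for r in map_rows],
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    mm = MarkerMap(table)
    order = mm.sort_order()
    mm = MarkerMap(table.iloc[order].reset_index(drop=True))
    codes = codes[:, order]
    return GenotypeMatrix(codes, sample_ids), mm, sample_ids


def write_ped_map(path_prefix, genotypes: GenotypeMatrix, marker_map: MarkerMap,
                  pedigree: pd.DataFrame | None = None) -> tuple[Path, Path]:
    """Write a PED/MAP pair that round-trips through :func:`read_ped_map`.

    Family/parent/sex/phenotype columns come from ``pedigree`` when given
    (by ``animal_id``), otherwise placeholders are written.
    """
    prefix = Path(path_prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")

    t = marker_map.table
    with open(map_path, "w") as fh:
        for row in t.itertuples(index=False):
            fh.write(f"{row.chrom} {row.snp_id} 0 {row.pos_bp}\n")

    ped_meta = {}
    if pedigree is not None:
        for row in pedigree.itertuples(index=False):
            sex_code = 1 if getattr(row, "sex", "M") == "M" else 2
            ped_meta[str(row.animal_id)] = (
                str(getattr(row, "line", "FAM")),
                str(getattr(row, "sire_id", 0) or 0),
                str(getattr(row, "dam_id", 0) or 0),
                sex_code,
            )

    aa = t["allele_a"].to_numpy()
    ab = t["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(genotypes.sample_ids):
            fam, sire, dam, sex = ped_meta.get(str(sid), ("FAM", "0", "0", 1))
            fields = [fam, str(sid), sire, dam, str(sex), "-9"]
            row = genotypes.codes[i]
            for j, c in enumerate(row):
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [aa[j], aa[j]]
                elif c == 1:
                    fields += [aa[j], ab[j]]
                else:
                    fields += [ab[j], ab[j]]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def _iter_lines(source):
    if hasattr(source, "read"):
        for line in source:
            if line.strip():
                yield line
    else:
        with open(source) as fh:
            for line in fh:
                if line.strip():
                    yield line


# ---------------------------------------------------------------------------
# QC primitives

def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy-Weinberg goodness-of-fit P (1-df chi-square).

    Expected genotype counts derive from the observed allele frequency.
    A monomorphic SNP fits HWE perfectly and returns P = 1.
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative genotype count")
    n = counts.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_aa + n_ab) / (2 * n)  # frequency of allele A
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test_matrix(codes: np.ndarray, subset: np.ndarray | None = None) -> np.ndarray:
    """Vector of HWE P values, one per SNP column of ``codes``."""
    c = codes if subset is None else codes[subset]
    out = np.empty(c.shape[1])
    for j in range(c.shape[1]):
        col = c[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            out[j] = 1.0
            continue
        out[j] = hwe_test(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
    return out


def qc_filter(
    genotypes: GenotypeMatrix,
    quality: SnpQuality,
    call_rate_min: float = 0.80,
    quality_min: float = 0.40,
    hwe_alpha: float = 1e-4,
) -> tuple[GenotypeMatrix, QcReport]:
    """Keep SNPs passing all three strict thresholds.

    A SNP is kept iff call_rate > call_rate_min AND quality_score >
    quality_min AND hwe_p > hwe_alpha; the report counts failures per
    criterion (a SNP may fail several).
    """
    for name, v in (("call_rate_min", call_rate_min), ("quality_min", quality_min), ("hwe_alpha", hwe_alpha)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if len(quality.call_rate) != genotypes.n_snps:
        raise ValueError("quality arrays not aligned to SNPs")
    pass_cr = quality.call_rate > call_rate_min
    pass_q = quality.quality_score > quality_min
    pass_hwe = quality.hwe_p > hwe_alpha
    kept = pass_cr & pass_q & pass_hwe
    report = QcReport(
        n_input=genotypes.n_snps,
        n_kept=int(kept.sum()),
        n_fail_call_rate=int((~pass_cr).sum()),
        n_fail_quality=int((~pass_q).sum()),
        n_fail_hwe=int((~pass_hwe).sum()),
        kept_mask=kept,
    )
    return genotypes.subset(cols=np.where(kept)[0]), report


def allele_frequency(codes: np.ndarray, subset: np.ndarray | None = None) -> np.ndarray:
    """allele_b frequency per SNP among non-missing genotypes.

    Columns with no non-missing genotype in the subset return NaN (an
    undefined-frequency flag, not a number to compute with).
    """
    c = np.asarray(codes)
    if c.ndim == 1:
        c = c[:, None]
        squeeze = True
    else:
        squeeze = False
    if subset is not None:
        c = c[subset]
    if c.shape[0] == 0:
        raise ValueError("empty subset")
    mask = c != MISSING
    n_obs = mask.sum(axis=0)
    sums = np.where(mask, c, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, sums / (2.0 * np.maximum(n_obs, 1)), np.nan)
    return float(freq[0]) if squeeze else freq


def encode_centered(genotypes: GenotypeMatrix | np.ndarray, scale: float = 10.0) -> np.ndarray:
    """Centred covariate coding: 0 -> -scale, 1 -> 0, 2 -> +scale.

    Missing genotypes are imputed with the SNP's mean coded value, which
    preserves each column's allele-frequency expectation.  An all-missing
    column encodes to zeros.
    """
    codes = genotypes.codes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    one_d = codes.ndim == 1
    if one_d:
        codes = codes[:, None]
    x = np.where(codes == MISSING, np.nan, (codes.astype(float) - 1.0) * scale)
    col_means = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    x = np.where(np.isnan(x), col_means[None, :], x)
    return x[:, 0] if one_d else x


# ---------------------------------------------------------------------------
# Pedigree / tables

PEDIGREE_COLUMNS = [
    "animal_id", "sire_id", "dam_id", "generation", "line",
    "sex", "parity", "pen", "group", "age_on_test",
]


def read_pedigree(path) -> pd.DataFrame:
    """Read a headered TSV pedigree and validate its ordering contract."""
    ped = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "sire_id": str, "dam_id": str})
    missing = set(PEDIGREE_COLUMNS) - set(ped.columns)
    if missing:
        raise ValueError(f"pedigree missing columns: {sorted(missing)}")
    validate_pedigree(ped)
    return ped


def write_pedigree(path, pedigree: pd.DataFrame) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def validate_pedigree(ped: pd.DataFrame) -> None:
    """Parents must precede offspring; sires male and dams female where known."""
    seen: set[str] = set()
    sex = dict(zip(ped["animal_id"].astype(str), ped["sex"]))
    for row in ped.itertuples(index=False):
        for parent, want in ((str(row.sire_id), "M"), (str(row.dam_id), "F")):
            if parent in ("0", "nan", "None", ""):
                continue
            if parent not in seen:
                raise ValueError(f"parent {parent} listed after (or missing before) offspring {row.animal_id}")
            if sex.get(parent) not in (want, None):
                raise ValueError(f"parent {parent} of {row.animal_id} has sex {sex.get(parent)}, expected {want}")
        seen.add(str(row.animal_id))
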
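"""Single-SNP association on pre-adjusted phenotypes, with genomic control.

Mirrors the two-step frequentist design: phenotypes are first residualised
on the fixed factors (sex, pen-by-group) and an age-at-on-test covariate
with a separate slope per line-by-parity cell, then each SNP is tested by
simple regression of the adjusted phenotype on allele count (the
quantitative-trait equivalent of a basic PLINK association).  Population
structure inflates the resulting 1-df chi-squares; genomic control divides
them by lambda = median(chi2)/0.4549364 when lambda exceeds 1.
Benjamini-Hochberg FDR is applied to the corrected P values.

Stratification diagnostics: an identity-by-state similarity matrix,
classical multidimensional scaling of 1-IBS, and Q-Q points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import GenotypeMatrix, MISSING
from .pheno import build_design
from .divscan import bh_fdr

__all__ = [
    "adjust_phenotype",
    "single_snp_assoc",
    "genomic_control",
    "ibs_mds",
    "qq_points",
    "MdsResult",
    "CHI2_MEDIAN_1DF",
    "association_pipeline",
]

# median of the 1-df chi-square distribution
CHI2_MEDIAN_1DF = 0.4549364


def adjust_phenotype(y, sex, pen_by_group, age_on_test, line, parity) -> np.ndarray:
    """OLS residuals of y on sex + pen-by-group + age with line x parity slopes.

    Line-by-parity cells with fewer than 2 animals are merged into the
    nearest parity within the line (with a warning) so every slope is
    estimable.  Residuals have mean zero by construction.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(y, dtype=float),
            "sex": [str(v) for v in sex],
            "pen_group": [str(v) for v in pen_by_group],
            "age": np.asarray(age_on_test, dtype=float),
            "line": [str(v) for v in line],
            "parity": [int(v) for v in parity],
        }
    )
    # merge undersized line x parity cells into the nearest parity
    for ln in df["line"].unique():
        sub = df[df["line"] == ln]
        counts = sub["parity"].value_counts()
        small = [p for p, c in counts.items() if c < 2]
        for p in small:
            others = sorted(c for c in counts.index if c not in small)
            if not others:
                continue
            target = min(others, key=lambda c: abs(c - p))
            warnings.warn(f"line {ln} parity {p} has <2 animals; merged into parity {target}")
            df.loc[(df["line"] == ln) & (df["parity"] == p), "parity"] = target
    df["line_parity"] = df["line"] + "x" + df["parity"].astype(str)
    X, _ = build_design(df, factors=["sex", "pen_group"], interactions=[("age", "line_parity")])
    beta, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
    return df["y"].to_numpy() - X @ beta


def single_snp_assoc(adjusted_y, genotypes: GenotypeMatrix | np.ndarray) -> pd.DataFrame:
    """Per-SNP simple regression of the adjusted phenotype on allele count.

    Returns beta, t (n-2 df), p_raw and chi2 (the squared standard-normal
    equivalent of t) per SNP.  Monomorphic SNPs get beta 0, p 1, chi2 0.
    Missing genotypes are dropped pairwise.
    """
    y = np.asarray(adjusted_y, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("adjusted phenotype must be finite")
    codes = genotypes.codes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    k = codes.shape[1]
    beta = np.zeros(k)
    tstat = np.zeros(k)
    p_raw = np.ones(k)
    chi2 = np.zeros(k)
    for j in range(k):
        col = codes[:, j]
        m = col != MISSING
        x = col[m].astype(float)
        yy = y[m]
        n = x.size
        if n < 3 or np.all(x == x[0]):
            continue
        xc = x - x.mean()
        yc = yy - yy.mean()
        sxx = float(xc @ xc)
        b = float(xc @ yc) / sxx
        resid = yc - b * xc
        s2 = float(resid @ resid) / (n - 2)
        if s2 <= 0:
            t = np.inf if b != 0 else 0.0
            p = 0.0 if b != 0 else 1.0
        else:
            se = np.sqrt(s2 / sxx)
            t = b / se
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        beta[j] = b
        tstat[j] = t
        p_raw[j] = p
        # squared standard-normal equivalent of the t statistic
        z = stats.norm.isf(np.clip(p / 2.0, 1e-300, 1.0))
        chi2[j] = z * z if np.isfinite(z) else np.inf
    return pd.DataFrame({"beta": beta, "t": tstat, "p_raw": p_raw, "chi2": chi2})


def genomic_control(chi2_values) -> tuple[float, np.ndarray]:
    """Genomic-control inflation factor and corrected P values.

    lambda = median(chi2) / 0.4549364; chi-squares are divided by lambda
    only when lambda > 1 (no anti-conservative inflation), and corrected
    P values come from the 1-df upper tail.
    """
    chi2 = np.asarray(chi2_values, dtype=float)
    if chi2.size < 10:
        raise ValueError("genomic control needs at least 10 SNPs")
    lam = float(np.median(chi2) / CHI2_MEDIAN_1DF)
    corrected = chi2 / lam if lam > 1.0 else chi2
    p_gc = stats.chi2.sf(corrected, df=1)
    return lam, p_gc


@dataclass
class MdsResult:
    ibs: np.ndarray          # (n, n) similarity, unit diagonal
    coordinates: np.ndarray  # (n, k) principal coordinates, centred
    eigenvalues: np.ndarray


def ibs_mds(genotypes: GenotypeMatrix | np.ndarray, k: int = 2) -> MdsResult:
    """IBS similarity and classical metric scaling of D = 1 - IBS.

    IBS(i, j) is the mean over SNPs non-missing in both individuals of
    (2 - |code_i - code_j|) / 2.  MDS double-centres -D^2/2... classical
    scaling here uses the squared-distance form of Torgerson: B =
    -J (D*D) J / 2, eigendecomposed, top-k coordinates scaled by root
    eigenvalues (non-positive eigenvalues give zero coordinates).
    """
    codes = genotypes.codes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    n = codes.shape[0]
    if n < 3:
        raise ValueError("MDS needs at least 3 individuals")
    obs = codes != MISSING
    if np.any(obs.sum(axis=1) == 0):
        raise ValueError("an individual has all genotypes missing")
    c = codes.astype(float)
    ibs = np.empty((n, n))
    for i in range(n):
        both = obs[i] & obs
        shared = 2.0 - np.abs(c[i] - c)
        shared = np.where(both, shared, 0.0)
        denom = both.sum(axis=1)
        ibs[i] = np.where(denom > 0, shared.sum(axis=1) / (2.0 * denom), 0.0)
    np.fill_diagonal(ibs, 1.0)
    ibs = (ibs + ibs.T) / 2.0

    D = 1.0 - ibs
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    coords = np.zeros((n, k))
    for c_idx, e_idx in enumerate(order):
        if vals[e_idx] > 0:
            coords[:, c_idx] = vecs[:, e_idx] * np.sqrt(vals[e_idx])
    coords -= coords.mean(axis=0)
    return MdsResult(ibs=ibs, coordinates=coords, eigenvalues=vals[order])


def qq_points(p_values) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) -log10 P pairs, sorted for a Q-Q plot."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p must be in (0, 1]")
    obs = np.sort(-np.log10(p))[::-1]  # largest observed first, matching expected
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    return expected, obs


def association_pipeline(y, phenotype_table: pd.DataFrame, genotypes: GenotypeMatrix,
                         gc_threshold: float = 0.01, fdr_threshold: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Adjust -> per-SNP test -> genomic control -> BH FDR, with flags.

    Returns the per-SNP table (beta, t, p_raw, chi2, p_gc, q,
    sig_gc, sig_fdr) and a summary dict with lambda.
    """
    adjusted = adjust_phenotype(
        y,
        phenotype_table["sex"],
        phenotype_table["pen"].astype(str) + "|" + phenotype_table["group"].astype(str),
        phenotype_table["age_on_test"],
        phenotype_table["line"],
        phenotype_table["parity"],
    )
    res = single_snp_assoc(adjusted, genotypes)
    lam, p_gc = genomic_control(res["chi2"].to_numpy())
    res["p_gc"] = p_gc
    res["q"] = bh_fdr(p_gc)
    res["sig_gc"] = res["p_gc"] < gc_threshold
    res["sig_fdr"] = res["q"] < fdr_threshold
    return res, {"lambda": lam, "n_sig_gc": int(res["sig_gc"].sum()), "n_sig_fdr": int(res["sig_fdr"].sum())}
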
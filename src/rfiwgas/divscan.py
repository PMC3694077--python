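"""Drift-controlled between-line allele-frequency divergence scan.

For every SNP the allele_b frequency is computed in each line at a focal
generation and the signed difference (HIGH - LOW) taken.  Because drift
moves rare alleles relatively further, SNPs are stratified into five
founder minor-allele-frequency bins (<0.1, 0.1-0.19, 0.2-0.29, 0.3-0.39,
0.4-0.5, on the generation-0 MAF) and each SNP's difference is Z-scored
against the mean and SD of the differences in its own bin.  Two-sided
normal P values follow, with Benjamini-Hochberg FDR over all scored SNPs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import GenotypeMatrix, MarkerMap, allele_frequency

__all__ = ["bin_by_founder_maf", "divergence_scan", "neg_log10", "bh_fdr", "MAF_BIN_EDGES"]

# half-open on the left edge; 0.5 belongs to the top bin
MAF_BIN_EDGES = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5])


def bin_by_founder_maf(founder_maf) -> np.ndarray:
    """Map founder MAF values to bin indices 0-4."""
    maf = np.asarray(founder_maf, dtype=float)
    if np.any(maf > 0.5) or np.any(maf < 0):
        raise ValueError("founder MAF must lie in [0, 0.5] (pass the minor-allele frequency)")
    idx = np.minimum((maf // 0.1).astype(int), 4)
    return idx


def neg_log10(p) -> np.ndarray | float:
    """-log10 of a P value; report formatting is 2 decimals."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p must be in (0, 1]")
    out = -np.log10(arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q values).

    q(i) = min_{j >= i} m * p(j) / j over ascending-sorted p, capped at 1,
    returned in input order.  NaNs pass through and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qs = np.empty(m)
    qs[order] = q
    out[ok] = qs
    return out


def divergence_scan(
    genotypes: GenotypeMatrix,
    pedigree: pd.DataFrame,
    marker_map: MarkerMap | None = None,
    focal_generation: int = 8,
    founder_generation: int = 0,
    min_bin_size: int = 2,
) -> pd.DataFrame:
    """Between-line allele-frequency difference scan at a focal generation.

    Returns a DataFrame with one row per SNP: freq_low, freq_high, diff
    (high - low), founder_maf, bin_index, bin_mean, bin_sd, z, p,
    neg_log10_p and q.  SNPs in bins with < ``min_bin_size`` members or
    zero bin SD, or with an undefined frequency, are flagged (scored=False,
    NaN statistics) and excluded from the BH multiplicity count.
    """
    gen = pedigree["generation"].to_numpy()
    line = pedigree["line"].astype(str).to_numpy()
    low = (gen == focal_generation) & (line == "LOW")
    high = (gen == focal_generation) & (line == "HIGH")
    founder = gen == founder_generation
    if low.sum() == 0 or high.sum() == 0:
        raise ValueError("both lines must be present at the focal generation")
    if founder.sum() == 0:
        raise ValueError("no animals at the founder generation")

    codes = genotypes.codes
    freq_low = allele_frequency(codes, low)
    freq_high = allele_frequency(codes, high)
    diff = freq_high - freq_low
    f0 = allele_frequency(codes, founder)
    founder_maf = np.minimum(f0, 1.0 - f0)

    scored = ~(np.isnan(freq_low) | np.isnan(freq_high) | np.isnan(founder_maf))
    bin_index = np.full(codes.shape[1], -1)
    bin_index[scored] = bin_by_founder_maf(founder_maf[scored])

    bin_mean = np.full(codes.shape[1], np.nan)
    bin_sd = np.full(codes.shape[1], np.nan)
    z = np.full(codes.shape[1], np.nan)
    for b in range(5):
        members = scored & (bin_index == b)
        if members.sum() < min_bin_size:
            scored = scored & ~members
            continue
        mu = diff[members].mean()
        sd = diff[members].std()  # population SD: within-bin z has mean 0, SD 1
        bin_mean[members] = mu
        bin_sd[members] = sd
        if sd == 0:
            scored = scored & ~members
            continue
        z[members] = (diff[members] - mu) / sd

    p = np.full(codes.shape[1], np.nan)
    p[scored] = 2.0 * stats.norm.sf(np.abs(z[scored]))
    q = bh_fdr(np.where(scored, p, np.nan))
    with np.errstate(divide="ignore"):
        nlp = np.where(scored & (p > 0), -np.log10(np.maximum(p, 1e-300)), np.nan)

    out = pd.DataFrame(
        {
            "freq_low": freq_low,
            "freq_high": freq_high,
            "diff": diff,
            "founder_maf": founder_maf,
            "bin_index": bin_index,
            "bin_mean": bin_mean,
            "bin_sd": bin_sd,
            "z": z,
            "p": p,
            "neg_log10_p": nlp,
            "q": q,
            "scored": scored,
        }
    )
    if marker_map is not None:
        out.insert(0, "snp_id", marker_map.snp_ids)
        out.insert(1, "chrom", marker_map.chrom)
        out.insert(2, "pos_bp", marker_map.pos_bp)
    return out
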
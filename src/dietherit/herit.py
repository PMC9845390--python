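"""SNP heritability: LD-score regression plus a Haseman-Elston cross-check.

Under a polygenic model the expected GWAS chi-square of SNP j is
1 + N*h2*l_j/M, where l_j is SNP j's LD score (the sum of its squared
correlations with nearby SNPs). Regressing observed chi-squares on in-sample
LD scores therefore yields h2 = slope*M/N; the intercept is left free so it
can absorb miscalibration. Haseman-Elston regression — regressing phenotype
cross-products on genomic relatedness over individual pairs — serves as an
individual-level estimator of the same quantity for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GenotypeMatrix


@dataclass
class H2Estimate:
    phenotype: str
    h2: float
    se: float
    intercept: float
    n: int
    m: int
    p: float  # one-sided Wald p for h2 > 0

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")


def compute_ld_scores(g: GenotypeMatrix, window_bp: int = 500_000) -> pd.DataFrame:
    """In-sample LD scores: l_j = sum over SNPs within window_bp of adjusted r^2.

    The small-sample adjustment r2_adj = r2 - (1 - r2)/(N - 2) makes the null
    contribution mean-zero; the self term survives as exactly 1. Scores are
    floored at 0.05 to keep downstream weights finite.
    """
    if g.n_individuals < 3:
        raise ValueError("need at least 3 individuals for adjusted r^2")
    z = g.standardized()  # raises on zero-variance SNPs
    z = z / z.std(axis=0)  # true sample correlations, not HWE-scaled covariances
    n, m = z.shape
    bp = g.snps["bp"].to_numpy()
    chrom = g.snps["chr"].to_numpy()

    l = np.empty(m)
    chunk = 512
    for chrom_label in pd.unique(chrom):
        idx = np.flatnonzero(chrom == chrom_label)
        cbp = bp[idx]
        for start in range(0, idx.size, chunk):
            end = min(start + chunk, idx.size)
            lo = int(np.searchsorted(cbp, cbp[start] - window_bp, side="left"))
            hi = int(np.searchsorted(cbp, cbp[end - 1] + window_bp, side="right"))
            block = z[:, idx[start:end]].T @ z[:, idx[lo:hi]] / n
            r2 = block**2
            r2_adj = r2 - (1.0 - r2) / (n - 2)
            in_window = np.abs(cbp[lo:hi][None, :] - cbp[start:end][:, None]) <= window_bp
            l[idx[start:end]] = np.where(in_window, r2_adj, 0.0).sum(axis=1)
    l = np.maximum(l, 0.05)
    return pd.DataFrame({"SNP": g.snps["id"], "L2": l, "WINDOW_BP": window_bp})


def ldsc_h2(
    ss: pd.DataFrame,
    ld: pd.DataFrame,
    m: int | None = None,
    phenotype: str = "trait",
    n_jackknife_blocks: int = 50,
) -> H2Estimate:
    """Heritability from summary statistics by weighted LD-score regression.

    Fits chisq_j = intercept + slope*l_j by weighted least squares with
    weights 1/max(l_j, 1) in a single pass; h2 = slope*M/N. Chi-squares of
    SNPs in LD are strongly correlated, so the slope variance comes from a
    delete-one-block jackknife over contiguous SNP blocks rather than a
    pointwise sandwich; the p-value is the one-sided Wald test of h2 > 0.
    """
    merged = ss.merge(ld[["SNP", "L2"]], on="SNP", how="inner")
    if len(merged) < 10:
        raise ValueError("need at least 10 SNPs for LD-score regression")
    if len(merged) < len(ss):
        raise ValueError("LD scores missing for some summary-statistic SNPs")
    m = m if m is not None else len(merged)
    n = int(merged["N"].iloc[0])

    l = merged["L2"].to_numpy(dtype=float)
    chisq = merged["CHISQ"].to_numpy(dtype=float)
    w = 1.0 / np.maximum(l, 1.0)

    x = np.column_stack([np.ones_like(l), l])
    xw = w[:, None] * x
    xtwx = x.T @ xw
    xtwy = xw.T @ chisq
    coef = np.linalg.solve(xtwx, xtwy)

    # delete-one-block jackknife over contiguous SNP blocks (preserves LD)
    k = len(merged)
    n_blocks = int(min(n_jackknife_blocks, max(2, k // 5)))
    bounds = np.linspace(0, k, n_blocks + 1).astype(int)
    slopes = np.empty(n_blocks)
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        xb, xwb, cb = x[sl], xw[sl], chisq[sl]
        coef_b = np.linalg.solve(xtwx - xb.T @ xwb, xtwy - xwb.T @ cb)
        slopes[b] = coef_b[1]
    slope = coef[1]
    slope_se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((slopes - slopes.mean()) ** 2)))

    h2 = slope * m / n
    se = max(slope_se * m / n, 1e-12)
    zscore = h2 / se
    p = float(stats.norm.sf(zscore))
    return H2Estimate(phenotype=phenotype, h2=float(h2), se=float(se),
                      intercept=float(coef[0]), n=n, m=m, p=max(p, 1e-300))


def genomic_relationship_matrix(g: GenotypeMatrix) -> np.ndarray:
    """GRM A = Z Z^T / M with Z the frequency-standardised dosages."""
    z = g.standardized()
    return (z @ z.T) / g.n_snps


def he_regression(
    phenotype: np.ndarray,
    g: GenotypeMatrix,
    grm: np.ndarray | None = None,
    phenotype_id: str = "trait",
) -> H2Estimate:
    """Haseman-Elston heritability: regress y_i*y_j on GRM_ij over pairs i<j.

    The phenotype is standardised internally. The standard error is a
    delete-one-individual jackknife, computed in closed form from
    per-individual sums so no pair set is ever rebuilt.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if n != g.n_individuals:
        raise ValueError("phenotype and genotype individuals are not aligned")
    if n < 50:
        import warnings

        warnings.warn("Haseman-Elston estimate unstable below 50 individuals")
    y = (y - y.mean()) / y.std()

    a = grm if grm is not None else genomic_relationship_matrix(g)
    iu = np.triu_indices(n, k=1)
    x = a[iu]
    prod = np.outer(y, y)[iu]

    def slope_from_sums(sx, sy, sxy, sxx, npairs):
        return (sxy - sx * sy / npairs) / (sxx - sx**2 / npairs)

    sx, sy = x.sum(), prod.sum()
    sxy, sxx = float(x @ prod), float(x @ x)
    npairs = x.size
    h2 = slope_from_sums(sx, sy, sxy, sxx, npairs)

    # delete-one-individual jackknife from per-individual row sums (vectorised)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    p0 = np.outer(y, y)
    np.fill_diagonal(p0, 0.0)
    rx = a0.sum(axis=1)
    ry = p0.sum(axis=1)
    rxy = np.einsum("ij,ij->i", a0, p0)
    rxx = np.einsum("ij,ij->i", a0, a0)

    jack = slope_from_sums(sx - rx, sy - ry, sxy - rxy, sxx - rxx, npairs - (n - 1))
    se = float(np.sqrt((n - 1) / n * np.sum((jack - jack.mean()) ** 2)))
    se = max(se, 1e-12)
    zscore = h2 / se
    p = float(stats.norm.sf(zscore))
    return H2Estimate(phenotype=phenotype_id, h2=float(h2), se=se,
                      intercept=0.0, n=n, m=g.n_snps, p=max(p, 1e-300))


def h2_table(estimates: list[H2Estimate]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in estimates])
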
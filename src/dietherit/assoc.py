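"""Covariate-adjusted per-SNP association scans (desk-scale GWAS).

Each phenotype is residualised on its covariates once, then regressed on
each SNP dosage separately by ordinary least squares. By the
Frisch-Waugh-Lovell theorem the per-SNP slope and chi-square match a joint
multiple regression with the covariates included. SNPs are pre-filtered on
minor allele frequency, minor allele count and missingness; output follows
the standard sumstats layout (SNP CHR BP A1 A2 N BETA SE CHISQ P) so it
feeds straight into LD-score regression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GenotypeMatrix

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "N", "BETA", "SE", "CHISQ", "P"]


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of y on the covariate columns plus an intercept.

    Raises on a rank-deficient design, naming the offending columns.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        x = np.ones((n, 1))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if np.isnan(c).any():
            raise ValueError("covariates contain missing values")
        x = np.column_stack([np.ones(n), c])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns that add no rank
        bad = []
        kept = x[:, :1]
        for j in range(1, x.shape[1]):
            trial = np.column_stack([kept, x[:, j]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                bad.append(j - 1)
            else:
                kept = trial
        raise ValueError(f"rank-deficient covariate design; collinear column index(es): {bad}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def build_covariate_design(
    covars: pd.DataFrame,
    factor_columns: tuple[str, ...] = ("center",),
) -> np.ndarray:
    """Numeric design matrix: factors one-hot encoded dropping a reference level."""
    parts = []
    for col in covars.columns:
        if col == "iid":
            continue
        if col in factor_columns:
            dummies = pd.get_dummies(covars[col], prefix=col, drop_first=True)
            parts.append(dummies.to_numpy(dtype=float))
        else:
            parts.append(covars[col].to_numpy(dtype=float)[:, None])
    return np.hstack(parts)


def snp_filter_mask(
    g: GenotypeMatrix,
    maf_min: float = 0.005,
    mac_min: int = 10,
    miss_max: float = 0.10,
) -> np.ndarray:
    """Boolean keep-mask over SNPs: MAF > maf_min, MAC > mac_min, missingness < miss_max."""
    d = g.dosages.astype(float)
    missing = np.isnan(d)
    miss_rate = missing.mean(axis=0)
    with np.errstate(invalid="ignore"):
        f = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    n_obs = (~missing).sum(axis=0)
    mac = np.minimum(np.nansum(d, axis=0), 2 * n_obs - np.nansum(d, axis=0))
    variance = np.nanvar(d, axis=0)
    keep = (maf > maf_min) & (mac > mac_min) & (miss_rate < miss_max) & (variance > 0)
    dropped_zero_var = int(((variance == 0) & (maf > maf_min)).sum())
    if dropped_zero_var:
        logger.info("dropped %d zero-variance SNPs", dropped_zero_var)
    return keep


def _scan(yres: np.ndarray, dc: np.ndarray, sxx: np.ndarray,
          snps: pd.DataFrame, n: int, dof: int) -> pd.DataFrame:
    """Assemble sumstats from residualised phenotype + residualised dosages."""
    yc = yres - yres.mean()
    sxy = dc.T @ yc
    beta = sxy / sxx
    ssy = float(yc @ yc)
    sigma2 = np.maximum(ssy - beta * sxy, 0.0) / dof
    se = np.sqrt(sigma2 / sxx)
    chisq = (beta / se) ** 2
    p = stats.chi2.sf(chisq, df=1)
    return pd.DataFrame(
        {
            "SNP": snps["id"],
            "CHR": snps["chr"],
            "BP": snps["bp"],
            "A1": snps["a1"],
            "A2": snps["a2"],
            "N": n,
            "BETA": beta,
            "SE": se,
            "CHISQ": chisq,
            "P": p,
        }
    )


def run_gwas(
    phenotype: np.ndarray,
    g: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    maf_min: float = 0.005,
    mac_min: int = 10,
    miss_max: float = 0.10,
    phenotype_id: str = "trait",
) -> pd.DataFrame:
    """Per-SNP OLS scan of a covariate-residualised phenotype on dosage.

    Both the phenotype and the dosages are projected off the covariates
    (Frisch-Waugh-Lovell), so beta, SE and chi-square match a joint multiple
    regression with the covariates included. Returns a sumstats DataFrame
    (SNP CHR BP A1 A2 N BETA SE CHISQ P), fully vectorised across SNPs.
    """
    y = residualize(phenotype, covariates)
    n = y.shape[0]
    if n != g.n_individuals:
        raise ValueError("phenotype and genotype individuals are not aligned")

    keep = snp_filter_mask(g, maf_min, mac_min, miss_max)
    dc, sxx, dof = _residual_dosages(g, keep, covariates)
    snps = g.snps.loc[keep].reset_index(drop=True)
    return _scan(y, dc, sxx, snps, n, dof)


def _residual_dosages(g: GenotypeMatrix, keep: np.ndarray,
                      covariates: np.ndarray | None) -> tuple[np.ndarray, np.ndarray, int]:
    """Dosages with intercept + covariates projected out, their SS, and the scan dof."""
    d = g.dosages[:, keep].astype(float)
    n = d.shape[0]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        x = np.ones((n, 1))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        x = np.column_stack([np.ones(n), c])
    coef, *_ = np.linalg.lstsq(x, d, rcond=None)
    dc = d - x @ coef
    sxx = np.einsum("ij,ij->j", dc, dc)
    dof = n - x.shape[1] - 1
    return dc, sxx, dof


def run_gwas_many(
    phenotypes: pd.DataFrame,
    g: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    maf_min: float = 0.005,
    mac_min: int = 10,
    miss_max: float = 0.10,
) -> dict[str, pd.DataFrame]:
    """Scan every phenotype column, sharing the SNP filter and residualised dosages."""
    keep = snp_filter_mask(g, maf_min, mac_min, miss_max)
    dc, sxx, dof = _residual_dosages(g, keep, covariates)
    snps = g.snps.loc[keep].reset_index(drop=True)
    n = g.n_individuals
    out = {}
    for col in phenotypes.columns:
        yres = residualize(phenotypes[col].to_numpy(dtype=float), covariates)
        out[col] = _scan(yres, dc, sxx, snps, n, dof)
    return out


def write_sumstats(ss: pd.DataFrame, path) -> None:
    ss.to_csv(path, sep="\t", index=False, columns=SUMSTATS_COLUMNS)


def read_sumstats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"CHR": str})
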
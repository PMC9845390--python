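"""Crude-vs-EB comparison: multiple testing, win rates, loci, concordance.

The number of effectively independent phenotypes is estimated from the
eigenvalues of the phenotype correlation matrix (after covariate
adjustment); 0.05 divided by that count gives the heritability significance
threshold. Pairs where at least one version (crude or EB) clears the
threshold are compared on their point heritability, overall and within ICC
quartiles computed separately for proportion and average phenotypes.
Genome-wide significant loci are greedily clumped in windows around lead
SNPs and, after collapsing windows across versions, locus-level concordance
asks whether the stronger association belongs to the more heritable version.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import residualize

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
DEFAULT_WINDOW_BP = 500_000
TIE_TOL = 1e-6


@dataclass
class MeffResult:
    m_observed: int
    eigenvalues: np.ndarray
    meff: float
    method: str

    @property
    def threshold(self) -> float:
        return 0.05 / self.meff


def effective_tests(
    phenotypes: pd.DataFrame | np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    method: str = "galwey",
    correlation: np.ndarray | None = None,
) -> MeffResult:
    """Effective number of independent phenotypes from correlation eigenvalues.

    Either a phenotype matrix (residualised on the covariates when given,
    then standardised) or a ready correlation matrix may be supplied.
    ``galwey`` computes (sum sqrt(lambda))^2 / sum(lambda) over the
    non-negative eigenvalues, ``li_ji`` counts
    sum_i [I(lambda_i >= 1) + (lambda_i - floor(lambda_i))].
    """
    if correlation is not None:
        corr = np.asarray(correlation, dtype=float)
        if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
            raise ValueError("correlation must be square")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        x = corr  # only the column count is used below
    else:
        x = np.asarray(phenotypes, dtype=float)
        if x.ndim != 2 or x.shape[1] < 2:
            raise ValueError("need at least two phenotype columns")
        if np.isnan(x).any():
            raise ValueError("complete cases required")
        if covariates is not None:
            x = np.column_stack(
                [residualize(x[:, j], covariates) for j in range(x.shape[1])])
        sd = x.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant phenotype column")
        corr = np.corrcoef(x, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    if lam.min() < -1e-8 * max(1.0, lam.max()):
        raise ValueError("correlation matrix not positive semidefinite within tolerance")
    lam = np.clip(lam, 0.0, None)[::-1]

    if method == "galwey":
        meff = float(np.sqrt(lam).sum() ** 2 / lam.sum())
    elif method == "li_ji":
        meff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    else:
        raise ValueError(f"unknown meff method {method!r}")
    meff = float(np.clip(meff, 1.0, x.shape[1]))
    return MeffResult(m_observed=x.shape[1], eigenvalues=lam, meff=meff, method=method)


def significance_filter(h2: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Keep (crude, EB) pairs where at least one version's heritability p < threshold.

    ``h2`` needs columns item, version in {crude, eb}, class, h2, se, p; one
    row per item x version. Returns one row per retained item with both
    versions' columns side by side.
    """
    versions = set(h2["version"].unique())
    if not {"crude", "eb"} <= versions:
        raise ValueError(f"both crude and eb versions required, got {sorted(versions)}")
    wide = h2.pivot(index=["item", "class"], columns="version",
                    values=["h2", "se", "p"])
    if wide[("h2", "crude")].isna().any() or wide[("h2", "eb")].isna().any():
        missing = wide.index[wide[("h2", "crude")].isna() | wide[("h2", "eb")].isna()]
        raise ValueError(f"missing partner version for item(s): {list(missing)[:5]}")
    wide.columns = [f"{v}_{ver}" for v, ver in wide.columns]
    wide = wide.reset_index()
    retained = wide[(wide["p_crude"] < threshold) | (wide["p_eb"] < threshold)]
    return retained.reset_index(drop=True)


@dataclass
class ComparisonSummary:
    n_retained: int
    eb_win_rate: float
    win_rate_by_class: dict[str, float]
    win_rate_by_quartile: dict[str, dict[int, float]]
    counts_by_quartile: dict[str, dict[int, int]]
    icc_h2_correlation: float
    icc_h2_correlation_by_class: dict[str, float]


def compare_versions(
    retained: pd.DataFrame,
    icc: pd.DataFrame,
    tie_tol: float = TIE_TOL,
) -> tuple[pd.DataFrame, ComparisonSummary]:
    """Winner per retained pair, win rates by class and ICC quartile, ICC-h2 correlation.

    ``icc`` maps item -> icc. Quartiles of ICC are computed empirically
    within each phenotype class (proportion vs. average); classes with fewer
    than 4 items skip stratification with a warning. The reported ICC-h2
    Pearson correlations use the crude heritability.
    """
    table = retained.merge(icc[["item", "icc"]], on="item", how="left")
    if table["icc"].isna().any():
        missing = table.loc[table["icc"].isna(), "item"].tolist()
        raise ValueError(f"no ICC available for item(s): {missing[:5]}")

    diff = table["h2_eb"] - table["h2_crude"]
    table["winner"] = np.where(
        np.abs(diff) < tie_tol, "equal", np.where(diff > 0, "eb", "crude")
    )

    win_by_class: dict[str, float] = {}
    win_by_quart: dict[str, dict[int, float]] = {}
    counts_by_quart: dict[str, dict[int, int]] = {}
    corr_by_class: dict[str, float] = {}
    table["icc_quartile"] = np.nan
    for cls, sub in table.groupby("class"):
        win_by_class[cls] = float((sub["winner"] == "eb").mean())
        if len(sub) >= 2 and sub["icc"].std() > 0 and sub["h2_crude"].std() > 0:
            corr_by_class[cls] = float(np.corrcoef(sub["icc"], sub["h2_crude"])[0, 1])
        else:
            corr_by_class[cls] = float("nan")
        if len(sub) < 4:
            logger.warning("class %s has %d items; quartile stratification skipped",
                           cls, len(sub))
            continue
        quart = pd.qcut(sub["icc"].rank(method="first"), 4, labels=[1, 2, 3, 4]).astype(int)
        table.loc[sub.index, "icc_quartile"] = quart
        win_by_quart[cls] = {
            int(qt): float((sub.loc[quart == qt, "winner"] == "eb").mean())
            for qt in (1, 2, 3, 4)
        }
        counts_by_quart[cls] = {int(qt): int((quart == qt).sum()) for qt in (1, 2, 3, 4)}

    overall_corr = (
        float(np.corrcoef(table["icc"], table["h2_crude"])[0, 1])
        if len(table) >= 2 and table["icc"].std() > 0 and table["h2_crude"].std() > 0
        else float("nan")
    )
    summary = ComparisonSummary(
        n_retained=len(table),
        eb_win_rate=float((table["winner"] == "eb").mean()) if len(table) else float("nan"),
        win_rate_by_class=win_by_class,
        win_rate_by_quartile=win_by_quart,
        counts_by_quartile=counts_by_quart,
        icc_h2_correlation=overall_corr,
        icc_h2_correlation_by_class=corr_by_class,
    )
    return table, summary


def clump_loci(
    ss: pd.DataFrame,
    p_threshold: float = GENOME_WIDE_P,
    window_bp: int = DEFAULT_WINDOW_BP,
    phenotype: str = "trait",
    version: str = "crude",
) -> pd.DataFrame:
    """Greedy clumping of significant SNPs into independent loci.

    Repeatedly takes the smallest-p SNP below ``p_threshold`` not yet
    absorbed, emits it as a lead, and absorbs every SNP within ``window_bp``
    (a radius) on the same chromosome. Ties broken by (p, chr, bp, SNP id).
    """
    sig = ss.loc[ss["P"] < p_threshold, ["SNP", "CHR", "BP", "P"]].copy()
    sig["CHR"] = sig["CHR"].astype(str)
    sig = sig.sort_values(["P", "CHR", "BP", "SNP"], kind="mergesort").reset_index(drop=True)
    absorbed = np.zeros(len(sig), dtype=bool)
    records = []
    for i in range(len(sig)):
        if absorbed[i]:
            continue
        lead = sig.iloc[i]
        near = (sig["CHR"] == lead["CHR"]) & (np.abs(sig["BP"] - lead["BP"]) <= window_bp)
        absorbed |= near.to_numpy()
        records.append(
            {
                "lead_snp": lead["SNP"],
                "chr": lead["CHR"],
                "bp": int(lead["BP"]),
                "lead_p": float(lead["P"]),
                "phenotype": phenotype,
                "version": version,
                "window_lo": int(lead["BP"]) - window_bp,
                "window_hi": int(lead["BP"]) + window_bp,
            }
        )
    return pd.DataFrame(
        records,
        columns=["lead_snp", "chr", "bp", "lead_p", "phenotype",
                 "version", "window_lo", "window_hi"],
    )


@dataclass
class ConcordanceReport:
    n_windows: int
    n_concordant: int
    fraction: float | None
    fraction_top25: float | None
    fraction_top10: float | None
    table: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def locus_concordance(
    crude_loci: pd.DataFrame,
    eb_loci: pd.DataFrame,
    h2_by_item: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> ConcordanceReport:
    """Per collapsed window x phenotype: does the smaller lead p sit with the higher h2?

    Loci from both versions of each phenotype are collapsed into windows
    (greedy by significance); a window is concordant when its strongest lead
    p belongs to the version with the higher heritability. Fractions are
    also reported within the top-25% and top-10% strata of the symmetric
    percent difference |h2_crude - h2_eb| / mean(h2_crude, h2_eb). With zero
    loci the fractions are reported as absent (None), never NaN-propagated.
    """
    h2_map = h2_by_item.set_index("item")
    loci = pd.concat([crude_loci, eb_loci], ignore_index=True)
    if loci.empty:
        return ConcordanceReport(0, 0, None, None, None)

    rows = []
    for item, sub in loci.groupby("phenotype"):
        sub = sub.sort_values(["lead_p", "chr", "bp", "lead_snp"],
                              kind="mergesort").reset_index(drop=True)
        absorbed = np.zeros(len(sub), dtype=bool)
        h2c = float(h2_map.loc[item, "h2_crude"])
        h2e = float(h2_map.loc[item, "h2_eb"])
        denom = 0.5 * (abs(h2c) + abs(h2e))
        pct_diff = abs(h2c - h2e) / denom if denom > 0 else 0.0
        better = "crude" if h2c > h2e else ("eb" if h2e > h2c else "equal")
        for i in range(len(sub)):
            if absorbed[i]:
                continue
            lead = sub.iloc[i]
            near = (sub["chr"] == lead["chr"]) & (
                np.abs(sub["bp"] - lead["bp"]) <= window_bp
            )
            window = sub.loc[near.to_numpy() & ~absorbed]
            absorbed |= near.to_numpy()
            strongest = window.iloc[0]  # already sorted by p
            rows.append(
                {
                    "phenotype": item,
                    "chr": lead["chr"],
                    "bp": int(lead["bp"]),
                    "stronger_version": strongest["version"],
                    "higher_h2_version": better,
                    "pct_diff_h2": pct_diff,
                    "concordant": bool(strongest["version"] == better),
                }
            )
    table = pd.DataFrame(rows)
    n = len(table)
    n_conc = int(table["concordant"].sum())

    def stratum_fraction(q: float) -> float | None:
        cut = table["pct_diff_h2"].quantile(q)
        sub = table[table["pct_diff_h2"] >= cut]
        return float(sub["concordant"].mean()) if len(sub) else None

    return ConcordanceReport(
        n_windows=n,
        n_concordant=n_conc,
        fraction=n_conc / n if n else None,
        fraction_top25=stratum_fraction(0.75) if n else None,
        fraction_top10=stratum_fraction(0.90) if n else None,
        table=table,
    )
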
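"""Crude and Empirical Bayes derivation of repeated-recall dietary phenotypes.

For each dietary item and individual with k questionnaires, the crude
proportion is s/k (times consumed over questionnaires taken) and the crude
average is the mean quantity over all k questionnaires, zeros included for
days the item was not consumed.

The Empirical Bayes versions shrink individuals with few questionnaires
toward the cohort: the EB proportion is the beta-binomial posterior mean
(s + alpha)/(k + alpha + beta), with (alpha, beta) the interior-beta
component of a zero-one-inflated fit to the cohort's crude proportions; the
EB average is the Dirichlet-multinomial posterior mean over the item's
response-category grid, sum_c value_c (count_c + alpha_c) / (k + sum alpha).
Both are convex combinations of the crude statistic (weight k/(k + prior
strength)) and the prior mean, so shrinkage vanishes as k grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

logger = logging.getLogger(__name__)

DEFAULT_MIN_INTERIOR = 50


@dataclass
class BetaPrior:
    """Zero-one-inflated beta fit to cohort crude proportions.

    Only (alpha, beta) feed the EB update; the point masses p0/p1 at exactly
    0 and 1 are reported but deliberately excluded from the posterior-mean
    formula. ``donor_item`` records which item's parameters were reused when
    this item's own fit did not converge.
    """

    alpha: float
    beta: float
    p0: float
    p1: float
    converged: bool
    donor_item: str | None = None

    def __post_init__(self) -> None:
        if self.converged and not (
            np.isfinite(self.alpha) and np.isfinite(self.beta)
            and self.alpha > 0 and self.beta > 0
        ):
            raise ValueError("converged prior requires finite positive alpha, beta")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass
class DMPrior:
    """Dirichlet-multinomial concentration over an item's response categories."""

    category_values: np.ndarray
    alpha_vec: np.ndarray
    converged: bool

    def __post_init__(self) -> None:
        self.category_values = np.asarray(self.category_values, dtype=float)
        self.alpha_vec = np.asarray(self.alpha_vec, dtype=float)
        if self.converged:
            if np.any(self.alpha_vec <= 0):
                raise ValueError("converged DM prior requires all alpha > 0")
            if np.any(np.diff(self.category_values) <= 0):
                raise ValueError("category values must be strictly increasing")

    @property
    def alpha_sum(self) -> float:
        return float(self.alpha_vec.sum())

    @property
    def mean(self) -> float:
        return float(self.category_values @ self.alpha_vec / self.alpha_sum)


def derive_crude(
    consumed: np.ndarray, quantities: np.ndarray | None = None
) -> tuple[float, float | None]:
    """Crude proportion and (for quantity items) crude average for one individual.

    ``consumed`` holds the 0/1 indicators over the individual's k retained
    questionnaires; ``quantities`` the matching quantities (0 when not
    consumed). The average runs over ALL k questionnaires, zeros included.
    """
    consumed = np.asarray(consumed)
    k = consumed.size
    if k == 0:
        raise ValueError("individual has no questionnaires; exclude upstream")
    prop = float(consumed.sum()) / k
    if quantities is None:
        return prop, None
    quantities = np.asarray(quantities, dtype=float)
    if quantities.size != k:
        raise ValueError("quantities and consumed must have equal length")
    return prop, float(quantities.mean())


# ---------------------------------------------------------------------------
# Prior fitting
# ---------------------------------------------------------------------------

def _beta_negloglik(log_ab: np.ndarray, slog_x: float, slog_1mx: float, n: int) -> float:
    a, b = np.exp(log_ab)
    return -(n * (special.gammaln(a + b) - special.gammaln(a) - special.gammaln(b))
             + (a - 1.0) * slog_x + (b - 1.0) * slog_1mx)


def _beta_grad(log_ab: np.ndarray, slog_x: float, slog_1mx: float, n: int) -> np.ndarray:
    a, b = np.exp(log_ab)
    dab = special.digamma(a + b)
    da = -(n * (dab - special.digamma(a)) + slog_x) * a
    db = -(n * (dab - special.digamma(b)) + slog_1mx) * b
    return np.array([da, db])


def fit_zoib(
    proportions: np.ndarray,
    min_interior: int = DEFAULT_MIN_INTERIOR,
    grad_tol: float = 1e-8,
) -> BetaPrior:
    """Fit a zero-one-inflated beta to cohort crude proportions.

    The masses at exactly 0 and 1 are their empirical fractions; (alpha,
    beta) maximise the beta likelihood of the strictly interior values,
    initialised at the method-of-moments point and iterated until the
    gradient norm of the log-likelihood falls below ``grad_tol``. The prior
    is flagged non-converged when fewer than ``min_interior`` interior
    observations exist or the optimiser fails.
    """
    x = np.asarray(proportions, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one observation")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("proportions must lie in [0,1]")

    p0 = float(np.mean(x == 0.0))
    p1 = float(np.mean(x == 1.0))
    interior = x[(x > 0.0) & (x < 1.0)]
    if interior.size < min_interior:
        return BetaPrior(alpha=np.nan, beta=np.nan, p0=p0, p1=p1, converged=False)

    m, v = interior.mean(), interior.var()
    if v <= 0 or v >= m * (1.0 - m):
        a0, b0 = 1.0, 1.0
    else:
        common = m * (1.0 - m) / v - 1.0
        a0, b0 = m * common, (1.0 - m) * common

    slog_x = float(np.log(interior).sum())
    slog_1mx = float(np.log1p(-interior).sum())
    n = interior.size
    res = optimize.minimize(
        _beta_negloglik,
        x0=np.log([a0, b0]),
        args=(slog_x, slog_1mx, n),
        jac=_beta_grad,
        method="L-BFGS-B",
        options={"gtol": grad_tol * n, "maxiter": 500},
    )
    # report the gradient on the per-likelihood scale
    grad_norm = float(np.linalg.norm(_beta_grad(res.x, slog_x, slog_1mx, n))) / n
    if not res.success and grad_norm > 1e-6:
        return BetaPrior(alpha=np.nan, beta=np.nan, p0=p0, p1=p1, converged=False)
    alpha, beta = np.exp(res.x)
    return BetaPrior(alpha=float(alpha), beta=float(beta), p0=p0, p1=p1, converged=True)


def eb_proportion(s, k, prior: BetaPrior) -> np.ndarray | float:
    """Beta-binomial posterior-mean proportion (s + alpha)/(k + alpha + beta)."""
    s_arr, k_arr = np.asarray(s, dtype=float), np.asarray(k, dtype=float)
    if np.any(k_arr < 1):
        raise ValueError("k must be at least 1")
    if np.any((s_arr < 0) | (s_arr > k_arr)):
        raise ValueError("successes must satisfy 0 <= s <= k")
    if not prior.converged:
        raise ValueError("prior did not converge; substitute a donor item's prior first")
    out = (s_arr + prior.alpha) / (k_arr + prior.alpha + prior.beta)
    return float(out) if out.ndim == 0 else out


def fit_dirichlet_multinomial(
    counts: np.ndarray,
    category_values: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200_000,
) -> DMPrior:
    """Maximum-likelihood Dirichlet-multinomial concentration by fixed point.

    ``counts`` is individuals x categories (row i sums to that individual's
    k_i questionnaires). Uses the standard digamma fixed-point update from a
    moment-matched start, stopping when successive log-likelihoods change by
    less than ``tol``. Non-converged when fewer than two categories carry
    mass or the iteration stalls.

    Because every count is a small integer (at most the number of
    questionnaires), the digamma/gammaln sums are computed from value
    histograms, making each iteration O(k_max x categories) regardless of
    cohort size.
    """
    counts = np.asarray(counts, dtype=float)
    category_values = np.asarray(category_values, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != category_values.size:
        raise ValueError("counts must be individuals x categories matching category_values")
    col_tot = counts.sum(axis=0)
    if np.count_nonzero(col_tot) < 2:
        return DMPrior(category_values, np.full(category_values.size, np.nan), converged=False)

    k_i = counts.sum(axis=1)
    if np.any(k_i < 1):
        raise ValueError("every individual needs at least one questionnaire")

    n, n_cat = counts.shape
    cmax = int(counts.max())
    vals = np.arange(cmax + 1, dtype=float)
    # hist[v, c] = number of individuals with count v in category c
    hist = np.stack([np.bincount(counts[:, c].astype(int), minlength=cmax + 1)
                     for c in range(n_cat)], axis=1).astype(float)
    kmax = int(k_i.max())
    kvals = np.arange(kmax + 1, dtype=float)
    khist = np.bincount(k_i.astype(int), minlength=kmax + 1).astype(float)

    # moment-matched start: category proportions scaled by an overdispersion guess
    props = counts / k_i[:, None]
    mean_p = props.mean(axis=0)
    var_p = props.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_guess = np.nanmedian(
            np.where(var_p > 0, mean_p * (1 - mean_p) / var_p - 1.0, np.nan)
        )
    if not np.isfinite(s_guess) or s_guess <= 0:
        s_guess = 1.0
    alpha = np.maximum(mean_p * s_guess, 1e-6)

    def loglik(a: np.ndarray) -> float:
        a0 = a.sum()
        ll = n * special.gammaln(a0) - float(khist @ special.gammaln(kvals + a0))
        ll += float(np.sum(hist * special.gammaln(vals[:, None] + a[None, :])))
        ll -= n * float(np.sum(special.gammaln(a)))
        return ll

    prev = loglik(alpha)
    converged = False
    for _ in range(max_iter):
        a0 = alpha.sum()
        num = np.sum(hist * special.digamma(vals[:, None] + alpha[None, :]), axis=0) \
            - n * special.digamma(alpha)
        den = float(khist @ special.digamma(kvals + a0)) - n * special.digamma(a0)
        alpha = np.maximum(alpha * num / den, 1e-12)
        cur = loglik(alpha)
        if abs(cur - prev) < tol:
            converged = True
            break
        prev = cur
    return DMPrior(category_values, alpha, converged=converged)


def eb_average(counts, k, prior: DMPrior) -> np.ndarray | float:
    """Dirichlet-multinomial posterior-mean intake for one or many individuals.

    sum_c value_c (count_c + alpha_c) / (k + sum alpha); shrinks the crude
    average toward the prior mean with weight alpha_sum/(k + alpha_sum).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    k_arr = np.atleast_1d(np.asarray(k, dtype=float))
    if counts.shape[1] != prior.alpha_vec.size:
        raise ValueError("count vector length must match the prior's categories")
    if not np.allclose(counts.sum(axis=1), k_arr):
        raise ValueError("counts must sum to k for every individual")
    if not prior.converged:
        raise ValueError("prior did not converge; substitute a donor item's prior first")
    num = (counts + prior.alpha_vec[None, :]) @ prior.category_values
    out = num / (k_arr + prior.alpha_sum)
    return float(out[0]) if out.size == 1 else out


# ---------------------------------------------------------------------------
# Cohort-level derivation
# ---------------------------------------------------------------------------

def quantity_categories(values: np.ndarray, precision: int = 0) -> np.ndarray:
    """Response-category grid for a quantity item: distinct rounded values, 0 kept."""
    vals = np.unique(np.round(np.asarray(values, dtype=float), precision))
    return vals


def _counts_matrix(values: pd.Series, iids: pd.Series, categories: np.ndarray,
                   precision: int = 0) -> tuple[pd.Index, np.ndarray]:
    rounded = np.round(values.to_numpy(dtype=float), precision)
    cat_idx = np.searchsorted(categories, rounded)
    ids, inv = np.unique(iids.to_numpy(), return_inverse=True)
    mat = np.zeros((ids.size, categories.size))
    np.add.at(mat, (inv, cat_idx), 1.0)
    return pd.Index(ids, name="iid"), mat


@dataclass
class ItemPhenotypes:
    """Fitted priors plus the per-individual phenotype columns for one item."""

    item: str
    is_quantity: bool
    beta_prior: BetaPrior
    dm_prior: DMPrior | None = None


def assign_donors(
    priors: dict[str, BetaPrior],
    donor_map: dict[str, str] | None = None,
) -> dict[str, BetaPrior]:
    """Resolve non-converged beta priors through donor items.

    A configured donor wins; otherwise the converged item with the closest
    overall crude-proportion mean (including the point masses) stands in.
    With no converged item available a hard error is raised rather than
    silently falling back to the crude statistic.
    """
    donor_map = donor_map or {}
    resolved = dict(priors)
    converged = {k: v for k, v in priors.items() if v.converged}
    for item, prior in priors.items():
        if prior.converged:
            continue
        if item in donor_map:
            donor = donor_map[item]
            if donor not in converged:
                raise ValueError(f"configured donor {donor!r} for {item!r} did not converge")
        else:
            if not converged:
                raise ValueError(f"no converged donor available for item {item!r}")

            def overall_mean(p: BetaPrior) -> float:
                interior = 1.0 - p.p0 - p.p1
                return p.p1 + interior * p.mean

            target = prior.p1 + (1.0 - prior.p0 - prior.p1) * 0.5
            donor = min(converged, key=lambda c: abs(overall_mean(converged[c]) - target))
        d = converged[donor]
        resolved[item] = BetaPrior(
            alpha=d.alpha, beta=d.beta, p0=prior.p0, p1=prior.p1,
            converged=True, donor_item=donor,
        )
        logger.info("item %s: beta prior borrowed from donor %s", item, donor)
    return resolved


def build_phenotype_table(
    encoded: pd.DataFrame,
    binary_items: list[str],
    quantity_items: list[str],
    donor_map: dict[str, str] | None = None,
    category_precision: int = 0,
    min_interior: int = DEFAULT_MIN_INTERIOR,
) -> tuple[pd.DataFrame, dict[str, ItemPhenotypes]]:
    """Derive crude and EB phenotypes for every item from filtered questionnaires.

    ``encoded`` is long-format with ``iid`` plus, per item, a 0/1 indicator
    column named after the item (binary) or ``<item>_consumed`` /
    ``<item>_qty`` (quantity). Every item yields a crude and an EB
    proportion; quantity items additionally yield a crude and an EB average,
    i.e. 2*(n_binary + n_quantity) + 2*n_quantity phenotype columns.
    """
    by_iid = encoded.groupby("iid", sort=True)
    k = by_iid.size()
    table = pd.DataFrame({"k": k})

    # fit all beta priors first so donor substitution can see the full set
    raw_priors: dict[str, BetaPrior] = {}
    s_by_item: dict[str, pd.Series] = {}
    for item in binary_items + quantity_items:
        col = item if item in encoded.columns else f"{item}_consumed"
        s = by_iid[col].sum()
        s_by_item[item] = s
        raw_priors[item] = fit_zoib((s / k).to_numpy(), min_interior=min_interior)
    priors = assign_donors(raw_priors, donor_map)

    fitted: dict[str, ItemPhenotypes] = {}
    cols: dict[str, np.ndarray] = {}
    for item in binary_items + quantity_items:
        s = s_by_item[item]
        crude = (s / k).to_numpy()
        cols[f"{item}_crude_prop"] = crude
        cols[f"{item}_eb_prop"] = eb_proportion(s.to_numpy(), k.to_numpy(), priors[item])
        fitted[item] = ItemPhenotypes(item=item, is_quantity=item in quantity_items,
                                      beta_prior=priors[item])

    for item in quantity_items:
        qty = encoded[f"{item}_qty"]
        categories = quantity_categories(qty.to_numpy(), category_precision)
        ids, counts = _counts_matrix(qty, encoded["iid"], categories, category_precision)
        dm = fit_dirichlet_multinomial(counts, categories)
        if not dm.converged:
            raise ValueError(f"Dirichlet-multinomial fit failed for quantity item {item!r}")
        k_vec = counts.sum(axis=1)
        order = ids.get_indexer(table.index)
        cols[f"{item}_crude_avg"] = ((counts @ categories) / k_vec)[order]
        cols[f"{item}_eb_avg"] = np.asarray(eb_average(counts, k_vec, dm))[order]
        fitted[item].dm_prior = dm

    pheno = pd.concat([table, pd.DataFrame(cols, index=table.index)], axis=1)
    return pheno, fitted


def expected_phenotype_columns(n_binary: int, n_continuous: int) -> int:
    """Phenotype column count from an item inventory: 2 per item + 2 extra per quantity item."""
    return 2 * (n_binary + n_continuous) + 2 * n_continuous
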
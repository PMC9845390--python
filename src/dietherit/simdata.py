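"""Synthetic cohort generator: genotypes with LD, latent dietary traits, 24HR records.

Genotypes are built from a Gaussian-copula AR(1) haplotype model: one latent
first-order autoregressive Gaussian process per haplotype, thresholded at
each site at the quantile of that site's allele frequency, so adjacent-site
LD decays geometrically with a single parameter. A single synthetic
chromosome is used, with 1-based positions on a fixed 1 kb grid.

Each dietary item is driven by its own latent liability built from a sparse
set of causal SNPs (variance-standardised so the genetic share equals the
target heritability). Repeated questionnaires then sample day-level
consumption (Bernoulli) and, for quantity items, a portion count on a small
integer grid (truncated Poisson), with the person-level effect scale
calibrated numerically so the one-way intra-class correlation of the raw
item hits its target.

All generator defaults reflect the cohort structure the analysis assumes:
1-5 questionnaires per person with a completion-count distribution
proportional to (81081, 46893, 31818, 15000, 2066), and a small fraction of
records deliberately violating each credibility filter so that QC code is
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

# Completion counts for 1..5 questionnaires used to default the k-distribution.
DEFAULT_COMPLETION_COUNTS = (81081, 46893, 31818, 15000, 2066)
DEFAULT_K_DISTRIBUTION = tuple(
    c / sum(DEFAULT_COMPLETION_COUNTS) for c in DEFAULT_COMPLETION_COUNTS
)

BP_SPACING = 1_000  # fixed 1 kb spacing on the single synthetic chromosome


@dataclass
class GenotypeMatrix:
    """Additive dosages for N individuals at M SNPs on one synthetic chromosome.

    Attributes
    ----------
    individuals : list[str]
        Ordered individual identifiers.
    snps : pandas.DataFrame
        One row per SNP: ``id, chr, bp, a1, a2, freq`` with ``freq`` the
        drawn frequency of the effect allele ``a1``.
    dosages : numpy.ndarray
        ``(N, M)`` int8 array with entries in {0, 1, 2} counting a1 alleles.
    """

    individuals: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def allele_freqs(self) -> np.ndarray:
        """Empirical a1 allele frequency per SNP."""
        return self.dosages.mean(axis=0) / 2.0

    def standardized(self) -> np.ndarray:
        """Dosages centred at 2f and scaled by sqrt(2f(1-f)), as float64."""
        f = self.allele_freqs()
        sd = np.sqrt(2.0 * f * (1.0 - f))
        if np.any(sd == 0):
            raise ValueError("monomorphic SNP cannot be standardized")
        return (self.dosages - 2.0 * f) / sd


@dataclass
class ItemSpec:
    """One dietary item of the simulated questionnaire.

    ``kind`` is "binary" (yes/no consumption only) or "quantity" (consumption
    plus a portion count on the integer grid 0..max_count, e.g. cups of
    coffee). ``prevalence`` is the marginal day-level consumption
    probability; ``icc`` is the target one-way intra-class correlation of
    the raw item across repeated questionnaires.
    """

    name: str
    kind: str = "binary"
    prevalence: float = 0.5
    icc: float = 0.5
    mean_quantity: float = 2.0
    max_count: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "quantity"):
            raise ValueError(f"unknown item kind {self.kind!r}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly in (0,1)")
        if not 0.0 <= self.icc <= 1.0:
            raise ValueError("icc target must lie in [0,1]")


@dataclass
class TraitModel:
    """Ground-truth generative settings for the latent dietary traits."""

    h2: float
    n_causal: int
    items: list[ItemSpec]
    seed: int = 0
    latent_weight: float = 1.0  # share of the person effect driven by liability

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 target must lie in [0,1]")
        if not 0.0 <= self.latent_weight <= 1.0:
            raise ValueError("latent_weight must lie in [0,1]")


@dataclass
class LatentTraits:
    """Per-individual liabilities, one column per item, plus their genetic parts."""

    liabilities: np.ndarray  # (N, n_items), unit variance by construction
    genetic_values: np.ndarray  # (N, n_items)
    causal_snps: dict[str, list[str]]
    model: TraitModel


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.8,
    seed: int = 0,
    rho_range: tuple[float, float] | None = None,
    block_snps: int = 25,
) -> GenotypeMatrix:
    """Draw an LD-structured genotype matrix from the AR(1) haplotype model.

    Two latent haplotypes per individual follow a first-order autoregressive
    Gaussian process; each site is thresholded at the normal quantile of its
    drawn allele frequency and the two haplotypes are summed to an additive
    dosage.

    With the default ``rho_range=None`` the adjacent-site correlation is the
    single value ``ld_rho`` everywhere. Passing ``rho_range=(lo, hi)``
    instead draws one AR coefficient per block of ``block_snps`` consecutive
    sites uniformly from that range, which makes LD scores vary along the
    chromosome the way real LD blocks do — a homogeneous coefficient leaves
    LD scores nearly constant, and LD-score regression then has almost no
    leverage.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be at least 2")
    if n_snps < 1:
        raise ValueError("n_snps must be at least 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a sub-interval of (0, 0.5]")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=n_snps)
    thresholds = stats.norm.ppf(freqs)

    if rho_range is None:
        rho = np.full(n_snps, ld_rho)
    else:
        rlo, rhi = rho_range
        if not (0.0 <= rlo <= rhi < 1.0):
            raise ValueError("rho_range must be a sub-interval of [0, 1)")
        if block_snps < 1:
            raise ValueError("block_snps must be at least 1")
        n_blocks = -(-n_snps // block_snps)
        rho = np.repeat(rng.uniform(rlo, rhi, size=n_blocks), block_snps)[:n_snps]

    n_hap = 2 * n_individuals
    innov_sd = np.sqrt(1.0 - rho**2)
    latent = np.empty((n_hap, n_snps))
    latent[:, 0] = rng.standard_normal(n_hap)
    for j in range(1, n_snps):
        latent[:, j] = rho[j] * latent[:, j - 1] + innov_sd[j] * rng.standard_normal(n_hap)

    alleles = (latent < thresholds).astype(np.int8)
    dosages = alleles[0::2] + alleles[1::2]

    snps = pd.DataFrame(
        {
            "id": [f"snp{j + 1}" for j in range(n_snps)],
            "chr": "1",
            "bp": np.arange(1, n_snps + 1, dtype=np.int64) * BP_SPACING,
            "a1": "A",
            "a2": "G",
            "freq": freqs,
        }
    )
    individuals = [f"ind{i + 1}" for i in range(n_individuals)]
    return GenotypeMatrix(individuals=individuals, snps=snps, dosages=dosages)


def simulate_latent_traits(g: GenotypeMatrix, model: TraitModel) -> LatentTraits:
    """Build one unit-variance liability per item with genetic share ``model.h2``.

    Each item draws its own causal subset of ``model.n_causal`` SNPs and its
    own normal effect sizes on standardized dosages; the genetic component is
    rescaled to variance h2 and independent Gaussian noise supplies the rest.
    """
    if model.n_causal > g.n_snps:
        raise ValueError("n_causal exceeds the number of simulated SNPs")
    if model.n_causal < 1:
        raise ValueError("n_causal must be at least 1")

    rng = np.random.default_rng(np.random.SeedSequence([model.seed, 101]))
    z = g.standardized()
    n, n_items = g.n_individuals, len(model.items)

    genetic = np.zeros((n, n_items))
    liab = np.zeros((n, n_items))
    causal: dict[str, list[str]] = {}
    snp_ids = g.snps["id"].to_numpy()

    for t, item in enumerate(model.items):
        idx = rng.choice(g.n_snps, size=model.n_causal, replace=False)
        w = rng.standard_normal(model.n_causal)
        gv = z[:, idx] @ w
        sd = gv.std()
        if model.h2 > 0 and sd > 0:
            gv = gv * (np.sqrt(model.h2) / sd)
        else:
            gv = np.zeros(n)
        e = rng.standard_normal(n)
        e = e - e.mean()
        ev = e * (np.sqrt(1.0 - model.h2) / e.std()) if model.h2 < 1 else np.zeros(n)
        genetic[:, t] = gv
        liab[:, t] = gv + ev
        causal[item.name] = list(snp_ids[np.sort(idx)])

    return LatentTraits(liabilities=liab, genetic_values=genetic, causal_snps=causal, model=model)


# ---------------------------------------------------------------------------
# ICC calibration machinery
# ---------------------------------------------------------------------------

_E_BOUND = 12.0  # integration range for the standard-normal person effect
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _quad_nodes(scale: float, breakpoints: list[float]) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights for E[f(e)], e ~ N(0,1), refined at breakpoints.

    Sigmoid and truncated-Poisson features have width ~1/scale around each
    breakpoint, so extra segment boundaries are placed at geometric offsets
    around every breakpoint; within a segment the integrand is smooth.
    """
    edges = {-_E_BOUND, _E_BOUND, -4.0, 0.0, 4.0}
    width = 1.0 / max(scale, 1.0)
    for b in breakpoints:
        if -_E_BOUND < b < _E_BOUND:
            for off in (0.0, width, -width, 8 * width, -8 * width, 64 * width, -64 * width):
                x = b + off
                if -_E_BOUND < x < _E_BOUND:
                    edges.add(x)
    edges = np.array(sorted(edges))
    mid = 0.5 * (edges[:-1] + edges[1:])
    half = 0.5 * np.diff(edges)
    nodes = (mid[:, None] + half[:, None] * _GL_NODES[None, :]).ravel()
    weights = (half[:, None] * _GL_WEIGHTS[None, :]).ravel() * stats.norm.pdf(nodes)
    return nodes, weights


def _solve_mu(scale: float, prevalence: float) -> float:
    """Intercept such that E[logistic(mu + scale*e)] = prevalence, e ~ N(0,1)."""

    def gap(mu: float) -> float:
        nodes, w = _quad_nodes(scale, [-mu / scale] if scale > 0 else [])
        return float(w @ _sigmoid(mu + scale * nodes)) - prevalence

    span = 40.0 + 14.0 * scale
    return optimize.brentq(gap, -span, span, xtol=1e-10)


def _trunc_pois_pmf(loglam: np.ndarray, max_count: int) -> np.ndarray:
    """Row-normalised pmf of a Poisson truncated to {1, ..., max_count}.

    On the truncated support the e^-lambda factor cancels, so the pmf is
    proportional to exp(x log(lambda) - log x!) and stays finite for any
    log-rate; everything is computed in log space.
    """
    x = np.arange(1, max_count + 1, dtype=float)
    logw = x[None, :] * loglam[:, None] - special.gammaln(x + 1)[None, :]
    logw -= logw.max(axis=1, keepdims=True)
    pmf = np.exp(logw)
    return pmf / pmf.sum(axis=1, keepdims=True)


def _trunc_pois_moments(loglam: np.ndarray, max_count: int) -> tuple[np.ndarray, np.ndarray]:
    """First two moments of a Poisson truncated to {1, ..., max_count}."""
    x = np.arange(1, max_count + 1, dtype=float)
    pmf = _trunc_pois_pmf(loglam, max_count)
    return pmf @ x, pmf @ x**2


def _expected_icc(scale: float, item: ItemSpec) -> float:
    """One-way ICC of the raw item implied by person-effect scale ``scale``.

    Person effect e ~ N(0,1); day-level response is Bernoulli (binary item)
    or Bernoulli x truncated Poisson (quantity item). ICC = Var of the
    person-conditional mean over (that plus) the mean person-conditional
    variance, evaluated by adaptive quadrature over the person effect.
    """
    mu = _solve_mu(scale, item.prevalence)
    brk = [-mu / scale] if scale > 0 else []
    if item.kind == "quantity" and scale > 0:
        # the truncated-Poisson mean shifts where log(lambda) crosses the
        # logs of the support values; mark those transitions too
        for c in range(1, item.max_count + 1):
            brk.append((np.log(c) - np.log(item.mean_quantity)) / (0.5 * scale))

    nodes, w = _quad_nodes(scale, brk)
    p = _sigmoid(mu + scale * nodes)
    if item.kind == "binary":
        cond_mean = p
        cond_var = p * (1.0 - p)
    else:
        loglam = np.log(item.mean_quantity) + 0.5 * scale * nodes
        m1, m2 = _trunc_pois_moments(loglam, item.max_count)
        cond_mean = p * m1
        cond_var = p * m2 - cond_mean**2

    mean = float(w @ cond_mean)
    mean_sq = float(w @ cond_mean**2)
    within = float(w @ cond_var)
    between = max(mean_sq - mean**2, 0.0)
    total = between + within
    return between / total if total > 0 else 0.0


_CALIBRATION_CACHE: dict[tuple, float] = {}


def calibrate_item_scale(item: ItemSpec, tol: float = 0.01) -> float:
    """Person-effect scale whose expected raw-item ICC equals ``item.icc``.

    1-D root search; the expected ICC is monotone increasing in the scale.
    Raises if the target is unreachable within the search bracket.
    """
    if item.icc >= 1.0:
        raise ValueError("icc = 1 items are generated deterministically, not calibrated")
    if item.icc <= 0.0:
        return 0.0
    key = (item.kind, item.prevalence, item.icc, item.mean_quantity, item.max_count)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    lo, hi = 1e-4, 60.0
    f_hi = _expected_icc(hi, item) - item.icc
    if f_hi < 0:
        raise ValueError(f"icc target {item.icc} unreachable for item {item.name!r}")
    scale = optimize.brentq(
        lambda s: _expected_icc(s, item) - item.icc, lo, hi, xtol=1e-6
    )
    achieved = _expected_icc(scale, item)
    if abs(achieved - item.icc) > tol:
        raise RuntimeError(
            f"ICC calibration for {item.name!r} off target: {achieved:.4f} vs {item.icc:.4f}"
        )
    _CALIBRATION_CACHE[key] = scale
    return scale


def simulate_questionnaires(
    latents: LatentTraits,
    model: TraitModel | None = None,
    k_distribution: tuple[float, ...] = DEFAULT_K_DISTRIBUTION,
    seed: int = 0,
    qc_violation_rate: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw repeated 24HR-style questionnaire records from the latent traits.

    Returns ``(questionnaires, covariates)``: a long-format table with one
    row per (individual, questionnaire) carrying QC fields plus per-item
    consumed indicators and quantities, and a per-individual covariate table
    (sex, age in months, assessment centre).

    ``qc_violation_rate`` is the per-rule probability that a record is made
    to fail one credibility filter (low/high energy, atypical diet, short
    duration, incomplete, recent pregnancy, recent cancer).
    """
    model = model if model is not None else latents.model
    k_dist = np.asarray(k_distribution, dtype=float)
    if k_dist.size == 0:
        raise ValueError("k_distribution must be non-empty")
    if abs(k_dist.sum() - 1.0) > 1e-8:
        raise ValueError("k_distribution must sum to 1")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    n = latents.liabilities.shape[0]
    ids = np.array([f"ind{i + 1}" for i in range(n)])

    k = rng.choice(np.arange(1, k_dist.size + 1), size=n, p=k_dist)
    row_iid = np.repeat(np.arange(n), k)
    n_rows = int(k.sum())
    qidx = np.concatenate([np.arange(1, ki + 1) for ki in k])

    # person effect per item: mixture of the item liability and person noise
    lw = model.latent_weight
    person_noise = rng.standard_normal(latents.liabilities.shape)
    effects = np.sqrt(lw) * latents.liabilities + np.sqrt(1.0 - lw) * person_noise

    sex = rng.integers(0, 2, size=n)  # 1 = male
    age_months = rng.integers(480, 829, size=n)
    center = rng.integers(0, 3, size=n)

    frame: dict[str, np.ndarray] = {
        "iid": ids[row_iid],
        "qidx": qidx,
        "energy_kj": np.clip(rng.normal(8000.0, 2500.0, n_rows), 1100.0, 17500.0),
        "typical_diet": np.ones(n_rows, dtype=np.int8),
        "completed": np.ones(n_rows, dtype=np.int8),
        "duration_min": np.clip(rng.lognormal(np.log(12.0), 0.4, n_rows), 5.5, 120.0),
        "hour": rng.integers(6, 23, size=n_rows),
        "weekend": rng.binomial(1, 3.0 / 7.0, size=n_rows).astype(np.int8),
        "pregnant_recent": np.zeros(n_rows, dtype=np.int8),
        "cancer_recent": np.zeros(n_rows, dtype=np.int8),
    }

    for t, item in enumerate(model.items):
        e_rows = effects[row_iid, t]
        if item.icc >= 1.0:
            # fully reliable item: response is a deterministic function of the person
            p_person = _sigmoid(_solve_mu(1.0, item.prevalence) + e_rows)
            consumed = (p_person >= 0.5).astype(np.int8)
            if item.kind == "quantity":
                lam = np.exp(np.minimum(np.log(item.mean_quantity) + 0.5 * e_rows, 20.0))
                qty = np.clip(np.round(lam), 1, item.max_count) * consumed
            else:
                qty = None
        else:
            scale = calibrate_item_scale(item)
            mu = _solve_mu(scale, item.prevalence)
            p = _sigmoid(mu + scale * e_rows)
            consumed = rng.binomial(1, p).astype(np.int8)
            if item.kind == "quantity":
                loglam = np.log(item.mean_quantity) + 0.5 * scale * e_rows
                # truncated Poisson on 1..max_count via inverse-CDF sampling
                pmf = _trunc_pois_pmf(loglam, item.max_count)
                cdf = np.cumsum(pmf, axis=1)
                u = rng.random(n_rows)
                draw = 1 + (u[:, None] > cdf).sum(axis=1)
                qty = np.minimum(draw, item.max_count) * consumed
            else:
                qty = None
        frame[f"{item.name}_consumed"] = consumed
        if qty is not None:
            frame[f"{item.name}_qty"] = qty.astype(float)

    q = pd.DataFrame(frame)

    # inject QC violations, one rule per affected record
    if qc_violation_rate > 0:
        sex_rows = sex[row_iid]
        masks = rng.random((7, n_rows)) < qc_violation_rate
        q.loc[masks[0], "energy_kj"] = 900.0
        q.loc[masks[1], "energy_kj"] = 21000.0
        q.loc[masks[2], "typical_diet"] = 0
        q.loc[masks[3], "duration_min"] = 4.0
        q.loc[masks[4], "completed"] = 0
        q.loc[masks[5] & (sex_rows == 0), "pregnant_recent"] = 1
        q.loc[masks[6], "cancer_recent"] = 1

    covars = pd.DataFrame(
        {"iid": ids, "sex": sex, "age_months": age_months, "center": center}
    )
    return q, covars


# ---------------------------------------------------------------------------
# TSV emission
# ---------------------------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, dosage_path, snpmap_path) -> None:
    """Write dosages (one row per individual, columns = SNP ids) and SNP map."""
    df = pd.DataFrame(g.dosages, columns=g.snps["id"], index=pd.Index(g.individuals, name="iid"))
    df.to_csv(dosage_path, sep="\t")
    g.snps.to_csv(snpmap_path, sep="\t", index=False)


def read_genotypes(dosage_path, snpmap_path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col="iid")
    snps = pd.read_csv(snpmap_path, sep="\t", dtype={"chr": str})
    return GenotypeMatrix(
        individuals=list(df.index),
        snps=snps,
        dosages=df.to_numpy(dtype=np.int8),
    )
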
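"""Standard study configurations and recovery experiments.

These functions freeze the simulation conditions the analysis is run and
validated under: the questionnaire completion-count distribution, the
40-item reliability benchmark (20 low-ICC vs 20 high-ICC consumption items),
and the parameter-recovery experiments for the shrinkage priors, the
heritability estimators and the intra-class correlation.

Every function takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

import numpy as np

from . import assoc, ebderive, herit, reliability, simdata
from .config import PipelineConfig, SimulationConfig
from .simdata import DEFAULT_COMPLETION_COUNTS

# conditions for the crude-vs-EB reliability benchmark: enough SNP blocks for
# usable LD-score regression estimates and enough individuals for the
# Haseman-Elston retention filter to detect h2_obs ~ 0.1 (see docs/methods.md)
BENCHMARK_N = 4_000
BENCHMARK_M = 8_000
BENCHMARK_H2 = 0.85


def completion_summary(counts: tuple[int, ...] = DEFAULT_COMPLETION_COUNTS) -> dict:
    """Cohort completion-count arithmetic implied by the k-distribution config.

    Returns the total number of individuals, the number completing at least
    two questionnaires and its percentage share.
    """
    total = int(sum(counts))
    repeat = int(sum(counts[1:]))
    return {
        "individuals": total,
        "repeat_individuals": repeat,
        "repeat_share_pct": 100.0 * repeat / total,
        "counts": {k + 1: int(c) for k, c in enumerate(counts)},
    }


def benchmark_items(seed: int, n_low: int = 20, n_high: int = 20,
                    low_icc: tuple[float, float] = (0.10, 0.20),
                    high_icc: tuple[float, float] = (0.70, 0.90)) -> list[dict]:
    """Item inventory for the reliability benchmark: low- vs high-ICC binary items."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    items = []
    for i in range(n_low):
        items.append({
            "name": f"lo{i}", "kind": "binary",
            "prevalence": float(rng.uniform(0.2, 0.7)),
            "icc": float(rng.uniform(*low_icc)),
        })
    for i in range(n_high):
        items.append({
            "name": f"hi{i}", "kind": "binary",
            "prevalence": float(rng.uniform(0.2, 0.7)),
            "icc": float(rng.uniform(*high_icc)),
        })
    return items


def benchmark_config(seed: int, output_dir: str = "results/benchmark") -> PipelineConfig:
    """Pipeline configuration for the 40-item reliability benchmark run."""
    return PipelineConfig(
        seed=seed,
        output_dir=output_dir,
        simulation=SimulationConfig(
            n_individuals=BENCHMARK_N,
            n_snps=BENCHMARK_M,
            h2=BENCHMARK_H2,
            n_causal=BENCHMARK_M // 2,
            items=benchmark_items(seed),
        ),
    )


def phenotype_inventory(seed: int, n_binary: int = 158, n_continuous: int = 243) -> list[dict]:
    """Item inventory matching the real questionnaire's variable counts.

    Prevalence and reliability are drawn from small grids so the ICC
    calibration cache keeps the simulation cheap even at 401 items.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 8]))
    prev_grid = (0.15, 0.3, 0.5, 0.7)
    icc_grid = (0.15, 0.3, 0.5, 0.7)
    items = []
    for i in range(n_binary):
        items.append({
            "name": f"bin{i}", "kind": "binary",
            "prevalence": float(rng.choice(prev_grid)),
            "icc": float(rng.choice(icc_grid)),
        })
    for i in range(n_continuous):
        items.append({
            "name": f"qty{i}", "kind": "quantity",
            "prevalence": float(rng.choice(prev_grid)),
            "icc": float(rng.choice(icc_grid)),
        })
    return items


def derive_full_inventory(seed: int, n_individuals: int = 400) -> tuple[int, int, int]:
    """Derive phenotypes for the full 158 binary + 243 continuous inventory.

    Returns (n_binary, n_continuous, phenotype column count). Everyone takes
    all five questionnaires so the derivation exercises the complete grid of
    crude proportions.
    """
    item_dicts = phenotype_inventory(seed)
    items = [simdata.ItemSpec(**d) for d in item_dicts]
    g = simdata.simulate_genotypes(n_individuals, 20, seed=seed)
    model = simdata.TraitModel(h2=0.3, n_causal=10, items=items, seed=seed)
    lat = simdata.simulate_latent_traits(g, model)
    q, _ = simdata.simulate_questionnaires(
        lat, model, k_distribution=(0, 0, 0, 0, 1), seed=seed, qc_violation_rate=0.0
    )
    binary = [it.name for it in items if it.kind == "binary"]
    quantity = [it.name for it in items if it.kind == "quantity"]
    pheno, _ = ebderive.build_phenotype_table(q, binary, quantity, min_interior=20)
    n_cols = len([c for c in pheno.columns if c != "k"])
    return len(binary), len(quantity), n_cols


def zoib_recovery(seed: int, n: int = 20_000, alpha: float = 2.0, beta: float = 5.0,
                  frac_zero: float = 0.20, frac_one: float = 0.05) -> ebderive.BetaPrior:
    """Fit the zero-one-inflated beta to draws with a known interior Beta(alpha, beta)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9]))
    n_zero = int(frac_zero * n)
    n_one = int(frac_one * n)
    interior = rng.beta(alpha, beta, size=n - n_zero - n_one)
    x = np.concatenate([np.zeros(n_zero), np.ones(n_one), interior])
    return ebderive.fit_zoib(x)


def dm_recovery(seed: int, n: int = 20_000,
                alpha: tuple[float, ...] = (1.0, 2.0, 3.0)) -> ebderive.DMPrior:
    """Fit the Dirichlet-multinomial to counts drawn from a known concentration."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
    alpha_arr = np.asarray(alpha, dtype=float)
    k = rng.integers(1, 6, size=n)
    p = rng.dirichlet(alpha_arr, size=n)
    counts = np.vstack([rng.multinomial(k[i], p[i]) for i in range(n)])
    return ebderive.fit_dirichlet_multinomial(counts, np.arange(len(alpha), dtype=float))


def simulate_liability_gwas(seed: int, n: int = 2_000, m: int = 2_000, h2: float = 0.25,
                            n_causal: int | None = None):
    """One replicate: genotypes, a liability with known h2, its GWAS and LD scores."""
    n_causal = n_causal if n_causal is not None else m // 2
    g = simdata.simulate_genotypes(n, m, seed=seed, rho_range=(0.1, 0.95))
    item = simdata.ItemSpec("trait", "binary", 0.5, 0.5)
    model = simdata.TraitModel(h2=h2, n_causal=n_causal, items=[item], seed=seed + 1)
    lat = simdata.simulate_latent_traits(g, model)
    y = lat.liabilities[:, 0]
    ss = assoc.run_gwas(y, g, None)
    ld = herit.compute_ld_scores(g, 500_000)
    return g, y, ss, ld


def h2_recovery(seed: int, n_ldsc: int = 50, n_he: int = 20,
                n: int = 2_000, m: int = 2_000, h2: float = 0.25) -> dict:
    """Replicate means of the LDSC and Haseman-Elston estimators at known h2."""
    base = int(np.random.SeedSequence([seed, 11]).generate_state(1)[0] % (2**30))
    ldsc_vals, he_vals = [], []
    for rep in range(n_ldsc):
        g, y, ss, ld = simulate_liability_gwas(base + rep, n=n, m=m, h2=h2)
        ldsc_vals.append(herit.ldsc_h2(ss, ld, m=m).h2)
        if rep < n_he:
            he_vals.append(herit.he_regression(y, g).h2)
    ldsc_arr, he_arr = np.asarray(ldsc_vals), np.asarray(he_vals)
    return {
        "truth": h2,
        "ldsc_mean": float(ldsc_arr.mean()),
        "ldsc_mcse": float(ldsc_arr.std(ddof=1) / np.sqrt(len(ldsc_arr))),
        "he_mean": float(he_arr.mean()),
        "he_mcse": float(he_arr.std(ddof=1) / np.sqrt(len(he_arr))),
    }


def icc_recovery(seed: int, n_subjects: int = 2_000, n_ratings: int = 5,
                 sigma2_between: float = 1.0, sigma2_within: float = 1.0) -> dict:
    """One-way ICC on a known variance-components simulation; closed-form target."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
    b = rng.normal(0.0, np.sqrt(sigma2_between), size=(n_subjects, 1))
    e = rng.normal(0.0, np.sqrt(sigma2_within), size=(n_subjects, n_ratings))
    est = reliability.icc_oneway(b + e)
    return {
        "icc": est.icc,
        "target": sigma2_between / (sigma2_between + sigma2_within),
    }
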
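"""End-to-end orchestration: simulate -> qc -> derive -> icc -> gwas -> h2 -> benchmark.

Every stage consumes and produces plain tab-separated tables under the
configured output directory and logs its input/output row counts; a manifest
of all written files (with row counts) is returned and saved. All randomness
descends from the single top-level seed through named per-stage substreams,
so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, benchmark, ebderive, herit, qc, reliability, simdata
from .config import PipelineConfig

logger = logging.getLogger(__name__)

# fixed substream labels so stage randomness is independent of stage order
_STREAM = {"genotypes": 11, "traits": 12, "questionnaires": 13}


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, _STREAM[stage]]).generate_state(1)[0] % (2**31))


def derived_covariates(records: pd.DataFrame, covars: pd.DataFrame,
                       g: simdata.GenotypeMatrix) -> pd.DataFrame:
    """Per-individual covariate table for the genetic model.

    Sex, age in months and its square, assessment centre (factor), proportion
    of questionnaires on a weekend, mean completion duration winsorized at
    25 min, number of questionnaires taken, and the top two genotype
    principal components.
    """
    per = records.groupby("iid").agg(
        weekend_prop=("weekend", "mean"),
        duration_w25=("duration_min", lambda s: np.minimum(s, 25.0).mean()),
        n_quest=("qidx", "size"),
    )
    out = covars.set_index("iid").join(per, how="inner")
    out["age_sq"] = out["age_months"].astype(float) ** 2

    z = g.standardized()
    # top-2 genotype PCs via the eigenvectors of the sample covariance
    u, s, _ = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    pcs = pd.DataFrame(u[:, :2] * s[:2], index=pd.Index(g.individuals, name="iid"),
                       columns=["pc1", "pc2"])
    out = out.join(pcs, how="inner")
    return out.reset_index()


def _pheno_long_name(col: str) -> tuple[str, str, str] | None:
    """Map a phenotype column to (pair key, class, version) or None for non-phenotypes."""
    for suffix, cls, ver in (
        ("_crude_prop", "proportion", "crude"),
        ("_eb_prop", "proportion", "eb"),
        ("_crude_avg", "average", "crude"),
        ("_eb_avg", "average", "eb"),
    ):
        if col.endswith(suffix):
            base = col[: -len(suffix)]
            key = f"{base}_prop" if cls == "proportion" else f"{base}_avg"
            return key, cls, ver
    return None


def run_all(cfg: PipelineConfig) -> dict:
    """Run the full pipeline; returns {'manifest': ..., 'summary': ...}."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=index)
        manifest.append({"file": name, "rows": len(df)})
        logger.info("[%s] wrote %d rows", name, len(df))

    sim = cfg.simulation
    items = sim.item_specs()
    if not items:
        raise ValueError("derivation stage: config declares zero items")

    # --- simulate -----------------------------------------------------------
    g = simdata.simulate_genotypes(
        sim.n_individuals, sim.n_snps, sim.maf_range, sim.ld_rho,
        seed=_stage_seed(cfg.seed, "genotypes"),
        rho_range=sim.rho_range, block_snps=sim.block_snps,
    )
    model = simdata.TraitModel(h2=sim.h2, n_causal=sim.n_causal, items=items,
                               seed=_stage_seed(cfg.seed, "traits"))
    latents = simdata.simulate_latent_traits(g, model)
    records, covars = simdata.simulate_questionnaires(
        latents, model, sim.k_distribution,
        seed=_stage_seed(cfg.seed, "questionnaires"),
        qc_violation_rate=sim.qc_violation_rate,
    )
    simdata.write_genotypes(g, out_dir / "genotypes.tsv", out_dir / "snps.tsv")
    manifest.append({"file": "genotypes.tsv", "rows": g.n_individuals})
    manifest.append({"file": "snps.tsv", "rows": g.n_snps})
    emit(records, "questionnaires_raw.tsv")
    emit(covars, "covariates.tsv")
    truth = {
        "h2": sim.h2,
        "icc": {it.name: it.icc for it in items},
        "causal_snps": latents.causal_snps,
    }
    (out_dir / "ground_truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))

    # --- qc -----------------------------------------------------------------
    sex = covars.set_index("iid")["sex"]
    kept, report = qc.filter_questionnaires(records, sex, cfg.qc)
    logger.info("[qc] %d -> %d records (%d individuals)",
                report.records_in, report.records_out, report.individuals_out)
    emit(report.to_frame(), "qc_report.tsv")
    emit(kept, "questionnaires_qc.tsv")

    # --- derive -------------------------------------------------------------
    binary_items = [it.name for it in items if it.kind == "binary"]
    quantity_items = [it.name for it in items if it.kind == "quantity"]
    pheno, fitted = ebderive.build_phenotype_table(
        kept, binary_items, quantity_items,
        donor_map=cfg.derivation.donor_map,
        category_precision=cfg.derivation.category_precision,
        min_interior=cfg.derivation.min_interior,
    )
    emit(pheno, "phenotypes.tsv", index=True)
    priors = pd.DataFrame(
        [
            {
                "item": name,
                "alpha": ip.beta_prior.alpha,
                "beta": ip.beta_prior.beta,
                "p0": ip.beta_prior.p0,
                "p1": ip.beta_prior.p1,
                "converged": ip.beta_prior.converged,
                "donor": ip.beta_prior.donor_item or "",
            }
            for name, ip in fitted.items()
        ]
    )
    emit(priors, "beta_priors.tsv")

    # --- icc ----------------------------------------------------------------
    raw_cols = [f"{n}_consumed" for n in binary_items + quantity_items]
    raw_cols += [f"{n}_qty" for n in quantity_items]
    n_ratings = reliability.max_feasible_ratings(kept, cap=len(sim.k_distribution))
    icc_raw = reliability.icc_table(kept, raw_cols, n_ratings=n_ratings)
    logger.info("[icc] using %d ratings per subject", n_ratings)
    emit(icc_raw, "icc.tsv")

    # --- gwas + h2 ----------------------------------------------------------
    pheno_aligned = pheno.reindex(g.individuals).dropna()
    sub_idx = [g.individuals.index(i) for i in pheno_aligned.index]
    g_sub = simdata.GenotypeMatrix(
        individuals=list(pheno_aligned.index), snps=g.snps, dosages=g.dosages[sub_idx]
    )
    cov_table = derived_covariates(kept, covars, g_sub)
    cov_table = cov_table.set_index("iid").reindex(pheno_aligned.index).reset_index()
    design = assoc.build_covariate_design(cov_table)

    ld = herit.compute_ld_scores(g_sub, window_bp=cfg.genetics.window_bp)
    pheno_cols = [c for c in pheno_aligned.columns if _pheno_long_name(c)]
    scans = assoc.run_gwas_many(
        pheno_aligned[pheno_cols], g_sub, design,
        cfg.genetics.maf_min, cfg.genetics.mac_min, cfg.genetics.miss_max,
    )
    # LDSC point estimates drive the crude-vs-EB comparison; the retention
    # filter uses the individual-level Haseman-Elston Wald test, which has
    # far more power at this sample size than summary-statistic LDSC
    grm = herit.genomic_relationship_matrix(g_sub)
    estimates = []
    loci_frames = []
    for col, ss in scans.items():
        key, cls, ver = _pheno_long_name(col)
        est = herit.ldsc_h2(ss, ld, m=g_sub.n_snps, phenotype=col)
        yres = assoc.residualize(pheno_aligned[col].to_numpy(float), design)
        he = herit.he_regression(yres, g_sub, grm=grm, phenotype_id=col)
        estimates.append({"item": key, "class": cls, "version": ver,
                          "h2": est.h2, "se": est.se, "p_ldsc": est.p,
                          "h2_he": he.h2, "se_he": he.se, "p": he.p})
        loci_frames.append(benchmark.clump_loci(
            ss, cfg.genetics.p_threshold, cfg.genetics.window_bp,
            phenotype=key, version=ver,
        ))
    h2_long = pd.DataFrame(estimates)
    emit(h2_long, "h2.tsv")
    nonempty = [f for f in loci_frames if len(f)]
    loci = pd.concat(nonempty, ignore_index=True) if nonempty else loci_frames[0]
    emit(loci, "loci.tsv")

    # --- benchmark ----------------------------------------------------------
    meff = benchmark.effective_tests(
        pheno_aligned[pheno_cols].to_numpy(float), design,
        method=cfg.genetics.meff_method,
    )
    retained = benchmark.significance_filter(h2_long, meff.threshold)

    # raw-item ICC keyed to the phenotype pair it validates
    icc_pairs = []
    for name in binary_items + quantity_items:
        row = icc_raw.loc[icc_raw["item"] == f"{name}_consumed", "icc"]
        icc_pairs.append({"item": f"{name}_prop", "icc": float(row.iloc[0])})
    for name in quantity_items:
        row = icc_raw.loc[icc_raw["item"] == f"{name}_qty", "icc"]
        icc_pairs.append({"item": f"{name}_avg", "icc": float(row.iloc[0])})
    icc_df = pd.DataFrame(icc_pairs)

    summary: dict = {
        "meff": meff.meff,
        "threshold": meff.threshold,
        "n_phenotypes": len(pheno_cols),
        "n_retained_pairs": len(retained),
    }
    if len(retained):
        comparison, comp_summary = benchmark.compare_versions(retained, icc_df)
        emit(comparison, "comparison.tsv")
        summary["comparison"] = dataclasses.asdict(comp_summary)
        crude_loci = loci[loci["version"] == "crude"]
        eb_loci = loci[loci["version"] == "eb"]
        # concordance uses every phenotype with loci, not only retained pairs
        h2_wide = h2_long.pivot(index="item", columns="version", values="h2")
        h2_wide.columns = [f"h2_{v}" for v in h2_wide.columns]
        conc = benchmark.locus_concordance(
            crude_loci, eb_loci, h2_wide.reset_index(), window_bp=cfg.genetics.window_bp
        )
        summary["locus_concordance"] = {
            "n_windows": conc.n_windows,
            "n_concordant": conc.n_concordant,
            "fraction": conc.fraction,
            "fraction_top25": conc.fraction_top25,
            "fraction_top10": conc.fraction_top10,
        }

    manifest_df = pd.DataFrame(manifest)
    manifest_df.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    (out_dir / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))
    return {"manifest": manifest, "summary": summary}
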
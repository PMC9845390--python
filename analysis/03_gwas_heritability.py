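"""GWAS every phenotype version and estimate SNP heritability two ways.

Each crude/EB phenotype column is residualised on the covariate design (sex,
age, age^2, centre, weekend share, winsorized duration, questionnaire count,
two genotype PCs) and scanned SNP-by-SNP; heritability comes from LD-score
regression on the resulting chi-squares (in-sample LD scores, 500 kb window)
and, as the individual-level benchmark used for the significance filter,
from Haseman-Elston regression. Genome-wide significant loci are clumped in
+-500 kb windows.
"""

import argparse
from pathlib import Path

import pandas as pd

from dietherit import assoc, benchmark, herit, simdata
from dietherit.config import load_config
from dietherit.pipeline import _pheno_long_name, derived_covariates


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--derived", default="results/derived")
    ap.add_argument("--out", default="results/genetics")
    args = ap.parse_args()

    data, derived, out = Path(args.data), Path(args.derived), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_config(data / "config.yaml")
    gen = cfg.genetics

    g = simdata.read_genotypes(data / "genotypes.tsv", data / "snps.tsv")
    pheno = pd.read_csv(derived / "phenotypes.tsv", sep="\t", index_col="iid")
    kept = pd.read_csv(derived / "questionnaires_qc.tsv", sep="\t")
    covars = pd.read_csv(data / "covariates.tsv", sep="\t")

    pheno = pheno.reindex(g.individuals).dropna()
    idx = [g.individuals.index(i) for i in pheno.index]
    g = simdata.GenotypeMatrix(list(pheno.index), g.snps, g.dosages[idx])
    cov = derived_covariates(kept, covars, g).set_index("iid").reindex(pheno.index)
    design = assoc.build_covariate_design(cov.reset_index())

    ld = herit.compute_ld_scores(g, window_bp=gen.window_bp)
    cols = [c for c in pheno.columns if _pheno_long_name(c)]
    scans = assoc.run_gwas_many(pheno[cols], g, design,
                                gen.maf_min, gen.mac_min, gen.miss_max)
    grm = herit.genomic_relationship_matrix(g)

    rows, loci = [], []
    for col, ss in scans.items():
        key, cls, ver = _pheno_long_name(col)
        est = herit.ldsc_h2(ss, ld, m=g.n_snps, phenotype=col)
        he = herit.he_regression(
            assoc.residualize(pheno[col].to_numpy(float), design), g,
            grm=grm, phenotype_id=col,
        )
        rows.append({"item": key, "class": cls, "version": ver,
                     "h2": est.h2, "se": est.se, "p_ldsc": est.p,
                     "h2_he": he.h2, "se_he": he.se, "p": he.p})
        loci.append(benchmark.clump_loci(ss, gen.p_threshold, gen.window_bp,
                                         phenotype=key, version=ver))
    h2 = pd.DataFrame(rows)
    h2.to_csv(out / "h2.tsv", sep="\t", index=False)
    nonempty = [f for f in loci if len(f)]
    loci_df = pd.concat(nonempty, ignore_index=True) if nonempty else loci[0]
    loci_df.to_csv(out / "loci.tsv", sep="\t", index=False)

    print(f"scanned {len(cols)} phenotypes x {len(ld)} SNPs")
    by = h2.groupby("version")[["h2", "h2_he"]].mean()
    print("mean h2 by version (LDSC / HE):")
    print(by.round(3).to_string())
    print(f"{len(loci_df)} genome-wide significant loci across all scans")


if __name__ == "__main__":
    main()
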
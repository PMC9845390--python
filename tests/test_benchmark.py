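"""Effective tests, significance filtering, winners, clumping, concordance."""

import numpy as np
import pandas as pd
import pytest

from dietherit.benchmark import (
    clump_loci,
    compare_versions,
    effective_tests,
    locus_concordance,
    significance_filter,
)


class TestEffectiveTests:
    def test_identity_correlation_gives_m(self):
        res = effective_tests(correlation=np.eye(10))
        assert res.meff == pytest.approx(10.0, abs=1e-12)
        assert res.threshold == pytest.approx(0.005)

    def test_duplicated_blocks_give_block_count(self):
        # 5 independent traits each duplicated: eigenvalues are five 2s, five 0s
        base = np.eye(5)
        corr = np.kron(base, np.ones((2, 2)))
        np.fill_diagonal(corr, 1.0)
        res = effective_tests(correlation=corr)
        assert res.meff == pytest.approx(5.0, abs=1e-10)

    def test_ar1_matches_independent_eigen_formula(self):
        m, rho = 20, 0.9
        corr = rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        res = effective_tests(correlation=corr)
        lam = np.linalg.eigvalsh(corr)
        lam = np.clip(lam, 0, None)
        expected = np.sqrt(lam).sum() ** 2 / lam.sum()
        assert res.meff == pytest.approx(expected, abs=1e-8)

    def test_li_ji_on_identity(self):
        res = effective_tests(correlation=np.eye(7), method="li_ji")
        assert res.meff == pytest.approx(7.0)

    def test_covariate_adjustment_removes_shared_signal(self, rng):
        n = 500
        shared = rng.standard_normal(n)
        x = np.column_stack([shared + 0.1 * rng.standard_normal(n) for _ in range(6)])
        raw = effective_tests(x)
        adj = effective_tests(x, covariates=shared[:, None])
        assert raw.meff < 2.0
        assert adj.meff > 4.0

    def test_duplicating_every_column_leaves_galwey_meff_unchanged(self, rng):
        # eigenvalues double and zeros appear, so (sum sqrt)^2/sum is invariant
        x = rng.standard_normal((200, 5))
        single = effective_tests(x)
        doubled = effective_tests(np.hstack([x, x]))
        assert doubled.meff == pytest.approx(single.meff, abs=1e-6)

    def test_threshold_matches_printed_arithmetic(self):
        from dietherit.benchmark import MeffResult
        res = MeffResult(m_observed=302, eigenvalues=np.array([]),
                         meff=46.1, method="galwey")
        assert res.threshold == pytest.approx(0.00108, abs=5e-6)


class TestSignificanceFilter:
    def _h2(self, rows):
        return pd.DataFrame(rows, columns=["item", "class", "version", "h2", "se", "p"])

    def test_one_significant_version_retains_pair(self):
        h2 = self._h2([
            ("tea_prop", "proportion", "crude", 0.05, 0.02, 0.1),
            ("tea_prop", "proportion", "eb", 0.08, 0.02, 0.0005),
            ("jam_prop", "proportion", "crude", 0.01, 0.02, 0.4),
            ("jam_prop", "proportion", "eb", 0.01, 0.02, 0.5),
        ])
        kept = significance_filter(h2, threshold=0.00108)
        assert kept["item"].tolist() == ["tea_prop"]

    def test_missing_partner_version_rejected(self):
        h2 = self._h2([("tea_prop", "proportion", "crude", 0.05, 0.02, 0.1)])
        with pytest.raises(ValueError):
            significance_filter(h2, threshold=0.01)


class TestCompareVersions:
    def _retained(self, h2_pairs):
        rows = []
        for i, (hc, he) in enumerate(h2_pairs):
            rows.append({"item": f"it{i}", "class": "proportion",
                         "h2_crude": hc, "h2_eb": he,
                         "se_crude": 0.01, "se_eb": 0.01,
                         "p_crude": 1e-5, "p_eb": 1e-5})
        return pd.DataFrame(rows)

    def test_tie_and_counting(self):
        pairs = [(0.1, 0.1)] + [(0.1, 0.2)] * 6 + [(0.2, 0.1)]
        retained = self._retained(pairs)
        icc = pd.DataFrame({"item": retained["item"],
                            "icc": np.linspace(0.1, 0.9, len(retained))})
        table, summary = compare_versions(retained, icc)
        assert (table["winner"] == "equal").sum() == 1
        assert summary.eb_win_rate == pytest.approx(6 / 8)

    def test_quartile_counts_partition_retained_set(self, rng):
        n = 17
        retained = self._retained([(rng.random(), rng.random()) for _ in range(n)])
        icc = pd.DataFrame({"item": retained["item"], "icc": rng.random(n)})
        _, summary = compare_versions(retained, icc)
        assert sum(summary.counts_by_quartile["proportion"].values()) == n

    def test_missing_icc_rejected(self):
        retained = self._retained([(0.1, 0.2)])
        with pytest.raises(ValueError, match="ICC"):
            compare_versions(retained, pd.DataFrame({"item": [], "icc": []}))


def brute_force_clump(ss, p_threshold, window_bp):
    """Re-scan oracle: repeatedly find the global best remaining SNP."""
    sig = ss[ss["P"] < p_threshold].copy()
    sig["CHR"] = sig["CHR"].astype(str)
    leads = []
    while len(sig):
        sig = sig.sort_values(["P", "CHR", "BP", "SNP"], kind="mergesort")
        lead = sig.iloc[0]
        leads.append(lead["SNP"])
        near = (sig["CHR"] == lead["CHR"]) & (np.abs(sig["BP"] - lead["BP"]) <= window_bp)
        sig = sig[~near]
    return leads


class TestClumpLoci:
    def _ss(self, bps, ps, chrom="1"):
        return pd.DataFrame({
            "SNP": [f"s{i}" for i in range(len(bps))],
            "CHR": chrom, "BP": bps, "P": ps,
        })

    def test_window_distance_forces_locus_count(self):
        near = self._ss([1_000_000, 1_100_000], [1e-9, 1e-10])
        far = self._ss([1_000_000, 1_600_000], [1e-9, 1e-10])
        assert len(clump_loci(near)) == 1
        assert len(clump_loci(far)) == 2

    def test_no_significant_snps_gives_empty_list(self):
        ss = self._ss([1000, 2000], [0.5, 1e-7])
        assert clump_loci(ss).empty

    def test_matches_brute_force_rescan(self, rng):
        bps = rng.choice(np.arange(1, 5_000) * 1_000, size=50, replace=False)
        ps = 10.0 ** rng.uniform(-30, -8, size=50)
        ss = self._ss(sorted(bps), ps)
        mine = clump_loci(ss)["lead_snp"].tolist()
        assert mine == brute_force_clump(ss, 5e-8, 500_000)

    def test_row_order_invariance(self, rng):
        bps = rng.choice(np.arange(1, 2_000) * 1_000, size=30, replace=False)
        ps = 10.0 ** rng.uniform(-20, -8, size=30)
        ss = self._ss(list(bps), list(ps))
        base = clump_loci(ss)
        shuffled = clump_loci(ss.sample(frac=1.0, random_state=3))
        pd.testing.assert_frame_equal(base, shuffled)

    def test_lead_snp_has_smallest_p(self, rng):
        bps = np.arange(1, 40) * 50_000
        ps = 10.0 ** rng.uniform(-15, -8, size=39)
        loci = clump_loci(self._ss(list(bps), list(ps)))
        assert loci["lead_p"].iloc[0] == ps.min()


class TestLocusConcordance:
    def _loci(self, rows, version):
        return pd.DataFrame([
            {"lead_snp": f"{version}{i}", "chr": "1", "bp": bp, "lead_p": p,
             "phenotype": item, "version": version,
             "window_lo": bp - 500_000, "window_hi": bp + 500_000}
            for i, (item, bp, p) in enumerate(rows)
        ])

    def test_counting_three_of_four(self):
        # crude is the more heritable version for every item
        h2 = pd.DataFrame({
            "item": [f"it{i}" for i in range(4)],
            "h2_crude": [0.3] * 4, "h2_eb": [0.1] * 4,
        })
        crude = self._loci([(f"it{i}", 10_000_000 * (i + 1), 1e-12) for i in range(3)]
                           + [("it3", 40_000_000, 1e-9)], "crude")
        eb = self._loci([(f"it{i}", 10_000_000 * (i + 1), 1e-10) for i in range(3)]
                        + [("it3", 40_000_000, 1e-12)], "eb")
        rep = locus_concordance(crude, eb, h2)
        assert rep.n_windows == 4
        assert rep.fraction == pytest.approx(0.75)

    def test_all_concordant(self):
        h2 = pd.DataFrame({"item": ["a"], "h2_crude": [0.1], "h2_eb": [0.4]})
        crude = self._loci([("a", 1_000_000, 1e-9)], "crude")
        eb = self._loci([("a", 1_000_000, 1e-15)], "eb")
        assert locus_concordance(crude, eb, h2).fraction == 1.0

    def test_zero_loci_reports_absent_fractions(self):
        h2 = pd.DataFrame({"item": [], "h2_crude": [], "h2_eb": []})
        empty = self._loci([], "crude")
        rep = locus_concordance(empty, empty, h2)
        assert rep.n_windows == 0
        assert rep.fraction is None and rep.fraction_top25 is None

    def test_percent_difference_stratification_matches_hand_oracle(self, rng):
        # 20 windows, one per item; concordance by construction alternates
        items = [f"it{i}" for i in range(20)]
        h2c = rng.uniform(0.1, 0.5, size=20)
        h2e = rng.uniform(0.1, 0.5, size=20)
        h2 = pd.DataFrame({"item": items, "h2_crude": h2c, "h2_eb": h2e})
        crude_p = 10.0 ** rng.uniform(-20, -9, 20)
        eb_p = 10.0 ** rng.uniform(-20, -9, 20)
        crude = self._loci([(it, 2_000_000 * (i + 1), crude_p[i])
                            for i, it in enumerate(items)], "crude")
        eb = self._loci([(it, 2_000_000 * (i + 1), eb_p[i])
                         for i, it in enumerate(items)], "eb")
        rep = locus_concordance(crude, eb, h2)

        pct = np.abs(h2c - h2e) / (0.5 * (np.abs(h2c) + np.abs(h2e)))
        stronger = np.where(crude_p < eb_p, "crude", "eb")
        better = np.where(h2c > h2e, "crude", "eb")
        conc = stronger == better
        assert rep.n_windows == 20
        assert rep.fraction == pytest.approx(conc.mean())
        cut = np.quantile(pct, 0.75)
        assert rep.fraction_top25 == pytest.approx(conc[pct >= cut].mean())
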
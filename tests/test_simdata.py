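"""Generator behaviour: LD structure, trait variance shares, ICC calibration."""

import numpy as np
import pandas as pd
import pytest

from dietherit import simdata
from dietherit.reliability import icc_oneway


def adjacent_r2(g: simdata.GenotypeMatrix) -> np.ndarray:
    z = g.standardized()
    n = g.n_individuals
    r = np.einsum("ij,ij->j", z[:, :-1], z[:, 1:]) / n
    return r**2


class TestSimulateGenotypes:
    def test_dosages_in_range_and_freqs_match(self):
        g = simdata.simulate_genotypes(10_000, 1, maf_range=(0.5, 0.5), seed=5)
        assert set(np.unique(g.dosages)) <= {0, 1, 2}
        assert abs(g.allele_freqs()[0] - 0.5) < 0.02

    def test_positions_strictly_increasing(self, small_genotypes):
        bp = small_genotypes.snps["bp"].to_numpy()
        assert np.all(np.diff(bp) > 0)

    def test_independent_snps_have_null_adjacent_r2(self):
        n = 5_000
        g = simdata.simulate_genotypes(n, 200, ld_rho=0.0, seed=7)
        # null r^2 expectation is ~1/n for independent sites
        mean_r2 = adjacent_r2(g).mean()
        assert mean_r2 < 5.0 / n

    def test_ld_decay_with_positive_rho(self):
        g = simdata.simulate_genotypes(3_000, 200, ld_rho=0.9, seed=8)
        assert adjacent_r2(g).mean() > 0.3

    def test_same_seed_bit_identical(self):
        a = simdata.simulate_genotypes(50, 40, seed=3, rho_range=(0.2, 0.9))
        b = simdata.simulate_genotypes(50, 40, seed=3, rho_range=(0.2, 0.9))
        assert np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.snps, b.snps)

    @pytest.mark.parametrize("kwargs", [
        {"n_individuals": 1},
        {"maf_range": (0.0, 0.5)},
        {"maf_range": (0.1, 0.6)},
        {"ld_rho": 1.0},
        {"rho_range": (0.5, 1.0)},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        base = {"n_individuals": 10, "n_snps": 5}
        base.update(kwargs)
        with pytest.raises(ValueError):
            simdata.simulate_genotypes(**base)

    def test_roundtrip_tsv(self, tmp_path):
        g = simdata.simulate_genotypes(20, 10, seed=1)
        simdata.write_genotypes(g, tmp_path / "d.tsv", tmp_path / "s.tsv")
        back = simdata.read_genotypes(tmp_path / "d.tsv", tmp_path / "s.tsv")
        assert np.array_equal(back.dosages, g.dosages)
        assert back.individuals == g.individuals


class TestLatentTraits:
    def _model(self, h2, items=None, seed=0):
        items = items or [simdata.ItemSpec("x", "binary", 0.5, 0.5)]
        return simdata.TraitModel(h2=h2, n_causal=100, items=items, seed=seed)

    def test_h2_one_means_no_noise(self, small_genotypes):
        lat = simdata.simulate_latent_traits(small_genotypes, self._model(1.0))
        assert np.allclose(lat.liabilities, lat.genetic_values)
        assert abs(lat.genetic_values[:, 0].var() - 1.0) < 1e-9

    def test_h2_zero_liability_independent_of_genotype(self, small_genotypes):
        lat = simdata.simulate_latent_traits(small_genotypes, self._model(0.0))
        assert np.allclose(lat.genetic_values, 0.0)
        z = small_genotypes.standardized()
        r = z.T @ lat.liabilities[:, 0] / small_genotypes.n_individuals
        # correlations with every SNP at null scale ~ 1/sqrt(n)
        assert np.abs(r).max() < 6.0 / np.sqrt(small_genotypes.n_individuals)

    def test_variance_partition(self, small_genotypes):
        lat = simdata.simulate_latent_traits(small_genotypes, self._model(0.25))
        assert abs(lat.genetic_values[:, 0].var() - 0.25) < 1e-9
        assert abs(lat.liabilities[:, 0].var() - 1.0) < 0.05

    def test_n_causal_exceeding_snps_rejected(self, small_genotypes):
        model = simdata.TraitModel(
            h2=0.5, n_causal=10**6, items=[simdata.ItemSpec("x")], seed=0)
        with pytest.raises(ValueError):
            simdata.simulate_latent_traits(small_genotypes, model)

    def test_h2_above_one_rejected(self):
        with pytest.raises(ValueError):
            simdata.TraitModel(h2=1.5, n_causal=10, items=[], seed=0)


class TestQuestionnaires:
    @pytest.fixture(scope="class")
    def latents(self):
        g = simdata.simulate_genotypes(2_500, 60, seed=21)
        items = [
            simdata.ItemSpec("bread", "binary", prevalence=0.5, icc=0.5),
            simdata.ItemSpec("coffee", "quantity", prevalence=0.6, icc=0.5),
            simdata.ItemSpec("oats", "quantity", prevalence=0.4, icc=1.0),
        ]
        model = simdata.TraitModel(h2=0.4, n_causal=30, items=items, seed=22)
        return simdata.simulate_latent_traits(g, model), model

    def test_forced_k_gives_five_rows_each(self, latents):
        lat, model = latents
        q, _ = simdata.simulate_questionnaires(
            lat, model, k_distribution=(0, 0, 0, 0, 1), seed=1, qc_violation_rate=0)
        assert (q.groupby("iid").size() == 5).all()
        assert (q.groupby("iid")["qidx"].nunique() == 5).all()

    def test_quantity_zero_when_not_consumed(self, latents):
        lat, model = latents
        q, _ = simdata.simulate_questionnaires(lat, model, seed=2)
        mask = q["coffee_consumed"] == 0
        assert (q.loc[mask, "coffee_qty"] == 0).all()
        assert (q.loc[~mask, "coffee_qty"] >= 1).all()

    def test_perfect_icc_item_repeats_identically(self, latents):
        lat, model = latents
        q, _ = simdata.simulate_questionnaires(
            lat, model, k_distribution=(0, 0, 0, 0, 1), seed=3, qc_violation_rate=0)
        per = q.groupby("iid")["oats_qty"].nunique()
        assert (per == 1).all()

    def test_realized_icc_matches_target(self, latents):
        lat, model = latents
        q, _ = simdata.simulate_questionnaires(
            lat, model, k_distribution=(0, 0, 0, 0, 1), seed=4, qc_violation_rate=0)
        for col in ("bread_consumed", "coffee_qty"):
            mat = q.sort_values(["iid", "qidx"])[col].to_numpy(float).reshape(-1, 5)
            assert abs(icc_oneway(mat).icc - 0.5) < 0.05

    def test_default_k_distribution_matches_cohort_counts(self, latents):
        lat, model = latents
        q, _ = simdata.simulate_questionnaires(lat, model, seed=5)
        k = q.groupby("iid").size()
        share_repeat = (k >= 2).mean()
        assert abs(share_repeat - 0.5415) < 0.04

    def test_qc_violations_injected(self, latents):
        lat, model = latents
        q, _ = simdata.simulate_questionnaires(lat, model, seed=6, qc_violation_rate=0.05)
        assert (q["energy_kj"] < 1000).any()
        assert (q["duration_min"] < 5).any()
        assert (q["completed"] == 0).any()

    def test_determinism(self, latents):
        lat, model = latents
        q1, c1 = simdata.simulate_questionnaires(lat, model, seed=9)
        q2, c2 = simdata.simulate_questionnaires(lat, model, seed=9)
        pd.testing.assert_frame_equal(q1, q2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_empty_k_distribution_rejected(self, latents):
        lat, model = latents
        with pytest.raises(ValueError):
            simdata.simulate_questionnaires(lat, model, k_distribution=(), seed=0)


class TestCalibration:
    @pytest.mark.parametrize("kind", ["binary", "quantity"])
    @pytest.mark.parametrize("target", [0.05, 0.3, 0.6, 0.9])
    def test_expected_icc_hits_target(self, kind, target):
        item = simdata.ItemSpec("x", kind, prevalence=0.35, icc=target)
        scale = simdata.calibrate_item_scale(item)
        assert abs(simdata._expected_icc(scale, item) - target) < 0.01

    def test_zero_target_gives_zero_scale(self):
        assert simdata.calibrate_item_scale(simdata.ItemSpec("x", icc=0.0)) == 0.0
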
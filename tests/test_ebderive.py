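"""Crude and Empirical Bayes derivations: formulas, prior fitting, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special, stats

from dietherit import ebderive
from dietherit.ebderive import (
    BetaPrior,
    DMPrior,
    assign_donors,
    derive_crude,
    eb_average,
    eb_proportion,
    fit_dirichlet_multinomial,
    fit_zoib,
)


class TestDeriveCrude:
    def test_proportion_and_average(self):
        prop, avg = derive_crude([1, 0, 0, 1], [2.0, 0.0, 0.0, 2.0])
        assert prop == 0.5
        assert avg == 1.0  # zeros for non-consumption enter the average

    def test_single_questionnaire(self):
        prop, avg = derive_crude([1])
        assert prop == 1.0 and avg is None

    def test_zero_questionnaires_rejected(self):
        with pytest.raises(ValueError):
            derive_crude([])


class TestEBProportion:
    PRIOR = BetaPrior(alpha=2.0, beta=5.0, p0=0.0, p1=0.0, converged=True)

    def test_printed_formula(self):
        assert eb_proportion(1, 2, self.PRIOR) == pytest.approx(3.0 / 9.0)
        flat = BetaPrior(1.0, 1.0, 0.0, 0.0, True)
        assert eb_proportion(0, 1, flat) == pytest.approx(1.0 / 3.0)

    def test_shrinkage_vanishes_with_k(self):
        assert abs(eb_proportion(5 * 10**5, 10**6, self.PRIOR) - 0.5) < 1e-5

    @given(s=st.integers(0, 5), k=st.integers(1, 5),
           a=st.floats(0.1, 20), b=st.floats(0.1, 20))
    @settings(max_examples=200, deadline=None)
    def test_convex_combination_identity(self, s, k, a, b):
        if s > k:
            s = k
        prior = BetaPrior(a, b, 0.0, 0.0, True)
        w = k / (k + a + b)
        expected = w * (s / k) + (1 - w) * a / (a + b)
        assert eb_proportion(s, k, prior) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_successes(self):
        vals = [eb_proportion(s, 5, self.PRIOR) for s in range(6)]
        assert np.all(np.diff(vals) > 0)

    def test_consistency_rate(self):
        # |EB - crude| halves when k doubles at fixed s/k
        gaps = [abs(eb_proportion(k // 2, k, self.PRIOR) - 0.5)
                for k in (1_000, 2_000, 4_000)]
        assert gaps[0] / gaps[1] == pytest.approx(2.0, rel=0.01)
        assert gaps[1] / gaps[2] == pytest.approx(2.0, rel=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            eb_proportion(3, 2, self.PRIOR)
        bad = BetaPrior(np.nan, np.nan, 0.5, 0.0, False)
        with pytest.raises(ValueError):
            eb_proportion(1, 2, bad)


class TestFitZoib:
    def test_point_masses_and_interior_fit(self, rng):
        interior = rng.beta(2.0, 5.0, size=16_000)
        x = np.concatenate([np.zeros(3_000), np.ones(1_000), interior])
        prior = fit_zoib(x)
        assert prior.converged
        assert prior.p0 == pytest.approx(0.15)
        assert prior.p1 == pytest.approx(0.05)
        assert 1.8 < prior.alpha < 2.2
        assert 4.5 < prior.beta < 5.5

    def test_uniform_interior_is_flat_beta(self, rng):
        prior = fit_zoib(rng.uniform(0, 1, size=20_000))
        assert abs(prior.alpha - 1.0) < 0.1
        assert abs(prior.beta - 1.0) < 0.1

    def test_agrees_with_independent_mle(self, rng):
        """Dual route: custom gradient MLE vs scipy.stats.beta.fit on 5,000 draws."""
        x = rng.beta(0.8, 3.0, size=5_000)
        prior = fit_zoib(x)
        a_ref, b_ref, _, _ = stats.beta.fit(x, floc=0, fscale=1)
        assert prior.alpha == pytest.approx(a_ref, abs=1e-3)
        assert prior.beta == pytest.approx(b_ref, abs=1e-3)

    def test_too_few_interior_values_flagged(self):
        x = np.concatenate([np.zeros(500), np.full(3, 0.4)])
        prior = fit_zoib(x)
        assert not prior.converged

    def test_donor_substitution(self):
        priors = {
            "milk_any": fit_zoib(np.concatenate([np.ones(997), [0.5, 0.4, 0.6]])),
            "milk_types": BetaPrior(3.0, 1.5, 0.1, 0.3, True),
        }
        resolved = assign_donors(priors, donor_map={"milk_any": "milk_types"})
        assert not priors["milk_any"].converged
        assert resolved["milk_any"].converged
        assert resolved["milk_any"].donor_item == "milk_types"
        assert resolved["milk_any"].alpha == 3.0
        # inflation masses stay the item's own
        assert resolved["milk_any"].p1 == priors["milk_any"].p1

    def test_no_donor_available_is_hard_error(self):
        bad = BetaPrior(np.nan, np.nan, 1.0, 0.0, False)
        with pytest.raises(ValueError):
            assign_donors({"only": bad})


class TestDirichletMultinomial:
    def _sample(self, rng, alpha, n):
        k = rng.integers(1, 6, size=n)
        p = rng.dirichlet(alpha, size=n)
        return np.vstack([rng.multinomial(k[i], p[i]) for i in range(n)])

    def test_symmetric_counts_give_equal_alphas(self):
        counts = np.tile([3.0, 2.0], (300, 1))
        counts[1::2] = [2.0, 3.0]
        prior = fit_dirichlet_multinomial(counts, np.array([0.0, 1.0]))
        assert prior.converged
        assert prior.alpha_vec[0] == pytest.approx(prior.alpha_vec[1], rel=1e-3)

    def test_agrees_with_direct_likelihood_maximisation(self, rng):
        """Dual route: fixed-point MLE vs Nelder-Mead on the DM log-likelihood."""
        counts = self._sample(rng, np.array([1.0, 2.0, 3.0]), 5_000)
        prior = fit_dirichlet_multinomial(counts, np.arange(3.0))
        k_i = counts.sum(axis=1)

        def negll(log_a):
            a = np.exp(log_a)
            a0 = a.sum()
            ll = len(counts) * special.gammaln(a0) - special.gammaln(k_i + a0).sum()
            ll += special.gammaln(counts + a).sum()
            ll -= len(counts) * special.gammaln(a).sum()
            return -ll

        res = optimize.minimize(negll, np.log(prior.alpha_vec * 1.3),
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10,
                                         "maxiter": 20_000})
        assert np.allclose(prior.alpha_vec, np.exp(res.x), atol=1e-3)

    def test_determinism(self, rng):
        counts = self._sample(rng, np.array([2.0, 2.0]), 500)
        a1 = fit_dirichlet_multinomial(counts, np.arange(2.0)).alpha_vec
        a2 = fit_dirichlet_multinomial(counts, np.arange(2.0)).alpha_vec
        assert np.array_equal(a1, a2)

    def test_single_nonzero_category_flagged(self):
        counts = np.column_stack([np.full(100, 3.0), np.zeros(100)])
        assert not fit_dirichlet_multinomial(counts, np.arange(2.0)).converged


class TestEBAverage:
    PRIOR = DMPrior(np.array([0.0, 1.0, 2.0]), np.array([1.0, 1.0, 1.0]), True)

    def test_printed_formula(self):
        assert eb_average([2, 0, 0], 2, self.PRIOR) == pytest.approx(0.6)

    def test_fixed_point_when_crude_equals_prior_mean(self):
        assert eb_average([1, 0, 1], 2, self.PRIOR) == pytest.approx(1.0)

    def test_shrinkage_vanishes_with_k(self):
        k = 10**6
        assert eb_average([0, 0, k], k, self.PRIOR) == pytest.approx(2.0, abs=1e-5)

    @given(c0=st.integers(0, 5), c1=st.integers(0, 5), c2=st.integers(0, 5))
    @settings(max_examples=100, deadline=None)
    def test_convex_combination_identity(self, c0, c1, c2):
        k = c0 + c1 + c2
        if k == 0:
            return
        counts = np.array([c0, c1, c2], dtype=float)
        crude = counts @ self.PRIOR.category_values / k
        w = k / (k + self.PRIOR.alpha_sum)
        expected = w * crude + (1 - w) * self.PRIOR.mean
        assert eb_average(counts, k, self.PRIOR) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            eb_average([1, 1], 2, self.PRIOR)


class TestBuildPhenotypeTable:
    @pytest.fixture(scope="class")
    def encoded(self):
        rng = np.random.default_rng(5)
        n, rows = 600, []
        for i in range(n):
            k = rng.integers(1, 6)
            p = rng.beta(2, 3)
            lam = rng.uniform(0.5, 4.0)
            for j in range(k):
                c = rng.binomial(1, p)
                rows.append({
                    "iid": f"i{i:04d}", "qidx": j + 1,
                    "tea": int(rng.binomial(1, p)),
                    "coffee_consumed": c,
                    "coffee_qty": float(min(rng.poisson(lam) + 1, 8) * c),
                })
        return pd.DataFrame(rows)

    def test_column_count(self, encoded):
        pheno, _ = ebderive.build_phenotype_table(encoded, ["tea"], ["coffee"])
        cols = [c for c in pheno.columns if c != "k"]
        # 2 per item plus 2 extra per quantity item
        assert len(cols) == 6
        assert ebderive.expected_phenotype_columns(1, 0) == 2
        assert ebderive.expected_phenotype_columns(0, 1) == 4

    def test_shrinkage_bounds_hold_for_everyone(self, encoded):
        pheno, fitted = ebderive.build_phenotype_table(encoded, ["tea"], ["coffee"])
        for item in ("tea", "coffee"):
            prior = fitted[item].beta_prior
            lo = np.minimum(pheno[f"{item}_crude_prop"], prior.mean) - 1e-12
            hi = np.maximum(pheno[f"{item}_crude_prop"], prior.mean) + 1e-12
            assert ((pheno[f"{item}_eb_prop"] >= lo) & (pheno[f"{item}_eb_prop"] <= hi)).all()
        dm = fitted["coffee"].dm_prior
        lo = np.minimum(pheno["coffee_crude_avg"], dm.mean) - 1e-12
        hi = np.maximum(pheno["coffee_crude_avg"], dm.mean) + 1e-12
        assert ((pheno["coffee_eb_avg"] >= lo) & (pheno["coffee_eb_avg"] <= hi)).all()

    def test_eb_proportion_between_zero_and_one(self, encoded):
        pheno, _ = ebderive.build_phenotype_table(encoded, ["tea"], ["coffee"])
        for col in ("tea_eb_prop", "coffee_eb_prop"):
            assert pheno[col].between(0, 1).all()
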
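"""Synthetic cohort generator: genotype structure, planted effects, stressors."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from brainwas.datatypes import ConfoundMatrix
from brainwas.preprocess import flag_technical_outliers, select_unrelated
from brainwas.simulate import (
    SimConfig,
    SimTruth,
    build_mediated_idp,
    inject_stressors,
    simulate_cc_summary,
    simulate_genotypes,
    simulate_idps,
    simulate_mediator,
    simulate_quant_summary,
)


class TestGenotypes:
    def test_dosages_are_hard_calls(self, small_genotypes):
        assert set(np.unique(small_genotypes.dosages.to_numpy())) <= {0, 1, 2}

    def test_zero_maf_gives_all_zero_column(self):
        cfg = SimConfig(n_subjects=500, n_variants=3, n_idps=1,
                        maf=np.array([0.0, 0.2, 0.3]), seed=1)
        g = simulate_genotypes(cfg)
        assert (g.dosages.iloc[:, 0] == 0).all()

    def test_half_maf_mean_dosage_near_one(self):
        # binomial(2, 0.5) has SE sqrt(2*0.25/n) on the mean dosage
        n = 10_000
        cfg = SimConfig(n_subjects=n, n_variants=2, n_idps=1, maf=0.5, seed=2)
        g = simulate_genotypes(cfg)
        se = np.sqrt(2 * 0.25 / n)
        assert abs(g.dosages.iloc[:, 0].mean() - 1.0) < 3 * se

    def test_zero_rho_gives_independent_adjacent_dosages(self):
        cfg = SimConfig(n_subjects=20_000, n_variants=4, n_idps=1, ld_rho=0.0, maf=0.3, seed=3)
        g = simulate_genotypes(cfg).dosages.to_numpy()
        r = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
        assert abs(r) < 3 / np.sqrt(20_000)

    def test_hwe_holds_per_variant(self):
        # chi-square GoF against (p^2, 2pq, q^2); expect ~alpha rejections
        cfg = SimConfig(n_subjects=20_000, n_variants=50, n_idps=1, ld_rho=0.4,
                        maf=np.linspace(0.05, 0.5, 50), seed=4)
        d = simulate_genotypes(cfg).dosages.to_numpy()
        n = d.shape[0]
        rejected = 0
        for j in range(d.shape[1]):
            counts = np.bincount(d[:, j], minlength=3)
            q = counts @ np.array([0, 1, 2]) / (2 * n)  # risk-allele freq
            expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
            chi2 = ((counts - expected) ** 2 / expected).sum()
            rejected += stats.chi2.sf(chi2, 1) < 0.01
        assert rejected / 50 <= 0.02  # >= 98% of variants in HWE at the 1% level

    def test_ld_decays_with_marker_distance(self, small_genotypes):
        d = small_genotypes.dosages.to_numpy()
        corr = np.corrcoef(d.T)
        lags = [np.mean([corr[i, i + k] for i in range(8 - k)]) for k in range(1, 4)]
        assert lags[0] > lags[1] > lags[2] > 0

    def test_fixed_seed_is_deterministic(self):
        cfg = SimConfig(n_subjects=200, n_variants=5, n_idps=1, seed=11)
        a = simulate_genotypes(cfg).dosages
        b = simulate_genotypes(cfg).dosages
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("bad", [{"ld_rho": 1.0}, {"maf": 0.7}, {"n_subjects": 0}])
    def test_invalid_parameters_raise(self, bad):
        with pytest.raises((ValueError, IndexError)):
            SimConfig(n_variants=3, n_idps=1, **bad)


class TestIdps:
    def test_null_idps_are_standard_normal(self, small_genotypes):
        idps = simulate_idps(small_genotypes, n_idps=5, noise_sd=1.0, seed=5)
        arr = idps.values.to_numpy()
        se = 1 / np.sqrt(arr.shape[0])
        assert np.all(np.abs(arr.mean(axis=0)) < 4 * se)
        assert np.allclose(arr.std(axis=0), 1.0, atol=0.05)

    def test_planted_effect_recovered_by_ols(self):
        # beta=0.2 SD planted on IDP 0; its 95% CI should cover truth in
        # >= 90% of seeds (repeated-simulation oracle, scaled to n=5000 x 40 seeds)
        beta, n, hits, n_seeds = 0.2, 5000, 0, 40
        for seed in range(n_seeds):
            cfg = SimConfig(n_subjects=n, n_variants=2, n_idps=1, maf=0.3, seed=seed)
            g = simulate_genotypes(cfg)
            truth = SimTruth(idp_effects=[(0, 0, beta)])
            y = simulate_idps(g, truth=truth, n_idps=1, seed=seed + 1000).values.iloc[:, 0]
            x = sm.add_constant(g.dosages.iloc[:, 0].to_numpy(dtype=float))
            res = sm.OLS(y.to_numpy(), x).fit()
            lo, hi = res.conf_int()[1]
            hits += lo <= beta <= hi
        assert hits >= 0.9 * n_seeds

    def test_effect_out_of_range_raises(self, small_genotypes):
        truth = SimTruth(idp_effects=[(0, 99, 0.2)])
        with pytest.raises(IndexError):
            simulate_idps(small_genotypes, truth=truth, n_idps=3)

    def test_same_seed_same_matrix(self, small_genotypes):
        a = simulate_idps(small_genotypes, n_idps=3, seed=9).values
        b = simulate_idps(small_genotypes, n_idps=3, seed=9).values
        pd.testing.assert_frame_equal(a, b)

    def test_confound_loadings_enter_linearly(self, small_genotypes):
        n = small_genotypes.n_subjects
        conf = ConfoundMatrix(
            pd.DataFrame({"c0": np.ones(n)}, index=small_genotypes.subject_ids),
            pd.Series({"c0": "raw"}),
        )
        loaded = simulate_idps(small_genotypes, conf, n_idps=1,
                               confound_loadings=np.array([[5.0]]), seed=12)
        plain = simulate_idps(small_genotypes, n_idps=1, seed=12)
        np.testing.assert_allclose(
            loaded.values.to_numpy() - plain.values.to_numpy(), 5.0, atol=1e-12
        )


class TestMediatorChain:
    def test_zero_a_means_mediator_independent_of_x(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 20_000).astype(float)
        m = simulate_mediator(x, a=0.0, seed=1)
        assert abs(np.corrcoef(x, m)[0, 1]) < 3 / np.sqrt(20_000)

    def test_large_n_recovers_all_three_paths(self):
        a, b, c_prime, n = 0.5, 0.3, 0.2, 50_000
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, n).astype(float)
        m = simulate_mediator(x, a, seed=3)
        y = build_mediated_idp(x, m, b, c_prime, seed=4)
        res_m = sm.OLS(m, sm.add_constant(x)).fit()
        assert abs(res_m.params[1] - a) < 3 * res_m.bse[1]
        res_y = sm.OLS(y, sm.add_constant(np.column_stack([x, m]))).fit()
        assert abs(res_y.params[1] - c_prime) < 3 * res_y.bse[1]
        assert abs(res_y.params[2] - b) < 3 * res_y.bse[2]

    def test_no_paths_means_y_independent_of_x(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, 10_000).astype(float)
        m = simulate_mediator(x, a=0.5, seed=6)
        y = build_mediated_idp(x, m, b=0.0, c_prime=0.0, seed=7)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        lo, hi = res.conf_int()[1]
        assert lo <= 0 <= hi

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            build_mediated_idp(np.zeros(5), np.zeros(4), 0.1, 0.1)


class TestCaseControlSummary:
    def test_null_pvalues_uniform(self):
        # KS against U(0,1) over 1,000 independent null variants
        cfg = SimConfig(n_subjects=800, n_variants=1000, n_idps=1, ld_rho=0.0,
                        maf=np.linspace(0.1, 0.5, 1000), seed=21)
        g = simulate_genotypes(cfg)
        table = simulate_cc_summary(g, causal_idx=0, log_or=0.0,
                                    n_cases=300, n_controls=500, seed=22)
        p = table.loc[~table["separation_flag"], "p"]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_causal_variant_has_smallest_p(self):
        # smallest p should land at or beside (in LD with) the causal variant
        hits = 0
        for seed in range(50):
            cfg = SimConfig(n_subjects=4000, n_variants=9, n_idps=1, ld_rho=0.6,
                            maf=0.3, seed=seed)
            g = simulate_genotypes(cfg)
            table = simulate_cc_summary(g, causal_idx=4, log_or=0.4,
                                        n_cases=2000, n_controls=2000, seed=seed + 500)
            best = int(np.nanargmin(table["p"].to_numpy()))
            hits += abs(best - 4) <= 1
        assert hits >= 45

    def test_matches_statsmodels_logit(self, small_genotypes):
        table = simulate_cc_summary(small_genotypes, causal_idx=2, log_or=0.3,
                                    n_cases=3000, n_controls=7000, seed=30)
        # refit one variant with statsmodels from the same case labels: the
        # simulator must agree with the reference implementation
        rng = np.random.default_rng(30)
        g = small_genotypes.dosages.to_numpy(dtype=float)
        s = 3000 / 10_000
        causal = g[:, 2]
        alpha = np.log(s / (1 - s)) - 0.3 * causal.mean()
        prob = 1 / (1 + np.exp(-(alpha + 0.3 * causal)))
        y = (rng.random(g.shape[0]) < prob).astype(float)
        ref = sm.Logit(y, sm.add_constant(g[:, 5])).fit(disp=0)
        assert table["beta"].iloc[5] == pytest.approx(ref.params[1], abs=1e-6)
        assert table["se"].iloc[5] == pytest.approx(ref.bse[1], rel=1e-4)

    def test_degenerate_design_raises(self, small_genotypes):
        with pytest.raises(ValueError):
            simulate_cc_summary(small_genotypes, 0, 0.4, n_cases=0, n_controls=100)


class TestQuantSummary:
    def test_null_beta_unbiased_and_p_uniform(self, small_genotypes):
        table = simulate_quant_summary(small_genotypes, None, 0.0, seed=40)
        assert np.all(np.abs(table["beta"] / table["se"]) < 5)
        cfg = SimConfig(n_subjects=500, n_variants=800, n_idps=1, ld_rho=0.0, maf=0.3, seed=41)
        g = simulate_genotypes(cfg)
        t2 = simulate_quant_summary(g, None, 0.0, seed=42)
        assert stats.kstest(t2["p"], "uniform").pvalue > 0.01

    def test_causal_effect_recovered(self, small_genotypes):
        table = simulate_quant_summary(small_genotypes, 3, 0.25, seed=43)
        row = table.iloc[3]
        assert abs(row["beta"] - 0.25) < 3 * row["se"]


class TestStressors:
    def test_noop_returns_input(self, idp_matrix):
        out, kin = inject_stressors(idp_matrix, rate_missing=0.0)
        pd.testing.assert_frame_equal(out.values, idp_matrix.values)
        assert kin.empty

    def test_injected_outliers_are_recovered_by_qc(self, idp_matrix):
        cells = [(2, 0, 8.0), (7, 1, -8.0), (11, 3, 9.0), (40, 4, 8.0), (99, 5, -7.0)]
        out, _ = inject_stressors(idp_matrix, outlier_spec=cells, seed=1)
        mask = flag_technical_outliers(out, k_sd=5)
        flagged = set(zip(*np.where(mask.to_numpy())))
        assert flagged == {(r, c) for r, c, _ in cells}

    def test_small_displacement_rejected(self, idp_matrix):
        with pytest.raises(ValueError):
            inject_stressors(idp_matrix, outlier_spec=[(0, 0, 3.0)])

    def test_related_pair_pruned_to_one(self, idp_matrix):
        out, kin = inject_stressors(idp_matrix, related_pairs_spec=1, seed=2)
        assert out.values.shape[0] == idp_matrix.values.shape[0] + 1
        assert (kin["kinship"] >= 0.2).all()
        kept = select_unrelated(kin, out.subject_ids)
        assert len(kept) == idp_matrix.values.shape[0]

    def test_missing_rate_applied(self, idp_matrix):
        out, _ = inject_stressors(idp_matrix, rate_missing=0.1, seed=3)
        frac = out.values.isna().to_numpy().mean()
        assert 0.05 < frac < 0.15
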
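"""Confound construction: imputation, MAD trimming, smoothing, drift PCs, deconfounding."""

import numpy as np
import pandas as pd
import pytest

from brainwas.confounds import (
    DriftSpec,
    augment_confounds,
    build_drift_confounds,
    deconfound,
    drift_components,
    impute_low_rank,
    mad_outlier_removal,
    temporal_smooth,
)
from brainwas.datatypes import ConfoundMatrix, IDPMatrix


def _idps(arr):
    values = pd.DataFrame(
        arr,
        index=pd.Index([f"S{i}" for i in range(arr.shape[0])]),
        columns=pd.Index([f"idp{j}" for j in range(arr.shape[1])]),
    )
    return IDPMatrix(values, pd.Series("GM-morphology", index=values.columns))


def _conf(df):
    return ConfoundMatrix(df, pd.Series("raw", index=df.columns))


class TestImputeLowRank:
    def test_complete_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20, 8))
        np.testing.assert_array_equal(impute_low_rank(x, rank=3), x)

    def test_rank_one_matrix_recovered(self):
        # exact rank-1 uv^T with 10% hidden cells -> near-exact completion
        rng = np.random.default_rng(1)
        u, v = rng.standard_normal(60), rng.standard_normal(25)
        x = np.outer(u, v)
        holes = rng.random(x.shape) < 0.1
        xm = np.where(holes, np.nan, x)
        filled = impute_low_rank(xm, rank=1, tol=1e-10, max_iter=500)
        rel = np.abs(filled[holes] - x[holes]) / (np.abs(x[holes]) + 1e-12)
        assert rel.max() < 1e-4

    def test_observed_cells_never_touched(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((15, 6))
        xm = x.copy()
        xm[3, 4] = np.nan
        filled = impute_low_rank(xm, rank=2)
        obs = ~np.isnan(xm)
        np.testing.assert_array_equal(filled[obs], x[obs])

    def test_infinite_tol_single_iteration_deterministic(self):
        rng = np.random.default_rng(3)
        xm = rng.standard_normal((10, 5))
        xm[0, 0] = np.nan
        a = impute_low_rank(xm, rank=2, tol=np.inf)
        b = impute_low_rank(xm, rank=2, tol=np.inf)
        np.testing.assert_array_equal(a, b)

    def test_fully_missing_column_raises(self):
        xm = np.ones((5, 2))
        xm[:, 1] = np.nan
        with pytest.raises(ValueError):
            impute_low_rank(xm, rank=1)


class TestMadOutlierRemoval:
    def test_constant_column_unchanged(self):
        x = np.ones((12, 1))
        np.testing.assert_array_equal(mad_outlier_removal(x), x)

    def test_gross_value_removed_by_enumeration(self):
        # column 1..9, 1000: median 5.5 -> MAD 2.5 -> only 1000 exceeds 5*MAD
        x = np.r_[np.arange(1.0, 10.0), 1000.0][:, None]
        out = mad_outlier_removal(x, mad_k=5)
        assert np.isnan(out[-1, 0]) and np.isfinite(out[:-1, 0]).all()

    def test_mask_invariant_to_positive_affine_transform(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((200, 1))
        x[10, 0] = 25.0
        base = np.isnan(mad_outlier_removal(x))
        scaled = np.isnan(mad_outlier_removal(3.0 * x + 7.0))
        np.testing.assert_array_equal(base, scaled)


class TestTemporalSmooth:
    def test_linear_in_date_reproduced(self):
        rng = np.random.default_rng(5)
        dates = rng.uniform(0, 1000, 300)
        col = (0.3 * dates - 7.0)[:, None]
        out = temporal_smooth(col, dates, spline_df=10)
        np.testing.assert_allclose(out, col, atol=1e-8)

    def test_white_noise_variance_collapses(self):
        # smoother with df degrees of freedom keeps ~df/n of noise variance
        rng = np.random.default_rng(6)
        dates = rng.uniform(0, 1000, 2000)
        col = rng.standard_normal((2000, 1))
        out = temporal_smooth(col, dates, spline_df=10)
        assert out.var() < 0.05 * col.var()

    def test_constant_column_unchanged(self):
        rng = np.random.default_rng(7)
        dates = rng.uniform(0, 100, 50)
        col = np.full((50, 2), 3.25)
        np.testing.assert_allclose(temporal_smooth(col, dates, 6), col, atol=1e-8)

    def test_low_df_polynomial_fallback(self):
        rng = np.random.default_rng(8)
        dates = rng.uniform(0, 10, 100)
        col = (2.0 * dates + 1.0)[:, None]
        np.testing.assert_allclose(temporal_smooth(col, dates, spline_df=2), col, atol=1e-8)

    def test_too_few_distinct_dates_raises(self):
        with pytest.raises(ValueError):
            temporal_smooth(np.ones((4, 1)), np.array([1.0, 1.0, 2.0, 2.0]), spline_df=4)


class TestDriftComponents:
    def test_rank_one_input_single_dominant_component(self):
        rng = np.random.default_rng(9)
        x = np.outer(rng.standard_normal(40), rng.standard_normal(12))
        scores = drift_components(x, n_components=3)
        var = scores.var(axis=0)
        assert var[0] / var.sum() > 0.9999

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(10)
        scores = drift_components(rng.standard_normal((50, 10)), n_components=5)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_matches_brute_force_eigendecomposition(self):
        # scores == projection onto covariance eigenvectors (20 x 8 oracle)
        rng = np.random.default_rng(11)
        x = rng.standard_normal((20, 8))
        centred = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(centred.T @ centred)
        order = np.argsort(evals)[::-1]
        expected = centred @ evecs[:, order[:4]]
        scores = drift_components(x, n_components=4)
        for k in range(4):  # sign convention may differ from eigh's
            assert np.allclose(scores[:, k], expected[:, k], atol=1e-8) or np.allclose(
                scores[:, k], -expected[:, k], atol=1e-8
            )

    def test_component_sign_fixed_by_largest_loading(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((30, 6))
        a = drift_components(x, 3)
        b = drift_components(-x, 3)  # flipping the data must not flip conventions twice
        np.testing.assert_allclose(np.abs(a), np.abs(b), atol=1e-8)


class TestAugmentConfounds:
    def test_column_counting(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(
            {
                "motion": rng.standard_normal(100),
                "head_size": rng.standard_normal(100),
                "site": rng.integers(1, 4, 100),
            },
            index=pd.Index([f"S{i}" for i in range(100)]),
        )
        out = augment_confounds(_conf(df), categorical=["site"])
        # 2 site indicators (3 levels, drop first) + 3 x 2 continuous
        assert out.n_confounds == 2 + 3 * 2
        assert (out.provenance == "indicator").sum() == 2
        assert (out.provenance == "quantile-normalised").sum() == 2
        assert (out.provenance == "centred-squared").sum() == 2

    def test_binary_column_gets_indicator_only(self):
        df = pd.DataFrame({"site": [1, 2, 1, 2, 1, 2]},
                          index=pd.Index([f"S{i}" for i in range(6)]))
        out = augment_confounds(_conf(df), categorical=["site"])
        assert out.n_confounds == 1
        assert list(out.provenance) == ["indicator"]

    def test_centred_square_uncorrelated_with_symmetric_raw(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(50_000)
        df = pd.DataFrame({"x": x}, index=pd.Index([f"S{i}" for i in range(50_000)]))
        out = augment_confounds(_conf(df))
        r = np.corrcoef(out.values["x"], out.values["x_csq"])[0, 1]
        assert abs(r) < 3 / np.sqrt(50_000) + 0.02

    def test_output_is_complete(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame({"x": np.r_[rng.standard_normal(99), 50.0]},
                          index=pd.Index([f"S{i}" for i in range(100)]))
        out = augment_confounds(_conf(df))  # the 50.0 is MAD-trimmed then refilled
        assert not out.values.isna().any().any()


class TestDeconfound:
    def test_idp_equal_to_confound_gives_zero_residual(self):
        rng = np.random.default_rng(16)
        c = rng.standard_normal(80)
        conf = _conf(pd.DataFrame({"c": c}, index=pd.Index([f"S{i}" for i in range(80)])))
        idps = _idps(c[:, None])
        out = deconfound(idps, conf)
        assert np.abs(out.values.to_numpy()).max() < 1e-10

    def test_intercept_only_mean_centres(self):
        idps = _idps(np.array([[1.0], [2.0], [3.0]]))
        conf = ConfoundMatrix(
            pd.DataFrame(index=idps.values.index), pd.Series(dtype=object)
        )
        out = deconfound(idps, conf)
        np.testing.assert_allclose(out.values.to_numpy()[:, 0], [-1, 0, 1], atol=1e-12)

    def test_residuals_orthogonal_to_confounds(self):
        rng = np.random.default_rng(17)
        conf_df = pd.DataFrame(
            rng.standard_normal((200, 10)),
            index=pd.Index([f"S{i}" for i in range(200)]),
            columns=[f"c{j}" for j in range(10)],
        )
        idps = _idps(rng.standard_normal((200, 5)))
        out = deconfound(idps, _conf(conf_df))
        ctr = conf_df.to_numpy().T @ out.values.to_numpy()
        assert np.abs(ctr).max() < 1e-8

    def test_idempotent(self):
        rng = np.random.default_rng(18)
        conf_df = pd.DataFrame(
            rng.standard_normal((150, 6)),
            index=pd.Index([f"S{i}" for i in range(150)]),
            columns=[f"c{j}" for j in range(6)],
        )
        idps = _idps(rng.standard_normal((150, 4)))
        once = deconfound(idps, _conf(conf_df))
        twice = deconfound(once, _conf(conf_df))
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-10
        )

    def test_missing_cells_stay_missing(self):
        rng = np.random.default_rng(19)
        arr = rng.standard_normal((100, 3))
        arr[4, 1] = np.nan
        conf_df = pd.DataFrame(
            rng.standard_normal((100, 2)),
            index=pd.Index([f"S{i}" for i in range(100)]),
            columns=["c0", "c1"],
        )
        out = deconfound(_idps(arr), _conf(conf_df))
        assert np.isnan(out.values.iloc[4, 1])
        assert out.values.notna().sum().sum() == 299

    def test_more_confounds_than_subjects_raises(self):
        rng = np.random.default_rng(20)
        conf_df = pd.DataFrame(
            rng.standard_normal((5, 6)),
            index=pd.Index([f"S{i}" for i in range(5)]),
            columns=[f"c{j}" for j in range(6)],
        )
        with pytest.raises(ValueError):
            deconfound(_idps(rng.standard_normal((5, 2))), _conf(conf_df))


class TestDriftChain:
    def test_deterministic_end_to_end(self):
        rng = np.random.default_rng(21)
        arr = rng.standard_normal((120, 15))
        arr[rng.random(arr.shape) < 0.05] = np.nan
        idps = _idps(arr)
        dates = pd.Series(rng.uniform(0, 1000, 120), index=idps.values.index)
        spec = DriftSpec(rank=3, spline_df=5, n_components=4)
        a = build_drift_confounds(idps, dates, spec)
        b = build_drift_confounds(idps, dates, spec)
        pd.testing.assert_frame_equal(a.values, b.values)
        assert list(a.provenance.unique()) == ["drift-PC"]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            DriftSpec(rank=0)
        with pytest.raises(ValueError):
            DriftSpec(mad_k=0)
        with pytest.raises(ValueError):
            DriftSpec(spline_df=1)
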
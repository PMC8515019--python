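import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qutece_bbb import preprocess
from qutece_bbb.biomarker import (
    CbvSeries,
    cbv_slope,
    compartment_refs,
    percent_volume_affected,
    quantify_session,
    region_cbv_series,
    subject_leak_map,
    voxel_slope_map,
)
from qutece_bbb.signal_model import CompartmentSignals
from qutece_bbb.synthetic_data import (
    PhantomSpec,
    simulate_cohort,
    simulate_session,
    _draw_cbv_field,
)

from conftest import SNR10_SIGMA


def ols_normal_equations_oracle(t, y):
    """Brute-force least squares via the normal equations, with t-test."""
    X = np.column_stack([np.ones_like(t), t])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    n = len(t)
    s2 = resid @ resid / (n - 2)
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(cov[1, 1])
    t_stat = beta[1] / se
    p_one = stats.t.sf(t_stat, df=n - 2)
    return beta[1], beta[0], t_stat, p_one


TIMES = np.arange(0, 7) * 420.0


class TestCbvSlope:
    def test_constant_series_null(self):
        s = CbvSeries(values=np.full(7, 0.04), timestamps=TIMES)
        fit = cbv_slope(s)
        assert fit.slope_pct_per_s == pytest.approx(0.0, abs=1e-15)
        assert fit.p_one_tailed == pytest.approx(0.5)

    def test_perfect_linear_increase(self):
        s = CbvSeries(values=0.04 + 1e-6 * TIMES, timestamps=TIMES)
        fit = cbv_slope(s)
        assert fit.p_one_tailed == 0.0
        assert fit.t_statistic == np.inf

    def test_perfect_linear_decrease(self):
        s = CbvSeries(values=0.04 - 1e-6 * TIMES, timestamps=TIMES)
        assert cbv_slope(s).p_one_tailed == 1.0

    def test_matches_normal_equations_oracle(self):
        values = np.array([0.040, 0.041, 0.042, 0.043, 0.044, 0.045, 0.046])
        values = values + np.array([1, -2, 0.5, 1.5, -1, 0.3, -0.2]) * 1e-4
        s = CbvSeries(values=values, timestamps=TIMES)
        fit = cbv_slope(s)
        slope, intercept, t_stat, p_one = ols_normal_equations_oracle(TIMES, values)
        assert fit.slope_raw == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert fit.t_statistic == pytest.approx(t_stat, rel=1e-10)
        assert fit.p_one_tailed == pytest.approx(p_one, rel=1e-10)
        assert fit.slope_pct_per_s == pytest.approx(slope / intercept * 100, rel=1e-10)

    def test_one_tailed_is_half_two_tailed(self, rng):
        values = 0.04 + 1e-6 * TIMES + rng.normal(0, 5e-4, 7)
        res = stats.linregress(TIMES, values)
        fit = cbv_slope(CbvSeries(values=values, timestamps=TIMES))
        if fit.t_statistic > 0:
            assert fit.p_one_tailed == pytest.approx(res.pvalue / 2, rel=1e-9)

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            cbv_slope(CbvSeries(values=np.array([1.0, 2.0]),
                                timestamps=np.array([0.0, 1.0])))

    def test_zero_time_variance(self):
        s = CbvSeries(values=np.ones(3), timestamps=np.array([5.0, 5.0, 5.0]))
        with pytest.raises(ValueError):
            cbv_slope(s)

    def test_mean_fallback_when_intercept_nonpositive(self):
        values = np.array([-0.01, 0.0, 0.01, 0.02, 0.03, 0.04, 0.05])
        fit = cbv_slope(CbvSeries(values=values, timestamps=TIMES))
        assert fit.normalization == "mean"
        assert fit.slope_pct_per_s == pytest.approx(
            fit.slope_raw / values.mean() * 100
        )

    def test_scale_equivariance(self, rng):
        # multiplying all intensities by a constant leaves slope stats
        # unchanged because the CBV quotient cancels the gain
        spec = PhantomSpec(grid_size=32, n_regions=4, noise_sigma=0.5, seed=9)
        timelines, _, atlas = simulate_cohort(spec, 1, {"baseline": 0.002})
        _, session = timelines[0].sessions[0]
        tab1 = quantify_session(session, atlas)
        scaled = preprocess.ScanSession(
            pre_volume=session.pre_volume * 7.3,
            post_volumes=[v * 7.3 for v in session.post_volumes],
            timestamps=session.timestamps,
            acq=session.acq,
            affine=session.affine,
            subject_id=session.subject_id,
            day_label=session.day_label,
        )
        tab2 = quantify_session(scaled, atlas)
        np.testing.assert_allclose(
            tab1.slope_pct_per_s, tab2.slope_pct_per_s, rtol=1e-9
        )
        np.testing.assert_allclose(tab1.t, tab2.t, rtol=1e-9)


class TestRegionSeries:
    def test_uniform_tissue_zero_series(self, small_spec, small_atlas, rng):
        cbv = np.zeros(small_atlas.labels.shape)
        cbv[small_atlas.blood_mask] = 1.0  # blood ref must stay pure blood
        session, _ = simulate_session(small_spec, small_atlas, cbv, {}, rng)
        series = region_cbv_series(session, small_atlas)
        for s in series.values():
            np.testing.assert_allclose(s.values, 0.0, atol=1e-12)

    def test_constant_known_cbv(self, small_spec, small_atlas, rng):
        cbv = np.zeros(small_atlas.labels.shape)
        cbv[small_atlas.brain_mask] = 0.04
        cbv[small_atlas.blood_mask] = 1.0
        session, _ = simulate_session(small_spec, small_atlas, cbv, {}, rng)
        series = region_cbv_series(session, small_atlas)
        for s in series.values():
            np.testing.assert_allclose(s.values, 0.04, atol=1e-12)

    def test_only_leaking_region_increases(self, small_spec, small_atlas, rng):
        cbv, _ = _draw_cbv_field(small_spec, small_atlas, rng)
        session, _ = simulate_session(small_spec, small_atlas, cbv, {2: 0.01}, rng)
        series = region_cbv_series(session, small_atlas)
        assert np.all(np.diff(series[2].values) > 0)
        flat = [rid for rid, s in series.items()
                if np.allclose(s.values, s.values[0], atol=1e-12)]
        assert sorted(flat) == [rid for rid in series if rid != 2]

    def test_absent_region_flagged(self, small_spec, small_atlas, rng):
        cbv, _ = _draw_cbv_field(small_spec, small_atlas, rng)
        session, _ = simulate_session(small_spec, small_atlas, cbv, {}, rng)
        atlas2 = small_atlas
        labels = atlas2.labels.copy()
        labels[labels == 1] = 2  # empty out region 1
        from qutece_bbb.atlas import AtlasLabels
        atlas2 = AtlasLabels(labels=labels, table=atlas2.table, affine=atlas2.affine,
                             blood_mask=atlas2.blood_mask,
                             tissue_mask=atlas2.tissue_mask,
                             tube_mask=atlas2.tube_mask)
        series = region_cbv_series(session, atlas2)
        assert series[1].scope == "region-absent"
        assert np.isnan(series[1].values).all()


class TestSubjectLeakMap:
    def _df(self, p_values):
        n = len(p_values)
        return pd.DataFrame({
            "subject_id": ["s"] * n,
            "day_label": ["baseline"] * n,
            "region": np.arange(1, n + 1),
            "p_one_tailed": p_values,
            "slope_pct_per_s": np.linspace(0.001, 0.01, n),
        })

    def test_all_null_none_significant(self):
        out = subject_leak_map(self._df([0.5] * 10), alpha=0.1)
        assert out.significant.sum() == 0
        assert out.slope_masked.isna().all()

    def test_single_extreme_p(self):
        p = [0.5] * 117 + [0.0]
        out = subject_leak_map(self._df(p), alpha=0.1)
        assert out.significant.sum() == 1
        assert out.loc[out.significant, "region"].iloc[0] == 118
        assert (out.family_size == 118).all()

    def test_fwer_controlled_monte_carlo(self, rng):
        # 118 null regions; p ~ Uniform(0,1); FWER over 500 replicates
        fw = 0
        for _ in range(500):
            p = rng.uniform(size=118)
            out = subject_leak_map(self._df(p), alpha=0.1)
            fw += out.significant.any()
        assert fw / 500 <= 0.1 + 3 * np.sqrt(0.1 * 0.9 / 500)

    def test_empty_family_rejected(self):
        df = self._df([np.nan])
        with pytest.raises(ValueError):
            subject_leak_map(df)


class TestPercentVolumeAffected:
    def test_no_significant_zero(self, small_atlas):
        df = pd.DataFrame({
            "subject_id": ["s"], "day_label": ["baseline"],
            "region": [1], "significant": [False],
        })
        assert percent_volume_affected(df, small_atlas).percent_of_brain == 0.0

    def test_all_significant_hundred(self, small_atlas):
        df = pd.DataFrame({
            "subject_id": ["s"] * 8, "day_label": ["baseline"] * 8,
            "region": list(range(1, 9)), "significant": [True] * 8,
        })
        assert percent_volume_affected(df, small_atlas).percent_of_brain == pytest.approx(100.0)

    def test_arithmetic(self, small_atlas):
        # fraction = voxels of region 1 / brain voxels
        df = pd.DataFrame({
            "subject_id": ["s"] * 8, "day_label": ["baseline"] * 8,
            "region": list(range(1, 9)),
            "significant": [True] + [False] * 7,
        })
        expected = 100.0 * (small_atlas.labels == 1).sum() / small_atlas.brain_mask.sum()
        assert percent_volume_affected(df, small_atlas).percent_of_brain == pytest.approx(expected)


class TestRecovery:
    def test_noiseless_slope_recovery_under_1pct(self):
        spec = PhantomSpec(grid_size=32, n_regions=4, seed=17)
        timelines, truth, atlas = simulate_cohort(
            spec, 1, {"baseline": 0.0, "hit1": 0.004}
        )
        for day, session in timelines[0].sessions[:2]:
            fixed, _ = preprocess.preprocess_session(session, atlas)
            tab = quantify_session(fixed, atlas)
            tr = truth.region_leak_slopes["sub01"][day]
            for row in tab.itertuples():
                true_val = tr[row.region]
                if abs(true_val) > 1e-9:
                    assert abs(row.slope_pct_per_s - true_val) / true_val < 0.01
                else:
                    assert abs(row.slope_pct_per_s) < 1e-9

    def test_snr10_rank_recovery(self):
        rates = {rid: 0.0004 * rid for rid in range(1, 21)}
        spec = PhantomSpec(grid_size=48, n_regions=10, noise_sigma=SNR10_SIGMA,
                           seed=5, leak_rates=rates)
        timelines, truth, atlas = simulate_cohort(spec, 1, {"baseline": 0.0})
        _, session = timelines[0].sessions[0]
        fixed, _ = preprocess.preprocess_session(session, atlas)
        tab = quantify_session(fixed, atlas)
        tr = truth.region_leak_slopes["sub01"]["baseline"]
        est = [r.slope_pct_per_s for r in tab.itertuples()]
        true = [tr[r.region] for r in tab.itertuples()]
        assert stats.spearmanr(est, true).statistic >= 0.9

    def test_null_phantom_under_1pct_volume(self):
        hits = []
        for seed in range(3):
            spec = PhantomSpec(grid_size=32, n_regions=4,
                               noise_sigma=SNR10_SIGMA, seed=seed)
            timelines, _, atlas = simulate_cohort(spec, 1, {"baseline": 0.0})
            _, session = timelines[0].sessions[0]
            fixed, _ = preprocess.preprocess_session(session, atlas)
            tab = quantify_session(fixed, atlas)
            hits.append(percent_volume_affected(tab, atlas).percent_of_brain)
        assert np.mean(hits) < 1.0


class TestVoxelSlopeMap:
    def test_maps_shapes_and_masking(self, small_spec, small_atlas, rng):
        cbv, _ = _draw_cbv_field(small_spec, small_atlas, rng)
        session, _ = simulate_session(small_spec, small_atlas, cbv, {2: 0.01}, rng)
        slope, p, sig = voxel_slope_map(session, small_atlas)
        brain = small_atlas.brain_mask
        assert np.isnan(slope[~brain]).all()
        assert np.isfinite(slope[brain]).all()
        # noiseless: leaking region voxels are significant, others not
        assert sig[small_atlas.labels == 2].all()
        assert not sig[small_atlas.labels == 1].any()

    def test_matches_region_slope_on_constant_region(self, small_spec, small_atlas, rng):
        cbv, base = _draw_cbv_field(small_spec, small_atlas, rng)
        session, _ = simulate_session(small_spec, small_atlas, cbv, {3: 0.005}, rng)
        slope, _, _ = voxel_slope_map(session, small_atlas)
        refs = compartment_refs(session, small_atlas)
        tab = region_cbv_series(session, small_atlas, refs)
        fit = cbv_slope(tab[3])
        np.testing.assert_allclose(
            slope[small_atlas.labels == 3], fit.slope_pct_per_s, rtol=1e-6
        )
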
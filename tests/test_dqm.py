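"""Detrended quantile mapping: training, application and invariants."""

import numpy as np
import pytest

from conftest import TRAINING_WINDOW, ols_slope
from helpers import dqm_oracle, ols_fit, quantile_oracle
from marindown.dqm import (
    DQMTransform,
    Series,
    apply_dqm,
    fit_dqm,
    fit_linear_trend,
    quantile_probs,
)
from marindown.errors import DomainError, ValidationError
from marindown.timeutils import fractional_years, monthly_range, select_period


def _series(values, start=(1993, 1)):
    values = np.asarray(values, dtype=float)
    end_total = start[0] * 12 + (start[1] - 1) + values.size - 1
    times = monthly_range(start[0], start[1], end_total // 12, end_total % 12 + 1)
    return Series(times=times, values=values)


class TestTrendFit:
    def test_matches_polyfit_oracle(self):
        rng = np.random.default_rng(0)
        s = _series(0.3 * np.arange(120) / 12 + rng.normal(size=120))
        tr = fit_linear_trend(s)
        frac = fractional_years(s.times)
        slope, at_mean = ols_fit(frac, s.values)
        assert tr.slope == pytest.approx(slope, rel=1e-10)
        assert tr.intercept == pytest.approx(at_mean, rel=1e-10)

    def test_exact_line_recovered(self):
        s = _series(5.0 + 0.02 * np.arange(60))
        tr = fit_linear_trend(s)
        frac = fractional_years(s.times)
        assert np.allclose(tr.line(frac), s.values, atol=1e-9)

    def test_detrending_preserves_mean(self):
        rng = np.random.default_rng(1)
        s = _series(rng.normal(size=240) + 0.5 * np.arange(240) / 12)
        tr = fit_linear_trend(s)
        det = s.values - tr.anomaly(fractional_years(s.times))
        assert det.mean() == pytest.approx(s.values.mean(), rel=1e-12)

    def test_residual_slope_is_zero(self):
        rng = np.random.default_rng(2)
        s = _series(rng.normal(size=120) + np.arange(120) / 60)
        tr = fit_linear_trend(s)
        frac = fractional_years(s.times)
        det = s.values - tr.anomaly(frac)
        assert abs(ols_slope(det, frac)) < 1e-10

    def test_missing_values_ignored(self):
        vals = 1.0 + 0.1 * np.arange(48) / 12
        vals[5] = np.nan
        tr = fit_linear_trend(_series(vals))
        assert tr.slope == pytest.approx(0.1, rel=1e-9)

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            fit_linear_trend(_series(np.full(24, np.nan)))

    def test_single_time_point_rejected(self):
        with pytest.raises(ValidationError):
            fit_linear_trend(Series(times=monthly_range(2000, 1, 2000, 1), values=np.array([1.0])))


class TestQuantileProbs:
    def test_centered_grid(self):
        p = quantile_probs(100)
        assert p[0] == pytest.approx(0.005)
        assert p[-1] == pytest.approx(0.995)
        assert np.allclose(np.diff(p), 0.01)

    def test_too_few_rejected(self):
        with pytest.raises(ValidationError):
            quantile_probs(1)


class TestFitDqm:
    def test_identity_training_gives_zero_adjustments(self):
        rng = np.random.default_rng(3)
        s = _series(rng.normal(size=240))
        tr = fit_dqm(s, s, n_quantiles=20)
        assert tr.scaling == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tr.adjustments, 0.0, atol=1e-10)

    def test_scaling_equalizes_means(self):
        rng = np.random.default_rng(4)
        m = _series(rng.normal(size=240))
        r = _series(m.values + 2.5)
        tr = fit_dqm(m, r)
        assert tr.scaling == pytest.approx(2.5, rel=1e-12)

    def test_quantiles_match_manual_oracle(self):
        rng = np.random.default_rng(5)
        m = _series(rng.normal(size=120))
        r = _series(rng.normal(loc=1.0, scale=2.0, size=120))
        n = 10
        tr = fit_dqm(m, r, n_quantiles=n)
        frac = fractional_years(m.times)
        scaled = m.values + tr.scaling
        ms, _ = ols_fit(frac, scaled)
        m_det = np.sort(scaled - ms * (frac - frac.mean()))
        rs, _ = ols_fit(frac, r.values)
        r_det = np.sort(r.values - rs * (frac - frac.mean()))
        for k, p in enumerate(quantile_probs(n)):
            mq = quantile_oracle(m_det, p)
            rq = quantile_oracle(r_det, p)
            assert tr.model_quantiles[k] == pytest.approx(mq, rel=1e-10)
            assert tr.adjustments[k] == pytest.approx(rq - mq, rel=1e-8, abs=1e-10)

    def test_multiplicative_requires_positive(self):
        m = _series(np.linspace(-1, 1, 48))
        r = _series(np.linspace(0.5, 1.5, 48))
        with pytest.raises(DomainError):
            fit_dqm(m, r, mode="multiplicative")

    def test_unknown_mode_rejected(self):
        s = _series(np.ones(24) + np.arange(24) * 0.01)
        with pytest.raises(ValidationError):
            fit_dqm(s, s, mode="robust")

    def test_monthly_fit_uses_only_that_month(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=240)
        m = _series(vals)
        r = _series(vals.copy())
        r.values[m.times.astype("datetime64[M]").astype(int) % 12 == 0] += 10.0  # January
        tr_jan = fit_dqm(m, r, month=1)
        tr_jul = fit_dqm(m, r, month=7)
        assert tr_jan.scaling == pytest.approx(10.0, rel=1e-9)
        assert tr_jul.scaling == pytest.approx(0.0, abs=1e-9)


class TestApplyDqm:
    def test_identity_transform_roundtrip(self):
        rng = np.random.default_rng(7)
        s = _series(rng.normal(size=240))
        tr = fit_dqm(s, s, n_quantiles=50)
        out = apply_dqm(tr, s)
        assert np.allclose(out.values, s.values, atol=1e-8)

    def test_constant_offset_corrected(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=240)
        m = _series(base)
        r = _series(base + 3.0)
        tr = fit_dqm(m, r)
        out = apply_dqm(tr, m)
        assert np.allclose(out.values, r.values, atol=1e-8)

    def test_historical_mean_aligned_after_correction(self):
        rng = np.random.default_rng(9)
        m = _series(rng.normal(loc=10.0, scale=1.5, size=336))
        r = _series(rng.normal(loc=8.0, scale=1.0, size=336))
        tr = fit_dqm(m, r)
        out = apply_dqm(tr, m)
        assert out.values.mean() == pytest.approx(r.values.mean(), abs=0.05)

    def test_matches_bruteforce_oracle_on_projection(self):
        rng = np.random.default_rng(10)
        n_hist, n_proj = 120, 180
        m = _series(rng.normal(size=n_hist) + 0.1 * np.arange(n_hist) / 12, start=(1993, 1))
        r = _series(rng.normal(loc=1.0, size=n_hist), start=(1993, 1))
        proj = _series(rng.normal(loc=0.5, size=n_proj) + 0.3 * np.arange(n_proj) / 12,
                       start=(2003, 1))
        n = 40
        tr = fit_dqm(m, r, n_quantiles=n)
        out = apply_dqm(tr, proj)
        expect = dqm_oracle(
            fractional_years(m.times), m.values,
            fractional_years(r.times), r.values,
            fractional_years(proj.times), proj.values,
            n,
        )
        assert np.allclose(out.values, expect, rtol=1e-9, atol=1e-9)

    def test_trend_preserved_exactly_on_noiseless_series(self):
        hist = 5.0 + 0.01 * np.arange(336) + 0.2 * np.sin(np.arange(336))
        m = _series(hist, start=(1993, 1))
        r = _series(hist + 1.0, start=(1993, 1))
        proj = _series(12.0 + 0.04 * np.arange(240), start=(2021, 1))
        tr = fit_dqm(m, r, n_quantiles=50)
        out = apply_dqm(tr, proj)
        frac = fractional_years(proj.times)
        assert ols_slope(out.values, frac) == pytest.approx(ols_slope(proj.values, frac), rel=1e-9)

    def test_trend_preserved_under_noise(self):
        rng = np.random.default_rng(11)
        m = _series(rng.normal(size=336), start=(1993, 1))
        r = _series(rng.normal(loc=2.0, scale=0.8, size=336), start=(1993, 1))
        proj_vals = 0.02 * np.arange(960) / 12 + rng.normal(scale=0.5, size=960)
        proj = _series(proj_vals, start=(2021, 1))
        tr = fit_dqm(m, r)
        out = apply_dqm(tr, proj)
        frac = fractional_years(proj.times)
        s_in = ols_slope(proj.values, frac)
        s_out = ols_slope(out.values, frac)
        assert abs(s_out - s_in) <= 0.05 * abs(s_in)

    def test_correction_is_monotone(self):
        rng = np.random.default_rng(12)
        m = _series(rng.normal(size=240))
        r = _series(rng.gamma(2.0, 1.0, size=240))
        tr = fit_dqm(m, r)
        x = np.linspace(-4, 4, 801)
        y = tr.correct(x)
        assert np.all(np.diff(y) >= -1e-12)

    def test_missing_in_missing_out(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(size=240)
        m = _series(vals)
        r = _series(vals + 1.0)
        tr = fit_dqm(m, r)
        proj_vals = vals.copy()
        proj_vals[[3, 50, 200]] = np.nan
        out = apply_dqm(tr, _series(proj_vals))
        assert np.isnan(out.values[[3, 50, 200]]).all()
        assert np.isfinite(np.delete(out.values, [3, 50, 200])).all()

    def test_monthly_transform_leaves_other_months_unchanged(self):
        rng = np.random.default_rng(14)
        vals = rng.normal(size=240)
        m = _series(vals)
        r = _series(vals + 5.0)
        tr = fit_dqm(m, r, month=3)
        out = apply_dqm(tr, m)
        months = m.times.astype("datetime64[M]").astype(int) % 12 + 1
        assert np.allclose(out.values[months != 3], m.values[months != 3])
        assert np.allclose(out.values[months == 3], r.values[months == 3], atol=1e-8)

    def test_multiplicative_output_positive(self):
        rng = np.random.default_rng(15)
        m = _series(rng.gamma(2.0, 2.0, size=336) + 0.1, start=(1993, 1))
        r = _series(rng.gamma(3.0, 1.0, size=336) + 0.1, start=(1993, 1))
        proj = _series(rng.gamma(2.0, 2.0, size=240) + 0.1, start=(2021, 1))
        tr = fit_dqm(m, r, mode="multiplicative")
        out = apply_dqm(tr, proj)
        assert np.all(out.values > 0)

    def test_multiplicative_ratio_bias_corrected(self):
        rng = np.random.default_rng(16)
        base = rng.gamma(4.0, 1.0, size=336) + 0.5
        m = _series(1.5 * base)
        r = _series(base)
        tr = fit_dqm(m, r, mode="multiplicative")
        assert tr.scaling == pytest.approx(1 / 1.5, rel=1e-12)
        out = apply_dqm(tr, m)
        assert np.allclose(out.values, r.values, rtol=1e-6)

    def test_variance_inflation_removed(self):
        rng = np.random.default_rng(17)
        base = rng.normal(size=2000)
        m = _series(2.0 * base[:1000])
        r = _series(base[1000:])
        tr = fit_dqm(m, r, n_quantiles=100)
        out = apply_dqm(tr, m)
        ratio = out.values.std() / r.values.std()
        assert ratio == pytest.approx(1.0, abs=0.05)


class TestTransformValidation:
    def _base(self, **kw):
        args = dict(
            mode="additive", scaling=0.0, probs=np.array([0.25, 0.75]),
            adjustments=np.zeros(2), model_quantiles=np.array([0.0, 1.0]),
            model_center=0.5, training_window=(np.datetime64("1993-01"), np.datetime64("2020-12")),
        )
        args.update(kw)
        return DQMTransform(**args)

    def test_bad_mode(self):
        with pytest.raises(ValidationError):
            self._base(mode="medium")

    def test_non_increasing_probs(self):
        with pytest.raises(ValidationError):
            self._base(probs=np.array([0.75, 0.25]))

    def test_decreasing_quantiles(self):
        with pytest.raises(ValidationError):
            self._base(model_quantiles=np.array([1.0, 0.0]))


class TestGriddedDqm:
    def test_bias_corrected_hist_mean_matches_reference(self, bias_corrected, ref_coarse):
        sel = select_period(bias_corrected.times, *TRAINING_WINDOW)
        sel_r = select_period(ref_coarse.times, *TRAINING_WINDOW)
        bc = np.nanmean(bias_corrected.values[sel], axis=0)
        rf = np.nanmean(ref_coarse.values[sel_r], axis=0)
        ok = np.isfinite(bc) & np.isfinite(rf)
        assert ok.any()
        assert np.max(np.abs(bc[ok] - rf[ok])) < 0.05

    def test_bias_corrected_variance_matches_reference(self, bias_corrected, ref_coarse):
        def det_std(field):
            sel = select_period(field.times, *TRAINING_WINDOW)
            frac = fractional_years(field.times[sel])
            v = field.values[sel].reshape(sel.sum(), -1)
            out = np.full(v.shape[1], np.nan)
            for j in range(v.shape[1]):
                col = v[:, j]
                if np.isfinite(col).sum() > 2:
                    s = ols_slope(col, frac)
                    out[j] = np.nanstd(col - s * (frac - frac.mean()))
            return out

        sb = det_std(bias_corrected)
        sr = det_std(ref_coarse)
        ok = np.isfinite(sb) & np.isfinite(sr)
        ratios = sb[ok] / sr[ok]
        assert np.all(np.abs(ratios - 1.0) < 0.05)

    def test_bias_correction_preserves_per_cell_trend(self, bias_corrected, member_245):
        member = member_245[0]
        frac = fractional_years(member.times)
        proj = frac >= 2021.0
        ny, nx = member.grid.shape
        for iy in range(ny):
            for ix in range(nx):
                v_in = member.values[proj, iy, ix]
                v_out = bias_corrected.values[proj, iy, ix]
                if not np.isfinite(v_in).all():
                    continue
                s_in = ols_slope(v_in, frac[proj])
                s_out = ols_slope(v_out, frac[proj])
                assert abs(s_out - s_in) <= 0.05 * abs(s_in)

    def test_land_cells_stay_missing(self, downscaled, reference):
        land = ~reference[0].grid.mask
        if land.any():
            assert np.isnan(downscaled.values[:, land]).all()

    def test_downscaled_fine_climatology_correlates_with_reference(self, downscaled, reference):
        sel = select_period(downscaled.times, *TRAINING_WINDOW)
        dc = np.nanmean(downscaled.values[sel], axis=0)
        rc = np.nanmean(reference[0].values[select_period(reference[0].times, *TRAINING_WINDOW)], axis=0)
        ok = np.isfinite(dc) & np.isfinite(rc)
        r = np.corrcoef(dc[ok], rc[ok])[0, 1]
        assert r > 0.99
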
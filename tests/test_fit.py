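"""ACF computation, the parametric ACF model, fitting and the QC rule."""

import numpy as np
import pytest

from sarcoshg import (
    QCRule,
    SarcomereParams,
    apply_qc,
    compute_acf,
    fit_sarcomere_model,
    model_acf,
    simulate_fiber_profile,
)
from sarcoshg.fit import ACF, SarcomereFit
from sarcoshg.geometry import IntensityProfile


def brute_force_acf(samples: np.ndarray, max_lag: int) -> np.ndarray:
    """O(n^2) sum-over-products oracle for the biased ACF estimator."""
    x = samples - samples.mean()
    n = len(x)
    var = np.mean(x**2)
    out = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        s = 0.0
        for i in range(n - lag):
            s += x[i] * x[i + lag]
        out[lag] = s / (n * var)
    return out


class TestComputeACF:
    def test_lag_zero_is_one(self, fetal_params):
        profile = simulate_fiber_profile(fetal_params, 12, noise=1.0, seed=4)
        acf = compute_acf(profile)
        assert acf.values[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(acf.values) <= 1 + 1e-9)

    def test_cosine_acf_peaks_at_period_multiples(self):
        period_um = 1.6
        s = np.arange(3000) * 0.04
        profile = IntensityProfile(
            samples=5.0 + np.cos(2 * np.pi * s / period_um), spacing_nm=40.0
        )
        acf = compute_acf(profile, max_lag_um=6.0)
        from scipy.signal import find_peaks

        idx, _ = find_peaks(acf.values)
        lags_um = acf.lags_nm[idx] / 1000.0
        for k, expected in enumerate([1.6, 3.2, 4.8]):
            assert abs(lags_um[k] - expected) <= 0.04 + 1e-9

    def test_matches_brute_force_oracle(self, fetal_params):
        rng = np.random.default_rng(1)
        profile = IntensityProfile(samples=rng.normal(5.0, 1.0, 200), spacing_nm=40.0)
        acf = compute_acf(profile, max_lag_um=3.0)
        oracle = brute_force_acf(profile.samples, 75)
        np.testing.assert_allclose(acf.values, oracle, atol=1e-10)

    def test_zero_variance_profile_rejected(self):
        profile = IntensityProfile(samples=np.full(400, 3.0), spacing_nm=40.0)
        with pytest.raises(ValueError, match="zero-variance"):
            compute_acf(profile)

    def test_too_short_profile_rejected(self, fetal_params):
        profile = IntensityProfile(samples=np.random.default_rng(0).normal(size=100), spacing_nm=40.0)
        with pytest.raises(ValueError, match="too short"):
            compute_acf(profile, max_lag_um=6.0)


class TestModelACF:
    def test_unit_value_at_lag_zero_and_global_max(self, fetal_params):
        lags = np.arange(0, 6001, 10.0)
        vals = model_acf(fetal_params, lags)
        assert vals[0] == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(vals) == 0

    def test_sl_lobe_dominates_intermediate_lags(self, fetal_params):
        """Numeric scan: the value at lag SL beats any lag in (ABL, SL)."""
        lags = np.arange(0, 6001, 2.0)
        vals = model_acf(fetal_params, lags)
        lags_um = lags / 1000.0
        at_sl = vals[np.argmin(np.abs(lags_um - fetal_params.sl_um))]
        between = vals[(lags_um > fetal_params.abl_um + 0.05) & (lags_um < fetal_params.sl_um - 0.05)]
        assert at_sl >= between.max()

    def test_matches_empirical_acf_of_clean_profile(self, fetal_params):
        """Closed form vs simulator: agreement within 0.02 RMS after tapering."""
        profile = simulate_fiber_profile(fetal_params, 40, noise=0.0)
        acf = compute_acf(profile)
        taper = 1.0 - (acf.lags_nm / acf.spacing_nm) / acf.n_samples
        model = taper * model_acf(fetal_params, acf.lags_nm)
        rms = np.sqrt(np.mean((model - acf.values) ** 2))
        assert rms < 0.02


class TestFit:
    def test_self_consistency_recovers_within_1nm(self, fetal_params):
        """Fitting an exactly model-generated ACF returns the generator params."""
        lags = np.arange(0, 151) * 40.0
        vals = model_acf(fetal_params, lags)
        n = 10**7  # effectively taper-free
        acf = ACF(lags_nm=lags, values=np.clip(vals, -1, 1), n_samples=n)
        fit = fit_sarcomere_model(acf)
        assert fit.converged
        assert fit.estimate.sl_um == pytest.approx(fetal_params.sl_um, abs=1e-3)
        assert fit.estimate.abl_um == pytest.approx(fetal_params.abl_um, abs=1e-3)
        assert fit.estimate.ttil_um == pytest.approx(fetal_params.ttil_um, abs=1e-3)

    def test_profile_pipeline_recovers_within_tolerance(self, fetal_params):
        fit = fit_sarcomere_model(
            compute_acf(simulate_fiber_profile(fetal_params, 14, noise=1.0, seed=9))
        )
        assert fit.converged
        assert fit.estimate.sl_um == pytest.approx(fetal_params.sl_um, abs=0.02)

    def test_shift_and_scale_invariance(self, fetal_params):
        profile = simulate_fiber_profile(fetal_params, 14, noise=1.0, seed=10)
        fits = []
        for a, b in [(1.0, 0.0), (3.7, 0.0), (1.0, 11.0), (0.5, 4.0)]:
            p = IntensityProfile(samples=a * profile.samples + b, spacing_nm=40.0)
            fits.append(fit_sarcomere_model(compute_acf(p)))
        ref = fits[0].estimate
        for f in fits[1:]:
            assert f.estimate.sl_um == pytest.approx(ref.sl_um, abs=1e-9)
            assert f.estimate.abl_um == pytest.approx(ref.abl_um, abs=1e-9)
            assert f.estimate.ttil_um == pytest.approx(ref.ttil_um, abs=1e-9)

    def test_featureless_acf_flagged_not_dropped(self):
        rng = np.random.default_rng(2)
        profile = IntensityProfile(samples=rng.normal(10.0, 1.0, 500), spacing_nm=40.0)
        fit = fit_sarcomere_model(compute_acf(profile, max_lag_um=6.0))
        if not fit.converged:
            assert "no off-zero ACF peak" in fit.reason or fit.reason

    def test_optimizer_matches_grid_search_oracle(self):
        """Coarse 10 nm grid search agrees with the continuous optimizer."""
        rng = np.random.default_rng(3)
        lags = np.arange(0, 151) * 40.0
        for _ in range(5):
            # draw physiological ratios; at SL/ABL = 2 the peak train becomes
            # periodic at SL/2 and the model is unidentifiable (QC territory)
            sl = rng.uniform(1.4, 1.9)
            truth = SarcomereParams(
                sl_um=sl,
                abl_um=sl / rng.uniform(2.05, 2.25),
                ttil_um=rng.uniform(0.08, 0.13),
            )
            vals = model_acf(truth, lags)
            acf = ACF(lags_nm=lags, values=np.clip(vals, -1, 1), n_samples=10**7)
            fit = fit_sarcomere_model(acf)
            # grid over +/-50 nm (SL, ABL) and +/-20 nm (TTIL) at 10 nm pitch
            sls = truth.sl_um + np.arange(-5, 6) * 0.01
            abls = truth.abl_um + np.arange(-5, 6) * 0.01
            ttils = truth.ttil_um + np.arange(-2, 3) * 0.01
            best, best_cost = None, np.inf
            for sl in sls:
                for abl in abls:
                    for ttil in ttils:
                        m = model_acf(SarcomereParams(sl, abl, ttil), lags)
                        cost = np.sum((m[2:] - vals[2:]) ** 2)
                        if cost < best_cost:
                            best, best_cost = (sl, abl, ttil), cost
            assert fit.estimate.sl_um == pytest.approx(best[0], abs=0.005)
            assert fit.estimate.abl_um == pytest.approx(best[1], abs=0.005)
            assert fit.estimate.ttil_um == pytest.approx(best[2], abs=0.005)


class TestQC:
    def _fit_with_ratio(self, ratio):
        params = SarcomereParams(1.6, 1.6 / ratio, 0.1)
        return SarcomereFit(estimate=params, residual_rms=0.01, converged=True)

    def test_above_threshold_excluded(self):
        kept, excluded = apply_qc([self._fit_with_ratio(2.30)])
        assert not kept and len(excluded) == 1
        assert "2.25" in excluded[0][1]

    def test_boundary_value_kept(self):
        kept, excluded = apply_qc([self._fit_with_ratio(2.25)])
        assert len(kept) == 1 and not excluded

    def test_mixed_ratios_counted(self):
        fits = [self._fit_with_ratio(r) for r in (2.10, 2.20, 2.26)]
        kept, excluded = apply_qc(fits)
        assert (len(kept), len(excluded)) == (2, 1)

    def test_non_converged_always_excluded(self):
        bad = SarcomereFit(estimate=None, residual_rms=np.nan, converged=False, reason="x")
        kept, excluded = apply_qc([bad])
        assert not kept and "not converged" in excluded[0][1]

    def test_rule_must_exceed_one(self):
        with pytest.raises(ValueError):
            QCRule(max_ratio=0.9)
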
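import numpy as np
import pytest

import perfseg as ps
import perfseg.perfusion as perf
from perfseg.kinetics import KineticParams
from perfseg.phantom import PhantomGeometry, render_phantom_slice


def brute_force_max_upslope(times, values, window):
    """Independent exhaustive all-windows OLS search (np.polyfit based)."""
    last = min(int(np.argmax(values)) + 2, len(values) - 1)
    max_s = min(len(values) - window, max(0, last - window + 1))
    slopes = [
        np.polyfit(times[s : s + window], values[s : s + window], 1)[0]
        for s in range(max_s + 1)
    ]
    best = int(np.argmax(slopes))  # earliest window on ties
    return slopes[best], best


@pytest.fixture(scope="module")
def uniform_phantom():
    aif = ps.generate_aif_curve(KineticParams(), np.arange(60.0), baseline=0.1)
    geom = PhantomGeometry()
    series, endo, epi, seg = render_phantom_slice(
        geom, aif, {sid: 0.7 for sid in (7, 8, 9, 10, 11, 12)},
        noise_sd=0.0, level="mid", dtype=np.float64,
    )
    return aif, series, endo, epi, seg


class TestMeanSignalCurve:
    def test_single_pixel_mask(self, uniform_phantom):
        _, series, *_ = uniform_phantom
        mask = np.zeros(series.frames.shape[1:], bool)
        mask[30, 30] = True
        curve = ps.mean_signal_curve(series, mask)
        np.testing.assert_array_equal(curve.values, series.frames[:, 30, 30])

    def test_uniform_image(self):
        frames = np.tile(np.arange(10.0)[:, None, None], (1, 8, 8))
        series = ps.PerfusionSeries(frames, np.arange(10.0), n_baseline=2)
        mask = np.ones((8, 8), bool)
        np.testing.assert_array_equal(
            ps.mean_signal_curve(series, mask).values, np.arange(10.0)
        )

    def test_random_mask_matches_direct_summation(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(size=(12, 16, 16))
        series = ps.PerfusionSeries(frames, np.arange(12.0), n_baseline=2)
        mask = rng.random((16, 16)) > 0.6
        got = ps.mean_signal_curve(series, mask).values
        expect = np.array([frames[t][mask].sum() / mask.sum() for t in range(12)])
        np.testing.assert_allclose(got, expect, rtol=1e-12)

    def test_empty_mask_rejected(self, uniform_phantom):
        _, series, *_ = uniform_phantom
        with pytest.raises(ValueError):
            ps.mean_signal_curve(series, np.zeros(series.frames.shape[1:], bool))


class TestBaselineCorrect:
    def test_constant_curve_zeroed(self):
        c = ps.TimeCurve(np.arange(10.0), np.full(10, 5.0), n_baseline=4)
        np.testing.assert_allclose(ps.baseline_correct(c).values, 0.0, atol=1e-14)

    def test_slope_invariance(self, std_aif):
        before = ps.max_upslope(std_aif)
        after = ps.max_upslope(ps.baseline_correct(std_aif))
        assert before.slope == pytest.approx(after.slope, rel=1e-12)
        assert (before.window_start, before.window_end) == (
            after.window_start, after.window_end)

    def test_baseline_mean_zero(self, std_aif):
        shifted = ps.TimeCurve(std_aif.times, std_aif.values + 100.0,
                               std_aif.n_baseline)
        corr = ps.baseline_correct(shifted)
        assert corr.values[: corr.n_baseline].mean() == pytest.approx(0.0, abs=1e-10)

    def test_requires_two_baseline_frames(self):
        c = ps.TimeCurve(np.arange(5.0), np.arange(5.0), n_baseline=1)
        with pytest.raises(ValueError):
            ps.baseline_correct(c)


class TestMaxUpslope:
    def test_pure_ramp(self):
        t = np.arange(20.0)
        fit = ps.max_upslope(ps.TimeCurve(t, 3.0 * t), window=5)
        assert fit.slope == pytest.approx(3.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_curve(self):
        fit = ps.max_upslope(ps.TimeCurve(np.arange(10.0), np.full(10, 2.0)))
        assert fit.slope == 0.0
        assert fit.r_squared == 1.0  # exact (degenerate) fit

    def test_too_short_curve(self):
        with pytest.raises(ValueError):
            ps.max_upslope(ps.TimeCurve(np.arange(3.0), np.arange(3.0)), window=5)

    def test_matches_brute_force_on_random_curves(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(12, 60))
            t = np.cumsum(rng.uniform(0.5, 2.0, n))
            v = np.cumsum(rng.normal(size=n)) + rng.normal(scale=0.1, size=n)
            w = int(rng.integers(2, 8))
            fit = ps.max_upslope(ps.TimeCurve(t, v), window=w)
            slope, start = brute_force_max_upslope(t, v, w)
            assert fit.slope == pytest.approx(slope, rel=1e-9, abs=1e-12)
            assert fit.window_start == start

    def test_tie_break_earliest_window(self):
        # two identical ramps -> identical slopes; earliest window wins
        v = np.array([0, 1, 2, 3, 0, 1, 2, 3, 4.0])
        fit = ps.max_upslope(ps.TimeCurve(np.arange(9.0), v), window=3)
        assert fit.window_start == 0

    def test_recirculation_excluded(self):
        # steeper rise after the first-pass peak must not be selected
        v = np.concatenate([np.zeros(3), [1, 2, 3.0], [2.0, 1.0], [1, 5, 9.0, 9.0]])
        t = np.arange(len(v), dtype=float)
        fit = ps.max_upslope(ps.TimeCurve(t, v), window=3)
        assert fit.window_end <= int(np.argmax(v)) + 2 + 1


class TestNormalizationAndRatio:
    def test_identity_and_zero(self):
        f1 = perf.UpslopeFit(2.0, 0, 5, 1.0)
        assert ps.normalized_upslope(f1, f1) == 1.0
        assert ps.normalized_upslope(perf.UpslopeFit(0.0, 0, 5, 1.0), f1) == 0.0

    def test_degenerate_aif(self):
        with pytest.raises(perf.DegenerateAIFError):
            ps.normalized_upslope(
                perf.UpslopeFit(1.0, 0, 5, 1.0), perf.UpslopeFit(-0.1, 0, 5, 1.0)
            )

    def test_ratio_arithmetic(self):
        assert ps.upslope_ratio(0.2, 0.1) == pytest.approx(2.0)
        assert ps.upslope_ratio(0.3, 0.3) == 1.0
        with pytest.raises(ValueError):
            ps.upslope_ratio(0.2, 0.0)

    def test_noiseless_phantom_recovers_k_exactly(self, uniform_phantom):
        aif, series, endo, epi, seg = uniform_phantom
        aif_fit = ps.max_upslope(ps.baseline_correct(
            ps.mean_signal_curve(series, _pool_mask(endo, series))))
        for sid in seg.segment_ids:
            fit = ps.max_upslope(ps.baseline_correct(
                ps.mean_signal_curve(series, seg.masks[sid])))
            assert ps.normalized_upslope(fit, aif_fit) == pytest.approx(0.7, rel=1e-12)

    def test_scale_invariance(self, uniform_phantom):
        aif, series, endo, epi, seg = uniform_phantom
        scaled = ps.PerfusionSeries(series.frames * 3.7, series.times,
                                    series.n_baseline)
        pool = _pool_mask(endo, series)
        for s in (series, scaled):
            a = ps.max_upslope(ps.mean_signal_curve(s, pool))
            t = ps.max_upslope(ps.mean_signal_curve(s, seg.masks[8]))
            if s is series:
                ref = ps.normalized_upslope(t, a)
            else:
                assert ps.normalized_upslope(t, a) == pytest.approx(ref, rel=1e-12)

    def test_shift_invariance(self, uniform_phantom):
        _, series, endo, epi, seg = uniform_phantom
        shifted = ps.PerfusionSeries(series.frames + 11.0, series.times,
                                     series.n_baseline)
        f0 = ps.max_upslope(ps.mean_signal_curve(series, seg.masks[9]))
        f1 = ps.max_upslope(ps.mean_signal_curve(shifted, seg.masks[9]))
        assert f0.slope == pytest.approx(f1.slope, rel=1e-12)


def _pool_mask(endo, series):
    import perfseg.geometry as geo

    return geo.contour_mask(endo, series.frames.shape[1:])


class TestPixelMapAndArea:
    def test_noiseless_uniform_map_constant(self, uniform_phantom):
        aif, series, endo, epi, seg = uniform_phantom
        aif_fit = ps.max_upslope(ps.baseline_correct(
            ps.mean_signal_curve(series, _pool_mask(endo, series))))
        umap = ps.pixel_upslope_map(series, seg.annulus, aif_fit)
        vals = umap[seg.annulus]
        np.testing.assert_allclose(vals, 0.7, rtol=1e-9)

    def test_two_sector_map_bimodal_matches_masks(self):
        aif = ps.generate_aif_curve(KineticParams(), np.arange(60.0), baseline=0.1)
        factors = {7: 1.0, 8: 1.0, 9: 0.4, 10: 1.0, 11: 1.0, 12: 1.0}
        series, endo, epi, seg = render_phantom_slice(
            PhantomGeometry(), aif, factors, noise_sd=0.0, level="mid",
            dtype=np.float64,
        )
        aif_fit = ps.max_upslope(ps.baseline_correct(
            ps.mean_signal_curve(series, _pool_mask(endo, series))))
        umap = ps.pixel_upslope_map(series, seg.annulus, aif_fit)
        assert np.allclose(umap[seg.masks[9]], 0.4, rtol=1e-6)
        for sid in (7, 8, 10, 11, 12):
            assert np.allclose(umap[seg.masks[sid]], 1.0, rtol=1e-6)

    def test_segment_mean_consistency(self, hcm_subject):
        # segment-curve upslope vs mean of the pixel map over the segment
        import perfseg.geometry as geo

        series = hcm_subject.stress_series["mid"]
        endo = hcm_subject.perfusion_contours.endo[1]
        epi = hcm_subject.perfusion_contours.epi[1]
        c_en, c_ep = ps.contract_annulus(endo, epi, 0.10)
        seg = ps.aha_sector_masks(c_en, c_ep,
                                  hcm_subject.perfusion_contours.rv_insertion_angle,
                                  "mid", series.frames.shape[1:])
        pool = geo.contour_mask(endo, series.frames.shape[1:])
        aif_fit = ps.max_upslope(ps.baseline_correct(
            ps.mean_signal_curve(series, pool)))
        umap = ps.pixel_upslope_map(series, seg.annulus, aif_fit)
        for sid in seg.segment_ids:
            fit = ps.max_upslope(ps.baseline_correct(
                ps.mean_signal_curve(series, seg.masks[sid])))
            norm = ps.normalized_upslope(fit, aif_fit)
            assert np.nanmean(umap[seg.masks[sid]]) == pytest.approx(norm, rel=0.15)

    def test_uniform_map_zero_area(self):
        mask = np.zeros((32, 32), bool)
        mask[8:24, 8:24] = True
        umap = np.where(mask, 1.0, np.nan)
        assert ps.hypoperfused_area(umap, mask) == 0.0

    def test_one_sector_below_threshold(self):
        mask = np.zeros((60, 60), bool)
        mask[10:50, 10:50] = True
        umap = np.where(mask, 1.0, np.nan)
        n = mask.sum()
        yy, xx = np.nonzero(mask)
        low = yy < np.quantile(yy, 1 / 6)
        umap[yy[low], xx[low]] = 0.1
        remote = mask & (umap > 0.5)
        got = ps.hypoperfused_area(umap, mask, remote_mask=remote)
        assert got == pytest.approx(100.0 * low.sum() / n, abs=1e-9)

    def test_area_monotone_in_threshold_and_bounded(self):
        rng = np.random.default_rng(1)
        mask = np.zeros((40, 40), bool)
        mask[5:35, 5:35] = True
        umap = np.where(mask, rng.uniform(0, 1, (40, 40)), np.nan)
        areas = [
            ps.hypoperfused_area(umap, mask, threshold_factor=f)
            for f in (0.2, 0.4, 0.6, 0.8)
        ]
        assert all(0.0 <= a <= 100.0 for a in areas)
        assert np.all(np.diff(areas) >= 0)  # nonincreasing in -factor direction


class TestExcludeMismatch:
    def test_clean_phantom_kept(self, hcm_fit):
        assert not hcm_fit.segments["excluded"].any()

    def test_noise_segment_dropped_for_low_r2(self):
        # seed chosen so the selected window's fit is representative of a
        # noise-replaced segment (most, not all, noise draws fall below 0.8)
        rng = np.random.default_rng(2)
        t = np.arange(40.0)
        noise = ps.TimeCurve(t, rng.normal(size=40), n_baseline=5)
        good = ps.TimeCurve(t, np.concatenate([np.zeros(10), np.arange(30.0)]),
                            n_baseline=5)
        f_noise = ps.max_upslope(noise)
        f_good = ps.max_upslope(good)
        keep, reason = ps.perfusion.exclude_mismatch(f_good, f_noise)
        assert not keep and "r2" in reason

    def test_geometric_mismatch_dropped(self):
        f = perf.UpslopeFit(1.0, 0, 5, 0.99)
        keep, reason = perf.exclude_mismatch(f, f, mask_dice=0.3)
        assert not keep and "Dice" in reason

    def test_dice_coefficient(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[:2] = True
        b[1:3] = True
        assert perf.dice_coefficient(a, b) == pytest.approx(0.5)
        assert perf.dice_coefficient(b, b) == 1.0
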
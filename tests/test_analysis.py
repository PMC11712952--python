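"""Filters, profile extraction, volume histograms and plan metrics."""

import numpy as np
import pytest
from scipy import ndimage

from dcslet.analysis import (median_filter, gaussian_smooth, find_bragg_peak,
                             planar_dose_weighted_letd, penumbra_letd_at_10pct,
                             volume_histogram, dose_percentile,
                             volume_at_least, plan_metrics, HistogramCurve)
from dcslet.scoring import VoxelGrid


def test_median_filter_constant_and_spike():
    const = np.full((6, 6, 6), 3.5)
    np.testing.assert_allclose(median_filter(const), const)
    spiked = const.copy()
    spiked[3, 3, 3] = 100.0
    out = median_filter(spiked)
    assert out[3, 3, 3] == pytest.approx(3.5)


def test_median_filter_brute_force_oracle(rng):
    vol = rng.normal(size=(5, 5, 5))
    got = median_filter(vol)
    for idx in [(0, 0, 0), (2, 2, 2), (4, 1, 3), (1, 4, 4)]:
        sl = tuple(slice(max(0, i - 1), min(5, i + 2)) for i in idx)
        assert got[idx] == pytest.approx(np.median(vol[sl]), rel=1e-6)


def test_median_filter_ignores_nan_neighbors():
    vol = np.full((4, 4, 4), 2.0)
    vol[0, 0, 0] = np.nan
    out = median_filter(vol)
    assert out[0, 0, 1] == pytest.approx(2.0)
    assert np.isnan(out[0, 0, 0]) or out[0, 0, 0] == pytest.approx(2.0)


def test_gaussian_smooth_preserves_constants_and_mass(rng):
    const = np.full((8, 8, 8), 1.7)
    np.testing.assert_allclose(gaussian_smooth(const)[2:-2, 2:-2, 2:-2],
                               1.7, rtol=1e-12)
    interior = np.zeros((16, 16, 16))
    interior[6:10, 6:10, 6:10] = rng.uniform(1, 2, (4, 4, 4))
    out = gaussian_smooth(interior)
    assert out.sum() == pytest.approx(interior.sum(), rel=1e-9)


def test_gaussian_smooth_matches_direct_convolution(rng):
    vol = rng.normal(size=(5, 5, 5))
    got = gaussian_smooth(vol, sigma=0.5)
    ref = ndimage.gaussian_filter(vol, 0.5, truncate=4.0, mode="constant")
    den = ndimage.gaussian_filter(np.ones_like(vol), 0.5, truncate=4.0,
                                  mode="constant")
    np.testing.assert_allclose(got, ref / den, rtol=1e-9)


def test_find_bragg_peak_triangle_and_monotone():
    z = np.arange(0, 10.0, 0.1)
    tri = 5.0 - np.abs(z - 4.0)
    assert find_bragg_peak(z, tri) == pytest.approx(4.0, abs=1e-9)
    with pytest.raises(ValueError):
        find_bragg_peak(z, z)  # monotone


def test_planar_dose_weighted_letd_limits():
    grid = VoxelGrid((0, 0, 0), (1, 1, 1), (4, 4, 3))
    letd = np.zeros((4, 4, 3))
    letd[:, :, 1] = np.arange(16).reshape(4, 4)
    dose = np.ones((4, 4, 3))
    got = planar_dose_weighted_letd(dose, letd, grid, 1.5)
    assert got == pytest.approx(np.mean(np.arange(16)))
    dose2 = np.zeros((4, 4, 3))
    dose2[2, 3, 1] = 5.0
    assert planar_dose_weighted_letd(dose2, letd, grid, 1.5) == \
        pytest.approx(letd[2, 3, 1])
    with pytest.raises(ValueError):
        planar_dose_weighted_letd(np.zeros((4, 4, 3)), letd, grid, 1.5)


def test_penumbra_letd_at_10pct():
    x = np.linspace(-3, 3, 301)
    rect = np.where(np.abs(x) <= 1.0, 1.0, 0.0)
    letd = np.where(np.abs(x) <= 1.0, 2.0, 8.0)
    left, right = penumbra_letd_at_10pct(x, rect, letd)
    assert left == pytest.approx(right)
    gauss = np.exp(-0.5 * x**2)
    flat = np.full_like(x, 3.0)
    l2, r2 = penumbra_letd_at_10pct(x, gauss, flat)
    assert l2 == pytest.approx(3.0) and r2 == pytest.approx(3.0)
    # LET ridge at the edge: penumbra LET_d above central LET_d
    ridge = 3.0 + 5.0 * np.exp(-0.5 * ((np.abs(x) - 2.146) / 0.1) ** 2)
    l3, r3 = penumbra_letd_at_10pct(x, gauss, ridge)
    assert l3 > 3.5 and r3 > 3.5
    with pytest.raises(ValueError):
        penumbra_letd_at_10pct(x, gauss, flat, level=1e-9)


def test_volume_histogram_step_and_d95():
    vol = np.full((5, 5, 5), 10.0)
    roi = np.zeros((5, 5, 5), bool)
    roi[1:4, 1:4, 1:4] = True
    hv = volume_histogram(vol, roi, bin_edges=np.linspace(0, 20, 100))
    assert np.all(np.diff(hv.volume_fraction) <= 0)
    assert hv.volume_fraction[0] == 1.0
    # step at 10
    below = hv.bin_edges < 10.0
    assert np.all(hv.volume_fraction[below] == 1.0)
    assert np.all(hv.volume_fraction[~below][1:] == 0.0)
    assert dose_percentile(vol, roi, 0.95) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        volume_histogram(vol, np.zeros((5, 5, 5), bool))


def test_plan_metrics_normalization_and_scale_invariance():
    shape = (10, 10, 10)
    rngl = np.random.default_rng(0)
    dose = rngl.uniform(20, 30, shape)
    letd = rngl.uniform(1, 5, shape)
    rois = {"target": np.zeros(shape, bool), "body": np.ones(shape, bool),
            "skin": np.zeros(shape, bool)}
    rois["target"][2:8, 2:8, 2:8] = True
    rois["skin"][:, :, 0] = True
    rois["ring_5mm"] = ~rois["target"]
    t1 = plan_metrics(dose, dose * 1.1, letd, rois, 25.0, 0.008)
    assert t1.set_index("metric").loc["target_D95", "physical"] == \
        pytest.approx(1.0)
    # scaling the plan and renormalizing leaves relative metrics unchanged
    t2 = plan_metrics(2 * dose, 2.2 * dose, letd, rois, 50.0, 0.008)
    for m in ("target_D95", "ring_5mm_median", "body_mean", "skin_max"):
        a = t1.set_index("metric").loc[m]
        b = t2.set_index("metric").loc[m]
        assert a.physical == pytest.approx(b.physical)
    # V50 in cm^3: scale-invariant after prescription rescaling
    v1 = t1.set_index("metric").loc["V50_cm3", "physical"]
    v2 = t2.set_index("metric").loc["V50_cm3", "physical"]
    assert v1 == pytest.approx(v2)


def test_histogram_curve_value_at_volume():
    edges = np.linspace(0, 10, 11)
    frac = np.linspace(1, 0, 11)
    hv = HistogramCurve(edges, frac)
    assert hv.value_at_volume(0.5) == pytest.approx(5.0)
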
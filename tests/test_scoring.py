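"""Voxel accumulators, the LET_t/LET_d/dose conversions and plane spectra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcslet.scoring import (ScoreMaps, VoxelGrid, PlaneSpectrum, score_step,
                            score_point, lett_map, letd_map, dose_map,
                            record_plane_crossing)

KEV_UM = 0.1  # keV/um per MeV/cm


def test_step_inside_one_voxel(small_maps):
    score_step(small_maps, (0.2, 0.2, 0.2), (0.2, 0.2, 0.9), eps=2.0, l=0.7)
    assert small_maps.sum_e[0, 0, 0] == pytest.approx(2.0)
    assert small_maps.sum_l[0, 0, 0] == pytest.approx(0.7)
    assert small_maps.sum_e2_over_l[0, 0, 0] == pytest.approx(4.0 / 0.7)


def test_step_split_evenly_across_two_voxels(small_maps):
    # straddles the z face at 1.0 symmetrically: each voxel gets
    # (eps/2, l/2, eps^2/(2 l))
    score_step(small_maps, (0.5, 0.5, 0.6), (0.5, 0.5, 1.4), eps=3.0, l=0.8)
    for k in (0, 1):
        assert small_maps.sum_e[0, 0, k] == pytest.approx(1.5)
        assert small_maps.sum_l[0, 0, k] == pytest.approx(0.4)
        assert small_maps.sum_e2_over_l[0, 0, k] == pytest.approx(
            9.0 / (2 * 0.8))


def test_split_conserves_energy_and_path(small_maps, rng):
    tot_eps = tot_l = 0.0
    for _ in range(40):
        p0 = rng.uniform(0.1, 3.9, 3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        l = float(rng.uniform(0.05, 1.2))
        p1 = p0 + d * l
        if np.any(p1 < 0.05) or np.any(p1 > 3.95):
            continue
        score_step(small_maps, p0, p1, eps=1.0, l=l)
        tot_eps += 1.0
        tot_l += l
    assert tot_eps > 0
    # summing sub-step contributions over voxels recovers every (eps, l)
    assert small_maps.sum_e.sum() == pytest.approx(tot_eps, rel=1e-9)
    assert small_maps.sum_l.sum() == pytest.approx(tot_l, rel=1e-9)


def test_zero_length_step_rejected(small_maps):
    with pytest.raises(ValueError):
        score_step(small_maps, (1, 1, 1), (1, 1, 1), eps=1.0, l=0.0)


def test_lett_letd_hand_examples(small_grid):
    # steps (eps=1, l=1) and (eps=3, l=1) in keV/um units: place two 1 um
    # steps (1e-4 cm) with 1 keV and 3 keV in one voxel
    maps = ScoreMaps(small_grid)
    um, kev = 1e-4, 1e-3
    score_step(maps, (1, 1, 1.0), (1, 1, 1.0 + um), eps=kev, l=um)
    score_step(maps, (1, 1, 1.0), (1, 1, 1.0 + um), eps=3 * kev, l=um)
    lt = lett_map(maps, dose_mask_rel=0.0)
    ld = letd_map(maps, dose_mask_rel=0.0)
    assert lt[1, 1, 1] == pytest.approx(2.0)          # (1+3)/(1+1) keV/um
    assert ld[1, 1, 1] == pytest.approx(2.5)          # (1+9)/(1+3) keV/um
    assert np.isnan(lt[0, 0, 0]) and np.isnan(ld[0, 0, 0])


@settings(max_examples=60, deadline=None)
@given(st.lists(st.tuples(st.floats(0.01, 5.0), st.floats(0.01, 2.0)),
                min_size=1, max_size=30))
def test_letd_at_least_lett_cauchy_schwarz(steps):
    """Dose-averaged LET dominates track-averaged LET for any step set."""
    grid = VoxelGrid((0, 0, 0), (10, 10, 10), (1, 1, 1))
    maps = ScoreMaps(grid)
    for eps, l in steps:
        score_step(maps, (5, 5, 4.0), (5, 5, 4.0 + l / 10), eps=eps, l=l / 10)
    lt = lett_map(maps, dose_mask_rel=0.0)[0, 0, 0]
    ld = letd_map(maps, dose_mask_rel=0.0)[0, 0, 0]
    # brute-force oracle straight from the definitions
    e = np.array([s[0] for s in steps])
    l = np.array([s[1] for s in steps]) / 10
    assert lt == pytest.approx(e.sum() / l.sum() * KEV_UM, rel=1e-9)
    assert ld == pytest.approx((e**2 / l).sum() / e.sum() * KEV_UM, rel=1e-9)
    assert ld >= lt * (1 - 1e-12)


def test_merge_equals_union_of_steps(small_grid, rng):
    a, b, union = (ScoreMaps(small_grid) for _ in range(3))
    for maps_list in ([a, union], [b, union]):
        p0 = rng.uniform(0.5, 3.5, 3)
        p1 = p0 + rng.uniform(-0.4, 0.4, 3)
        l = float(np.linalg.norm(p1 - p0))
        for m in maps_list:
            score_step(m, p0, p1, eps=1.7, l=l)
    merged = a.merge(b)
    np.testing.assert_allclose(merged.sum_e, union.sum_e)
    np.testing.assert_allclose(merged.sum_l, union.sum_l)
    np.testing.assert_allclose(merged.sum_e2_over_l, union.sum_e2_over_l)


def test_let_maps_invariant_under_weight_rescaling(small_grid):
    maps = ScoreMaps(small_grid)
    score_step(maps, (1, 1, 1), (1, 1, 2), eps=2.0, l=1.0)
    scaled = ScoreMaps(small_grid, maps.sum_e * 7, maps.sum_l * 7,
                       maps.sum_e2_over_l * 7)
    np.testing.assert_allclose(letd_map(maps, 0.0), letd_map(scaled, 0.0))
    np.testing.assert_allclose(lett_map(maps, 0.0), lett_map(scaled, 0.0))


def test_dose_map_linearity_and_conservation(small_grid):
    maps = ScoreMaps(small_grid)
    score_step(maps, (0.5, 0.5, 0.5), (2.5, 2.5, 2.5), eps=10.0,
               l=float(np.sqrt(12.0)))
    d1 = dose_map(maps)
    doubled = ScoreMaps(small_grid, maps.sum_e * 2, maps.sum_l,
                        maps.sum_e2_over_l)
    np.testing.assert_allclose(dose_map(doubled), 2 * d1)
    # integral dose times voxel mass recovers total energy
    assert (d1 * small_grid.voxel_volume).sum() == pytest.approx(10.0)
    assert dose_map(ScoreMaps(small_grid)).sum() == 0.0


def test_point_deposit_enters_dose_not_let(small_maps):
    score_point(small_maps, (1.5, 1.5, 1.5), eps=4.0)
    assert small_maps.sum_e_point[1, 1, 1] == 4.0
    assert small_maps.sum_l[1, 1, 1] == 0.0
    assert dose_map(small_maps)[1, 1, 1] == pytest.approx(4.0)
    assert np.isnan(letd_map(small_maps, dose_mask_rel=0.0)[1, 1, 1])


def test_plane_spectrum_binning_convention():
    sp = PlaneSpectrum(z_plane=0.0)
    record_plane_crossing(sp, [149.95, 149.95, 80.0])
    assert sp.energy_hist[1499] == 2       # [149.9, 150.0)
    assert sp.energy_hist[800] == 1
    assert sp.total() == 3
    # monoenergetic crossings occupy a single bin
    sp2 = PlaneSpectrum(z_plane=0.0)
    record_plane_crossing(sp2, np.full(50, 120.02))
    assert (sp2.energy_hist > 0).sum() == 1


def test_plane_spectrum_rejects_nonpositive_energy():
    sp = PlaneSpectrum(z_plane=0.0)
    with pytest.raises(ValueError):
        record_plane_crossing(sp, [0.0])
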
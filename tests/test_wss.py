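"""Wall shear stress: Poiseuille traction oracles, histogram bookkeeping,
stimulation bands and subregion averages."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import VOX_UM, make_plates_image
from scaffoldflow import (
    MicroBC,
    WSSField,
    area_fraction_in_band,
    build_fluid_domain,
    compute_wss,
    flow_rate,
    solve_stokes,
    subregion_average_wss,
    wss_histogram,
)


def interior_mean_wss(w, z0, z1):
    z = w.positions[:, 2]
    sel = (z >= z0) & (z < z1)
    return float((w.wss[sel] * w.areas[sel]).sum() / w.areas[sel].sum())


class TestPoiseuilleTraction:
    def test_parallel_plates_wall_stress(self, plates_field, props):
        """Gap h = 0.2 mm at u_mean = 500 µm/s: τ_w = 6µu/h = 15 mPa."""
        w = compute_wss(plates_field)
        gap = 20 * plates_field.voxel_size_m
        q = flow_rate(plates_field, 30)
        u_mean = q / (gap * plates_field.domain.shape[1]
                      * plates_field.voxel_size_m)
        expected = 6 * props.mu * u_mean / gap
        tau = interior_mean_wss(w, 150.0, 450.0)
        assert tau == pytest.approx(expected, rel=0.05)

    def test_cylindrical_channel_wall_stress(self, cylinder_field, props):
        """R = 100 µm: τ_w = 4µ·u_mean/R, with the smoothed-normal surface
        model correcting the staircase bias of the voxelized wall."""
        w = compute_wss(cylinder_field)
        h = cylinder_field.voxel_size_m
        radius = 10 * h
        q = flow_rate(cylinder_field, 20)
        u_mean = q / (np.pi * radius**2)
        expected = 4 * props.mu * u_mean / radius
        tau = interior_mean_wss(w, 100.0, 300.0)
        assert tau == pytest.approx(expected, rel=0.05)

    def test_staircase_surface_area_bias_is_corrected(self, cylinder_field):
        """The exposed voxel-face area of a cylinder exceeds the true
        lateral area by ~4/π; the smoothed-normal projection recovers it."""
        h_um = VOX_UM
        radius_um = 10 * h_um
        w = compute_wss(cylinder_field)
        z = w.positions[:, 2]
        sel = (z >= 100.0) & (z < 300.0)
        true_area = 2 * np.pi * radius_um * 200.0
        assert w.areas[sel].sum() == pytest.approx(true_area, rel=0.05)
        raw = compute_wss(cylinder_field, surface_model="staircase")
        zr = raw.positions[:, 2]
        selr = (zr >= 100.0) & (zr < 300.0)
        assert raw.areas[selr].sum() == pytest.approx(true_area * 4 / np.pi,
                                                      rel=0.05)

    def test_zero_flow_zero_wss(self, props):
        dom = build_fluid_domain(make_plates_image(gap=8, nz=16))
        f = solve_stokes(dom, MicroBC("velocity", 0.0, 0.0, "symmetric"),
                         props, tol=1e-6)
        w = compute_wss(f)
        assert len(w) > 0 and np.all(w.wss == 0)

    def test_wss_scales_linearly_with_inlet(self, props):
        dom = build_fluid_domain(make_plates_image(gap=10, nz=20))
        taus = []
        for v in (1e-4, 3e-4):
            f = solve_stokes(dom, MicroBC("velocity", v, 0.0, "symmetric"),
                             props, tol=1e-10)
            taus.append(compute_wss(f).wss)
        ratio = taus[1] / taus[0]
        assert np.max(np.abs(ratio - 3.0)) <= 1e-8 * 3.0


def _field_from_values(values_mpa, areas=None):
    n = len(values_mpa)
    areas = np.ones(n) if areas is None else np.asarray(areas, float)
    return WSSField(
        positions=np.zeros((n, 3)), areas=areas,
        normals=np.tile([1.0, 0, 0], (n, 1)),
        wss=np.asarray(values_mpa, float) * 1e-3,
    )


class TestHistogram:
    def test_value_lands_in_right_open_bin(self):
        h = wss_histogram(_field_from_values([7.0]), bin_width=5.0)
        k = np.flatnonzero(h.weights)
        assert len(k) == 1
        assert (h.bin_edges[k[0]], h.bin_edges[k[0] + 1]) == (5.0, 10.0)

    def test_area_weights_sum_to_total_area(self):
        rng = np.random.default_rng(0)
        f = _field_from_values(rng.uniform(0, 150, 200),
                               areas=rng.uniform(0.5, 2.0, 200))
        h = wss_histogram(f, bin_width=5.0, max_mpa=100.0, weighting="area")
        assert h.weights.sum() == pytest.approx(f.total_area, rel=1e-12)

    def test_doubling_bin_width_merges_adjacent_bins(self):
        rng = np.random.default_rng(1)
        f = _field_from_values(rng.uniform(0, 99, 500))
        fine = wss_histogram(f, bin_width=5.0, max_mpa=100.0)
        coarse = wss_histogram(f, bin_width=10.0, max_mpa=100.0)
        merged = fine.weights[:-1].reshape(-1, 2).sum(axis=1)
        np.testing.assert_allclose(coarse.weights[:-1], merged, rtol=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**31), st.floats(0.5, 20.0))
    def test_conservation_under_any_bin_width(self, seed, width):
        rng = np.random.default_rng(seed)
        f = _field_from_values(rng.uniform(0, 200, 100),
                               areas=rng.uniform(0.1, 3.0, 100))
        h = wss_histogram(f, bin_width=width, max_mpa=100.0)
        assert h.weights.sum() == pytest.approx(f.total_area, rel=1e-9)


class TestBands:
    def test_full_band_is_unity(self):
        rng = np.random.default_rng(2)
        f = _field_from_values(rng.uniform(0, 80, 50))
        assert area_fraction_in_band(f, 0.0, np.inf) == pytest.approx(1.0)

    def test_complementary_bands_partition(self):
        rng = np.random.default_rng(3)
        f = _field_from_values(rng.uniform(0, 80, 101))
        a = area_fraction_in_band(f, 0.0, 30.0)
        b = area_fraction_in_band(f, 30.0, np.inf)
        assert a + b == pytest.approx(1.0, rel=1e-12)

    def test_matches_brute_force_element_scan(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 60, 300)
        areas = rng.uniform(0.2, 2.0, 300)
        f = _field_from_values(vals, areas)
        got = area_fraction_in_band(f, 10.0, 30.0)
        expected = areas[(vals >= 10.0) & (vals < 30.0)].sum() / areas.sum()
        assert got == expected


class TestSubregions:
    FOOT = ((0.0, 500.0), (0.0, 500.0))

    def _random_field(self, n=400, seed=5):
        rng = np.random.default_rng(seed)
        pos = np.column_stack([
            rng.uniform(0, 500, n), rng.uniform(0, 500, n),
            rng.uniform(0, 1000, n),
        ])
        return WSSField(pos, rng.uniform(0.5, 2.0, n),
                        np.tile([1.0, 0, 0], (n, 1)),
                        rng.uniform(0, 0.05, n))

    def test_uniform_field_gives_equal_averages(self):
        f = self._random_field()
        f.wss[:] = 0.012
        avgs = subregion_average_wss(f, self.FOOT, n_regions=5, width=50.0)
        np.testing.assert_allclose(avgs, 12.0, rtol=1e-12)

    def test_five_regions_tile_the_footprint(self):
        """5 × 0.05 mm annuli on a 0.5 mm RVE reach exactly the center:
        every element is classified."""
        f = self._random_field()
        x, y = f.positions[:, 0], f.positions[:, 1]
        d = np.minimum.reduce([x, 500 - x, y, 500 - y])
        assert (d < 5 * 50.0).all()
        avgs = subregion_average_wss(f, self.FOOT, n_regions=5, width=50.0)
        assert not np.isnan(avgs).any()

    def test_matches_brute_force_classification(self):
        f = self._random_field(seed=6)
        avgs = subregion_average_wss(f, self.FOOT, n_regions=5, width=50.0)
        x, y = f.positions[:, 0], f.positions[:, 1]
        d = np.minimum.reduce([x, 500 - x, y, 500 - y])
        for k in range(5):
            sel = (d >= k * 50.0) & (d < (k + 1) * 50.0)
            expected = (f.wss[sel] * f.areas[sel]).sum() / f.areas[sel].sum()
            assert avgs[k] == expected * 1e3

    def test_too_many_regions_rejected(self):
        with pytest.raises(ValueError):
            subregion_average_wss(self._random_field(), self.FOOT,
                                  n_regions=6, width=50.0)


class TestInvariants:
    def test_negative_wss_rejected(self):
        with pytest.raises(ValueError):
            WSSField(np.zeros((1, 3)), np.ones(1), np.ones((1, 3)),
                     np.array([-1.0]))
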
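import dataclasses

import numpy as np
import pytest

import mugrid as mg
from mugrid.anatomy import MuscleGeometry
from mugrid.conductor import TissueElectrical, compute_muaps, fiber_potential, intracellular_ap


class TestIntracellularAP:
    def test_resting_at_origin(self):
        assert intracellular_ap(0.0) == pytest.approx(-90.0)

    def test_peak_region_value(self):
        assert intracellular_ap(3.0) == pytest.approx(96 * 27 * np.exp(-3) - 90, abs=1e-9)
        assert intracellular_ap(3.0) == pytest.approx(39.05, abs=0.01)

    def test_resting_far_field_and_behind(self):
        assert intracellular_ap(-5.0) == pytest.approx(-90.0)
        assert intracellular_ap(80.0) == pytest.approx(-90.0, abs=1e-6)


class TestFiberPotential:
    geometry = MuscleGeometry()

    def _wave(self, depth_mm, electrode=(0.0, 0.0)):
        R = self.geometry.outer_radius
        return fiber_potential(
            fiber_xy=(0.0, R - depth_mm),
            endplate_z=0.0,
            cv=4.0,
            electrode=np.asarray(electrode),
            geometry=self.geometry,
        )

    def test_zero_window_empty(self):
        v = fiber_potential((0, 20), 0.0, 4.0, np.array([0.0, 0.0]), window_ms=0.0)
        assert v.size == 0

    def test_depth_attenuates_and_broadens(self):
        shallow = self._wave(8.0)
        deep = self._wave(18.0)
        assert np.ptp(deep) < np.ptp(shallow)
        # energy-weighted duration grows with depth (stronger tissue low-pass)
        def duration(v):
            e = v**2
            t = np.arange(v.size)
            mu = np.sum(t * e) / np.sum(e)
            return np.sqrt(np.sum((t - mu) ** 2 * e) / np.sum(e))
        assert duration(deep) > duration(shallow)

    def test_superposition_doubles(self):
        one = self._wave(10.0)
        np.testing.assert_allclose(one + one, 2 * one)

    def test_electrode_below_surface_rejected(self):
        with pytest.raises(ValueError):
            fiber_potential(
                (0, 20), 0.0, 4.0, np.array([0.0, 0.0]),
                electrode_radius_from_axis=20.0,
            )


class TestComputeMUAPs:
    def test_single_fiber_unit_equals_fiber_potential(self, small_pool):
        unit = small_pool.units[0]
        single = dataclasses.replace(
            unit,
            fiber_positions=unit.fiber_positions[:1],
            endplate_z=unit.endplate_z[:1],
        )
        pool1 = dataclasses.replace(small_pool, units=(single,))
        grid = mg.simulated_grid(4, 8)
        muaps = compute_muaps(pool1, grid)
        tissue = TissueElectrical()
        direct = fiber_potential(
            unit.fiber_positions[0],
            unit.endplate_z[0],
            float(tissue.cv(unit.n_fibers)),
            grid.electrode_positions(),
            geometry=small_pool.geometry,
            tissue=tissue,
        )
        np.testing.assert_allclose(muaps.waveforms[0], direct, rtol=2e-4, atol=1e-7)

    def test_subsample_at_full_count_is_exact(self, small_pool):
        grid = mg.simulated_grid(4, 12)
        full = compute_muaps(small_pool, grid, fiber_subsample=None, seed=0)
        same = compute_muaps(small_pool, grid, fiber_subsample=10**6, seed=0)
        np.testing.assert_array_equal(full.waveforms, same.waveforms)

    def test_merged_unit_is_additive(self, small_pool):
        # splitting a unit's fibers into two half-units (same CV) and summing
        # their MUAPs reproduces the full unit's MUAP exactly
        grid = mg.simulated_grid(4, 12)
        unit = small_pool.units[5]
        h = unit.fiber_positions.shape[0] // 2
        half_a = dataclasses.replace(
            unit, fiber_positions=unit.fiber_positions[:h], endplate_z=unit.endplate_z[:h]
        )
        half_b = dataclasses.replace(
            unit, fiber_positions=unit.fiber_positions[h:], endplate_z=unit.endplate_z[h:]
        )
        w_full = compute_muaps(
            dataclasses.replace(small_pool, units=(unit,)), grid
        ).waveforms[0]
        w_a = compute_muaps(
            dataclasses.replace(small_pool, units=(half_a,)), grid
        ).waveforms[0]
        w_b = compute_muaps(
            dataclasses.replace(small_pool, units=(half_b,)), grid
        ).waveforms[0]
        np.testing.assert_allclose(w_a + w_b, w_full, rtol=1e-4, atol=1e-6)

    def test_amplitude_decreases_with_depth(self, small_pool):
        grid = mg.simulated_grid(4, 8)
        geometry = small_pool.geometry
        unit = small_pool.units[5]
        p2p = []
        for depth in (8.0, 14.0, 20.0):
            y = geometry.outer_radius - depth
            shift = np.array([0.0, y]) - unit.center
            moved = dataclasses.replace(
                unit,
                center=unit.center + shift,
                fiber_positions=unit.fiber_positions + shift,
            )
            pool = dataclasses.replace(small_pool, units=(moved,))
            w = compute_muaps(pool, grid).waveforms[0]
            p2p.append(np.ptp(w))
        assert p2p[0] > p2p[1] > p2p[2]

    def test_axial_translation_equivariance(self, small_pool):
        grid = mg.simulated_grid(4, 12)
        shifted_grid = dataclasses.replace(
            grid, origin=(grid.origin[0] + 7.0, grid.origin[1])
        )
        base = compute_muaps(small_pool, grid, seed=1)
        moved = compute_muaps(small_pool, shifted_grid, seed=1, axial_center=7.0)
        np.testing.assert_allclose(base.waveforms, moved.waveforms, atol=1e-7)

    def test_empty_inputs_rejected(self, small_pool):
        grid = mg.simulated_grid(4, 12)
        empty = dataclasses.replace(small_pool, units=())
        with pytest.raises(ValueError):
            compute_muaps(empty, grid)

    def test_disc_stencil_close_to_point_electrodes(self, small_pool):
        grid = mg.simulated_grid(4, 12)
        point = compute_muaps(small_pool, grid, seed=0)
        disc = compute_muaps(small_pool, grid, seed=0, disc_electrode_stencil=True)
        # 1-mm contacts barely differ from point electrodes at >=2-mm IED
        num = np.sum(point.waveforms * disc.waveforms)
        den = np.sqrt(np.sum(point.waveforms**2) * np.sum(disc.waveforms**2))
        assert num / den > 0.999


class TestFiberSubsampling:
    def test_subsample_rarely_changes_identifiability(self, pool200):
        # identifiability decisions from <=100 subsampled fibers per unit
        # match the full-fiber computation for almost every unit
        from mugrid.discriminability import identifiable_set

        grid = mg.simulated_grid(4, 16)
        sub = compute_muaps(pool200, grid, fiber_subsample=100, seed=9)
        full = compute_muaps(pool200, grid, fiber_subsample=None)
        changed = np.mean(identifiable_set(sub) != identifiable_set(full))
        assert changed < 0.05


class TestTissueElectrical:
    def test_cv_range_enforced(self):
        with pytest.raises(ValueError):
            TissueElectrical(cv_min=1.0)

    def test_cv_increases_with_size(self):
        t = TissueElectrical()
        assert t.cv(15) < t.cv(200) < t.cv(1500)
        assert 3.5 <= t.cv(15) and t.cv(1500) <= 4.5

    def test_positive_parameters_enforced(self):
        with pytest.raises(ValueError):
            TissueElectrical(anisotropy_ratio=0.0)
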
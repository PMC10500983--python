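import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mugrid.synthesis import (
    MAX_DISCHARGE_RATE,
    RateModel,
    fth,
    invert_fth,
    render_emg,
    simulate_discharges,
    trapezoid_profile,
)


class TestRecruitmentLaw:
    def test_zero_index(self):
        assert fth(0.0) == 0.0

    def test_top_threshold(self):
        assert fth(1.0) == pytest.approx(89.06, abs=1e-9)

    def test_strictly_increasing(self):
        j = np.linspace(0, 1, 1000)
        f = fth(j)
        assert np.all(np.diff(f) > 0)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            fth(1.2)

    def test_inverse_round_trip(self):
        assert invert_fth(fth(0.3)) == pytest.approx(0.3, abs=1e-9)

    def test_inverse_of_30_percent(self):
        j = invert_fth(30.0)
        assert fth(j) == pytest.approx(30.0, abs=1e-6)
        assert j == pytest.approx(0.4845, abs=5e-4)

    def test_inverse_out_of_range(self):
        with pytest.raises(ValueError):
            invert_fth(95.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_inverse_round_trips_everywhere(self, j):
        assert invert_fth(fth(j)) == pytest.approx(j, abs=1e-8)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_monotone_everywhere(self, a, b):
        lo, hi = sorted((a, b))
        if hi > lo:
            assert fth(hi) > fth(lo)


class TestTrapezoid:
    def test_duration_30_percent(self):
        p = trapezoid_profile(30.0, plateau_s=20.0)
        assert p.duration_s == pytest.approx(32.0, abs=1e-3)

    def test_duration_50_percent(self):
        p = trapezoid_profile(50.0, plateau_s=15.0)
        assert p.duration_s == pytest.approx(35.0, abs=1e-3)

    def test_peak_equals_target(self):
        p = trapezoid_profile(30.0, plateau_s=20.0)
        assert p.samples.max() == pytest.approx(30.0)

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            trapezoid_profile(-1.0, plateau_s=5.0)


class TestDischarges:
    profile = trapezoid_profile(30.0, plateau_s=10.0, fs=2048)

    def test_units_above_target_silent(self):
        trains = simulate_discharges(self.profile, 20, seed=0)
        for i, t in enumerate(trains.spike_times):
            if trains.thresholds[i] > 30.0:
                assert len(t) == 0

    def test_recruitment_follows_threshold_order(self):
        trains = simulate_discharges(self.profile, 20, seed=1)
        onsets = [t[0] for t in trains.spike_times if len(t)]
        assert onsets == sorted(onsets)

    def test_zero_jitter_gives_constant_plateau_isi(self):
        trains = simulate_discharges(self.profile, 5, isi_cov=0.0, seed=2)
        t = np.asarray(trains.spike_times[0])
        plateau = t[(t > 7.0) & (t < 15.0)]
        isi = np.diff(plateau)
        assert np.allclose(isi, isi[0], atol=1e-9)

    def test_rates_below_ceiling(self):
        trains = simulate_discharges(self.profile, 30, seed=3)
        for t in trains.spike_times:
            if len(t) > 1:
                assert (1.0 / np.diff(t)).max() <= MAX_DISCHARGE_RATE + 1e-9

    def test_early_labels_split_active_pool(self):
        trains = simulate_discharges(self.profile, 100, seed=4)
        active = trains.active_units()
        early = trains.early_labels
        assert early.sum() > 0
        assert np.all(~early[~active])  # inactive units are never early

    def test_rate_model_validation(self):
        with pytest.raises(ValueError):
            RateModel(rate_min=10, rate_max=60)


class TestRenderEMG:
    def test_single_spike_noise_free_reproduces_muap(self, small_muaps):
        from mugrid.synthesis import SpikeTrainSet

        fs = small_muaps.fs
        t0 = 0.25
        trains = SpikeTrainSet(
            spike_times=(np.array([t0]),),
            thresholds=np.array([0.0]),
            pool_indices=np.array([0.0]),
            early_labels=np.array([True]),
            fs=fs,
            duration_s=1.0,
            seed=0,
        )
        emg = render_emg(small_muaps.select_units([0]), trains, snr_db=np.inf)
        i0 = int(round(t0 * fs))
        wlen = small_muaps.n_samples
        np.testing.assert_allclose(
            emg.data[:, i0 : i0 + wlen],
            small_muaps.waveforms[0],
            atol=1e-5,
        )
        assert np.allclose(emg.data[:, : i0 - 1], 0.0)

    def test_noise_power_matches_snr(self, small_muaps):
        prof = trapezoid_profile(30.0, plateau_s=4.0)
        trains = simulate_discharges(prof, small_muaps.n_units, seed=5)
        clean = render_emg(small_muaps, trains, snr_db=np.inf)
        noisy = render_emg(small_muaps, trains, snr_db=20.0, seed=6)
        p_signal = np.mean(clean.data.astype(np.float64) ** 2)
        p_noise = np.mean((noisy.data - clean.data).astype(np.float64) ** 2)
        assert 10 * np.log10(p_signal / p_noise) == pytest.approx(20.0, abs=0.1)

    def test_superposition_noise_free(self, small_muaps):
        prof = trapezoid_profile(30.0, plateau_s=2.0)
        trains = simulate_discharges(prof, small_muaps.n_units, seed=7)
        full = render_emg(small_muaps, trains, snr_db=np.inf)
        # silence half the units in two complementary copies
        def silenced(keep):
            times = tuple(
                t if i in keep else np.empty(0)
                for i, t in enumerate(trains.spike_times)
            )
            return dataclasses.replace(trains, spike_times=times)
        half_a = render_emg(small_muaps, silenced(set(range(0, 6))), snr_db=np.inf)
        half_b = render_emg(small_muaps, silenced(set(range(6, 12))), snr_db=np.inf)
        np.testing.assert_allclose(half_a.data + half_b.data, full.data, atol=1e-4)

    def test_seeded_determinism(self, small_muaps):
        prof = trapezoid_profile(30.0, plateau_s=2.0)
        trains = simulate_discharges(prof, small_muaps.n_units, seed=8)
        a = render_emg(small_muaps, trains, snr_db=15.0, seed=9)
        b = render_emg(small_muaps, trains, snr_db=15.0, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_empty_trains_give_pure_noise(self, small_muaps):
        from mugrid.synthesis import SpikeTrainSet

        trains = SpikeTrainSet(
            spike_times=tuple(np.empty(0) for _ in range(small_muaps.n_units)),
            thresholds=np.zeros(small_muaps.n_units),
            pool_indices=np.zeros(small_muaps.n_units),
            early_labels=np.zeros(small_muaps.n_units, dtype=bool),
            fs=small_muaps.fs,
            duration_s=2.0,
            seed=0,
        )
        emg = render_emg(small_muaps, trains, snr_db=20.0, seed=3)
        rms = np.sqrt(np.mean(emg.data.astype(np.float64) ** 2))
        assert rms == pytest.approx(1.0, abs=1e-3)  # unit-RMS noise, nothing else

    def test_mismatched_rate_rejected(self, small_muaps):
        prof = trapezoid_profile(30.0, plateau_s=2.0, fs=1024)
        trains = simulate_discharges(prof, small_muaps.n_units, seed=8)
        with pytest.raises(ValueError):
            render_emg(small_muaps, trains)
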
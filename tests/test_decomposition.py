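import dataclasses

import numpy as np
import pytest

from mugrid.decomposition import (
    DecompConfig,
    PulseTrain,
    WhitenedEMG,
    _two_means_split,
    cov_isi,
    decompose,
    extend_and_whiten,
    extend_channels,
    extract_source,
    pnr,
    preprocess,
    refine_by_cov,
    remove_duplicates,
    shared_discharge_fraction,
)
from mugrid.mu_metrics import match_to_ground_truth, rate_of_agreement

FS = 2048.0


def _tone(freq, n_ch=10, dur=2.0, fs=FS, seed=0):
    t = np.arange(int(dur * fs)) / fs
    g = np.random.default_rng(seed)
    base = np.sin(2 * np.pi * freq * t)
    return np.stack([base + 0.001 * g.standard_normal(t.size) for _ in range(n_ch)])


class TestPreprocess:
    def test_stopband_attenuation(self):
        out_hi, _ = preprocess(_tone(1000.0), FS)
        out_in, _ = preprocess(_tone(100.0), FS)
        gain_hi = np.sqrt(np.mean(out_hi**2)) / np.sqrt(0.5)
        gain_in = np.sqrt(np.mean(out_in**2)) / np.sqrt(0.5)
        assert 20 * np.log10(gain_hi) < -20.0
        assert gain_in == pytest.approx(1.0, abs=0.02)

    def test_outlier_channel_rejected(self):
        g = np.random.default_rng(1)
        clean = g.standard_normal((12, 4096))
        clean[4] *= 40.0  # one channel of huge noise
        _, keep = preprocess(clean, FS)
        assert not keep[4]
        assert keep.sum() == 11

    def test_too_few_channels_fails(self):
        g = np.random.default_rng(2)
        with pytest.raises(RuntimeError):
            # every channel wildly different RMS -> mass rejection
            data = g.standard_normal((9, 2048)) * (10.0 ** np.arange(9))[:, None]
            preprocess(data, FS)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((8, 100)), 500.0)


class TestExtension:
    @pytest.mark.parametrize("m,expected", [(64, 1024), (256, 1024), (63, 1008)])
    def test_extended_row_count(self, m, expected):
        R = int(np.ceil(1000 / m))
        x = np.zeros((m, 100), dtype=np.float32)
        assert extend_channels(x, R).shape == (expected, 100)

    def test_delay_structure(self):
        x = np.arange(10, dtype=float).reshape(1, 10)
        e = extend_channels(x, 3)
        np.testing.assert_array_equal(e[0], x[0])
        np.testing.assert_array_equal(e[1][1:], x[0][:-1])
        assert e[1][0] == 0.0
        np.testing.assert_array_equal(e[2][2:], x[0][:-2])


class TestWhitening:
    def test_identity_covariance_on_white_noise(self):
        g = np.random.default_rng(3)
        data = g.standard_normal((16, 20000))
        wh = extend_and_whiten(data, FS, DecompConfig(target_extended_channels=64))
        Z = wh.Z.astype(np.float64)
        C = Z @ Z.T / Z.shape[1]
        off = C - np.diag(np.diag(C))
        # covariance is computed on the untrimmed signals; the trimmed-frame
        # estimate deviates only through the edge margin
        assert np.abs(off).max() < 1e-2
        assert np.allclose(np.diag(C), 1.0, atol=1e-2)

    def test_degenerate_input_fails(self):
        with pytest.raises(RuntimeError):
            extend_and_whiten(np.zeros((8, 5000)), FS)


class TestSpikeDetection:
    def test_two_means_split_bimodal(self):
        values = np.array([1.0, 0.1, 0.12, 1.05, 0.09, 0.95, 0.11])
        mask = _two_means_split(values)
        np.testing.assert_array_equal(mask, values > 0.5)


class TestToyMixture:
    def _toy(self):
        # two sources with distinct multichannel impulse responses and
        # disjoint regular spike trains, noise-free
        g = np.random.default_rng(7)
        fs = FS
        n = int(12 * fs)
        h1 = g.standard_normal((12, 30)) * np.hanning(30)[None, :]
        h2 = g.standard_normal((12, 30)) * np.hanning(30)[None, :]
        t1 = np.arange(0.5, 11.0, 0.101)
        t2 = np.arange(0.55, 11.0, 0.127)
        data = 0.001 * g.standard_normal((12, n))
        for times, h in ((t1, h1), (t2, h2)):
            for t in times:
                i = int(round(t * fs))
                data[:, i : i + 30] += h
        return data, (t1, t2)

    def test_recovers_a_source(self):
        data, (t1, t2) = self._toy()
        cfg = DecompConfig(target_extended_channels=120, n_runs=4)
        res = decompose((data, FS), config=cfg)
        assert res.n_units >= 1
        best = max(
            max(rate_of_agreement(tr.times, t1), rate_of_agreement(tr.times, t2))
            for tr in res.accepted
        )
        assert best > 0.99

    def test_deflation_orthogonality(self):
        data, _ = self._toy()
        cfg = DecompConfig(target_extended_channels=120)
        wh = extend_and_whiten(data, FS, cfg)
        act = np.sum(wh.Z.astype(np.float64) ** 2, axis=0)
        first = extract_source(wh, int(np.argmax(act)), None, cfg)
        second = extract_source(
            wh, int(np.argsort(act)[-50]), [first.separation_vector], cfg
        )
        dot = float(first.separation_vector @ second.separation_vector)
        assert abs(dot) < 1e-6

    def test_determinism(self):
        data, _ = self._toy()
        cfg = DecompConfig(target_extended_channels=120, n_runs=3)
        a = decompose((data, FS), config=cfg)
        b = decompose((data, FS), config=cfg)
        assert a.n_units == b.n_units
        for ta, tb in zip(a.accepted, b.accepted):
            np.testing.assert_array_equal(ta.times, tb.times)


class TestPNR:
    def test_reference_value(self):
        s = np.full(1000, 0.1)
        s[::2] *= -1  # baseline power exactly 0.01
        spikes = np.array([100, 300, 500])
        s[spikes] = 1.0
        assert pnr(s, spikes) == pytest.approx(20.0, abs=1e-6)

    def test_zero_baseline_saturates(self):
        s = np.zeros(100)
        s[10] = 1.0
        assert np.isinf(pnr(s, np.array([10])))

    def test_empty_spikes_rejected(self):
        with pytest.raises(ValueError):
            pnr(np.ones(10), np.array([], dtype=int))


class TestRefinement:
    def _whitened_toy(self):
        g = np.random.default_rng(11)
        fs = FS
        n = int(10 * fs)
        h = g.standard_normal((10, 25)) * np.hanning(25)[None, :]
        times = np.arange(0.5, 9.5, 0.09)
        data = 0.001 * g.standard_normal((10, n))
        for t in times:
            i = int(round(t * fs))
            data[:, i : i + 25] += h
        # near-noise-free toy: drop the numerically tiny noise directions so
        # whitening does not amplify them past the source subspace
        cfg = DecompConfig(target_extended_channels=100, whiten_rtol=1e-3)
        wh = extend_and_whiten(data, fs, cfg)
        return wh, times, cfg

    def _train_from(self, wh, times, cfg):
        spikes = np.round(times * wh.fs).astype(int) - wh.offset_samples
        spikes = spikes[(spikes > 0) & (spikes < wh.Z.shape[1])]
        w = wh.Z[:, spikes].mean(axis=1)
        w = (w / np.linalg.norm(w)).astype(np.float32)
        s = w @ wh.Z
        s = s / (np.linalg.norm(s) / np.sqrt(s.size))
        t = wh.to_time(spikes)
        return PulseTrain(
            times=t, separation_vector=w, source=s, fs=wh.fs,
            pnr_db=pnr(s * np.abs(s), spikes), cov_isi=cov_isi(t),
        )

    def test_ground_truth_is_fixed_point(self):
        wh, times, cfg = self._whitened_toy()
        train = self._train_from(wh, times, cfg)
        out = refine_by_cov(train, wh, cfg)
        assert out.cov_isi <= train.cov_isi + 1e-12
        assert rate_of_agreement(out.times, times) > 0.99

    def test_recovers_deleted_spikes(self):
        wh, times, cfg = self._whitened_toy()
        g = np.random.default_rng(13)
        keep = np.sort(g.choice(times.size, size=int(0.9 * times.size), replace=False))
        degraded = self._train_from(wh, times[keep], cfg)
        out = refine_by_cov(degraded, wh, cfg)
        n_deleted = times.size - keep.size
        recovered = out.n_spikes - degraded.n_spikes
        assert recovered >= n_deleted / 2
        assert out.cov_isi < degraded.cov_isi
        assert rate_of_agreement(out.times, times) > 0.95

    def test_tiny_train_returned_unchanged(self):
        wh, times, cfg = self._whitened_toy()
        t = self._train_from(wh, times[:2], cfg)
        out = refine_by_cov(t, wh, cfg)
        np.testing.assert_array_equal(out.times, t.times)


def _make_train(times, cov=0.1, fs=FS):
    times = np.asarray(times, dtype=float)
    return PulseTrain(
        times=times,
        separation_vector=np.zeros(4, dtype=np.float32),
        source=np.zeros(8, dtype=np.float32),
        fs=fs,
        pnr_db=30.0,
        cov_isi=cov,
    )


class TestDuplicates:
    def test_identical_trains_collapse(self):
        t = np.arange(0.5, 20.0, 0.08)
        out = remove_duplicates([_make_train(t, 0.2), _make_train(t, 0.1)])
        assert len(out) == 1
        assert out[0].cov_isi == 0.1  # lowest CoV-ISI survives

    def test_share_below_threshold_keeps_both(self):
        g = np.random.default_rng(17)
        a = np.sort(g.uniform(0, 30, 100)); a = a[np.diff(a, prepend=-1) > 0.005]
        b = np.sort(np.concatenate([
            a[: int(0.29 * a.size)],
            g.uniform(40, 70, a.size - int(0.29 * a.size)),
        ]))
        share = shared_discharge_fraction(a, b, FS, 0.0005, 0.05)
        assert share < 0.30
        out = remove_duplicates([_make_train(a), _make_train(b)])
        assert len(out) == 2

    def test_lagged_copy_detected(self):
        t = np.arange(0.5, 20.0, 0.08)
        out = remove_duplicates([_make_train(t, 0.1), _make_train(t + 0.003, 0.2)])
        assert len(out) == 1


class TestBenchmarkRecording:
    def test_accepted_trains_match_ground_truth(self, benchmark_emg, benchmark_decomposition):
        res = benchmark_decomposition
        assert res.n_units >= 5
        df = match_to_ground_truth(res.accepted, benchmark_emg.trains)
        assert (df.roa >= 0.85).all()

    def test_no_accepted_pair_violates_dedup_rule(self, benchmark_decomposition):
        cfg = benchmark_decomposition.config
        trains = benchmark_decomposition.accepted
        for i in range(len(trains)):
            for j in range(i + 1, len(trains)):
                share = shared_discharge_fraction(
                    trains[i].times, trains[j].times, trains[i].fs,
                    cfg.dedup_window_ms / 1000.0, cfg.dedup_max_lag_ms / 1000.0,
                )
                assert share < cfg.dedup_share

    def test_pnr_gate_holds(self, benchmark_decomposition):
        for t in benchmark_decomposition.accepted:
            assert t.saturated or t.pnr_db > 28.0

    def test_physiological_rates(self, benchmark_decomposition):
        for t in benchmark_decomposition.accepted:
            assert t.mean_rate() < 50.0


class TestQuadrantMode:
    def test_quadrant_pipeline_on_composite_recording(self):
        from mugrid.montage import composite_grid
        from mugrid.synthesis import validation_recording

        emg = validation_recording(
            seed=21, grid=composite_grid(), target_mvc=50.0, plateau_s=2.0
        )
        cfg = DecompConfig(n_runs=8)
        res = decompose(emg, mode="quadrants", config=cfg)
        assert any(log.startswith("quadrant3") for log in res.logs)
        if res.n_units:
            df = match_to_ground_truth(res.accepted, emg.trains)
            assert (df.roa >= 0.85).all()
        # cross-quadrant dedup audit
        for i in range(res.n_units):
            for j in range(i + 1, res.n_units):
                share = shared_discharge_fraction(
                    res.accepted[i].times, res.accepted[j].times, FS,
                    cfg.dedup_window_ms / 1000.0, cfg.dedup_max_lag_ms / 1000.0,
                )
                assert share < cfg.dedup_share
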
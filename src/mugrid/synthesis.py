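"""Ground-truth EMG synthesis: recruitment, firing, and the mixing model.

The pool recruits in order of size following the tibialis-anterior
recruitment-threshold distribution

    Fth(j) = 0.50 * (58.12 * j + 120 * j**1.83),   j in [0, 1]

(thresholds in %MVC over the normalized pool index).  Discharge trains follow
a standard linear rate-coding model (onset rate plus a gain on the force
above threshold, saturating at a peak rate) with Gaussian inter-spike-
interval jitter.  Surface EMG is the sum over units of the spike train
convolved with the unit's multichannel MUAP, plus band-limited additive
noise at a prescribed SNR — with every discharge time retained as ground
truth for validating decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .conductor import MUAPSet
from .montage import GridSpec

__all__ = [
    "validation_recording",
    "RecruitmentModel",
    "ForceProfile",
    "SpikeTrainSet",
    "SyntheticEMG",
    "RateModel",
    "fth",
    "invert_fth",
    "trapezoid_profile",
    "simulate_discharges",
    "render_emg",
]

#: hard physiological ceiling on instantaneous discharge rate during
#: submaximal isometric contractions, spikes/s
MAX_DISCHARGE_RATE = 50.0


@dataclass(frozen=True)
class RecruitmentModel:
    """Constants of the recruitment-threshold distribution Fth(j), %MVC."""

    c0: float = 0.50
    c1: float = 58.12
    c2: float = 120.0
    gamma: float = 1.83

    def __call__(self, j):
        return fth(j, self)

    @property
    def max_threshold(self) -> float:
        """Fth(1), the highest threshold in the pool, %MVC."""
        return self.c0 * (self.c1 + self.c2)


def fth(j, model: RecruitmentModel | None = None):
    """Force recruitment threshold (%MVC) of normalized pool index ``j``.

    Strictly increasing on [0, 1] with Fth(0) = 0; the default constants give
    Fth(1) = 89.06 %MVC.
    """
    model = model or RecruitmentModel()
    j = np.asarray(j, dtype=float)
    if np.any((j < 0) | (j > 1)):
        raise ValueError("pool index j must lie in [0, 1]")
    out = model.c0 * (model.c1 * j + model.c2 * j**model.gamma)
    return float(out) if out.ndim == 0 else out


def invert_fth(F: float, model: RecruitmentModel | None = None, tol: float = 1e-9) -> float:
    """Pool index ``j`` with Fth(j) = F, by bisection to ``tol``."""
    model = model or RecruitmentModel()
    if F < 0 or F > model.max_threshold + 1e-12:
        raise ValueError(f"force {F} outside [0, {model.max_threshold:.2f}] %MVC")
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fth(mid, model) < F:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class ForceProfile:
    """Trapezoidal isometric force trace in %MVC."""

    samples: np.ndarray
    fs: float
    target: float
    ramp_rate: float
    plateau_s: float

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


def trapezoid_profile(
    target: float, plateau_s: float, ramp_rate: float = 5.0, fs: float = 2048.0
) -> ForceProfile:
    """Ramp up at ``ramp_rate`` %MVC/s, hold ``plateau_s`` seconds at
    ``target``, ramp down at the same rate (e.g. 30 %MVC with a 20-s plateau
    lasts 6 + 20 + 6 = 32 s)."""
    if target <= 0 or ramp_rate <= 0:
        raise ValueError("target and ramp rate must be positive")
    if plateau_s < 0:
        raise ValueError("plateau duration must be nonnegative")
    ramp_s = target / ramp_rate
    t = np.arange(int(round((2 * ramp_s + plateau_s) * fs))) / fs
    f = np.minimum.reduce(
        [np.full(t.shape, float(target)), ramp_rate * t, ramp_rate * (t[-1] + 1 / fs - t)]
    )
    f = np.maximum(f, 0.0)
    return ForceProfile(samples=f, fs=fs, target=float(target), ramp_rate=float(ramp_rate), plateau_s=float(plateau_s))


@dataclass(frozen=True)
class RateModel:
    """Linear rate coding: rate = rate_min + gain * (force - threshold),
    clipped to [rate_min, rate_max]; rate_max stays below the 50/s ceiling."""

    rate_min: float = 8.0
    rate_max: float = 35.0
    gain: float = 0.3  # spikes/s per %MVC above threshold

    def __post_init__(self):
        if not 0 < self.rate_min <= self.rate_max < MAX_DISCHARGE_RATE:
            raise ValueError("rates must satisfy 0 < rate_min <= rate_max < 50/s")

    def rate(self, force, threshold):
        excess = np.maximum(np.asarray(force, dtype=float) - threshold, 0.0)
        return np.clip(self.rate_min + self.gain * excess, self.rate_min, self.rate_max)


@dataclass(frozen=True)
class SpikeTrainSet:
    """Ground-truth discharge times (s) and recruitment data per unit."""

    spike_times: tuple  # tuple of float arrays, one per unit
    thresholds: np.ndarray  # recruitment threshold per unit, %MVC
    pool_indices: np.ndarray  # normalized pool index j per unit
    early_labels: np.ndarray  # bool: recruited in the first half of the active pool
    fs: float
    duration_s: float
    seed: int

    @property
    def n_units(self) -> int:
        return len(self.spike_times)

    def active_units(self) -> np.ndarray:
        return np.array([len(s) > 0 for s in self.spike_times])


@dataclass
class SyntheticEMG:
    """Multichannel surface EMG (uV) with full ground truth attached."""

    data: np.ndarray  # (channels, samples)
    fs: float
    grid: GridSpec
    trains: SpikeTrainSet
    muaps: MUAPSet
    snr_db: float
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def validation_recording(
    seed: int = 0,
    n_units: int = 15,
    grid: GridSpec | None = None,
    target_mvc: float = 50.0,
    plateau_s: float = 10.0,
    snr_db: float = 20.0,
    pool_size: int = 200,
    fiber_subsample: int | None = 100,
    isi_cov: float = 0.15,
):
    """Ground-truth benchmark recording for decomposition validation.

    Builds a full anatomical pool, keeps the ``n_units`` units with the
    largest surface RMS on the montage (the physiologically detectable
    sample — units on the far side of the limb contribute nothing a surface
    algorithm could recover), simulates their discharge trains for a
    trapezoidal contraction and renders noisy EMG.  Returns the
    :class:`SyntheticEMG` with ground truth attached.
    """
    from .anatomy import build_pool
    from .conductor import compute_muaps
    from .montage import composite_grid, split_quadrants

    rng = np.random.default_rng(seed)
    s_pool, s_muap, s_train, s_noise = rng.integers(2**31, size=4)
    if grid is None:
        grid = split_quadrants(composite_grid())[0].grid
    pool = build_pool(count=pool_size, seed=int(s_pool))
    muaps = compute_muaps(pool, grid, fiber_subsample=fiber_subsample, seed=int(s_muap))
    order = np.argsort(muaps.surface_rms())
    keep = np.sort(order[-n_units:])  # retain ascending-size order
    sub = muaps.select_units(keep)
    profile = trapezoid_profile(target_mvc, plateau_s=plateau_s)
    trains = simulate_discharges(profile, n_units, isi_cov=isi_cov, seed=int(s_train))
    emg = render_emg(sub, trains, snr_db=snr_db, seed=int(s_noise))
    emg.meta["pool_units"] = keep
    return emg


def simulate_discharges(
    profile: ForceProfile,
    pool_size: int,
    rate_model: RateModel | None = None,
    isi_cov: float = 0.15,
    seed: int = 0,
    recruitment: RecruitmentModel | None = None,
) -> SpikeTrainSet:
    """Simulate the pool's discharge trains for a force profile.

    Unit ``i`` (0-based, size-ordered) has pool index j = i/(pool_size-1) and
    fires only while the force is at or above Fth(j).  Inter-spike intervals
    are 1/rate at the current force, jittered by a Gaussian factor with
    coefficient of variation ``isi_cov`` (truncated at 3 SD); a unit stops
    when the force drops below its threshold on the down-ramp.  The first
    half of the units active at the target force is labelled early-recruited.
    """
    rate_model = rate_model or RateModel()
    recruitment = recruitment or RecruitmentModel()
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if isi_cov < 0:
        raise ValueError("isi_cov must be nonnegative")
    rng = np.random.default_rng(seed)
    f = profile.samples
    fs = profile.fs
    duration = profile.duration_s
    j = np.zeros(pool_size) if pool_size == 1 else np.arange(pool_size) / (pool_size - 1)
    thresholds = np.asarray(fth(j, recruitment), dtype=float).reshape(-1)
    trains = []
    for i in range(pool_size):
        th = thresholds[i]
        active = f >= th if th > 0 else f > 0
        if not np.any(active):
            trains.append(np.empty(0))
            continue
        t = np.flatnonzero(active)[0] / fs
        t_end = (np.flatnonzero(active)[-1] + 1) / fs
        spikes = []
        while t < t_end:
            force_now = f[min(int(t * fs), f.size - 1)]
            if force_now < th:
                break
            spikes.append(t)
            r = float(rate_model.rate(force_now, th))
            isi = (1.0 / r) * (1.0 + isi_cov * float(np.clip(rng.standard_normal(), -3.0, 3.0)))
            isi = max(isi, 1.0 / MAX_DISCHARGE_RATE)  # never exceed 50/s
            t += isi
        trains.append(np.asarray(spikes))
    # early/late ground truth at the task target
    j_target = invert_fth(min(profile.target, recruitment.max_threshold), recruitment)
    early = j <= 0.5 * j_target
    return SpikeTrainSet(
        spike_times=tuple(trains),
        thresholds=thresholds,
        pool_indices=j,
        early_labels=early,
        fs=fs,
        duration_s=duration,
        seed=seed,
    )


def render_emg(
    muaps: MUAPSet,
    trains: SpikeTrainSet,
    snr_db: float = 20.0,
    seed: int = 0,
    noise_band_hz: tuple = (20.0, 500.0),
) -> SyntheticEMG:
    """Mix spike trains with MUAPs and add band-limited Gaussian noise.

    Each channel is the sum over units of the discharge train convolved with
    that unit's MUAP; noise is Gaussian, band-pass filtered to
    ``noise_band_hz`` and scaled so the overall signal-to-noise ratio equals
    ``snr_db`` (infinite SNR gives a noise-free mixture).
    """
    if abs(muaps.fs - trains.fs) > 1e-9:
        raise ValueError(f"sampling rates differ: MUAPs {muaps.fs} Hz, trains {trains.fs} Hz")
    if muaps.n_units < trains.n_units:
        raise ValueError("fewer MUAPs than spike-train units")
    fs = muaps.fs
    n_samp = int(round(trains.duration_s * fs))
    n_ch = muaps.n_electrodes
    wlen = muaps.n_samples
    clean = np.zeros((n_ch, n_samp + wlen), dtype=np.float64)
    for u, times in enumerate(trains.spike_times):
        if len(times) == 0:
            continue
        idx = np.round(np.asarray(times) * fs).astype(int)
        idx = idx[(idx >= 0) & (idx < n_samp)]
        if idx.size == 0:
            continue
        w = muaps.waveforms[u].astype(np.float64)
        for i in idx:
            clean[:, i : i + wlen] += w
    clean = clean[:, :n_samp]
    if np.isinf(snr_db):
        noise = np.zeros_like(clean)
    else:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(clean.shape)
        sos = butter(2, noise_band_hz, btype="bandpass", fs=fs, output="sos")
        noise = sosfiltfilt(sos, noise, axis=1)
        p_signal = float(np.mean(clean**2))
        p_noise = float(np.mean(noise**2))
        if p_noise > 0 and p_signal > 0:
            target_noise = p_signal / (10.0 ** (snr_db / 10.0))
            noise *= np.sqrt(target_noise / p_noise)
        elif p_noise > 0:
            # no signal to reference: deliver unit-RMS band-limited noise
            noise /= np.sqrt(p_noise)
    return SyntheticEMG(
        data=(clean + noise).astype(np.float32),
        fs=fs,
        grid=muaps.grid,
        trains=trains,
        muaps=muaps,
        snr_db=snr_db,
        meta={"noise_seed": seed, "noise_band_hz": noise_band_hz},
    )
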
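"""Convolutive blind source separation of multichannel EMG into motor-unit
pulse trains.

Pipeline: band-pass filtering and automated channel rejection; extension of
each channel by delayed copies (to turn the convolutive mixture into an
instantaneous one) up to a target number of extended channels; spatial
whitening; repeated fixed-point source extraction with the log-cosh contrast
and deflation; spike extraction by peak detection and two-class clustering of
peak amplitudes; iterative re-estimation of the motor-unit filter until the
inter-spike-interval coefficient of variation stops improving; quality gating
by the pulse-to-noise ratio (PNR); and duplicate removal across sources by
cross-correlation alignment and shared-discharge counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .montage import GridSpec, split_quadrants

__all__ = [
    "DecompConfig",
    "PulseTrain",
    "DecompositionResult",
    "preprocess",
    "extend_channels",
    "extend_and_whiten",
    "WhitenedEMG",
    "extract_source",
    "refine_by_cov",
    "pnr",
    "cov_isi",
    "remove_duplicates",
    "decompose",
]


@dataclass(frozen=True)
class DecompConfig:
    """All thresholds and sizes of the decomposition pipeline."""

    bandpass_hz: tuple = (20.0, 500.0)
    bandpass_order: int = 2
    channel_reject_z: float = 3.0
    target_extended_channels: int = 1000
    whiten_rtol: float = 1e-12  # eigenvalues below rtol * max are dropped
    tolerance: float = 1e-4  # convergence tolerance on the sparsity measure
    max_iterations: int = 50
    n_runs: int = 50
    peak_distance_ms: float = 10.0
    dedup_window_ms: float = 0.5
    dedup_share: float = 0.30
    dedup_max_lag_ms: float = 50.0
    pnr_threshold_db: float = 28.0
    refine_max_iterations: int = 20
    min_spikes: int = 8
    max_mean_rate_hz: float = 50.0
    max_cov_isi: float = 0.5  # isometric discharge is regular; reject erratic trains
    min_active_s: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 0.0 < self.dedup_share < 1.0:
            raise ValueError("dedup_share must lie in (0, 1)")


@dataclass
class PulseTrain:
    """One decomposed source: discharge times plus quality descriptors.

    ``source`` is the linear projection of the whitened observations on the
    separation vector (unit RMS); the motor-unit *pulse train* used for peak
    picking and the PNR is its square-rectified form ``source * |source|``,
    which skews small values toward zero and sharpens the discharges.
    """

    times: np.ndarray  # discharge times, s, strictly increasing
    separation_vector: np.ndarray  # motor-unit filter in whitened space
    source: np.ndarray  # projected source signal (unit RMS)
    fs: float
    pnr_db: float
    cov_isi: float
    origin: str = "whole"
    saturated: bool = False  # PNR baseline was exactly zero
    converged: bool = True

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def pulse_train(self) -> np.ndarray:
        """Square-rectified source (the series the PNR is computed on)."""
        return self.source * np.abs(self.source)

    def mean_rate(self) -> float:
        if self.times.size < 2:
            return 0.0
        span = self.times[-1] - self.times[0]
        return (self.times.size - 1) / span if span > 0 else np.inf


@dataclass
class DecompositionResult:
    accepted: list
    rejected: dict
    config: DecompConfig
    channel_mask: np.ndarray
    logs: list = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return len(self.accepted)


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(data: np.ndarray, fs: float, config: DecompConfig | None = None):
    """Zero-phase band-pass filter and automated channel rejection.

    Channels whose RMS deviates from the montage median by more than
    ``channel_reject_z`` robust z-scores (median/MAD) are discarded — an
    automated stand-in for the visual channel screening used in practice.
    Returns ``(filtered, keep_mask)``; raises if fewer than 8 channels
    survive.
    """
    config = config or DecompConfig()
    if fs <= 1000:
        raise ValueError("sampling rate must exceed 1000 Hz")
    data = np.asarray(data, dtype=np.float64)
    sos = butter(config.bandpass_order, config.bandpass_hz, btype="bandpass", fs=fs, output="sos")
    filt = sosfiltfilt(sos, data, axis=1)
    rms = np.sqrt(np.mean(filt**2, axis=1))
    med = np.median(rms)
    mad = np.median(np.abs(rms - med))
    scale = 1.4826 * mad if mad > 0 else (np.std(rms) or 1.0)
    z = (rms - med) / scale
    keep = np.abs(z) <= config.channel_reject_z
    if keep.sum() < 8:
        raise RuntimeError(f"only {int(keep.sum())} channels survive rejection (need >= 8)")
    return filt[keep], keep


def extend_channels(data: np.ndarray, factor: int) -> np.ndarray:
    """Stack ``factor`` delayed copies (delays 0..factor-1, zero-padded) of
    every channel: (m, N) -> (m * factor, N)."""
    m, n = data.shape
    out = np.zeros((m * factor, n), dtype=data.dtype)
    for d in range(factor):
        out[d * m : (d + 1) * m, d:] = data[:, : n - d] if d else data
    return out


@dataclass
class WhitenedEMG:
    """Whitened extended observations plus the transform that produced them."""

    Z: np.ndarray  # (k, N) whitened signals, identity covariance
    extension_factor: int
    eigenvalues: np.ndarray  # retained eigenvalues of the extended covariance
    n_original_channels: int
    fs: float
    offset_samples: int = 0  # samples trimmed from the recording start

    @property
    def n_samples(self) -> int:
        return self.Z.shape[1]

    def to_time(self, indices: np.ndarray) -> np.ndarray:
        """Convert sample indices in the trimmed frame to recording times."""
        return (np.asarray(indices) + self.offset_samples) / self.fs


def extend_and_whiten(
    data: np.ndarray, fs: float, config: DecompConfig | None = None
) -> WhitenedEMG:
    """Extend channels to reach the target count, then spatially whiten.

    The extension factor is ``ceil(target / m)``.  Whitening uses the
    eigen-decomposition of the extended covariance; eigenvalues below
    ``whiten_rtol`` times the largest (numerically degenerate directions) are
    dropped, so the output covariance is the identity on the retained
    subspace.
    """
    config = config or DecompConfig()
    data = np.asarray(data)
    m, n = data.shape
    if m < 1:
        raise ValueError("need at least one channel")
    R = int(np.ceil(config.target_extended_channels / m))
    X = extend_channels(data.astype(np.float32, copy=False), R)
    X -= X.mean(axis=1, keepdims=True)
    # accumulate in float64: the informative tail eigenvalues sit far below
    # float32 matmul precision
    X64 = X.astype(np.float64)
    C = (X64 @ X64.T) / n
    del X64
    d, V = np.linalg.eigh(C)
    if d[-1] <= 0:
        raise RuntimeError("degenerate extended covariance (zero signal)")
    keep = d > config.whiten_rtol * d[-1]
    d, V = d[keep], V[:, keep]
    W = (V / np.sqrt(d)).T.astype(np.float32)  # (k, mR)
    Z = W @ X
    # the zero-padded extension and the filter transients corrupt the first
    # and last few tens of milliseconds; trim them so source extraction never
    # initializes on (or detects) edge artifacts
    edge = R + int(round(0.05 * fs))
    if Z.shape[1] > 4 * edge:
        Z = np.ascontiguousarray(Z[:, edge:-edge])
    else:
        edge = 0
    return WhitenedEMG(Z=Z, extension_factor=R, eigenvalues=d, n_original_channels=m,
                       fs=fs, offset_samples=edge)


# ---------------------------------------------------------------------------
# source extraction


def _two_means_split(values: np.ndarray):
    """Exact two-class K-means on 1-D data (optimal split of sorted values).

    Returns a boolean mask of the class with the highest centroid.
    """
    v = np.sort(values)
    n = v.size
    if n < 2:
        return np.ones(values.shape, dtype=bool)
    csum = np.cumsum(v)
    total = csum[-1]
    k = np.arange(1, n)  # split: low class = v[:k], high class = v[k:]
    mean_lo = csum[:-1] / k
    mean_hi = (total - csum[:-1]) / (n - k)
    # within-class sum of squares up to constants: -(k*mean_lo^2 + (n-k)*mean_hi^2)
    score = k * mean_lo**2 + (n - k) * mean_hi**2
    split = int(np.argmax(score))
    thr = 0.5 * (v[split] + v[split + 1])
    return values > thr


def _detect_spikes(source: np.ndarray, fs: float, config: DecompConfig):
    """Peak detection on the squared source plus two-class clustering of peak
    amplitudes; the high-amplitude class is the spike set."""
    s = source.copy()
    # a source is sign-ambiguous: orient so discharges are positive peaks
    if np.abs(s.min()) > np.abs(s.max()):
        s = -s
    energy = s * np.abs(s)
    distance = max(int(round(config.peak_distance_ms * fs / 1000.0)), 1)
    peaks, props = find_peaks(energy, distance=distance, height=0.0)
    if peaks.size < 2:
        return peaks, s
    heights = props["peak_heights"]
    high = _two_means_split(heights)
    return peaks[high], s


def extract_source(
    whitened: WhitenedEMG,
    init_index: int,
    prior_vectors: np.ndarray | None = None,
    config: DecompConfig | None = None,
) -> PulseTrain:
    """One fixed-point source extraction from the whitened observations.

    The separation vector starts at the whitened observation column at
    ``init_index`` (a time of high extended-signal activity), is deflated
    against ``prior_vectors`` (Gram-Schmidt) after every update, and follows
    the fixed-point iteration for the log-cosh contrast
    (g' = tanh, g'' = 1 - tanh^2).  Iteration stops when the sparsity measure
    mean(log cosh s) changes by less than ``tolerance``.  Spikes are then
    extracted from the projected source.
    """
    config = config or DecompConfig()
    Z = whitened.Z
    k, n = Z.shape
    B = None
    if prior_vectors is not None and len(prior_vectors):
        B = np.asarray(prior_vectors, dtype=np.float64).reshape(-1, k).T  # (k, q)
        # Gram-Schmidt deflation is only a projection for an orthonormal
        # basis; orthonormalize once so correlated prior vectors (e.g. the
        # delayed templates of one unit) are fully removed
        B, _ = np.linalg.qr(B, mode="reduced")

    def _orthonormalize(w):
        if B is not None:
            w = w - B @ (B.T @ w)
        nw = np.linalg.norm(w)
        if nw == 0:
            raise RuntimeError("separation vector collapsed during deflation")
        return w / nw

    w = _orthonormalize(Z[:, init_index].astype(np.float64)).astype(np.float32)
    sparsity_prev = np.inf
    converged = False
    for _ in range(config.max_iterations):
        s = w @ Z
        th = np.tanh(s)
        w = (Z @ th) / np.float32(n) - np.float32(np.mean(1.0 - th**2)) * w
        w = _orthonormalize(w.astype(np.float64)).astype(np.float32)
        s = w @ Z
        # log cosh overflows for large |s|; use the numerically stable form
        sa = np.abs(s.astype(np.float64))
        sparsity = float(np.mean(sa + np.log1p(np.exp(-2.0 * sa)) - np.log(2.0)))
        if abs(sparsity - sparsity_prev) < config.tolerance:
            converged = True
            break
        sparsity_prev = sparsity
    s = w @ Z
    s = s / (np.linalg.norm(s) / np.sqrt(n) + 1e-30)  # unit RMS
    spikes, s_oriented = _detect_spikes(s, whitened.fs, config)
    times = whitened.to_time(spikes)
    train = PulseTrain(
        times=times,
        separation_vector=w,
        source=s_oriented.astype(np.float32),
        fs=whitened.fs,
        pnr_db=pnr(s_oriented * np.abs(s_oriented), spikes) if spikes.size else -np.inf,
        cov_isi=cov_isi(times),
        converged=converged,
    )
    return train


def cov_isi(times: np.ndarray) -> float:
    """Coefficient of variation of the inter-spike intervals."""
    times = np.asarray(times)
    if times.size < 3:
        return np.inf
    isi = np.diff(times)
    m = isi.mean()
    return float(isi.std(ddof=1) / m) if m > 0 else np.inf


def pnr(source: np.ndarray, spikes: np.ndarray) -> float:
    """Pulse-to-noise ratio, dB: energy of the source at discharge samples
    over its energy everywhere else.  Returns +inf when the baseline is
    identically zero (flagged as saturated by callers)."""
    spikes = np.asarray(spikes, dtype=int)
    if spikes.size == 0:
        raise ValueError("PNR needs at least one spike")
    s2 = np.asarray(source, dtype=np.float64) ** 2
    mask = np.zeros(s2.size, dtype=bool)
    mask[spikes] = True
    pulse = float(s2[mask].mean())
    rest = s2[~mask]
    base = float(rest.mean()) if rest.size else 0.0
    if base == 0.0:
        return np.inf
    return 10.0 * np.log10(pulse / base)


def refine_by_cov(
    train: PulseTrain, whitened: WhitenedEMG, config: DecompConfig | None = None
) -> PulseTrain:
    """Iteratively re-estimate the motor-unit filter from the current spikes
    until the ISI coefficient of variation stops decreasing.

    Each pass sets the filter to the mean whitened observation at the spike
    instants, reprojects, re-extracts spikes, and keeps the iterate with the
    lowest CoV-ISI (the accepted CoV sequence is nonincreasing).  Trains with
    fewer than 4 spikes are returned unchanged.
    """
    config = config or DecompConfig()
    if train.n_spikes < 4:
        return replace(train, converged=train.converged)
    Z = whitened.Z
    n = Z.shape[1]
    fs = whitened.fs
    best = train
    best_cov = train.cov_isi
    spikes = np.round(train.times * fs).astype(int) - whitened.offset_samples
    spikes = spikes[(spikes >= 0) & (spikes < n)]
    for _ in range(config.refine_max_iterations):
        w = Z[:, spikes].mean(axis=1)
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w = (w / nw).astype(np.float32)
        s = w @ Z
        s = s / (np.linalg.norm(s) / np.sqrt(n) + 1e-30)
        new_spikes, s_oriented = _detect_spikes(s, fs, config)
        if new_spikes.size < 4:
            break
        # the re-estimated filter must keep describing the same unit: stop if
        # the spike set drifts away from the previous iterate (a constant
        # detection offset is fine, so compare after lag alignment)
        overlap = shared_discharge_fraction(
            new_spikes / fs, spikes / fs, fs,
            2.0 * config.dedup_window_ms / 1000.0, 0.02,
        )
        if overlap < 0.5:
            break
        times = whitened.to_time(new_spikes)
        cov = cov_isi(times)
        if cov >= best_cov:
            break
        best_cov = cov
        best = PulseTrain(
            times=times,
            separation_vector=w,
            source=s_oriented.astype(np.float32),
            fs=fs,
            pnr_db=pnr(s_oriented * np.abs(s_oriented), new_spikes),
            cov_isi=cov,
            origin=train.origin,
            converged=train.converged,
        )
        spikes = new_spikes
    return best


# ---------------------------------------------------------------------------
# duplicates


def _best_lag_s(a: np.ndarray, b: np.ndarray, fs: float, max_lag_s: float) -> float:
    """Lag (s) maximizing the cross-correlation of two binarized trains."""
    if a.size == 0 or b.size == 0:
        return 0.0
    t_max = max(a.max(), b.max())
    n = int(round(t_max * fs)) + 1
    xa = np.zeros(n)
    xb = np.zeros(n)
    xa[np.round(a * fs).astype(int)] = 1.0
    xb[np.round(b * fs).astype(int)] = 1.0
    max_lag = int(round(max_lag_s * fs))
    nfft = int(2 ** np.ceil(np.log2(n + max_lag + 1)))
    corr = np.fft.irfft(np.fft.rfft(xa, nfft) * np.conj(np.fft.rfft(xb, nfft)), nfft)
    lags = np.concatenate([np.arange(0, max_lag + 1), np.arange(-max_lag, 0)])
    window = np.concatenate([corr[: max_lag + 1], corr[nfft - max_lag :]])
    return float(lags[np.argmax(window)] / fs)


def shared_discharge_fraction(
    a: np.ndarray, b: np.ndarray, fs: float, window_s: float, max_lag_s: float
) -> float:
    """Fraction of discharges in common (of the smaller train) after
    cross-correlation alignment; two discharges are common when they fall
    within ``window_s`` of each other."""
    if a.size == 0 or b.size == 0:
        return 0.0
    lag = _best_lag_s(a, b, fs, max_lag_s)
    b_shift = b + lag
    common = _count_matches(a, b_shift, window_s)
    return common / min(a.size, b.size)


def _count_matches(a: np.ndarray, b: np.ndarray, tol: float) -> int:
    """Greedy one-to-one matching of two sorted time series within ``tol``."""
    i = j = matches = 0
    while i < a.size and j < b.size:
        dt = a[i] - b[j]
        if abs(dt) <= tol + 1e-12:
            matches += 1
            i += 1
            j += 1
        elif dt > 0:
            j += 1
        else:
            i += 1
    return matches


def remove_duplicates(trains: list, config: DecompConfig | None = None) -> list:
    """Collapse groups of duplicate pulse trains, keeping the member with the
    lowest CoV-ISI in each group.

    Two trains are duplicates when, after alignment by the cross-correlation
    lag of their binary trains, at least ``dedup_share`` of the smaller
    train's discharges coincide within ``dedup_window_ms``.
    """
    config = config or DecompConfig()
    n = len(trains)
    if n <= 1:
        return list(trains)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            share = shared_discharge_fraction(
                trains[i].times,
                trains[j].times,
                trains[i].fs,
                config.dedup_window_ms / 1000.0,
                config.dedup_max_lag_ms / 1000.0,
            )
            if share >= config.dedup_share:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    survivors = []
    for members in groups.values():
        best = min(members, key=lambda ix: (trains[ix].cov_isi, ix))
        survivors.append(best)
    return [trains[i] for i in sorted(survivors)]


# ---------------------------------------------------------------------------
# full pipeline


def _decompose_channels(
    data: np.ndarray, fs: float, config: DecompConfig, origin: str, logs: list
):
    """Whole-montage decomposition of one channel block; returns candidate
    trains passing quality gates (dedup is left to the caller)."""
    filt, keep = preprocess(data, fs, config)
    logs.append(f"{origin}: kept {int(keep.sum())}/{keep.size} channels")
    wh = extend_and_whiten(filt, fs, config)
    logs.append(
        f"{origin}: extension factor {wh.extension_factor}, "
        f"{wh.Z.shape[0]} whitened components"
    )
    activity = np.sum(wh.Z.astype(np.float64) ** 2, axis=0)
    guard = max(int(round(0.001 * fs)), 1)
    spike_guard = max(int(round(0.005 * fs)), 1)
    used = np.zeros(activity.size, dtype=bool)
    vectors = []
    accepted = []
    rejected = {"not_converged": 0, "low_pnr": 0, "physiology": 0, "too_few_spikes": 0}

    def _mark(idx_array, half):
        for i in idx_array:
            used[max(0, i - half) : i + half + 1] = True

    def _delay_subspace(train):
        # an accepted unit reappears as delayed copies of itself in the
        # extended space; deflating against its spike-triggered templates at
        # all delays keeps later runs from re-extracting it
        spikes = np.round(train.times * fs).astype(int) - wh.offset_samples
        spikes = spikes[(spikes >= 0) & (spikes < wh.Z.shape[1])]
        if spikes.size == 0:
            return []
        R = wh.extension_factor
        out = []
        for delta in range(-2 * R, 2 * R + 1):
            idx = spikes + delta
            idx = idx[(idx >= 0) & (idx < wh.Z.shape[1])]
            if idx.size:
                v = wh.Z[:, idx].mean(axis=1).astype(np.float64)
                nv = np.linalg.norm(v)
                if nv > 0:
                    out.append((v / nv).astype(np.float32))
        return out

    for _ in range(config.n_runs):
        masked = np.where(used, -np.inf, activity)
        init = int(np.argmax(masked))
        if not np.isfinite(masked[init]):
            break
        _mark([init], guard)
        train = extract_source(wh, init, vectors, config)
        vectors.append(train.separation_vector)
        if train.converged and train.n_spikes >= config.min_spikes:
            # keep later initializations away from activity this source
            # already explains, so successive runs visit different units
            _mark(np.round(train.times * fs).astype(int) - wh.offset_samples, spike_guard)
        if not train.converged:
            rejected["not_converged"] += 1
            continue
        if train.n_spikes < config.min_spikes:
            rejected["too_few_spikes"] += 1
            continue
        train = refine_by_cov(train, wh, config)
        train.origin = origin
        active_span = train.times[-1] - train.times[0]
        if (
            train.mean_rate() > config.max_mean_rate_hz
            or active_span < config.min_active_s
            or train.cov_isi > config.max_cov_isi
        ):
            rejected["physiology"] += 1
            continue
        if not np.isfinite(train.pnr_db):
            train.saturated = True
        elif train.pnr_db <= config.pnr_threshold_db:
            rejected["low_pnr"] += 1
            continue
        accepted.append(train)
        vectors.extend(_delay_subspace(train))
        _mark(np.round(train.times * fs).astype(int) - wh.offset_samples, spike_guard)
    return accepted, rejected, keep


def decompose(
    emg,
    grid: GridSpec | None = None,
    config: DecompConfig | None = None,
    mode: str = "whole",
) -> DecompositionResult:
    """Decompose a multichannel EMG recording into motor-unit pulse trains.

    ``emg`` is a :class:`~mugrid.synthesis.SyntheticEMG`, an
    :class:`~mugrid.io.EMGContainer`, or an ``(array, fs)`` tuple.  In
    ``quadrants`` mode the montage is split into its four sub-grids, each is
    decomposed independently, and duplicates are removed across sub-grids —
    the strategy that maximizes identified units on composite 256-electrode
    montages.
    """
    config = config or DecompConfig()
    if isinstance(emg, tuple):
        data, fs = emg
    else:
        data, fs = emg.data, emg.fs
        if grid is None:
            grid = getattr(emg, "grid", None)
    data = np.asarray(data)
    if grid is not None and data.shape[0] != grid.n_electrodes:
        raise ValueError(
            f"recording has {data.shape[0]} channels but montage has "
            f"{grid.n_electrodes} electrodes"
        )
    logs: list = []
    if mode == "whole":
        accepted, rejected, keep = _decompose_channels(data, fs, config, "whole", logs)
    elif mode == "quadrants":
        if grid is None:
            raise ValueError("quadrant mode needs the montage")
        accepted = []
        rejected = {}
        keep = np.zeros(data.shape[0], dtype=bool)
        for qi, quad in enumerate(split_quadrants(grid)):
            qdata = data[quad.parent_channels]
            qacc, qrej, qkeep = _decompose_channels(
                qdata, fs, config, f"quadrant{qi}", logs
            )
            accepted.extend(qacc)
            for k, v in qrej.items():
                rejected[k] = rejected.get(k, 0) + v
            keep[quad.parent_channels] = qkeep
    else:
        raise ValueError("mode must be 'whole' or 'quadrants'")
    before = len(accepted)
    accepted = remove_duplicates(accepted, config)
    rejected["duplicates"] = before - len(accepted)
    logs.append(f"accepted {len(accepted)} trains ({rejected})")
    return DecompositionResult(
        accepted=accepted,
        rejected=rejected,
        config=config,
        channel_mask=keep,
        logs=logs,
    )
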
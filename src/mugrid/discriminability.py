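"""Theoretical motor-unit identifiability from multichannel MUAP shapes.

Two units are discriminable when, after the best global time alignment, the
normalized mean-square difference (NMSD) between their multichannel MUAPs is
at least a criterion (5% by default).  A unit is *theoretically identifiable*
when it is discriminable from every other unit in the pool — an upper bound
on what any EMG decomposition algorithm can recover, independent of the
algorithm itself.  The sweep evaluates this percentage over a ladder of grid
sizes and interelectrode distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len

from .anatomy import MotorUnitPool
from .conductor import MUAPSet, TissueElectrical, compute_muaps
from .montage import GridSpec, channel_indices_in, decimate, crop_center, simulated_grid

__all__ = [
    "DiscriminabilityConfig",
    "align_and_nmsd",
    "nmsd_matrix",
    "identifiable_set",
    "sweep_configs",
    "sweep_shared_master",
    "plot_sweep_heatmap",
    "default_ied_ladder",
    "default_length_ladder",
]

#: IED ladder (mm) used by the default 84-configuration sweep; every value is
#: an even multiple of the 2-mm master lattice so all grids share electrodes
DEFAULT_IED_LADDER = (2, 4, 6, 8, 10, 12, 14, 16, 18, 24, 30, 36)
#: grid lengths (cm) of the default sweep at 3.6-cm width: areas 14.4-36 cm^2
DEFAULT_LENGTH_LADDER = (4, 5, 6, 7, 8, 9, 10)


def default_ied_ladder() -> tuple:
    return DEFAULT_IED_LADDER


def default_length_ladder() -> tuple:
    return DEFAULT_LENGTH_LADDER


@dataclass(frozen=True)
class DiscriminabilityConfig:
    """Criterion and alignment settings for pairwise MUAP comparison.

    normalization: "max" (default) divides the aligned squared difference by
    the larger of the two waveform energies — a pair is discriminable only
    when the difference is substantial relative to the stronger waveform;
    "mean" divides by the mean energy (symmetric, slightly more permissive
    for amplitude-mismatched pairs).
    """

    nmsd_threshold: float = 0.05
    max_lag_ms: float = 10.0
    normalization: str = "max"

    def __post_init__(self):
        if not 0.0 < self.nmsd_threshold < 1.0:
            raise ValueError("nmsd_threshold must lie in (0, 1)")
        if self.normalization not in ("mean", "max"):
            raise ValueError("normalization must be 'mean' or 'max'")


def _norm(ea, eb, mode: str):
    return 0.5 * (ea + eb) if mode == "mean" else np.maximum(ea, eb)


def align_and_nmsd(
    a: np.ndarray,
    b: np.ndarray,
    fs: float,
    max_lag_ms: float = 10.0,
    normalization: str = "mean",
) -> tuple:
    """Best-lag normalized mean-square difference between two multichannel
    waveforms.

    A single global lag (shared by all channels) is chosen by maximizing the
    magnitude of the summed cross-correlation; per-channel alignment would
    discard the inter-electrode propagation delays that distinguish units.
    Returns ``(lag_samples, nmsd)``: the lag maximizes
    ``sum_t a[t] * b[t - lag]`` (a copy of ``a`` delayed by ``k`` samples
    yields lag ``-k``); nmsd is a fraction (>= 0; 4.0 for sign-flipped copies
    under mean-energy normalization).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"waveform shapes differ: {a.shape} vs {b.shape}")
    L = int(round(max_lag_ms * fs / 1000.0))
    T = a.shape[1]
    L = min(L, T - 1)
    corr = np.zeros(2 * T - 1)
    for ch in range(a.shape[0]):
        corr += np.correlate(a[ch], b[ch], mode="full")
    # np.correlate 'full' index i corresponds to lag l = i - (T - 1) with
    # c[l] = sum_t a[t] b[t - l]
    lags = np.arange(-L, L + 1)
    window = corr[(T - 1) + lags]
    best = int(np.argmax(np.abs(window)))
    lag = int(lags[best])
    c = float(window[best])
    ea = float(np.sum(a**2))
    eb = float(np.sum(b**2))
    denom = _norm(ea, eb, normalization)
    if denom == 0.0:
        return 0, 0.0
    return lag, (ea + eb - 2.0 * c) / denom


def nmsd_matrix(
    muaps: MUAPSet | np.ndarray,
    fs: float | None = None,
    config: DiscriminabilityConfig | None = None,
) -> np.ndarray:
    """All-pairs aligned NMSD matrix (units x units, zero diagonal).

    FFT-based: cross-spectra summed over channels give every pair's
    cross-correlation in one batch, the best lag within the allowed window is
    chosen by magnitude, and the aligned squared difference follows from the
    waveform energies.  Agrees with :func:`align_and_nmsd` pair by pair.
    """
    config = config or DiscriminabilityConfig()
    if isinstance(muaps, MUAPSet):
        W = muaps.waveforms
        fs = muaps.fs
    else:
        W = np.asarray(muaps)
        if fs is None:
            raise ValueError("fs required for raw waveform arrays")
    W = W.astype(np.float32, copy=False)
    U, C, T = W.shape
    L = min(int(round(config.max_lag_ms * fs / 1000.0)), T - 1)
    nfft = next_fast_len(T + L)
    X = np.fft.rfft(W, n=nfft, axis=2).astype(np.complex64)
    Xf = np.ascontiguousarray(np.moveaxis(X, 2, 0))  # (F, U, C)
    F = Xf.shape[0]
    S = np.empty((F, U, U), dtype=np.complex64)
    for f in range(F):
        S[f] = Xf[f] @ Xf[f].conj().T
    c = np.fft.irfft(S, n=nfft, axis=0)  # circular cross-correlation
    idx = np.concatenate([np.arange(0, L + 1), np.arange(nfft - L, nfft)])
    lags_window = c[idx]  # (2L+1, U, U); first L+1 rows are lags 0..L
    best = np.argmax(np.abs(lags_window), axis=0)
    cmax = np.take_along_axis(lags_window, best[None], axis=0)[0]
    E = np.sum(W.astype(np.float64) ** 2, axis=(1, 2))
    denom = _norm(E[:, None], E[None, :], config.normalization)
    with np.errstate(invalid="ignore", divide="ignore"):
        nmsd = (E[:, None] + E[None, :] - 2.0 * cmax) / denom
    nmsd[~np.isfinite(nmsd)] = 0.0
    np.fill_diagonal(nmsd, 0.0)
    return nmsd


def identifiable_set(
    muaps: MUAPSet | np.ndarray,
    config: DiscriminabilityConfig | None = None,
    fs: float | None = None,
) -> np.ndarray:
    """Boolean mask of units discriminable from *every* other unit.

    A unit is identifiable when its aligned NMSD to each other unit meets the
    criterion.  A pool of one unit is identifiable by convention (the
    pairwise condition is vacuous).
    """
    config = config or DiscriminabilityConfig()
    n = muaps.n_units if isinstance(muaps, MUAPSet) else np.asarray(muaps).shape[0]
    if n < 1:
        raise ValueError("need at least one unit")
    if n == 1:
        return np.array([True])
    D = nmsd_matrix(muaps, fs=fs, config=config)
    off = D + np.diag(np.full(n, np.inf))
    return np.min(off, axis=1) >= config.nmsd_threshold


def _summarize(length_cm, grid, mask, depths, seed) -> dict:
    sel = depths[mask]
    return {
        "length_cm": float(length_cm),
        "area_cm2": grid.area_cm2,
        "ied_mm": grid.ied,
        "n_electrodes": grid.n_electrodes,
        "pct_identifiable": 100.0 * float(np.mean(mask)),
        "mean_depth_mm": float(np.mean(sel)) if sel.size else np.nan,
        "sd_depth_mm": float(np.std(sel, ddof=1)) if sel.size > 1 else np.nan,
        "seed": seed,
    }


def plot_sweep_heatmap(sweep: pd.DataFrame, value: str = "pct_identifiable", ax=None):
    """Heat map of a sweep statistic over (grid area x IED).

    Requires matplotlib (optional dependency); returns the axes.
    """
    import matplotlib.pyplot as plt

    piv = sweep.pivot_table(index="ied_mm", columns="length_cm", values=value)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(piv.to_numpy(), origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(range(piv.shape[1]), [f"{c:g}" for c in piv.columns])
    ax.set_yticks(range(piv.shape[0]), [f"{r:g}" for r in piv.index])
    ax.set_xlabel("grid length (cm)")
    ax.set_ylabel("IED (mm)")
    ax.figure.colorbar(im, ax=ax, label=value)
    return ax


def sweep_configs(
    pool: MotorUnitPool,
    configs: list,
    fs: float = 2048.0,
    window_ms: float = 30.0,
    seed: int = 0,
    fiber_subsample: int | None = 100,
    tissue: TissueElectrical | None = None,
    width_cm: float = 3.6,
    disc_config: DiscriminabilityConfig | None = None,
) -> pd.DataFrame:
    """Identifiable percentage and depth statistics for each (length, IED)
    grid configuration, computing the MUAPs of each grid independently.

    ``configs`` is a list of ``(length_cm, ied_mm)`` pairs.  For large config
    ladders sharing a lattice, :func:`sweep_shared_master` computes the same
    statistics far faster.
    """
    if not configs:
        raise ValueError("empty configuration list")
    disc_config = disc_config or DiscriminabilityConfig()
    rows = []
    for length_cm, ied in configs:
        grid = simulated_grid(length_cm, ied, width_cm)
        muaps = compute_muaps(
            pool, grid, fs=fs, window_ms=window_ms,
            fiber_subsample=fiber_subsample, tissue=tissue, seed=seed,
        )
        mask = identifiable_set(muaps, disc_config)
        rows.append(_summarize(length_cm, grid, mask, muaps.unit_depths, seed))
    return pd.DataFrame(rows)


def sweep_shared_master(
    pool: MotorUnitPool,
    lengths_cm=DEFAULT_LENGTH_LADDER,
    ieds_mm=DEFAULT_IED_LADDER,
    fs: float = 2048.0,
    window_ms: float = 30.0,
    seed: int = 0,
    fiber_subsample: int | None = 100,
    tissue: TissueElectrical | None = None,
    width_cm: float = 3.6,
    disc_config: DiscriminabilityConfig | None = None,
    master: MUAPSet | None = None,
) -> pd.DataFrame:
    """Full (size x IED) sweep on sublattices of a single master grid.

    MUAPs are computed once on the densest, largest grid (min IED, max
    length); every configuration is then a centered crop and decimation of
    that lattice, so its channels are a subset of the master channels.  All
    IEDs must be integer multiples of the master IED.
    """
    lengths_cm = sorted(lengths_cm)
    ieds_mm = sorted(ieds_mm)
    base_ied = float(ieds_mm[0])
    for ied in ieds_mm:
        if abs(ied / base_ied - round(ied / base_ied)) > 1e-9:
            raise ValueError("all IEDs must be integer multiples of the smallest IED")
    disc_config = disc_config or DiscriminabilityConfig()
    master_grid = simulated_grid(max(lengths_cm), base_ied, width_cm)
    if master is None:
        master = compute_muaps(
            pool, master_grid, fs=fs, window_ms=window_ms,
            fiber_subsample=fiber_subsample, tissue=tissue, seed=seed,
        )
    rows = []
    for length_cm in lengths_cm:
        keep_rows = int(np.floor(length_cm * 10.0 / base_ied + 1e-9)) + 1
        cropped = crop_center(master_grid, keep_rows, master_grid.cols)
        for ied in ieds_mm:
            k = int(round(ied / base_ied))
            # centered decimation phase keeps the sub-grid symmetric
            phase = (((cropped.rows - 1) % k) // 2, ((cropped.cols - 1) % k) // 2)
            sub = decimate(cropped, k, phase)
            chans = channel_indices_in(master_grid, sub)
            muaps = master.select_channels(chans, sub)
            mask = identifiable_set(muaps, disc_config)
            rows.append(_summarize(length_cm, sub, mask, master.unit_depths, seed))
    return pd.DataFrame(rows)
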
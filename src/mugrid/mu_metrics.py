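"""Post-decomposition motor-unit analyses.

Covers the recruitment-based early/late classification, spike-triggered MUAP
averaging, the adjacent-electrode correlation used to quantify information
redundancy across a grid, per-subject normalization of identified-unit
counts, weighted logarithmic trend fits, and the rate of agreement between a
decomposed spike train and its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .montage import GridSpec
from .synthesis import RecruitmentModel, fth, invert_fth

__all__ = [
    "TrendFit",
    "classify_early_late",
    "percent_early",
    "sta_muap",
    "adjacent_correlation",
    "normalize_counts",
    "fit_log_trend",
    "rate_of_agreement",
    "match_to_ground_truth",
]


def classify_early_late(
    thresholds, target: float, model: RecruitmentModel | None = None
) -> np.ndarray:
    """Label measured recruitment thresholds as early (True) or late (False).

    The active pool at a task target F is the index range [0, j*] with
    fth(j*) = F; units recruited in the first half of that range (measured
    threshold at or below fth(j*/2)) are early-recruited.
    """
    model = model or RecruitmentModel()
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds > target + 1e-9):
        raise ValueError("measured threshold exceeds the task target")
    j_star = invert_fth(min(target, model.max_threshold), model)
    boundary = fth(0.5 * j_star, model)
    return thresholds <= boundary


def percent_early(
    labels_per_subject: dict,
    min_units: int = 5,
    min_subjects: int = 3,
):
    """Mean percentage of early-recruited units across subjects for one
    condition.

    ``labels_per_subject`` maps subject id to a boolean early/late array.
    Returns ``(percent, suppressed)``: the statistic is suppressed (reported
    as unreliable) when ``min_units`` or fewer units were identified for at
    least ``min_subjects`` subjects.
    """
    counts = [len(v) for v in labels_per_subject.values()]
    few = sum(c <= min_units for c in counts)
    suppressed = few >= min_subjects
    per_subject = [
        100.0 * float(np.mean(v)) for v in labels_per_subject.values() if len(v) > 0
    ]
    pct = float(np.mean(per_subject)) if per_subject else np.nan
    return pct, suppressed


def sta_muap(
    data: np.ndarray, fs: float, spike_times, window_ms: float = 50.0
) -> np.ndarray:
    """Spike-triggered average of the multichannel recording.

    Segments of ``window_ms`` centered on each discharge are averaged per
    channel; segments clipped by the recording edges are dropped.  Returns a
    (channels, window_samples) waveform.
    """
    data = np.asarray(data)
    spikes = np.round(np.asarray(spike_times, dtype=float) * fs).astype(int)
    half = int(round(window_ms * fs / 2000.0))
    wlen = 2 * half + 1
    n = data.shape[1]
    usable = spikes[(spikes - half >= 0) & (spikes + half < n)]
    if usable.size == 0:
        raise ValueError("no discharge with a complete window inside the recording")
    acc = np.zeros((data.shape[0], wlen))
    for s in usable:
        acc += data[:, s - half : s + half + 1]
    return acc / usable.size


def adjacent_correlation(muap: np.ndarray, grid: GridSpec, d_mm: float) -> float:
    """Mean correlation between the MUAP at its peak-to-peak-maximal
    electrode and the (up to four) electrodes at lattice distance ``d_mm``
    along the two grid axes.

    ``d_mm`` must be a multiple of the grid IED; missing neighbors (outside
    the lattice or missing electrodes) are skipped.
    """
    muap = np.asarray(muap)
    steps = d_mm / grid.ied
    if abs(steps - round(steps)) > 1e-9 or steps < 1:
        raise ValueError(f"distance {d_mm} mm is not a positive multiple of the {grid.ied}-mm IED")
    k = int(round(steps))
    positions = grid.lattice_positions()
    if muap.shape[0] != len(positions):
        raise ValueError("waveform channel count does not match the montage")
    index = {rc: i for i, rc in enumerate(positions)}
    best = int(np.argmax(np.ptp(muap, axis=1)))
    r0, c0 = positions[best]
    ref = muap[best]
    rhos = []
    for dr, dc in ((k, 0), (-k, 0), (0, k), (0, -k)):
        i = index.get((r0 + dr, c0 + dc))
        if i is None:
            continue
        neigh = muap[i]
        if np.std(ref) == 0 or np.std(neigh) == 0:
            continue
        rhos.append(float(np.corrcoef(ref, neigh)[0, 1]))
    if not rhos:
        raise ValueError(f"no electrode at distance {d_mm} mm from the peak electrode")
    return float(np.mean(rhos))


def normalize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject normalization of identified-unit counts.

    ``table`` has columns (subject, condition, N); adds ``N_norm`` = 100 * N
    divided by the subject's maximum N across conditions.
    """
    table = table.copy()
    if not {"subject", "condition", "N"} <= set(table.columns):
        raise ValueError("table needs columns 'subject', 'condition', 'N'")
    out = []
    for subject, sub in table.groupby("subject"):
        peak = sub["N"].max()
        if peak <= 0:
            raise ValueError(f"subject {subject} has no identified units in any condition")
        s = sub.copy()
        s["N_norm"] = 100.0 * s["N"] / peak
        out.append(s)
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class TrendFit:
    """Weighted fit of y = a + b * ln(x)."""

    intercept: float
    slope: float
    r_squared: float
    p_value: float
    weights: np.ndarray

    def predict(self, x):
        return self.intercept + self.slope * np.log(np.asarray(x, dtype=float))


def fit_log_trend(x, y, weights=None) -> TrendFit:
    """Weighted least-squares logarithmic trend y = a + b*ln(x).

    The natural logarithm is used throughout; ``weights`` (default all ones)
    down-weight points in the minimization, e.g. 0.5 for conditions sharing
    an electrode count.  The p-value is the two-sided t-test on the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a trend fit")
    if np.any(x <= 0):
        raise ValueError("x values must be positive for a logarithmic fit")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    X = sm.add_constant(np.log(x))
    res = sm.WLS(y, X, weights=w).fit()
    return TrendFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        weights=w,
    )


def rate_of_agreement(
    found, truth, tol_s: float = 0.0005, max_lag_s: float = 0.025
) -> float:
    """Rate of agreement between two discharge-time series.

    The found train is shifted by the constant lag (within ``max_lag_s``)
    maximizing the number of one-to-one matches within ``tol_s``; RoA =
    common / (common + only_found + only_truth).  1.0 for identical trains,
    0.0 for disjoint ones.
    """
    found = np.sort(np.asarray(found, dtype=float))
    truth = np.sort(np.asarray(truth, dtype=float))
    if found.size == 0 and truth.size == 0:
        return 1.0
    if found.size == 0 or truth.size == 0:
        return 0.0
    # candidate lags from nearest-difference histogram, plus exhaustive scan
    # at tol resolution within the window
    lags = np.arange(-max_lag_s, max_lag_s + tol_s / 2, tol_s / 2)
    best = 0
    for lag in lags:
        m = _match_count(found + lag, truth, tol_s)
        if m > best:
            best = m
    common = best
    return common / (common + (found.size - common) + (truth.size - common))


def _match_count(a: np.ndarray, b: np.ndarray, tol: float) -> int:
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


def match_to_ground_truth(
    trains: list, truth: "SpikeTrainSet", tol_s: float = 0.0005
) -> pd.DataFrame:
    """Best-matching ground-truth unit and RoA for each decomposed train.

    Returns a DataFrame with one row per decomposed train: the index of the
    ground-truth unit with the highest rate of agreement, and that RoA.
    """
    rows = []
    for ti, train in enumerate(trains):
        best_u, best_roa = -1, 0.0
        for u, times in enumerate(truth.spike_times):
            if len(times) == 0:
                continue
            roa = rate_of_agreement(train.times, times, tol_s)
            if roa > best_roa:
                best_u, best_roa = u, roa
        rows.append({"train": ti, "truth_unit": best_u, "roa": best_roa,
                     "n_spikes": train.n_spikes, "pnr_db": train.pnr_db})
    return pd.DataFrame(rows)
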
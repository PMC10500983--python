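"""Recording and result I/O: the HDF5 EMG container, delimited imports,
montage files, spike tables, and YAML configuration.

The native container is an HDF5 file with three groups: ``/emg`` (the
channel x sample matrix in uV plus the sampling rate), ``/montage`` (the
grid description) and ``/provenance`` (seeds and configuration echoes), so
every artifact can be traced back to the run that produced it.  Delimited
text and headerless binary imports cover the common export formats of EMG
acquisition software; vendor-native formats are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .montage import GridSpec

__all__ = [
    "EMGContainer",
    "save_emg",
    "load_emg",
    "load_delimited",
    "load_raw_binary",
    "save_montage",
    "load_montage",
    "save_spike_trains",
    "load_spike_trains",
    "load_config",
]


@dataclass
class EMGContainer:
    """A validated multichannel EMG recording with montage and provenance."""

    data: np.ndarray  # (channels, samples), uV
    fs: float
    grid: GridSpec | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("EMG data must be a (channels, samples) matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.grid is not None and self.data.shape[0] != self.grid.n_electrodes:
            raise ValueError(
                f"recording has {self.data.shape[0]} channels but the montage "
                f"has {self.grid.n_electrodes} electrodes"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def save_emg(path, container: EMGContainer) -> None:
    """Write an :class:`EMGContainer` to the HDF5 container layout."""
    with h5py.File(path, "w") as f:
        g = f.create_group("emg")
        g.create_dataset("data", data=container.data)
        g.attrs["fs_hz"] = container.fs
        g.attrs["units"] = "uV"
        m = f.create_group("montage")
        if container.grid is not None:
            m.attrs["json"] = json.dumps(container.grid.to_dict())
        p = f.create_group("provenance")
        p.attrs["json"] = json.dumps(container.provenance, default=str)


def load_emg(path) -> EMGContainer:
    """Read the HDF5 container back; montage consistency is re-validated."""
    with h5py.File(path, "r") as f:
        data = f["emg/data"][()]
        fs = float(f["emg"].attrs["fs_hz"])
        grid = None
        if "json" in f["montage"].attrs:
            grid = GridSpec.from_dict(json.loads(f["montage"].attrs["json"]))
        prov = {}
        if "provenance" in f and "json" in f["provenance"].attrs:
            prov = json.loads(f["provenance"].attrs["json"])
    return EMGContainer(data=data, fs=fs, grid=grid, provenance=prov)


def load_delimited(
    path, fs: float, grid: GridSpec | None = None, delimiter=None, channels_in_columns: bool = True
) -> EMGContainer:
    """Import a delimited text export (one column per channel by default;
    a header row is detected and skipped)."""
    df = pd.read_csv(path, sep=delimiter, engine="python")
    arr = df.to_numpy(dtype=float)
    data = arr.T if channels_in_columns else arr
    return EMGContainer(data=data, fs=fs, grid=grid)


def load_raw_binary(
    path, n_channels: int, fs: float, dtype="float32", grid: GridSpec | None = None
) -> EMGContainer:
    """Import a headerless interleaved binary dump (sample-major)."""
    raw = np.fromfile(path, dtype=dtype)
    if raw.size % n_channels:
        raise ValueError(
            f"file length {raw.size} is not a multiple of {n_channels} channels"
        )
    data = raw.reshape(-1, n_channels).T.astype(np.float64)
    return EMGContainer(data=data, fs=fs, grid=grid)


def save_montage(path, grid: GridSpec) -> None:
    Path(path).write_text(json.dumps(grid.to_dict(), indent=2))


def load_montage(path) -> GridSpec:
    return GridSpec.from_dict(json.loads(Path(path).read_text()))


def save_spike_trains(path, trains) -> None:
    """Spike tables as tidy CSV (unit_id, time_s).

    Accepts a :class:`~mugrid.synthesis.SpikeTrainSet`, a list of
    :class:`~mugrid.decomposition.PulseTrain`, or a list of time arrays.
    """
    rows = []
    if hasattr(trains, "spike_times"):
        seqs = trains.spike_times
    else:
        seqs = [getattr(t, "times", t) for t in trains]
    for u, times in enumerate(seqs):
        for t in np.asarray(times, dtype=float):
            rows.append((u, t))
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(path, index=False)


def load_spike_trains(path) -> list:
    """Read a spike CSV back into a list of time arrays (one per unit id)."""
    df = pd.read_csv(path)
    out = []
    for u in sorted(df["unit_id"].unique()):
        out.append(np.sort(df.loc[df.unit_id == u, "time_s"].to_numpy()))
    return out


def load_config(path):
    """Load a YAML configuration with decomposition and discriminability
    sections into their config objects, rejecting unknown keys."""
    from .decomposition import DecompConfig
    from .discriminability import DiscriminabilityConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    sections = {
        "decomposition": DecompConfig,
        "discriminability": DiscriminabilityConfig,
    }
    for name, cls in sections.items():
        params = raw.get(name, {}) or {}
        valid = {f.name for f in dc_fields(cls)}
        unknown = set(params) - valid
        if unknown:
            raise ValueError(f"unknown keys in '{name}' config: {sorted(unknown)}")
        if "bandpass_hz" in params:
            params["bandpass_hz"] = tuple(params["bandpass_hz"])
        out[name] = cls(**params)
    out["raw"] = raw
    return out
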
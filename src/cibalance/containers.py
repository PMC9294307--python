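"""In-memory containers shared across the pipeline.

The analysis passes three kinds of objects between stages: multichannel
epoched EEG (:class:`EpochSet`), trial-averaged evoked responses
(:class:`Evoked`), and volumetric pseudo-Z activation maps
(:class:`SourceMap`). All time axes are in milliseconds, voltages in
microvolts, and source-space coordinates in MNI millimetres (RAS).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["EpochSet", "Evoked", "SourceMap"]


@dataclass
class EpochSet:
    """Epoched multichannel EEG: ``data[channel, sample, trial]`` in μV.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples, n_trials)
    times : ndarray of ms, e.g. −200 .. 799 at 1000 Hz
    channel_positions : ndarray, shape (n_channels, 3), scalp positions in mm
    fs : sampling rate in Hz
    reference : label of the recording reference ("A2" earlobe or "CAR")
    condition : stimulation condition ("CI1", "CI2" or "CIB")
    metadata : free-form participant / session information
    """

    data: np.ndarray
    times: np.ndarray
    channel_positions: np.ndarray
    fs: float = 1000.0
    reference: str = "A2"
    condition: str = "CI1"
    channel_names: list[str] | None = None
    bad_channels: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, samples, trials)")
        if self.data.shape[1] != self.times.size:
            raise ValueError("times length does not match data samples")
        if self.channel_positions is not None:
            self.channel_positions = np.asarray(self.channel_positions, float)
            if self.channel_positions.shape[0] != self.data.shape[0]:
                raise ValueError("channel count does not match positions")
        if self.bad_channels is None:
            self.bad_channels = np.zeros(self.data.shape[0], dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def good_mask(self) -> np.ndarray:
        return ~self.bad_channels

    def time_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Boolean sample mask for the closed interval [start_ms, stop_ms]."""
        return (self.times >= start_ms) & (self.times <= stop_ms)

    def copy_with(self, **kw) -> "EpochSet":
        args = dict(
            data=self.data,
            times=self.times,
            channel_positions=self.channel_positions,
            fs=self.fs,
            reference=self.reference,
            condition=self.condition,
            channel_names=self.channel_names,
            bad_channels=self.bad_channels,
            metadata=dict(self.metadata),
        )
        args.update(kw)
        return EpochSet(**args)

    # -- HDF5 round trip ---------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            f.create_dataset("channel_positions", data=self.channel_positions)
            f.create_dataset("bad_channels", data=self.bad_channels)
            f.attrs["fs"] = self.fs
            f.attrs["reference"] = self.reference
            f.attrs["condition"] = self.condition
            f.attrs["metadata"] = json.dumps(self.metadata)
            if self.channel_names is not None:
                f.attrs["channel_names"] = json.dumps(list(self.channel_names))

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            names = f.attrs.get("channel_names")
            return cls(
                data=f["data"][()],
                times=f["times"][()],
                channel_positions=f["channel_positions"][()],
                bad_channels=f["bad_channels"][()].astype(bool),
                fs=float(f.attrs["fs"]),
                reference=str(f.attrs["reference"]),
                condition=str(f.attrs["condition"]),
                channel_names=json.loads(names) if names is not None else None,
                metadata=json.loads(f.attrs["metadata"]),
            )


@dataclass
class Evoked:
    """Trial-averaged response: ``data[channel, sample]`` in μV."""

    data: np.ndarray
    times: np.ndarray
    channel_positions: np.ndarray
    fs: float = 1000.0
    reference: str = "CAR"
    condition: str = "CI1"
    n_epochs_included: int = 0
    channel_names: list[str] | None = None
    bad_channels: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("evoked data must be (channels, samples)")
        if self.bad_channels is None:
            self.bad_channels = np.zeros(self.data.shape[0], dtype=bool)

    def good_mask(self) -> np.ndarray:
        return ~self.bad_channels

    def time_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        return (self.times >= start_ms) & (self.times <= stop_ms)

    def to_csv(self, path) -> None:
        """Plain delimited-text export: one column per channel, μV."""
        import pandas as pd

        names = (self.channel_names if self.channel_names
                 else [f"ch{i}" for i in range(self.data.shape[0])])
        df = pd.DataFrame(self.data.T, columns=names)
        df.insert(0, "time_ms", self.times)
        df.to_csv(path, index=False)


@dataclass
class SourceMap:
    """Per-voxel pseudo-Z activation on a volumetric MNI grid.

    ``pz_corrected = pz − omnibus_value`` holds elementwise; positive
    corrected values mark activation above the baseline threshold.
    """

    grid: np.ndarray          # (n_voxels, 3) MNI mm
    pz: np.ndarray            # (n_voxels,) raw pseudo-Z, ≥ 0
    omnibus_value: float
    signal_window: tuple
    baseline_window: tuple = (-200.0, -80.0)
    spacing: float = 10.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        self.pz = np.asarray(self.pz, float)
        if np.any(self.pz < 0):
            raise ValueError("pseudo-Z values must be non-negative")

    @property
    def pz_corrected(self) -> np.ndarray:
        return self.pz - self.omnibus_value

    def to_hdf5(self, path) -> None:
        header = dict(
            omnibus_value=self.omnibus_value,
            signal_window=list(self.signal_window),
            baseline_window=list(self.baseline_window),
            spacing=self.spacing,
            metadata=self.metadata,
        )
        with h5py.File(path, "w") as f:
            f.create_dataset("grid", data=self.grid)
            f.create_dataset("pz", data=self.pz)
            f.attrs["header"] = json.dumps(header)

    @classmethod
    def from_hdf5(cls, path) -> "SourceMap":
        with h5py.File(path, "r") as f:
            header = json.loads(f.attrs["header"])
            return cls(
                grid=f["grid"][()],
                pz=f["pz"][()],
                omnibus_value=float(header["omnibus_value"]),
                signal_window=tuple(header["signal_window"]),
                baseline_window=tuple(header["baseline_window"]),
                spacing=float(header["spacing"]),
                metadata=header.get("metadata", {}),
            )
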
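"""In-memory containers and file I/O for epochs, trial tables, and TF decompositions.

Epochs are stored as plain ``trials x sensors x time`` arrays with an explicit
time axis anchored at the onset of the first flash (t = 0).  Trial tables are
pandas DataFrames with a documented column set; they travel as CSV.  EpochSet
and TFResult round-trip through a single HDF5 file per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

#: Canonical trial-table columns.  ``response`` is "intermediate" /
#: "not-intermediate"; ``label`` is assigned by :func:`prestim.behavior.classify_trials`.
TRIAL_COLUMNS = [
    "trial",
    "block",
    "condition",
    "direction",
    "soa",
    "iti",
    "response",
    "rt",
    "label",
]

CONDITIONS = ("test", "control")
DIRECTIONS = ("inward", "outward")
RESPONSES = ("intermediate", "not-intermediate")
LABELS = ("ILL", "no-ILL", "CTRL-correct", "CTRL-incorrect")


@dataclass
class EpochSet:
    """Per-subject epoched data: ``data[trial, sensor, time]``.

    ``times`` is in seconds relative to first-flash onset and must be uniformly
    spaced at ``1 / sampling_rate``.
    """

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    trial_ids: np.ndarray
    subject_id: str = "S00"
    sensor_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x sensors x time")
        if self.data.shape[0] != len(self.trial_ids):
            raise ValueError("trial_ids length does not match data")
        if self.data.shape[2] != len(self.times):
            raise ValueError("times length does not match data")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniform at 1/sampling_rate")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if not self.sensor_ids:
            self.sensor_ids = [f"S{i:03d}" for i in range(self.data.shape[1])]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def select_trials(self, index) -> "EpochSet":
        """Return a new EpochSet restricted to the given trial index array."""
        index = np.asarray(index)
        return EpochSet(
            data=self.data[index],
            times=self.times,
            sampling_rate=self.sampling_rate,
            trial_ids=self.trial_ids[index],
            subject_id=self.subject_id,
            sensor_ids=list(self.sensor_ids),
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip", shuffle=True)
            f.create_dataset("times", data=self.times)
            f.create_dataset("trial_ids", data=np.asarray(self.trial_ids, dtype="i8"))
            f.attrs["sampling_rate"] = self.sampling_rate
            f.attrs["subject_id"] = self.subject_id
            f.attrs["sensor_ids"] = [str(s) for s in self.sensor_ids]

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                times=f["times"][()],
                sampling_rate=float(f.attrs["sampling_rate"]),
                trial_ids=f["trial_ids"][()],
                subject_id=str(f.attrs["subject_id"]),
                sensor_ids=[str(s) for s in f.attrs["sensor_ids"]],
            )


@dataclass
class TFResult:
    """Complex Morlet coefficients ``coefficients[trial, sensor, freq, time]``.

    Power is the squared modulus, phase the complex argument.  No baseline
    normalization is ever applied; prestimulus quantities are read off the raw
    coefficients.
    """

    coefficients: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    sampling_rate: float
    sensor_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coefficients.ndim != 4:
            raise ValueError("coefficients must be trials x sensors x freqs x time")
        if self.coefficients.shape[2] != len(self.freqs):
            raise ValueError("freqs length mismatch")
        if self.coefficients.shape[3] != len(self.times):
            raise ValueError("times length mismatch")

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.coefficients)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("coefficients", data=self.coefficients, compression="gzip")
            f.create_dataset("freqs", data=self.freqs)
            f.create_dataset("times", data=self.times)
            f.attrs["sampling_rate"] = self.sampling_rate
            f.attrs["sensor_ids"] = [str(s) for s in self.sensor_ids]

    @classmethod
    def from_hdf5(cls, path) -> "TFResult":
        with h5py.File(path, "r") as f:
            return cls(
                coefficients=f["coefficients"][()],
                freqs=f["freqs"][()],
                times=f["times"][()],
                sampling_rate=float(f.attrs["sampling_rate"]),
                sensor_ids=[str(s) for s in f.attrs["sensor_ids"]],
            )


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("condition", "direction") if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")
    return df
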
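"""Morlet time-frequency decomposition and band-level utilities.

The wavelet family uses a *fixed spectral bandwidth* rather than a fixed
number of cycles: the bandwidth (defined as twice the spectral standard
deviation of the Morlet kernel) is held at 3 Hz across frequencies, which
makes the number of cycles grow linearly with frequency,

    n_cycles(f) = 2 f / bandwidth

e.g. 3.7 cycles at 5.5 Hz and 6.7 cycles at 10 Hz for a 3 Hz bandwidth.
Power is the squared modulus of the coefficients, ITC the length of the mean
unit phasor across trials.  No baseline normalization is applied anywhere:
the quantities of interest live in the prestimulus window (-600 to -200 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .containers import EpochSet, TFResult

__all__ = [
    "MorletSpec",
    "BAND_DEFINITIONS",
    "cycles_for_frequency",
    "morlet_transform",
    "compute_itc",
    "band_average",
    "combine_planar",
    "extract_prestim",
    "reject_epochs",
    "equalize_trials",
]

#: Frequency bands of interest, Hz (edges inclusive).
BAND_DEFINITIONS = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "low_gamma": (30.0, 45.0),
    "high_gamma": (60.0, 100.0),
}


def cycles_for_frequency(f, bandwidth: float = 3.0):
    """Cycles of a Morlet wavelet with fixed spectral bandwidth at frequency f.

    Bandwidth is twice the spectral SD of the kernel, so sigma_f = bw/2 and
    n_cycles = f / sigma_f * ... = 2 f / bw.  Exactly linear in f.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or bandwidth <= 0:
        raise ValueError("frequency and bandwidth must be positive")
    out = 2.0 * f / bandwidth
    return float(out) if out.ndim == 0 else out


@dataclass
class MorletSpec:
    """Wavelet family: center frequencies plus the fixed spectral bandwidth."""

    center_frequencies: np.ndarray = field(default_factory=lambda: np.arange(8.0, 13.0))
    bandwidth: float = 3.0

    def __post_init__(self):
        self.center_frequencies = np.atleast_1d(np.asarray(self.center_frequencies, float))

    @property
    def n_cycles(self) -> np.ndarray:
        return cycles_for_frequency(self.center_frequencies, self.bandwidth)

    @classmethod
    def for_band(cls, band: str | tuple, bandwidth: float = 3.0, step: float = 1.0) -> "MorletSpec":
        lo, hi = BAND_DEFINITIONS[band] if isinstance(band, str) else band
        freqs = np.arange(np.ceil(lo / step) * step, hi + 1e-9, step)
        return cls(freqs, bandwidth)


def morlet_transform(epochs: EpochSet, spec: MorletSpec) -> TFResult:
    """Single-trial complex Morlet decomposition (no baseline normalization)."""
    freqs = spec.center_frequencies
    n_cycles = spec.n_cycles
    # wavelet support is +-5 temporal SDs; refuse frequencies whose kernel
    # does not fit in the epoch
    sigma_t = n_cycles / (2 * np.pi * freqs)
    too_long = 10 * sigma_t > (epochs.n_times - 1) / epochs.sampling_rate
    if np.any(too_long):
        bad = freqs[too_long]
        raise ValueError(f"wavelet longer than epoch at frequencies {bad.tolist()} Hz")
    coeffs = tfr_array_morlet(
        epochs.data,
        sfreq=epochs.sampling_rate,
        freqs=freqs,
        n_cycles=n_cycles,
        zero_mean=True,
        output="complex",
    )
    return TFResult(
        coefficients=coeffs,
        freqs=freqs,
        times=epochs.times,
        sampling_rate=epochs.sampling_rate,
        sensor_ids=list(epochs.sensor_ids),
    )


def compute_itc(phase: np.ndarray, axis: int = 0) -> np.ndarray:
    """Intertrial phase coherence: length of the mean unit phasor over trials."""
    phase = np.asarray(phase)
    if phase.shape[axis] < 2:
        raise ValueError("ITC requires at least 2 trials")
    return np.abs(np.mean(np.exp(1j * phase), axis=axis))


def _band_mask(freqs, band):
    lo, hi = BAND_DEFINITIONS[band] if isinstance(band, str) else band
    return (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)


def band_average(values: np.ndarray, freqs: np.ndarray, band, freq_axis: int = -2) -> np.ndarray:
    """Arithmetic mean over center frequencies inside the band (edges inclusive)."""
    freqs = np.asarray(freqs, float)
    mask = _band_mask(freqs, band)
    if not mask.any():
        raise ValueError(f"no center frequencies inside band {band!r}")
    return np.take(values, np.flatnonzero(mask), axis=freq_axis).mean(axis=freq_axis)


def combine_planar(values: np.ndarray, site_of_channel: np.ndarray, axis: int = 0) -> np.ndarray:
    """Combine orthogonal planar channel pairs per site via the Euclidean norm.

    ``site_of_channel`` maps each channel along ``axis`` to its site; each
    site must have exactly two channels.
    """
    site_of_channel = np.asarray(site_of_channel)
    values = np.moveaxis(np.asarray(values, float), axis, 0)
    sites, counts = np.unique(site_of_channel, return_counts=True)
    if np.any(counts != 2):
        raise ValueError("every site must have exactly two channels")
    out = np.empty((len(sites),) + values.shape[1:], dtype=float)
    for k, s in enumerate(sites):
        pair = np.flatnonzero(site_of_channel == s)
        out[k] = np.sqrt(values[pair[0]] ** 2 + values[pair[1]] ** 2)
    return np.moveaxis(out, 0, axis)


def prestim_slice(times: np.ndarray, window=(-0.6, -0.2)) -> slice:
    """Sample slice covering ``window``, endpoints snapped to nearest samples."""
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("window must satisfy start < end")
    times = np.asarray(times, float)
    if t0 < times[0] - 0.5 / _fs(times) or t1 > times[-1] + 0.5 / _fs(times):
        raise ValueError("window outside epoch")
    i0 = int(np.argmin(np.abs(times - t0)))
    i1 = int(np.argmin(np.abs(times - t1)))
    return slice(i0, i1 + 1)


def _fs(times):
    return 1.0 / (times[1] - times[0])


def extract_prestim(obj, window=(-0.6, -0.2)):
    """Restrict an EpochSet or TFResult to the prestimulus window.

    Window endpoints are snapped to the nearest samples (inclusive), so the
    default -600..-200 ms at 333 Hz retains 134 samples.
    """
    sl = prestim_slice(obj.times, window)
    if isinstance(obj, EpochSet):
        return EpochSet(
            data=obj.data[:, :, sl],
            times=obj.times[sl],
            sampling_rate=obj.sampling_rate,
            trial_ids=obj.trial_ids,
            subject_id=obj.subject_id,
            sensor_ids=list(obj.sensor_ids),
        )
    if isinstance(obj, TFResult):
        return TFResult(
            coefficients=obj.coefficients[..., sl],
            freqs=obj.freqs,
            times=obj.times[sl],
            sampling_rate=obj.sampling_rate,
            sensor_ids=list(obj.sensor_ids),
        )
    raise TypeError("extract_prestim expects an EpochSet or TFResult")


def reject_epochs(epochs: EpochSet, threshold: float):
    """Drop epochs whose peak absolute amplitude exceeds ``threshold``.

    Returns ``(kept_epochs, kept_index)``.  May return an empty set.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    keep = np.flatnonzero(peak <= threshold)
    return epochs.select_trials(keep), keep


def equalize_trials(labels, directions, seed: int) -> np.ndarray:
    """Subsample so every response x direction cell has the minimum cell count.

    Returns sorted indices of the retained trials.  Raises on an empty cell.
    Reproducible given the seed.
    """
    labels = np.asarray(labels)
    directions = np.asarray(directions)
    rng = np.random.default_rng(seed)
    cells = {}
    for lab in np.unique(labels):
        for d in np.unique(directions):
            idx = np.flatnonzero((labels == lab) & (directions == d))
            if len(idx) == 0:
                raise ValueError(f"empty cell: label={lab!r}, direction={d!r}")
            cells[(lab, d)] = idx
    n_min = min(len(v) for v in cells.values())
    keep = np.concatenate(
        [rng.choice(idx, size=n_min, replace=False) for idx in cells.values()]
    )
    return np.sort(keep)
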
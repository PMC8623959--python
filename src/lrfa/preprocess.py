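"""Time-domain preprocessing of laser-induced vibration records.

A measurement consists of a train of impulse responses: the excitation laser
fires at a fixed repetition rate while the vibrometer output is logged
continuously. The record is cut into one segment per pulse, the segments are
averaged to suppress uncorrelated noise, the first couple of milliseconds
after each pulse (dominated by the broadband shock of the impact itself) are
purged, and the remainder is Fourier-transformed with a rectangular window to
give a one-sided amplitude spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionConfig",
    "VibrationRecord",
    "Spectrum",
    "segment_pulses",
    "average_pulses",
    "purge_head",
    "compute_spectrum",
    "record_to_spectrum",
    "read_record",
    "write_record",
    "write_spectrum",
    "read_spectrum",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Data-logger settings for one vibration measurement.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz). Default 100 kHz.
    record_duration : float
        Length of one record in seconds. Default 2 s, i.e. 0.2 Mpoint at
        the default sampling rate.
    pulse_rate : float
        Excitation-laser repetition rate (Hz). Default 10 Hz, giving 20
        impulse responses per 2-s record.
    purge_duration : float
        Initial portion of the averaged response, in seconds, discarded
        before spectral analysis. Default 2 ms.
    """

    sampling_rate: float = 100_000.0
    record_duration: float = 2.0
    pulse_rate: float = 10.0
    purge_duration: float = 0.002

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.record_duration <= 0:
            raise ValueError("sampling_rate and record_duration must be positive")
        if self.pulse_rate <= 0:
            raise ValueError("pulse_rate must be positive")
        if not 0 <= self.purge_duration < 1.0 / self.pulse_rate:
            raise ValueError(
                "purge_duration must lie in [0, pulse period); got "
                f"{self.purge_duration} s against a period of {1.0 / self.pulse_rate} s"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.record_duration))

    @property
    def n_pulses(self) -> int:
        return int(round(self.pulse_rate * self.record_duration))

    @property
    def samples_per_pulse(self) -> float:
        return self.sampling_rate / self.pulse_rate


@dataclass
class VibrationRecord:
    """Raw vibrometer voltage trace plus its acquisition settings."""

    samples: np.ndarray
    acquisition: AcquisitionConfig
    t0: float = 0.0
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if len(self.samples) != self.acquisition.n_samples:
            raise ValueError(
                f"record '{self.id}' has {len(self.samples)} samples; acquisition "
                f"settings imply {self.acquisition.n_samples}"
            )

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.acquisition.sampling_rate


@dataclass
class Spectrum:
    """One-sided amplitude spectrum on a uniform frequency grid."""

    frequencies: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.frequencies.shape != self.intensities.shape:
            raise ValueError("frequencies and intensities must have equal length")
        if len(self.frequencies) >= 2:
            df = np.diff(self.frequencies)
            # tolerate text round-trip rounding of the frequency grid
            if np.any(df <= 0) or not np.allclose(df, df[0], rtol=1e-6, atol=1e-3):
                raise ValueError("frequencies must be strictly increasing and uniform")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def resolution(self) -> float:
        if len(self.frequencies) < 2:
            raise ValueError("resolution undefined for a single-bin spectrum")
        return float(self.frequencies[1] - self.frequencies[0])

    @property
    def peak_frequency(self) -> float:
        """Frequency of the maximum-intensity bin (ties -> lowest frequency)."""
        return float(self.frequencies[int(np.argmax(self.intensities))])


def segment_pulses(record: VibrationRecord) -> list[np.ndarray]:
    """Cut a multi-pulse record into one equal-length segment per pulse.

    Pulse onsets are assumed at segment boundaries (the logger is triggered
    by the excitation laser's Q-switch). Concatenating the returned segments
    reproduces the record exactly.
    """
    acq = record.acquisition
    per_pulse = acq.samples_per_pulse
    if abs(per_pulse - round(per_pulse)) > 1e-9:
        raise ValueError(
            f"sampling_rate / pulse_rate = {per_pulse} is not an integer sample count"
        )
    per_pulse = int(round(per_pulse))
    n_pulses = acq.n_pulses
    if n_pulses < 1:
        raise ValueError("record contains no complete pulse period")
    if n_pulses * per_pulse != len(record.samples):
        raise ValueError(
            f"record length {len(record.samples)} is not {n_pulses} x {per_pulse}"
        )
    return [
        record.samples[i * per_pulse : (i + 1) * per_pulse] for i in range(n_pulses)
    ]


def average_pulses(segments: list[np.ndarray]) -> np.ndarray:
    """Element-wise arithmetic mean of the pulse segments."""
    if len(segments) == 0:
        raise ValueError("no segments to average")
    lengths = {len(s) for s in segments}
    if len(lengths) != 1:
        raise ValueError(f"segments have unequal lengths {sorted(lengths)}")
    return np.mean(np.stack([np.asarray(s, dtype=float) for s in segments]), axis=0)


def purge_head(response: np.ndarray, acquisition: AcquisitionConfig) -> np.ndarray:
    """Drop the first ``purge_duration`` seconds of an averaged response.

    The early samples carry the broadband shock of the laser impact; removing
    them leaves a clean view of the low-order natural frequencies.
    """
    response = np.asarray(response, dtype=float)
    n_purge = int(round(acquisition.purge_duration * acquisition.sampling_rate))
    if n_purge >= len(response):
        raise ValueError(
            f"purge of {n_purge} samples would remove the whole {len(response)}-sample response"
        )
    return response[n_purge:]


def compute_spectrum(response: np.ndarray, acquisition: AcquisitionConfig) -> Spectrum:
    """One-sided amplitude spectrum of a response, rectangular window.

    Intensities are physical amplitudes: the DFT magnitude is scaled by 1/N
    at DC (and at Nyquist for even N) and by 2/N elsewhere, so a pure
    sinusoid of amplitude A shows a peak of height ~A. No taper, no zero
    padding, no detrending. Frequency resolution is sampling_rate / N.
    """
    response = np.asarray(response, dtype=float)
    n = len(response)
    if n == 0:
        raise ValueError("cannot compute the spectrum of an empty response")
    mags = np.abs(np.fft.rfft(response))
    scale = np.full(len(mags), 2.0 / n)
    scale[0] = 1.0 / n
    if n % 2 == 0:
        scale[-1] = 1.0 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / acquisition.sampling_rate)
    return Spectrum(frequencies=freqs, intensities=mags * scale)


def record_to_spectrum(record: VibrationRecord) -> Spectrum:
    """Full preprocessing chain: segment, average, purge, FFT."""
    segments = segment_pulses(record)
    averaged = average_pulses(segments)
    purged = purge_head(averaged, record.acquisition)
    return compute_spectrum(purged, record.acquisition)


# ---------------------------------------------------------------------------
# plain-text I/O


def write_record(record: VibrationRecord, path: str | Path) -> None:
    """Write a record as two-column delimited text (time_s, voltage)."""
    df = pd.DataFrame({"time_s": record.times, "voltage": record.samples})
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_record(
    path: str | Path, acquisition: AcquisitionConfig, id: str = ""
) -> VibrationRecord:
    df = pd.read_csv(path, sep="\t")
    if not {"time_s", "voltage"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s and voltage")
    return VibrationRecord(
        samples=df["voltage"].to_numpy(),
        acquisition=acquisition,
        t0=float(df["time_s"].iloc[0]),
        id=id or Path(path).stem,
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    df = pd.DataFrame(
        {"frequency_hz": spectrum.frequencies, "intensity": spectrum.intensities}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_spectrum(path: str | Path) -> Spectrum:
    df = pd.read_csv(path, sep="\t")
    return Spectrum(
        frequencies=df["frequency_hz"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
    )
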
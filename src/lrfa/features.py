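"""Band-wise spectral explanatory variables.

The vibration spectrum is divided into a handful of frequency bands chosen
so that the characteristic resonance peaks are separated, and eight
variables are extracted per band: peak frequency, peak intensity, centroid
frequency, centroid intensity, average intensity, dispersion, kurtosis and
skewness. The band edges are screw-specific presets (a fixed-head monoaxial
screw uses eight bands, 8 x 8 = 64 variables; a movable-head polyaxial screw
uses six bands, 6 x 8 = 48).

Shape statistics of the band intensities x_1..x_n with mean x-bar and sample
standard deviation s (n-1 denominator):

    dispersion  V = (1/n) * sum (x_i - x_bar)^2            (population form)
    kurtosis    K = n(n+1) / ((n-1)(n-2)(n-3)) * sum ((x_i - x_bar)/s)^4
                    - 3 (n-1)^2 / ((n-2)(n-3))             (adjusted excess)
    skewness    S = n / ((n-1)(n-2)) * sum ((x_i - x_bar)/s)^3   (adjusted)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Spectrum

__all__ = [
    "FrequencyBand",
    "BandScheme",
    "MONOAXIAL_SCHEME",
    "POLYAXIAL_SCHEME",
    "FEATURE_NAMES",
    "band_slice",
    "extract_band_features",
    "build_feature_table",
    "write_feature_table",
    "read_feature_table",
    "get_scheme",
]

FEATURE_NAMES = (
    "peak_frequency",
    "peak_intensity",
    "centroid_frequency",
    "centroid_intensity",
    "average_intensity",
    "dispersion",
    "kurtosis",
    "skewness",
)

OBJECTIVE_COLUMN = "peak_torque_nm"


@dataclass(frozen=True)
class FrequencyBand:
    """Half-open frequency interval [low, high) in Hz."""

    low: float
    high: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.low < 0 or self.low >= self.high:
            raise ValueError(f"need 0 <= low < high, got [{self.low}, {self.high})")
        if not self.label:
            object.__setattr__(self, "label", f"{self.low:g}-{self.high:g}Hz")


@dataclass(frozen=True)
class BandScheme:
    """Ordered list of analysis bands. Bands may overlap: a whole-range
    band alongside the sub-bands is deliberate."""

    bands: tuple[FrequencyBand, ...]
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValueError("a band scheme needs at least one band")
        labels = [b.label for b in self.bands]
        if len(set(labels)) != len(labels):
            raise ValueError("band labels must be unique")

    @property
    def n_variables(self) -> int:
        return len(self.bands) * len(FEATURE_NAMES)


def _scheme(name: str, edges: list[tuple[float, float]]) -> BandScheme:
    return BandScheme(
        bands=tuple(FrequencyBand(lo, hi) for lo, hi in edges), preset_name=name
    )


#: Eight bands for fixed-head (monoaxial) screws -> 64 explanatory variables.
MONOAXIAL_SCHEME = _scheme(
    "monoaxial",
    [
        (30, 150),
        (150, 500),
        (500, 1000),
        (1000, 5000),
        (5000, 10_000),
        (10_000, 15_000),
        (15_000, 20_000),
        (30, 20_000),
    ],
)

#: Six bands for movable-head (polyaxial) screws -> 48 explanatory variables.
POLYAXIAL_SCHEME = _scheme(
    "polyaxial",
    [
        (0, 1500),
        (1500, 6500),
        (6500, 11_500),
        (11_500, 15_000),
        (15_000, 25_000),
        (0, 25_000),
    ],
)

_PRESETS = {"monoaxial": MONOAXIAL_SCHEME, "polyaxial": POLYAXIAL_SCHEME}


def get_scheme(name: str) -> BandScheme:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown band-scheme preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def band_slice(spectrum: Spectrum, band: FrequencyBand) -> Spectrum:
    """Bins of ``spectrum`` with band.low <= f < band.high, order preserved."""
    mask = (spectrum.frequencies >= band.low) & (spectrum.frequencies < band.high)
    if not mask.any():
        raise ValueError(
            f"band {band.label} contains no spectrum bins "
            f"(spectrum covers {spectrum.frequencies[0]:g}-{spectrum.frequencies[-1]:g} Hz)"
        )
    return Spectrum(
        frequencies=spectrum.frequencies[mask], intensities=spectrum.intensities[mask]
    )


def _adjusted_moments(x: np.ndarray) -> tuple[float, float]:
    """Bias-adjusted excess kurtosis and skewness of x (returns (K, S)).

    Degenerate inputs (n < 4 or zero spread) yield 0 for both with a
    warning: a flat band carries no shape information, and a numeric zero
    keeps downstream design matrices complete.
    """
    n = len(x)
    s = float(np.std(x, ddof=1)) if n >= 2 else 0.0
    if n < 4 or s == 0.0:
        warnings.warn(
            f"kurtosis/skewness degenerate (n={n}, s={s:g}); emitting 0",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0, 0.0
    z = (x - x.mean()) / s
    kurt = (
        n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * float(np.sum(z**4))
        - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    )
    skew = n / ((n - 1) * (n - 2)) * float(np.sum(z**3))
    return kurt, skew


def extract_band_features(
    sub: Spectrum, centroid_intensity_mode: str = "interpolate"
) -> dict[str, float]:
    """The eight explanatory variables of one band slice.

    Peak ties are broken toward the lowest frequency. The centroid frequency
    is the intensity-weighted mean frequency; its intensity is read off the
    spectrum by linear interpolation (``centroid_intensity_mode =
    'interpolate'``) or from the nearest bin (``'nearest'``).
    """
    f, x = sub.frequencies, sub.intensities
    n = len(x)
    if n < 1:
        raise ValueError("band slice is empty")
    i_peak = int(np.argmax(x))  # argmax takes the first maximum: lowest frequency
    total = float(np.sum(x))
    if total > 0:
        centroid_f = float(np.sum(f * x) / total)
    else:
        centroid_f = float(np.mean(f))  # all-zero band: geometric center
    if centroid_intensity_mode == "interpolate":
        centroid_x = float(np.interp(centroid_f, f, x))
    elif centroid_intensity_mode == "nearest":
        centroid_x = float(x[int(np.argmin(np.abs(f - centroid_f)))])
    else:
        raise ValueError("centroid_intensity_mode must be 'interpolate' or 'nearest'")
    mean_x = float(np.mean(x))
    dispersion = float(np.mean((x - mean_x) ** 2))
    kurt, skew = _adjusted_moments(x)
    return {
        "peak_frequency": float(f[i_peak]),
        "peak_intensity": float(x[i_peak]),
        "centroid_frequency": centroid_f,
        "centroid_intensity": centroid_x,
        "average_intensity": mean_x,
        "dispersion": dispersion,
        "kurtosis": kurt,
        "skewness": skew,
    }


def build_feature_table(
    spectra: list[Spectrum],
    torques: list[float],
    scheme: BandScheme,
    ids: list[str] | None = None,
    centroid_intensity_mode: str = "interpolate",
) -> pd.DataFrame:
    """Per-measurement feature table over a band scheme.

    One row per measurement; columns ``<band_label>:<feature_name>`` in
    scheme-then-feature order, with the objective ``peak_torque_nm``
    appended last. The index holds measurement ids.
    """
    if len(spectra) == 0:
        raise ValueError("no measurements supplied")
    if len(spectra) != len(torques):
        raise ValueError("spectra and torques must have equal length")
    if ids is None:
        ids = [f"m{i:03d}" for i in range(len(spectra))]
    rows = []
    for mid, spec, torque in zip(ids, spectra, torques):
        if torque is None or not np.isfinite(torque):
            raise ValueError(f"measurement {mid}: missing objective value")
        row: dict[str, float] = {}
        for band in scheme.bands:
            try:
                sub = band_slice(spec, band)
                feats = extract_band_features(sub, centroid_intensity_mode)
            except ValueError as exc:
                raise ValueError(
                    f"measurement {mid}, band {band.label}: {exc}"
                ) from exc
            for name, value in feats.items():
                row[f"{band.label}:{name}"] = value
        row[OBJECTIVE_COLUMN] = float(torque)
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(ids, name="measurement_id"))
    ordered = [
        f"{band.label}:{name}" for band in scheme.bands for name in FEATURE_NAMES
    ] + [OBJECTIVE_COLUMN]
    return table[ordered]


def explanatory_columns(table: pd.DataFrame) -> list[str]:
    """All columns of a feature table except the objective."""
    return [c for c in table.columns if c != OBJECTIVE_COLUMN]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="measurement_id")
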
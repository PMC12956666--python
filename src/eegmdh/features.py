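"""Per-electrode time/frequency features for motor-task decoding.

Ten features per channel: five frequency-band powers, the dominant frequency,
and four amplitude statistics (mean and standard deviation of |x|, median of
the signed samples, peak-to-peak range).  With the 16-channel montage this
yields the 160-element descriptor the classifier consumes.

Spectral conventions
--------------------
The spectrum is the unnormalized one-sided DFT magnitude squared on a
rectangular window over the full epoch; no Welch averaging, zero padding or
detrending is applied, so frequency resolution is fs/N.  Band power sums bins
with f_low <= f <= f_high, inclusive at both ends — a bin sitting exactly on a
shared boundary (e.g. 4 Hz between delta and theta) is therefore counted in
both bands.  The dominant frequency is the argmax of power over the
positive-frequency bins; DC is excluded (a nonzero mean would otherwise always
win) and ties break toward the lower frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EEGTrial

__all__ = [
    "BandDefinition",
    "Spectrum",
    "DEFAULT_BANDS",
    "MU_BETA_BANDS",
    "DominantFrequencyError",
    "compute_spectrum",
    "band_power",
    "dominant_frequency",
    "mean_amplitude",
    "std_amplitude",
    "median_amplitude",
    "ptp_amplitude",
    "channel_features",
    "extract_features",
    "feature_names",
    "N_AMPLITUDE_FEATURES",
]

#: features appended after the band powers: dominant_freq, mean, std, median, ptp
N_AMPLITUDE_FEATURES = 5


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency interval [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_low < self.f_high:
            raise ValueError(f"band {self.name!r}: need 0 <= f_low < f_high")


#: The five classical EEG rhythm bands.
DEFAULT_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)

#: Sensorimotor-rhythm variant restricted to the dataset's 7–31 Hz passband.
MU_BETA_BANDS = (
    BandDefinition("mu", 7.5, 12.5),
    BandDefinition("beta", 16.0, 31.0),
)


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectrum: |X(f_k)|² at bin centers k·fs/N."""

    frequencies: np.ndarray
    power: np.ndarray


class DominantFrequencyError(ValueError):
    """Raised when no positive-frequency bin carries power."""


def compute_spectrum(x, fs: float) -> Spectrum:
    """Unnormalized one-sided DFT power spectrum of a real sequence."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sequence of at least 2 samples")
    if not fs > 0:
        raise ValueError("sampling rate must be positive")
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    return Spectrum(freqs, np.abs(spectrum) ** 2)


def band_power(spectrum: Spectrum, band: BandDefinition) -> float:
    """Sum of spectral power over bins with f_low <= f <= f_high (inclusive)."""
    mask = (spectrum.frequencies >= band.f_low) & (spectrum.frequencies <= band.f_high)
    return float(np.sum(spectrum.power[mask]))


def dominant_frequency(spectrum: Spectrum) -> float:
    """Bin-center frequency of maximal power over positive-frequency bins.

    DC is excluded; ties break toward the lowest frequency.  Raises
    :class:`DominantFrequencyError` when every positive-frequency bin is zero
    (e.g. a constant signal), since "most prominent rhythm" is then undefined.
    """
    positive = spectrum.frequencies > 0
    if not positive.any():
        raise DominantFrequencyError("spectrum has no positive-frequency bins")
    power = spectrum.power[positive]
    if np.max(power) <= 0:
        raise DominantFrequencyError("all positive-frequency power is zero")
    # np.argmax returns the first maximum -> lowest-frequency tie-break
    return float(spectrum.frequencies[positive][int(np.argmax(power))])


def _require_nonempty(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty sequence")
    return x


def mean_amplitude(x) -> float:
    """Mean of |x[n]|."""
    return float(np.mean(np.abs(_require_nonempty(x))))


def std_amplitude(x) -> float:
    """Population standard deviation of |x[n]| around its mean."""
    return float(np.std(np.abs(_require_nonempty(x))))


def median_amplitude(x) -> float:
    """Median of the raw signed samples (note: not of |x|)."""
    return float(np.median(_require_nonempty(x)))


def ptp_amplitude(x) -> float:
    """Peak-to-peak range max(x) − min(x)."""
    return float(np.ptp(_require_nonempty(x)))


def channel_features(x, fs: float, bands=DEFAULT_BANDS) -> np.ndarray:
    """The per-channel feature block: band powers, f_dom, μ, σ, median, ptp."""
    spectrum = compute_spectrum(x, fs)
    values = [band_power(spectrum, b) for b in bands]
    values.append(dominant_frequency(spectrum))
    values.extend([
        mean_amplitude(x),
        std_amplitude(x),
        median_amplitude(x),
        ptp_amplitude(x),
    ])
    return np.array(values, dtype=np.float64)


def feature_names(bands=DEFAULT_BANDS, channel_names=None) -> list[str]:
    """Deterministic column names, electrode-major: ``{electrode}_{feature}``."""
    suffixes = [f"power_{b.name}" for b in bands] + [
        "dominant_freq", "mean_amp", "std_amp", "median_amp", "ptp_amp",
    ]
    if channel_names is None:
        return suffixes
    return [f"{ch}_{s}" for ch in channel_names for s in suffixes]


def extract_features(trial: EEGTrial, bands=DEFAULT_BANDS) -> np.ndarray:
    """Assemble the trial's feature vector, electrode-major.

    Length is n_channels × (len(bands) + 5); 160 at the study defaults
    (16 channels, 5 bands).  A silent channel (no rhythmic power) is an error,
    surfaced with the channel name.
    """
    if len(bands) == 0:
        raise ValueError("need at least one band definition")
    blocks = []
    for ci, name in enumerate(trial.channel_names):
        try:
            blocks.append(channel_features(trial.samples[:, ci], trial.sampling_rate, bands))
        except DominantFrequencyError as exc:
            raise DominantFrequencyError(f"channel {name!r}: {exc}") from None
    return np.concatenate(blocks)
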
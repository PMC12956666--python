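"""Synthetic labeled EEG with the statistical structure the classifier assumes.

Each task class carries a spectral signature: a distinct dominant sinusoid in
the 7–31 Hz sensorimotor passband plus weaker band-limited components whose
gains differ by class.  Subjects differ by a single amplitude scalar drawn
once per subject, channels differ by random phases, and white Gaussian noise
is added per sample.  An optional passband mask (zeroing DFT bins outside
7–31 Hz) emulates the source dataset's preprocessing.

This is deliberately NOT physiological EEG — no 1/f background, no ERD/ERS
dynamics, no volume conduction.  It is a faithful testbed for exactly the
spectral/statistical features the pipeline extracts: class structure lives in
dominant frequency and band powers, subject variability in amplitude, and the
noise level controls how far below ceiling the classifier lands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DEFAULT_CHANNEL_NAMES, EEGTrial, TaskVocabulary, TrialDataset
from .features import DEFAULT_BANDS

__all__ = [
    "ClassSignature",
    "GeneratorConfig",
    "default_signatures",
    "generate_trial",
    "generate_dataset",
]

#: representative frequencies (Hz) of the five default bands, used for the
#: secondary components; components outside an active passband are removed by
#: the bandpass mask
_BAND_CENTER_FREQS = tuple((b.f_low + b.f_high) / 2 for b in DEFAULT_BANDS)


@dataclass(frozen=True)
class ClassSignature:
    """Spectral fingerprint of one task class."""

    label: str
    dominant_freq: float      # Hz, inside the 7–31 Hz passband by default
    band_gains: tuple[float, ...]   # amplitude multiplier per default band
    base_amplitude: float = 1.0


@dataclass
class GeneratorConfig:
    """Study-shaped defaults: 60 subjects × 8 tasks, 16 channels, 125 Hz,
    4 s epochs, 7–31 Hz passband."""

    n_subjects: int = 60
    vocabulary: TaskVocabulary = field(default_factory=TaskVocabulary)
    fs: float = 125.0
    duration: float = 4.0
    n_channels: int = 16
    noise_sd: float = 2.5
    subject_amp_sd: float = 0.10
    apply_bandpass: bool = True
    passband: tuple[float, float] = (7.0, 31.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.duration * self.fs < 2:
            raise ValueError("epoch must contain at least 2 samples")
        if self.noise_sd < 0 or self.subject_amp_sd < 0:
            raise ValueError("noise levels must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def default_signatures(vocabulary: TaskVocabulary | None = None
                       ) -> list[ClassSignature]:
    """Deterministic signatures: dominant frequencies evenly spaced in
    [8, 30] Hz and a distinct alpha/beta gain trade-off per class."""
    vocab = vocabulary or TaskVocabulary()
    K = vocab.n_classes
    freqs = np.linspace(8.0, 30.0, K) if K > 1 else np.array([15.0])
    signatures = []
    for k, label in enumerate(vocab.labels):
        frac = k / (K - 1) if K > 1 else 0.0
        gains = (0.05, 0.08, 0.10 + 0.35 * (1 - frac), 0.10 + 0.35 * frac, 0.05)
        signatures.append(ClassSignature(label, float(freqs[k]), gains))
    return signatures


def _bandpass_mask(x: np.ndarray, fs: float, passband: tuple[float, float]) -> np.ndarray:
    """Exact frequency-domain bandpass: zero every DFT bin outside the band."""
    spec = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(x.shape[0], d=1.0 / fs)
    keep = (freqs >= passband[0]) & (freqs <= passband[1])
    spec[~keep] = 0
    return np.fft.irfft(spec, n=x.shape[0], axis=0)


def generate_trial(signature: ClassSignature, config: GeneratorConfig,
                   subject_effect: float, rng: np.random.Generator,
                   subject_id: str = "S00") -> EEGTrial:
    """One trial: per channel, the dominant sinusoid at a random phase plus
    band-limited secondaries scaled by the class band gains, plus white noise."""
    n = config.n_samples
    t = np.arange(n) / config.fs
    amp = signature.base_amplitude * (1.0 + subject_effect)
    samples = np.empty((n, config.n_channels))
    for c in range(config.n_channels):
        phase = rng.uniform(0, 2 * np.pi)
        x = np.sin(2 * np.pi * signature.dominant_freq * t + phase)
        for gain, f in zip(signature.band_gains, _BAND_CENTER_FREQS):
            x = x + gain * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        samples[:, c] = amp * x
    if config.noise_sd > 0:
        samples = samples + rng.normal(0, config.noise_sd, samples.shape)
    if config.apply_bandpass:
        samples = _bandpass_mask(samples, config.fs, config.passband)
    names = (DEFAULT_CHANNEL_NAMES if config.n_channels == len(DEFAULT_CHANNEL_NAMES)
             else tuple(f"ch{i}" for i in range(config.n_channels)))
    return EEGTrial(samples, config.fs, names, label=signature.label,
                    subject_id=subject_id)


def generate_dataset(config: GeneratorConfig | None = None) -> TrialDataset:
    """One trial per (subject, class): n_subjects × K balanced trials,
    bit-identical under a fixed seed.  Defaults yield 480 trials (60 × 8)."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    signatures = default_signatures(config.vocabulary)
    subject_effects = rng.normal(0, config.subject_amp_sd, config.n_subjects)
    trials = []
    for s in range(config.n_subjects):
        sid = f"S{s + 1:02d}"
        for sig in signatures:
            trials.append(generate_trial(sig, config, float(subject_effects[s]),
                                         rng, subject_id=sid))
    return TrialDataset(trials, config.vocabulary)
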
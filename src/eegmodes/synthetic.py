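"""Seeded surrogate EEG generator and reference stochastic processes.

The package's analyses are exercised on synthetic multichannel EEG epochs
that mimic the geometry of a clinical pre-seizure/seizure data set: 100 Hz
sampling, one-minute epochs, ten bipolar temporal/frontal channels, one
pre-seizure and one seizure epoch per subject.  Each channel of each epoch
is treated as an independent labelled segment, so the default configuration
(16 subjects x 10 channels x 2 epochs) yields 320 segments, 160 per class.

Class structure of the signals:

* pre-seizure: 1/f-shaped broadband background plus an alpha-band (10 Hz)
  oscillation — the ordinary awake background rhythm;
* seizure: the same background plus a high-amplitude rhythmic 3–5 Hz
  component (4 Hz with one harmonic at 8 Hz), whose amplitude scales with
  ``effect_size`` so that class separation is tunable down to zero.

The module also provides exact fractional Gaussian noise synthesis
(circulant embedding), used as the ground-truth process when validating
the Hurst-exponent estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

__all__ = [
    "CHANNELS_LEFT",
    "CHANNELS_RIGHT",
    "CHANNELS_10",
    "LABELS",
    "EEGEpoch",
    "GeneratorConfig",
    "generate_epoch",
    "generate_dataset",
    "generate_fgn",
]

#: Left-hemisphere bipolar channels used for the hemisphere summary.
CHANNELS_LEFT = ("Fp1-F7", "F7-T1", "T1-T3", "T3-T5", "Fp1-F3")
#: Right-hemisphere bipolar channels.
CHANNELS_RIGHT = ("Fp2-F8", "F8-T2", "T2-T4", "T4-T6", "Fp2-F4")
#: The ten temporal/frontal-weighted channels, left block first.
CHANNELS_10 = CHANNELS_LEFT + CHANNELS_RIGHT

LABELS = ("pre_seizure", "seizure")

# Amplitude scale of the signal model, in microvolt-like arbitrary units.
_BACKGROUND_STD = 20.0
_ALPHA_AMPLITUDE = 6.0
_SEIZURE_AMPLITUDE = 8.0  # multiplied by effect_size
_HARMONIC_RATIO = 0.5
_ALPHA_HZ = 10.0
_SEIZURE_HZ = 4.0
_CHANNEL_JITTER_SD = 0.1  # lognormal sigma of per-channel gain


@dataclass
class EEGEpoch:
    """One labelled multichannel EEG segment.

    ``data`` is channels x samples.  Single-channel segments (the unit of
    classification) are EEGEpoch instances with one row.
    """

    data: np.ndarray
    fs: float
    label: str
    subject_id: str
    channel_names: Sequence[str]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data must be finite")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def split_channels(self) -> List["EEGEpoch"]:
        """Flatten a multichannel epoch into single-channel segments."""
        return [
            EEGEpoch(
                data=self.data[i : i + 1],
                fs=self.fs,
                label=self.label,
                subject_id=self.subject_id,
                channel_names=[self.channel_names[i]],
            )
            for i in range(self.n_channels)
        ]


@dataclass
class GeneratorConfig:
    """Study-scale parameters of the surrogate data set."""

    n_subjects: int = 16
    n_channels: int = 10
    fs: float = 100.0
    duration: float = 60.0
    effect_size: float = 3.0
    seed: int = 0
    channel_names: Sequence[str] = field(default=CHANNELS_10)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def names(self) -> List[str]:
        base = list(self.channel_names)
        if self.n_channels <= len(base):
            return base[: self.n_channels]
        extra = [f"CH{i + 1}" for i in range(len(base), self.n_channels)]
        return base + extra


def _one_over_f_noise(rng: np.random.Generator, n: int, exponent: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f^exponent-shaped Gaussian noise via spectral shaping."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spectrum * shape, n)
    sd = shaped.std()
    if sd > 0:
        shaped /= sd
    return shaped


def generate_epoch(
    label: str,
    config: GeneratorConfig | None = None,
    subject_index: int = 0,
    epoch_seed: int = 0,
) -> EEGEpoch:
    """Generate one multichannel epoch of the requested class.

    Reproducibility: all randomness flows from
    ``SeedSequence([config.seed, subject_index, epoch_seed])`` which spawns
    one child stream per channel, so regenerating any single epoch gives
    bit-identical data regardless of what else was generated.
    """
    if config is None:
        config = GeneratorConfig()
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    n = config.n_samples
    t = np.arange(n) / config.fs
    ss = np.random.SeedSequence([config.seed, subject_index, epoch_seed])
    channel_streams = ss.spawn(config.n_channels)
    rows = np.empty((config.n_channels, n))
    for ch, child in enumerate(channel_streams):
        rng = np.random.default_rng(child)
        gain = float(np.exp(rng.normal(0.0, _CHANNEL_JITTER_SD)))
        x = _BACKGROUND_STD * _one_over_f_noise(rng, n)
        x += _ALPHA_AMPLITUDE * np.sin(2 * np.pi * _ALPHA_HZ * t + rng.uniform(0, 2 * np.pi))
        if label == "seizure":
            amp = config.effect_size * _SEIZURE_AMPLITUDE
            phase = rng.uniform(0, 2 * np.pi)
            x += amp * np.sin(2 * np.pi * _SEIZURE_HZ * t + phase)
            x += amp * _HARMONIC_RATIO * np.sin(2 * np.pi * 2 * _SEIZURE_HZ * t + phase)
        rows[ch] = gain * x
    return EEGEpoch(
        data=rows,
        fs=config.fs,
        label=label,
        subject_id=f"S{subject_index + 1:02d}",
        channel_names=config.names(),
    )


def generate_dataset(config: GeneratorConfig | None = None) -> List[EEGEpoch]:
    """Generate the full surrogate data set as single-channel segments.

    For every subject one pre-seizure and one seizure multichannel epoch is
    generated and split channel-wise, giving
    ``n_subjects * n_channels * 2`` labelled segments with balanced classes
    (320 at the default 16 x 10 scale).
    """
    if config is None:
        config = GeneratorConfig()
    segments: List[EEGEpoch] = []
    for subject in range(config.n_subjects):
        for epoch_idx, label in enumerate(LABELS):
            epoch = generate_epoch(label, config, subject_index=subject, epoch_seed=epoch_idx)
            segments.extend(epoch.split_channels())
    return segments


def generate_fgn(hurst: float, n: int, seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """Exact fractional Gaussian noise via circulant embedding.

    Returns a stationary zero-mean series of length ``n`` whose
    autocovariance is exactly gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2
    (unit variance at lag 0).  The Davies–Harte construction embeds the
    Toeplitz covariance in a circulant matrix of order 2(n-1) whose
    eigenvalues are obtained by FFT; for fGn with 0 < H < 1 these are
    nonnegative, so the synthesis is exact rather than approximate.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie strictly in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    k = np.arange(n, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    m = 2 * (n - 1)
    circ = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(circ).real
    # Tiny negative eigenvalues can appear from rounding; clip them.
    lam = np.clip(lam, 0.0, None)
    w = np.empty(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    w[n - 1] = np.sqrt(lam[n - 1] / m) * rng.standard_normal()
    u = rng.standard_normal(n - 2)
    v = rng.standard_normal(n - 2)
    w[1 : n - 1] = np.sqrt(lam[1 : n - 1] / (2 * m)) * (u + 1j * v)
    w[n:] = np.conj(w[1 : n - 1][::-1])
    return np.fft.fft(w).real[:n]
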
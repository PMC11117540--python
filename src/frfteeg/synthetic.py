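"""Synthetic two-class EEG-like generator.

Each trial is a sum of band-limited sinusoids (delta 2 Hz, theta 6 Hz,
alpha 10 Hz, beta 20 Hz) with per-trial random phases, plus stationary
AR(1) background noise. The two classes differ only in the sinusoid
amplitudes; by default the "normal" class carries the larger amplitudes, so
its fast-FrFT scatter is larger and more dispersed — the contrast the
scale-type geometric features pick up. Optional high-amplitude spikes
emulate movement artifacts that the >73.3 uV rule should catch.

This is a test-bench signal, not physiological EEG: no 1/f spectrum,
no volume conduction, no non-stationarity beyond the random phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .data_io import ARTIFACT_THRESHOLD_UV, ClassLabel, Epoch, RawRecording

__all__ = ["BAND_FREQS", "SynthConfig", "generate_trial", "generate_recording", "generate_dataset"]

#: Band centre frequencies in Hz.
BAND_FREQS: dict[str, float] = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0}

_DEFAULT_AMPLITUDES: dict[str, tuple[float, float]] = {
    # band -> (normal uV, alcoholic uV); alcoholic = half of normal
    "delta": (15.0, 7.5),
    "theta": (8.0, 4.0),
    "alpha": (12.0, 6.0),
    "beta": (6.0, 3.0),
}


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the 120-trials-per-class study shape."""

    n_trials_per_class: int = 120
    epoch_len: int = 2048
    fs: float = 256.0
    band_amplitudes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_AMPLITUDES)
    )
    ar_coeff: float = 0.8
    noise_sd: float = 3.0
    spike_rate: float = 0.0
    spike_amplitude: float = 200.0
    n_channels: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must be in [0, 1)")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ValueError("spike_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for band, (a_n, a_a) in self.band_amplitudes.items():
            if band not in BAND_FREQS:
                raise ValueError(f"unknown band {band!r}")
            if a_n < 0 or a_a < 0:
                raise ValueError("band amplitudes must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _ar1(rng: np.random.Generator, n: int, coeff: float, sd: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd, size=n)
    if coeff > 0:
        # start from the stationary distribution so the series is stationary
        innov[0] = rng.normal(0.0, sd / np.sqrt(1.0 - coeff**2))
    return lfilter([1.0], [1.0, -coeff], innov)


def _sinusoids(cfg: SynthConfig, label: ClassLabel, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(cfg.epoch_len) / cfg.fs
    col = 0 if label is ClassLabel.NORMAL else 1
    x = np.zeros(cfg.epoch_len)
    for band, amps in cfg.band_amplitudes.items():
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += amps[col] * np.sin(2.0 * np.pi * BAND_FREQS[band] * t + phase)
    return x


def _maybe_spike(cfg: SynthConfig, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if cfg.spike_rate > 0 and rng.uniform() < cfg.spike_rate:
        pos = rng.integers(0, len(x))
        x = x.copy()
        x[pos] += cfg.spike_amplitude * rng.choice([-1.0, 1.0])
    return x


def generate_trial(
    cfg: SynthConfig, label: ClassLabel, rng: np.random.Generator | None = None
) -> Epoch:
    """One labelled epoch: class-scaled sinusoids + AR(1) noise (+ optional spike)."""
    if rng is None:
        rng = cfg.rng()
    x = _sinusoids(cfg, label, rng)
    x = x + _ar1(rng, cfg.epoch_len, cfg.ar_coeff, cfg.noise_sd)
    x = _maybe_spike(cfg, x, rng)
    return Epoch(samples=x, channel="SYN0", label=label)


def generate_recording(
    cfg: SynthConfig,
    label: ClassLabel,
    rng: np.random.Generator | None = None,
    n_channels: int | None = None,
) -> RawRecording:
    """A multichannel trial whose channels share the sinusoidal content.

    Channels carry the same band sinusoids scaled by per-channel gains (drawn
    once per trial in [0.8, 1.2]) plus independent AR(1) noise, giving the
    correlated-signal / uncorrelated-noise structure that across-channel
    PCA denoising assumes.
    """
    if rng is None:
        rng = cfg.rng()
    if n_channels is None:
        n_channels = cfg.n_channels
    base = _sinusoids(cfg, label, rng)
    gains = rng.uniform(0.8, 1.2, size=n_channels)
    rows = []
    for g in gains:
        chan = g * base + _ar1(rng, cfg.epoch_len, cfg.ar_coeff, cfg.noise_sd)
        rows.append(_maybe_spike(cfg, chan, rng))
    return RawRecording(
        samples=np.vstack(rows),
        channel_labels=[f"SYN{i}" for i in range(n_channels)],
        fs=cfg.fs,
        subject_class=label,
    )


def generate_dataset(cfg: SynthConfig) -> tuple[list[Epoch], np.ndarray]:
    """Balanced, seeded, shuffled dataset of single-channel epochs.

    Returns ``2 * n_trials_per_class`` epochs and the matching 0/1 label
    array (0 = normal, 1 = alcoholic).
    """
    rng = cfg.rng()
    epochs = [
        generate_trial(cfg, ClassLabel.NORMAL, rng)
        for _ in range(cfg.n_trials_per_class)
    ] + [
        generate_trial(cfg, ClassLabel.ALCOHOLIC, rng)
        for _ in range(cfg.n_trials_per_class)
    ]
    perm = rng.permutation(len(epochs))
    epochs = [epochs[i] for i in perm]
    labels = np.array(
        [0 if e.label is ClassLabel.NORMAL else 1 for e in epochs], dtype=int
    )
    return epochs, labels


def artifact_threshold() -> float:
    """The amplitude rule the injected spikes are meant to violate."""
    return ARTIFACT_THRESHOLD_UV
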
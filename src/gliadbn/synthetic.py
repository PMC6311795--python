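"""Synthetic multichannel EEG with label-dependent band structure.

Generates labeled trials that mimic the statistical structure of
affect-rating EEG experiments: 32 named scalp channels sampled at 128 Hz,
band-limited oscillatory content in the theta/alpha/beta/gamma bands,
1/f background noise, and interchannel correlation through a fixed mixing
matrix.  The two binary label dimensions modulate the signal the way the
downstream feature pipeline expects:

* arousal shifts broadband beta+gamma oscillation amplitude;
* valence shifts the right-minus-left alpha amplitude of homologous
  channel pairs (frontal/parietal asymmetry).

Everything is reproducible from ``(seed, subject_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import signal as sps

__all__ = [
    "DEAP_CHANNELS",
    "HOMOLOGOUS_PAIRS",
    "EEGTrial",
    "SimConfig",
    "ConfigError",
    "simulate_subject",
    "simulate_dataset",
    "bandlimited_noise",
    "pink_noise",
    "save_subject",
    "load_subject",
    "export_feature_matrix",
]

#: 32-channel montage (10-20 names) in recording order.
DEAP_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: The 14 homologous (right, left) scalp pairs used for asymmetry features.
HOMOLOGOUS_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp2", "Fp1"), ("AF4", "AF3"), ("F4", "F3"), ("F8", "F7"),
    ("FC6", "FC5"), ("FC2", "FC1"), ("C4", "C3"), ("T8", "T7"),
    ("CP6", "CP5"), ("CP2", "CP1"), ("P4", "P3"), ("P8", "P7"),
    ("PO4", "PO3"), ("O2", "O1"),
)

# Oscillator bands synthesised by the generator (Hz) and their baseline
# amplitudes (arbitrary microvolt-scale units).
_GEN_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}
_BASE_AMP: dict[str, float] = {"theta": 4.0, "alpha": 5.0, "beta": 3.0, "gamma": 2.0}
_TRIAL_JITTER = 0.2    # trial-to-trial amplitude sd, as a fraction of baseline
_CHANNEL_JITTER = 0.1  # per-channel amplitude sd, fraction of baseline


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass
class EEGTrial:
    """One trial: a channels-by-samples matrix with labels.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
    fs : float
        Sampling rate in Hz.
    channels : tuple of str
        Ordered, duplicate-free channel names; one per data row.
    label : tuple (arousal, valence)
        Binary labels, each in {0, 1}.
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...]
    label: tuple[int, int]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows for {len(self.channels)} channels"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        self.label = (int(self.label[0]), int(self.label[1]))
        if any(v not in (0, 1) for v in self.label):
            raise ValueError("labels must be binary")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters.

    Defaults follow the benchmark recording protocol the generator
    emulates: 32 subjects x 40 one-minute trials over 32 channels at
    128 Hz.  ``effect_size`` is the standardized separation (Cohen's d)
    between class-conditional means of the targeted band-amplitude
    summaries; ``mixing_strength`` in [0, 1] blends each channel with a
    fixed random row-stochastic mixture of all channels.
    """

    n_subjects: int = 32
    n_trials_per_subject: int = 40
    n_channels: int = 32
    fs: float = 128.0
    duration: float = 60.0
    effect_size: float = 1.0
    noise_sd: float = 1.0
    mixing_strength: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_trials_per_subject", "n_channels"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not self.fs > 0:
            raise ConfigError("fs must be positive")
        if self.duration < 4.0:
            raise ConfigError("duration must be >= 4 s")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0.0 <= self.mixing_strength <= 1.0:
            raise ConfigError("mixing_strength must be in [0, 1]")

    def channel_names(self) -> tuple[str, ...]:
        if self.n_channels == 32:
            return DEAP_CHANNELS
        return tuple(f"Ch{i + 1}" for i in range(self.n_channels))


def _subject_rng(cfg: SimConfig, subject_index: int, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(subject_index, stream))
    return np.random.default_rng(ss)


def pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-shaped noise of length ``n``."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    scale = 1.0 / np.sqrt(np.maximum(f, f[1]))
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-RMS band-limited oscillation (filtered Gaussian noise)."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    warmup = int(fs)
    x = sps.sosfilt(sos, rng.standard_normal(n + warmup))[warmup:]
    return x / np.sqrt(np.mean(x**2))


def _balanced_labels(rng: np.random.Generator, n: int) -> np.ndarray:
    """Binary assignment with class counts differing by at most 1."""
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    if n % 2:
        y[n // 2] = rng.integers(0, 2)
    rng.shuffle(y)
    return y


def _pair_indices(channels: tuple[str, ...]) -> list[tuple[int, int]]:
    """(right, left) index pairs: named montage pairs, else consecutive."""
    name_to_idx = {c: i for i, c in enumerate(channels)}
    if set(DEAP_CHANNELS) <= set(channels):
        return [(name_to_idx[r], name_to_idx[l]) for r, l in HOMOLOGOUS_PAIRS]
    return [(2 * i + 1, 2 * i) for i in range(len(channels) // 2)]


def _mixing_matrix(cfg: SimConfig, subject_index: int) -> np.ndarray:
    m = cfg.mixing_strength
    n = cfg.n_channels
    rng = _subject_rng(cfg, subject_index, 0)
    raw = np.abs(rng.standard_normal((n, n)))
    raw /= raw.sum(axis=1, keepdims=True)
    return (1.0 - m) * np.eye(n) + m * raw


def simulate_subject(cfg: SimConfig, subject_index: int) -> list[EEGTrial]:
    """Generate one subject's labeled trials.

    Labels are balanced per dimension; arousal raises beta+gamma
    amplitude, valence tilts the alpha amplitude of right vs left
    homologous channels.  Bit-reproducible for a given ``(cfg, subject)``.
    """
    if not 0 <= subject_index < cfg.n_subjects:
        raise ConfigError("subject_index out of range")
    n_ch = cfg.n_channels
    n = int(round(cfg.duration * cfg.fs))
    channels = cfg.channel_names()
    pairs = _pair_indices(channels)
    right = np.array([r for r, _ in pairs], dtype=int)
    left = np.array([l for _, l in pairs], dtype=int)
    A = _mixing_matrix(cfg, subject_index)

    lab_rng = _subject_rng(cfg, subject_index, 1)
    arousal = _balanced_labels(lab_rng, cfg.n_trials_per_subject)
    valence = _balanced_labels(lab_rng, cfg.n_trials_per_subject)

    rng = _subject_rng(cfg, subject_index, 2)
    trials: list[EEGTrial] = []
    for t in range(cfg.n_trials_per_subject):
        ya, yv = arousal[t], valence[t]
        raw = np.zeros((n_ch, n))
        for band, (lo, hi) in _GEN_BANDS.items():
            base = _BASE_AMP[band]
            trial_sd = _TRIAL_JITTER * base
            amp = base + trial_sd * rng.standard_normal() + (
                _CHANNEL_JITTER * base
            ) * rng.standard_normal(n_ch)
            if band in ("beta", "gamma"):
                amp = amp + 0.5 * cfg.effect_size * trial_sd * (2 * ya - 1)
            if band == "alpha" and len(pairs):
                shift = 0.25 * cfg.effect_size * trial_sd * (2 * yv - 1)
                amp[right] = amp[right] + shift
                amp[left] = amp[left] - shift
            amp = np.maximum(amp, 0.05 * base)
            for ch in range(n_ch):
                raw[ch] += amp[ch] * bandlimited_noise(rng, n, cfg.fs, (lo, hi))
        for ch in range(n_ch):
            raw[ch] += cfg.noise_sd * pink_noise(rng, n)
        trials.append(
            EEGTrial(data=A @ raw, fs=cfg.fs, channels=channels, label=(ya, yv))
        )
    return trials


def simulate_dataset(cfg: SimConfig) -> list[list[EEGTrial]]:
    """All subjects' trials: ``n_subjects`` lists of ``n_trials_per_subject``."""
    return [simulate_subject(cfg, s) for s in range(cfg.n_subjects)]


# ---------------------------------------------------------------------------
# Container I/O (one HDF5 file per subject)
# ---------------------------------------------------------------------------

def save_subject(path, trials: list[EEGTrial]) -> None:
    """Write one subject's trials to an HDF5 container.

    Layout: ``data`` (trials x channels x samples), ``fs`` scalar,
    ``channels`` string list, ``labels`` (trials x 2).
    """
    if not trials:
        raise ValueError("no trials to save")
    data = np.stack([t.data for t in trials])
    labels = np.array([t.label for t in trials], dtype=int)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data)
        f.create_dataset("fs", data=float(trials[0].fs))
        f.create_dataset("channels", data=np.array(trials[0].channels, dtype="S"))
        f.create_dataset("labels", data=labels)


def load_subject(path) -> list[EEGTrial]:
    """Read trials written by :func:`save_subject`."""
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f["fs"][()])
        channels = tuple(c.decode() for c in f["channels"][()])
        labels = f["labels"][()]
    return [
        EEGTrial(data=data[i], fs=fs, channels=channels,
                 label=(int(labels[i, 0]), int(labels[i, 1])))
        for i in range(data.shape[0])
    ]


def export_feature_matrix(path, X: np.ndarray, labels: np.ndarray,
                          feature_names=None) -> None:
    """Plain delimited-text export: instances x (features + 2 label columns)."""
    import pandas as pd

    X = np.asarray(X)
    labels = np.asarray(labels).reshape(X.shape[0], 2)
    cols = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(X.shape[1])
    ]
    df = pd.DataFrame(X, columns=cols)
    df["arousal"] = labels[:, 0]
    df["valence"] = labels[:, 1]
    df.to_csv(path, sep="\t", index=False)
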
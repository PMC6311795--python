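"""Preprocessing and the 664-dimensional multi-domain EEG feature vector.

One trial maps to 664 features partitioned into five disjoint subsets:

* F1 (128): per-channel time statistics — mean, variance, zero-crossing
  rate, approximate entropy (4 x 32 channels);
* F2 (160): average Welch PSD in theta / slow-alpha / alpha / beta / gamma
  (5 x 32 channels);
* F3 (56): right-minus-left band-PSD differences over 14 homologous
  channel pairs in theta / alpha / beta / gamma (4 x 14);
* F4 (160): Hilbert–Huang mean squared amplitude per band (5 x 32);
* F5 (160): Hilbert–Huang amplitude-weighted instantaneous frequency per
  band (5 x 32).

Preprocessing is anti-aliased decimation to 128 Hz followed by a
zero-phase 4–45 Hz Butterworth band-pass.  The delta band (1–4 Hz) keeps
its HHS slots even though the band-pass removes most of its energy, so
the printed 664-wide layout is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import cdist

from .synthetic import DEAP_CHANNELS, HOMOLOGOUS_PAIRS, EEGTrial

__all__ = [
    "BANDS",
    "PSD_BANDS",
    "DIFF_BANDS",
    "HHS_BANDS",
    "FeatureSchema",
    "FeatureVector",
    "preprocess",
    "time_stats",
    "band_psd",
    "power_differences",
    "hhs_features",
    "extract",
    "extract_subject",
    "standardize_subject",
    "apply_standardization",
    "approximate_entropy",
    "zero_crossing_rate",
    "emd",
]

#: Named frequency intervals in Hz, half-open [lo, hi).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "slow_alpha": (8.0, 10.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}
PSD_BANDS = ("theta", "slow_alpha", "alpha", "beta", "gamma")
DIFF_BANDS = ("theta", "alpha", "beta", "gamma")
HHS_BANDS = ("delta", "theta", "alpha", "beta", "gamma")

_SUBSET_SIZES = {"F1": 128, "F2": 160, "F3": 56, "F4": 160, "F5": 160}
TOTAL_FEATURES = 664


@dataclass(frozen=True)
class FeatureSchema:
    """Named layout of the 664-wide feature vector.

    ``subset_index`` maps subset ids F1..F5 to disjoint ``range`` objects
    that cover 0..663; ``pair_list`` holds the 14 (right, left) channel
    pairs used by F3.
    """

    channels: tuple[str, ...]
    names: tuple[str, ...]
    subset_index: dict[str, range]
    pair_list: tuple[tuple[str, str], ...]

    @classmethod
    def default(cls, channels=DEAP_CHANNELS, pair_list=HOMOLOGOUS_PAIRS
                ) -> "FeatureSchema":
        channels = tuple(channels)
        pair_list = tuple(tuple(p) for p in pair_list)
        if len(channels) != 32:
            raise ValueError("the 664-wide layout requires 32 channels")
        if len(pair_list) != 14:
            raise ValueError("exactly 14 channel pairs required")
        missing = {c for pair in pair_list for c in pair} - set(channels)
        if missing:
            raise ValueError(f"pair channels not in montage: {sorted(missing)}")
        names: list[str] = []
        for ch in channels:
            names += [f"F1|{ch}|time|{s}" for s in ("mean", "var", "zcr", "apen")]
        for ch in channels:
            names += [f"F2|{ch}|psd|{b}" for b in PSD_BANDS]
        for r, l in pair_list:
            names += [f"F3|{r}-{l}|psd_diff|{b}" for b in DIFF_BANDS]
        for ch in channels:
            names += [f"F4|{ch}|hhs_amp2|{b}" for b in HHS_BANDS]
        for ch in channels:
            names += [f"F5|{ch}|hhs_if|{b}" for b in HHS_BANDS]
        subset_index, start = {}, 0
        for key, size in _SUBSET_SIZES.items():
            subset_index[key] = range(start, start + size)
            start += size
        return cls(channels=channels, names=tuple(names),
                   subset_index=subset_index, pair_list=pair_list)

    def __post_init__(self):
        covered = sorted(i for r in self.subset_index.values() for i in r)
        if covered != list(range(len(self.names))):
            raise ValueError("subsets must disjointly cover all feature indices")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class FeatureVector:
    """A 664-wide feature vector tied to a schema and a binary label pair."""

    values: np.ndarray
    schema: FeatureSchema
    label: tuple[int, int]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.schema),):
            raise ValueError("value length does not match schema")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    def subset(self, key: str) -> np.ndarray:
        r = self.schema.subset_index[key]
        return self.values[r.start:r.stop]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(trial: EEGTrial, target_fs: float = 128.0) -> EEGTrial:
    """Decimate to ``target_fs`` and band-pass 4–45 Hz (zero phase).

    Decimation uses polyphase resampling with an anti-alias low-pass; the
    band-pass is a 4th-order Butterworth applied forward-backward.
    """
    if target_fs > trial.fs:
        raise ValueError(f"target_fs {target_fs} exceeds trial fs {trial.fs}")
    if not target_fs > 2 * 45.0:
        raise ValueError("target_fs must exceed twice the 45 Hz band edge")
    data = trial.data
    if trial.fs != target_fs:
        frac = Fraction(target_fs / trial.fs).limit_denominator(1000)
        data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    sos = sps.butter(4, (4.0, 45.0), btype="bandpass", fs=target_fs, output="sos")
    n_sect = sos.shape[0]
    padlen = 3 * (2 * n_sect + 1)
    if data.shape[1] <= padlen:
        raise ValueError(
            f"trial too short for zero-phase filtering ({data.shape[1]} samples)"
        )
    data = sps.sosfiltfilt(sos, data, axis=1)
    return EEGTrial(data=data, fs=target_fs, channels=trial.channels,
                    label=trial.label)


# ---------------------------------------------------------------------------
# F1: time-domain statistics
# ---------------------------------------------------------------------------

def zero_crossing_rate(x: np.ndarray) -> float:
    """Sign changes of the mean-removed signal divided by (N - 1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    y = x - x.mean()
    return float(np.count_nonzero(y[:-1] * y[1:] < 0) / (x.size - 1))


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r) with self-matches included.

    ``r`` defaults to 0.2 times the signal's standard deviation.  A
    constant signal has ApEn 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        raise ValueError(f"need at least {m + 2} samples for ApEn(m={m})")
    sd = x.std()
    if r is None:
        r = 0.2 * sd
    if sd == 0 or r <= 0:
        return 0.0

    def phi(mm: int) -> float:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        n = emb.shape[0]
        logs = np.empty(n)
        block = 2048
        for s in range(0, n, block):
            d = cdist(emb[s:s + block], emb, metric="chebyshev")
            logs[s:s + block] = np.log(np.count_nonzero(d <= r, axis=1) / n)
        return float(logs.mean())

    return phi(m) - phi(m + 1)


def time_stats(trial: EEGTrial, m: int = 2, r_fraction: float = 0.2) -> np.ndarray:
    """Per channel: mean, population variance, zero-crossing rate, ApEn."""
    out = np.empty(4 * len(trial.channels))
    for i, x in enumerate(trial.data):
        sd = x.std()
        out[4 * i: 4 * i + 4] = (
            x.mean(),
            x.var(),  # population convention (divide by N)
            zero_crossing_rate(x),
            approximate_entropy(x, m=m, r=r_fraction * sd),
        )
    return out


# ---------------------------------------------------------------------------
# F2/F3: band PSDs and hemispheric power differences
# ---------------------------------------------------------------------------

def band_psd(trial: EEGTrial, window_seconds: float = 2.0) -> np.ndarray:
    """Mean Welch PSD per channel per band (channel-major, band-minor).

    Welch with ``window_seconds`` Hann segments at 50% overlap; a band's
    value is the mean PSD over frequency bins with lo <= f < hi.
    """
    fs = trial.fs
    for b in PSD_BANDS:
        if BANDS[b][1] > fs / 2:
            raise ValueError(f"band {b} exceeds Nyquist for fs={fs}")
    nperseg = int(round(window_seconds * fs))
    if trial.n_samples < nperseg:
        raise ValueError("trial shorter than one PSD window")
    f, pxx = sps.welch(trial.data, fs=fs, nperseg=nperseg,
                       noverlap=nperseg // 2, axis=1)
    out = np.empty(len(trial.channels) * len(PSD_BANDS))
    for j, b in enumerate(PSD_BANDS):
        lo, hi = BANDS[b]
        mask = (f >= lo) & (f < hi)
        out[j::len(PSD_BANDS)] = pxx[:, mask].mean(axis=1)
    return out


def power_differences(psd_values: np.ndarray, schema: FeatureSchema) -> np.ndarray:
    """Right-minus-left band-PSD differences (14 pairs x 4 bands = 56)."""
    psd = np.asarray(psd_values, dtype=float)
    n_ch = len(schema.channels)
    if psd.shape != (n_ch * len(PSD_BANDS),):
        raise ValueError("psd_values must come from band_psd on this schema")
    psd = psd.reshape(n_ch, len(PSD_BANDS))
    idx = {c: i for i, c in enumerate(schema.channels)}
    band_col = {b: PSD_BANDS.index(b) for b in DIFF_BANDS}
    out = np.empty(len(schema.pair_list) * len(DIFF_BANDS))
    k = 0
    for right, left in schema.pair_list:
        if right not in idx or left not in idx:
            raise ValueError(f"pair channel missing from schema: {right}-{left}")
        for b in DIFF_BANDS:
            out[k] = psd[idx[right], band_col[b]] - psd[idx[left], band_col[b]]
            k += 1
    return out


# ---------------------------------------------------------------------------
# F4/F5: Hilbert–Huang spectrum features
# ---------------------------------------------------------------------------

def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dx = np.diff(x)
    maxima = np.flatnonzero((dx[:-1] > 0) & (dx[1:] <= 0)) + 1
    minima = np.flatnonzero((dx[:-1] < 0) & (dx[1:] >= 0)) + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    # Mirror the two outermost extrema past each end so the spline does
    # not swing free at the boundaries.
    n = x.size
    k = min(2, idx.size)
    tl, vl = -idx[:k][::-1], x[idx[:k]][::-1]
    tr = 2 * (n - 1) - idx[-k:][::-1]
    vr = x[idx[-k:]][::-1]
    t = np.concatenate([tl, idx, tr]).astype(float)
    v = np.concatenate([vl, x[idx], vr])
    t, keep = np.unique(t, return_index=True)
    return CubicSpline(t, v[keep])(np.arange(n))


def emd(x: np.ndarray, max_imfs: int = 10, sd_threshold: float = 0.2,
        max_siftings: int = 50) -> list[np.ndarray]:
    """Empirical mode decomposition by standard sifting.

    Sifting of each mode stops when the Cauchy-type criterion
    ``sum((h_prev - h)^2) / sum(h_prev^2)`` drops below ``sd_threshold``;
    extraction stops when the residual has too few extrema to envelope
    or ``max_imfs`` modes have been pulled out.  Returns possibly-empty
    list of IMFs (a constant signal has none).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    imfs: list[np.ndarray] = []
    residual = x.copy()
    total = float(np.sum(x**2)) or 1.0
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        if float(np.sum(residual**2)) < 1e-12 * total:
            break
        h = residual.copy()
        for _ in range(max_siftings):
            mx, mn = _local_extrema(h)
            if mx.size < 2 or mn.size < 2:
                break
            mean_env = 0.5 * (_envelope(h, mx) + _envelope(h, mn))
            h_new = h - mean_env
            denom = float(np.sum(h**2)) or 1.0
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            if sd < sd_threshold:
                break
        imfs.append(h)
        residual = residual - h
    return imfs


def hhs_features(trial: EEGTrial, edge_fraction: float = 0.05) -> np.ndarray:
    """Hilbert–Huang band summaries: 160 mean squared amplitudes then 160
    amplitude-weighted instantaneous frequencies (channel-major).

    Per channel the signal is decomposed into IMFs; each IMF's analytic
    signal gives amplitude a(t) and instantaneous frequency f(t).  A
    band's squared-amplitude feature is the mean of a(t)^2 over all
    (IMF, t) samples whose f(t) falls in the band (0 if none), and its
    frequency feature is the a^2-weighted mean of f(t) over those
    samples.  The outer ``edge_fraction`` of samples on each side is
    excluded from the averages.
    """
    n_ch = len(trial.channels)
    n = trial.n_samples
    k = int(np.ceil(edge_fraction * n))
    keep = slice(k, n - k)
    amp2 = np.zeros((n_ch, len(HHS_BANDS)))
    ifreq = np.zeros((n_ch, len(HHS_BANDS)))
    for ch in range(n_ch):
        x = trial.data[ch]
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite samples in channel {trial.channels[ch]}")
        imfs = emd(x)
        # drop numerically negligible modes (sifting residue), which would
        # otherwise dilute the in-band sample averages
        total = float(np.sum(x**2))
        imfs = [m for m in imfs if np.sum(m**2) > 1e-6 * total]
        if not imfs:
            continue  # constant / trivial channel: all band slots stay 0
        a_all, f_all = [], []
        for imf in imfs:
            analytic = sps.hilbert(imf)
            a = np.abs(analytic)[keep]
            phase = np.unwrap(np.angle(analytic))
            f = np.gradient(phase) * trial.fs / (2 * np.pi)
            a_all.append(a)
            f_all.append(f[keep])
        a2 = np.concatenate(a_all) ** 2
        f = np.concatenate(f_all)
        for j, b in enumerate(HHS_BANDS):
            lo, hi = BANDS[b]
            mask = (f >= lo) & (f < hi)
            if not mask.any():
                continue
            amp2[ch, j] = a2[mask].mean()
            w = a2[mask].sum()
            if w > 0:
                ifreq[ch, j] = float(np.sum(a2[mask] * f[mask]) / w)
    return np.concatenate([amp2.ravel(), ifreq.ravel()])


# ---------------------------------------------------------------------------
# Assembly and standardization
# ---------------------------------------------------------------------------

def extract(trial: EEGTrial, schema: FeatureSchema | None = None) -> FeatureVector:
    """Full 664-wide feature vector [F1 | F2 | F3 | F4 | F5] for one trial."""
    if schema is None:
        schema = FeatureSchema.default()
    if tuple(trial.channels) != schema.channels:
        raise ValueError("trial channels do not match schema")
    psd = band_psd(trial)
    values = np.concatenate([
        time_stats(trial),
        psd,
        power_differences(psd, schema),
        hhs_features(trial),
    ])
    return FeatureVector(values=values, schema=schema, label=trial.label)


def extract_subject(trials, schema: FeatureSchema | None = None,
                    target_fs: float = 128.0) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess and extract all trials of one subject.

    Returns (X, Y): an instances-by-664 matrix and an instances-by-2
    label matrix (arousal, valence).
    """
    if schema is None:
        schema = FeatureSchema.default()
    rows, labels = [], []
    for trial in trials:
        fv = extract(preprocess(trial, target_fs), schema)
        rows.append(fv.values)
        labels.append(fv.label)
    return np.asarray(rows), np.asarray(labels, dtype=int)


def standardize_subject(matrix: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column z-scores of a subject's instance matrix.

    Returns (Z, mean, sd).  Columns with zero spread map to all zeros
    (their sd is reported as 0).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 instances to standardize")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    return apply_standardization(X, mean, sd), mean, sd


def apply_standardization(X: np.ndarray, mean: np.ndarray, sd: np.ndarray
                          ) -> np.ndarray:
    """Apply stored (mean, sd); zero-sd columns map to 0."""
    X = np.asarray(X, dtype=float)
    safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / safe
    Z[:, sd == 0] = 0.0
    return Z
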
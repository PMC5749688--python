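"""Static spectro-temporal feature extraction from instance epochs.

Per channel the extractor emits filter-bank log-amplitudes and RMS for the
full post-stimulus segment and for every sliding window, plus six
full-segment descriptors (spectral centroid, positions of extrema, spectral
entropy, standard deviation, filter-bank slope), giving
``(1 + n_windows) * (n_banks + 1) + 6`` features per channel: 96 for the
EEG layout and 94 for the EMG layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

EPS = 1e-10


@dataclass(frozen=True)
class FeatureParams:
    modality: str = "EEG"
    full_segment_ms: float = 1500.0
    window_ms: float = 200.0
    overlap_fraction: float = 0.5
    window_limit_ms: Optional[float] = 1000.0
    n_banks: int = 8
    f_lo: float = 1.0
    f_hi: float = 40.0
    fade_fraction: float = 0.10
    fade_per_end: bool = True  # False: the fade fraction is split across both ends
    allow_truncated_last_window: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.n_banks < 2:
            raise ValueError("n_banks must be >= 2")

    @classmethod
    def eeg_default(cls) -> "FeatureParams":
        """200-ms windows at 50% overlap over the first 1000 ms; 8 banks, 1-40 Hz."""
        return cls()

    @classmethod
    def emg_default(cls) -> "FeatureParams":
        """400-ms windows at 50% overlap over the full segment (truncated last
        window allowed); 10 banks, 20-60 Hz."""
        return cls(
            modality="EMG",
            window_ms=400.0,
            window_limit_ms=None,
            n_banks=10,
            f_lo=20.0,
            f_hi=60.0,
            allow_truncated_last_window=True,
        )


@dataclass
class FeatureTable:
    """Instances x features matrix with labeled columns and grouping ids."""

    X: np.ndarray
    columns: list[str]
    labels: np.ndarray
    participants: np.ndarray
    check: str = ""
    n_averaged: object = 1

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.participants = np.asarray(self.participants)
        if self.X.shape != (len(self.labels), len(self.columns)):
            raise ValueError("X shape inconsistent with labels/columns")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "participant", self.participants)
        df.insert(1, "label", self.labels)
        return df

    def to_tsv(self, path) -> None:
        """TSV with a header naming each (channel/window/descriptor) column."""
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def make_windows(
    n_samples: int,
    fs: float,
    window_ms: float,
    overlap_fraction: float,
    limit_ms: Optional[float] = None,
    allow_truncated: bool = False,
) -> list[tuple[int, int]]:
    """Half-open sample ranges of a sliding window starting at sample 0.

    The step is ``window * (1 - overlap)``; windows stop at ``limit_ms`` (or
    the signal end).  A final truncated window is emitted only when
    `allow_truncated` and at least one step of signal remains.
    """
    duration_ms = n_samples * 1000.0 / fs
    if window_ms > duration_ms:
        raise ValueError(
            f"window of {window_ms} ms exceeds the {duration_ms:.1f} ms signal"
        )
    step_ms = window_ms * (1.0 - overlap_fraction)
    if limit_ms is None:
        limit_ms = duration_ms
    elif limit_ms > duration_ms:
        achievable = make_windows(
            n_samples, fs, window_ms, overlap_fraction, None, allow_truncated
        )
        raise ValueError(
            f"window limit {limit_ms} ms exceeds the {duration_ms:.1f} ms signal; "
            f"only {len(achievable)} windows are achievable"
        )

    def to_sample(ms: float) -> int:
        return int(round(ms * fs / 1000.0))

    windows: list[tuple[int, int]] = []
    start = 0.0
    while start + window_ms <= limit_ms + 1e-9:
        windows.append((to_sample(start), to_sample(start + window_ms)))
        start += step_ms
    if allow_truncated and limit_ms - start >= step_ms - 1e-9:
        windows.append((to_sample(start), to_sample(limit_ms)))
    return windows


def apply_taper(segment: np.ndarray, fade_fraction: float) -> np.ndarray:
    """Rectangular window with a raised-cosine (Hanning) fade at both ends.

    The first and last ``fade_fraction * len`` samples are ramped (the very
    first and last samples go to zero); the middle is untouched.
    """
    if not 0 <= fade_fraction <= 0.5:
        raise ValueError("fade_fraction must be in [0, 0.5]")
    x = np.asarray(segment, dtype=float)
    return x * _cached_taper(x.shape[-1], float(fade_fraction))


def _bank_centers(n_banks: int, f_lo: float, f_hi: float) -> np.ndarray:
    return np.geomspace(f_lo, f_hi, n_banks)


@lru_cache(maxsize=128)
def _cached_weights(n_samples: int, fs: float, n_banks: int, f_lo: float, f_hi: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    return _bank_weights(freqs, n_banks, f_lo, f_hi)


@lru_cache(maxsize=128)
def _cached_taper(n_samples: int, fade_fraction: float) -> np.ndarray:
    n_fade = int(round(fade_fraction * n_samples))
    w = np.ones(n_samples)
    if n_fade:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_fade) / n_fade))
        w[:n_fade] = ramp
        w[n_samples - n_fade:] = ramp[::-1]
    return w


def _bank_weights(freqs: np.ndarray, n_banks: int, f_lo: float, f_hi: float) -> np.ndarray:
    """Triangular filters on the magnitude spectrum; centers log-spaced on
    [f_lo, f_hi], edges at neighbouring centers, end filters extended to the
    band edges.  Returns n_banks x n_bins weights."""
    centers = _bank_centers(n_banks, f_lo, f_hi)
    lowers = np.concatenate(([f_lo], centers[:-1]))
    uppers = np.concatenate((centers[1:], [f_hi]))
    w = np.zeros((n_banks, freqs.size))
    for i, (lo, c, hi) in enumerate(zip(lowers, centers, uppers)):
        rising = (freqs >= lo) & (freqs <= c)
        falling = (freqs > c) & (freqs <= hi)
        w[i, rising] = 1.0 if c == lo else (freqs[rising] - lo) / (c - lo)
        if hi > c:
            w[i, falling] = (hi - freqs[falling]) / (hi - c)
    return w


def filterbank_log_amps(
    segment: np.ndarray, fs: float, n_banks: int, f_lo: float, f_hi: float
) -> np.ndarray:
    """Natural-log amplitudes of triangular filter banks with log-spaced
    center frequencies; `segment` is expected to be tapered already."""
    x = np.asarray(segment, dtype=float)
    if f_hi > fs / 2:
        raise ValueError(f"f_hi={f_hi} Hz above Nyquist ({fs / 2} Hz)")
    freqs = np.fft.rfftfreq(x.shape[-1], d=1.0 / fs)
    # Short windows may resolve fewer bins than banks inside the band; then
    # the narrow low-frequency triangles simply sit at the log-eps floor.
    n_bins = x.shape[-1] // 2
    if n_bins < n_banks:
        raise ValueError(
            f"{n_banks} banks exceed the {n_bins} resolvable spectral bins of "
            f"a {x.shape[-1]}-sample segment"
        )
    mag = np.abs(np.fft.rfft(x))
    weights = _cached_weights(x.shape[-1], float(fs), n_banks, float(f_lo), float(f_hi))
    return np.log(mag @ weights.T + EPS)


def rms(segment: np.ndarray) -> float:
    x = np.asarray(segment, dtype=float)
    return float(np.sqrt(np.mean(x * x)))


def _spectral_input(segment: np.ndarray, fade_fraction: float) -> np.ndarray:
    """De-mean then taper: spectra describe fluctuations, so a constant
    segment yields an exactly empty spectrum (all banks at the log-eps floor)."""
    x = np.asarray(segment, dtype=float)
    mu = x.mean(axis=-1, keepdims=True)
    y = x - mu
    # flush pure cancellation residue so constant segments are exactly silent
    tiny = np.abs(y).max(axis=-1, keepdims=True) <= 1e-12 * np.abs(mu)
    y = np.where(tiny, 0.0, y)
    return apply_taper(y, fade_fraction)


def _descriptors_multi(X: np.ndarray, fs: float, params: FeatureParams) -> np.ndarray:
    """Window descriptors for all channels at once: (n_ch, n_banks + 1)."""
    tapered = _spectral_input(X, params.fade_fraction)
    banks = filterbank_log_amps(tapered, fs, params.n_banks, params.f_lo, params.f_hi)
    r = np.sqrt((X * X).mean(axis=-1))
    return np.concatenate([banks, r[:, None]], axis=1)


def _extras_multi(X: np.ndarray, fs: float, params: FeatureParams) -> np.ndarray:
    """Full-segment extras for all channels at once: (n_ch, 6)."""
    n = X.shape[-1]
    tapered = _spectral_input(X, params.fade_fraction)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mag = np.abs(np.fft.rfft(tapered, axis=-1))
    band = (freqs >= params.f_lo) & (freqs <= params.f_hi)
    f_b, m_b = freqs[band], mag[:, band]
    total = m_b.sum(axis=1)
    nonzero = total > EPS
    safe_total = np.where(nonzero, total, 1.0)
    centroid = np.where(nonzero, (m_b * f_b).sum(axis=1) / safe_total, 0.0)
    p = m_b / safe_total[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = np.where(nonzero, -plogp.sum(axis=1), 0.0)
    denom = max(n - 1, 1)
    pos_min = np.argmin(X, axis=-1) / denom
    pos_max = np.argmax(X, axis=-1) / denom
    std = X.std(axis=-1)
    banks = filterbank_log_amps(tapered, fs, params.n_banks, params.f_lo, params.f_hi)
    lc = np.log(_bank_centers(params.n_banks, params.f_lo, params.f_hi))
    lc_c = lc - lc.mean()
    slope = (banks @ lc_c) / (lc_c @ lc_c)
    flat = np.ptp(banks, axis=1) < 1e-12
    slope = np.where(flat, 0.0, slope)
    return np.column_stack([centroid, pos_min, pos_max, entropy, std, slope])


def window_descriptors(segment: np.ndarray, fs: float, params: FeatureParams) -> np.ndarray:
    """[filter-bank log-amps of the de-meaned, tapered segment, RMS of the
    raw segment]."""
    return _descriptors_multi(np.atleast_2d(np.asarray(segment, dtype=float)), fs, params)[0]


def segment_extras(segment: np.ndarray, fs: float, params: FeatureParams) -> np.ndarray:
    """Six full-segment descriptors.

    Spectral centroid and entropy are computed from the magnitude spectrum
    of the de-meaned, tapered segment restricted to [f_lo, f_hi] (both 0 for
    an empty spectrum, by convention); extrema positions are time-domain
    sample indices normalized to [0, 1]; std is the time-domain standard
    deviation; the slope is the least-squares slope of bank log-amplitude
    against log bank center frequency.
    """
    return _extras_multi(np.atleast_2d(np.asarray(segment, dtype=float)), fs, params)[0]


EXTRA_NAMES = ("centroid", "pos_min", "pos_max", "entropy", "std", "slope")


def feature_names_per_channel(params: FeatureParams, n_windows: int) -> list[str]:
    names: list[str] = []
    for seg in ["full"] + [f"w{i}" for i in range(n_windows)]:
        names.extend(f"{seg}/bank{b}" for b in range(params.n_banks))
        names.append(f"{seg}/rms")
    names.extend(f"full/{e}" for e in EXTRA_NAMES)
    return names


def extract_features(
    epoch: np.ndarray,
    params: FeatureParams,
    fs: float = 256.0,
    time_axis: Optional[np.ndarray] = None,
    channel_labels: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, list[str]]:
    """Extract the per-channel static feature vector from one epoch.

    Only the post-stimulus part of the epoch (time >= 0 when `time_axis` is
    given, otherwise the whole epoch) is described.  Per channel the vector
    is: full-segment descriptors, each sliding-window's descriptors, then
    the six extras; channels are concatenated in input order.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if time_axis is not None:
        post = np.asarray(time_axis) >= 0
        epoch = epoch[:, post]
    n_ch, n_s = epoch.shape
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(n_ch)]
    elif len(channel_labels) != n_ch:
        raise ValueError("channel_labels length does not match epoch channels")

    windows = make_windows(
        n_s,
        fs,
        params.window_ms,
        params.overlap_fraction,
        params.window_limit_ms,
        params.allow_truncated_last_window,
    )
    per_channel_names = feature_names_per_channel(params, len(windows))
    parts = [_descriptors_multi(epoch, fs, params)]
    parts.extend(_descriptors_multi(epoch[:, a:b], fs, params) for a, b in windows)
    parts.append(_extras_multi(epoch, fs, params))
    per_channel = np.concatenate(parts, axis=1)
    names = [f"{ch}/{n}" for ch in channel_labels for n in per_channel_names]
    return per_channel.ravel(), names


def features_per_channel(params: FeatureParams, n_windows: int) -> int:
    """(1 + n_windows) * (n_banks + 1) + 6."""
    return (1 + n_windows) * (params.n_banks + 1) + 6


def build_feature_table(instances, params: FeatureParams, fs: Optional[float] = None) -> FeatureTable:
    """Extract features for every instance of an InstanceSet."""
    if fs is None:
        fs = instances.sampling_rate
    rows: list[np.ndarray] = []
    columns: list[str] = []
    for inst in instances.instances:
        vec, names = extract_features(
            inst.signal,
            params,
            fs=fs,
            time_axis=instances.time_axis,
            channel_labels=instances.channel_labels,
        )
        if not columns:
            columns = names
        rows.append(vec)
    return FeatureTable(
        X=np.vstack(rows),
        columns=columns,
        labels=np.array(instances.labels),
        participants=np.array(instances.participants),
        check=instances.check,
        n_averaged=instances.n_averaged,
    )
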
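"""Signal conditioning, baseline correction, and trial-rejection rules.

All filters are zero-phase 4th-order Butterworth (corner frequencies are the
only values fixed by the protocol; zero-phase filtering preserves component
latencies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from appraisal_decode.synthgen import EpochSet

TARGET_FS = 256.0


@dataclass(frozen=True)
class RejectionRules:
    """Per-channel epoch artifact thresholds.

    The default set rejects on absolute amplitude (> 75 uV), within-epoch
    range (> 100 uV), flat stretches (> 100 ms below 0.50 uV), and
    sample-to-sample steps (> 50 uV).  The alternative variant enables only
    the absolute-amplitude rule at +/-110 uV.
    """

    max_abs_uV: float = 75.0
    max_range_uV: float = 100.0
    flat_window_ms: float = 100.0
    flat_threshold_uV: float = 0.50
    max_step_uV: float = 50.0
    enabled: tuple[str, ...] = ("max_abs", "max_range", "flat", "max_step")

    def __post_init__(self) -> None:
        for name in ("max_abs_uV", "max_range_uV", "flat_window_ms",
                     "flat_threshold_uV", "max_step_uV"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        unknown = set(self.enabled) - {"max_abs", "max_range", "flat", "max_step"}
        if unknown:
            raise ValueError(f"unknown rules enabled: {sorted(unknown)}")

    @classmethod
    def study1(cls) -> "RejectionRules":
        return cls()

    @classmethod
    def study2(cls) -> "RejectionRules":
        return cls(max_abs_uV=110.0, enabled=("max_abs",))


@dataclass(frozen=True)
class EmgOutlierPolicy:
    """Range-based EMG outlier policy.

    Per muscle, the threshold is ``range_multiplier`` times the P75 of
    per-trial ranges pooled over all participants and conditions; a trial
    exceeding any muscle's threshold in either the baseline or post-stimulus
    segment is removed, and a participant losing more than
    ``participant_drop_fraction`` of their trials loses all of them.
    """

    range_multiplier: float = 2.0
    percentile: float = 75.0
    participant_drop_fraction: float = 0.50
    segments: tuple[str, ...] = ("baseline", "post")

    def __post_init__(self) -> None:
        if self.range_multiplier <= 0:
            raise ValueError("range_multiplier must be > 0")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if not 0 < self.participant_drop_fraction <= 1:
            raise ValueError("participant_drop_fraction must be in (0, 1]")


def emg_condition(raw: np.ndarray, fs_in: float) -> np.ndarray:
    """Condition a raw single-channel EMG signal to 256 Hz.

    Band-pass 20-400 Hz, full-wave rectify, smooth with a 40 Hz low-pass,
    and downsample to 256 Hz.  `fs_in` must be at least 800 Hz so the 400 Hz
    band edge stays below Nyquist.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("emg_condition expects a single-channel 1-D signal")
    if fs_in < 800.0:
        raise ValueError(
            f"fs_in={fs_in} Hz violates Nyquist for the 400 Hz band edge (need >= 800 Hz)"
        )
    sos_bp = sps.butter(4, [20.0, 400.0], btype="bandpass", fs=fs_in, output="sos")
    x = sps.sosfiltfilt(sos_bp, raw)
    x = np.abs(x)
    sos_lp = sps.butter(4, 40.0, btype="lowpass", fs=fs_in, output="sos")
    x = sps.sosfiltfilt(sos_lp, x)
    up, down = int(TARGET_FS), int(round(fs_in))
    y = sps.resample_poly(x, up, down)
    n_out = int(round(len(raw) * TARGET_FS / fs_in))
    return y[:n_out]


def baseline_correct(
    epoch: np.ndarray, baseline_window: tuple[float, float], time_axis: np.ndarray
) -> np.ndarray:
    """Subtract each channel's mean over the (half-open) baseline window."""
    epoch = np.asarray(epoch, dtype=float)
    t = np.asarray(time_axis, dtype=float)
    lo, hi = baseline_window
    mask = (t >= lo) & (t < hi)
    if not mask.any():
        raise ValueError(
            f"baseline window [{lo}, {hi}) ms contains no samples of the time axis"
        )
    return epoch - epoch[:, mask].mean(axis=1, keepdims=True)


def _flat_run_samples(channel: np.ndarray, threshold: float) -> int:
    """Longest run of consecutive samples with |x| < threshold."""
    below = np.abs(channel) < threshold
    if not below.any():
        return 0
    edges = np.diff(np.concatenate(([0], below.astype(int), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int((ends - starts).max())


def reject_eeg_epoch(
    epoch: np.ndarray, rules: RejectionRules, fs: float
) -> tuple[bool, list[str]]:
    """Return ``(keep, violated_rules)`` for one channels x samples epoch.

    Rules are evaluated per channel; a violation on any channel rejects the
    epoch.  Every violated rule is reported.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if not np.isfinite(epoch).all():
        raise ValueError("epoch contains non-finite values")
    violated: list[str] = []
    if "max_abs" in rules.enabled and np.abs(epoch).max() > rules.max_abs_uV:
        violated.append("max_abs")
    if "max_range" in rules.enabled:
        if (epoch.max(axis=1) - epoch.min(axis=1)).max() > rules.max_range_uV:
            violated.append("max_range")
    if "flat" in rules.enabled:
        # "period > flat_window_ms": a run of k samples spans k/fs seconds
        limit = rules.flat_window_ms * fs / 1000.0
        if any(
            _flat_run_samples(ch, rules.flat_threshold_uV) > limit for ch in epoch
        ):
            violated.append("flat")
    if "max_step" in rules.enabled and epoch.shape[1] > 1:
        if np.abs(np.diff(epoch, axis=1)).max() > rules.max_step_uV:
            violated.append("max_step")
    return (not violated, violated)


@dataclass
class EmgOutlierReport:
    thresholds: dict[str, float]
    removed: list[tuple[str, int, str, str]]  # (participant, trial, muscle, segment)
    dropped_participants: list[str]
    percentile_definition: str = "linear interpolation"


def reject_emg_outliers(
    epochs: EpochSet, policy: EmgOutlierPolicy
) -> tuple[EpochSet, EmgOutlierReport]:
    """Remove range-outlier EMG trials and over-contaminated participants.

    Thresholds are ``multiplier x P75`` of per-trial ranges pooled over all
    participants, conditions and checked segments, computed per muscle.
    """
    if epochs.design.modality != "EMG":
        raise ValueError("reject_emg_outliers applies to EMG epoch sets")
    t = epochs.time_axis
    seg_masks = {}
    if "baseline" in policy.segments:
        seg_masks["baseline"] = t < 0
    if "post" in policy.segments:
        seg_masks["post"] = t >= 0
    seg_masks = {k: m for k, m in seg_masks.items() if m.any()}
    if not seg_masks:
        raise ValueError("no checked segment is covered by the time axis")

    muscles = epochs.channel_labels
    ranges: dict[str, list[float]] = {m: [] for m in muscles}
    per_trial: list[tuple[str, int, dict[tuple[str, str], float]]] = []
    for pid, idx, _, ep in epochs.iter_trials():
        vals: dict[tuple[str, str], float] = {}
        for ci, muscle in enumerate(muscles):
            for seg, mask in seg_masks.items():
                r = float(ep[ci, mask].max() - ep[ci, mask].min())
                vals[(muscle, seg)] = r
                ranges[muscle].append(r)
        per_trial.append((pid, idx, vals))

    n_pooled = len(per_trial) * len(seg_masks)
    if n_pooled < 4:
        raise ValueError(
            f"only {n_pooled} pooled ranges; need >= 4 for a defined percentile"
        )
    thresholds = {
        m: policy.range_multiplier * float(np.percentile(rs, policy.percentile))
        for m, rs in ranges.items()
    }

    removed: list[tuple[str, int, str, str]] = []
    removed_keys: set[tuple[str, int]] = set()
    for pid, idx, vals in per_trial:
        for (muscle, seg), r in vals.items():
            if r > thresholds[muscle]:
                removed.append((pid, idx, muscle, seg))
                removed_keys.add((pid, idx))

    dropped: list[str] = []
    for pid, trials in epochs.data.items():
        n = len(trials)
        n_removed = sum(1 for (p, _) in removed_keys if p == pid)
        if n and n_removed / n > policy.participant_drop_fraction:
            dropped.append(pid)
    keep = {
        (pid, i)
        for pid, trials in epochs.data.items()
        if pid not in dropped
        for i in range(len(trials))
        if (pid, i) not in removed_keys
    }
    report = EmgOutlierReport(thresholds=thresholds, removed=removed, dropped_participants=dropped)
    return epochs.filtered(keep), report


def reject_eeg_epochs(
    epochs: EpochSet, rules: RejectionRules
) -> tuple[EpochSet, list[tuple[str, int, list[str]]]]:
    """Apply `reject_eeg_epoch` across an EpochSet; returns the filtered set
    and a (participant, trial, violated-rules) report of rejections."""
    keep: set[tuple[str, int]] = set()
    report: list[tuple[str, int, list[str]]] = []
    for pid, idx, _, ep in epochs.iter_trials():
        ok, violated = reject_eeg_epoch(ep, rules, epochs.sampling_rate)
        if ok:
            keep.add((pid, idx))
        else:
            report.append((pid, idx, violated))
    return epochs.filtered(keep), report
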
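"""Synthetic generation of factorial EEG/EMG epoch sets.

Epochs are built as a sum of class-dependent Gaussian-in-time components
(scaled per channel by a fixed topography), a 1/f^beta background, and white
noise, with per-participant gain and per-trial latency jitter.  All
randomness flows from a single integer seed, so identical inputs yield
bit-identical epoch sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import signal as sps

from appraisal_decode.montage import EEG_64

Cell = tuple[str, ...]

MODALITIES = ("EEG", "EMG")


@dataclass(frozen=True)
class DesignSpec:
    """Generative description of a factorial psychophysiology experiment.

    Parameters
    ----------
    study_label : str
        Free-text identifier.
    modality : {"EEG", "EMG"}
    participants : int
        Number of participants; at least 3 (one per cross-validation fold).
    checks : sequence of (name, levels)
        Ordered factors; every condition cell is one level per check.
    trials_per_cell : mapping cell -> int
        Per-participant trial count for every full factorial cell.
    sampling_rate : float, default 256
    epoch_window : (start_ms, end_ms)
        Relative to stimulus onset at 0 ms; half-open sample windows.
    channel_labels : sequence of str
    """

    study_label: str
    modality: str
    participants: int
    checks: tuple[tuple[str, tuple[str, ...]], ...]
    trials_per_cell: Mapping[Cell, int]
    sampling_rate: float = 256.0
    epoch_window: tuple[float, float] = (-200.0, 1000.0)
    channel_labels: tuple[str, ...] = EEG_64

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.participants < 3:
            raise ValueError("need at least 3 participants (one per fold)")
        object.__setattr__(
            self,
            "checks",
            tuple((name, tuple(levels)) for name, levels in self.checks),
        )
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        cells = self.cells
        tpc = {tuple(k): int(v) for k, v in self.trials_per_cell.items()}
        if set(tpc) != set(cells):
            raise ValueError("trials_per_cell must cover exactly the full factorial cells")
        if any(v < 0 for v in tpc.values()):
            raise ValueError("trials_per_cell values must be >= 0")
        object.__setattr__(self, "trials_per_cell", tpc)
        start, end = self.epoch_window
        if not start < end:
            raise ValueError("epoch_window start must precede end")

    @property
    def check_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.checks)

    def levels(self, check: str) -> tuple[str, ...]:
        for name, levels in self.checks:
            if name == check:
                return levels
        raise KeyError(f"unknown check {check!r}; available: {list(self.check_names)}")

    @property
    def cells(self) -> tuple[Cell, ...]:
        return tuple(itertools.product(*(levels for _, levels in self.checks)))

    def cell_level(self, cell: Cell, check: str) -> str:
        try:
            idx = self.check_names.index(check)
        except ValueError:
            raise KeyError(
                f"unknown check {check!r}; available: {list(self.check_names)}"
            ) from None
        return cell[idx]

    def _sample_span(self) -> tuple[int, int]:
        # grid anchored at stimulus onset: sample i sits at i/fs; the
        # half-open window [start, end) then holds exactly round(end*fs/1000)
        # post-stimulus samples
        start, end = self.epoch_window
        i0 = int(np.ceil(start * self.sampling_rate / 1000.0 - 1e-9))
        i1 = int(round(end * self.sampling_rate / 1000.0))
        return i0, i1

    @property
    def n_samples(self) -> int:
        i0, i1 = self._sample_span()
        return i1 - i0

    @property
    def time_axis(self) -> np.ndarray:
        i0, i1 = self._sample_span()
        return np.arange(i0, i1) * 1000.0 / self.sampling_rate

    @property
    def participant_ids(self) -> tuple[str, ...]:
        return tuple(f"p{i + 1:02d}" for i in range(self.participants))

    @property
    def trials_per_participant(self) -> int:
        return sum(self.trials_per_cell.values())


@dataclass(frozen=True)
class EffectSpec:
    """A class-dependent component: topography x Gaussian-in-time bump.

    ``amplitude`` and ``peak_latency_ms`` are keyed by the levels of
    ``check``; channels missing from ``channel_topography`` get weight 0.
    An effect whose amplitudes are all zero contributes nothing.
    """

    check: str
    channel_topography: Mapping[str, float]
    peak_latency_ms: Mapping[str, float]
    temporal_sd_ms: float
    amplitude: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.temporal_sd_ms <= 0:
            raise ValueError("temporal_sd_ms must be > 0")
        if set(self.amplitude) != set(self.peak_latency_ms):
            raise ValueError("amplitude and peak_latency_ms must list the same levels")


@dataclass(frozen=True)
class NoiseSpec:
    """Background and variability parameters; every scale must be >= 0."""

    background_exponent: float = 1.0
    background_scale: float = 1.0
    white_sd: float = 0.3
    participant_gain_sd: float = 0.1
    latency_jitter_sd_ms: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "background_exponent",
            "background_scale",
            "white_sd",
            "participant_gain_sd",
            "latency_jitter_sd_ms",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class EpochSet:
    """Participant-indexed collection of fixed-length multi-channel epochs."""

    design: DesignSpec
    data: dict[str, list[np.ndarray]]
    condition: dict[str, list[Cell]]
    time_axis: np.ndarray = field(default=None)  # type: ignore[assignment]
    sampling_rate: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.time_axis is None:
            self.time_axis = self.design.time_axis
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.sampling_rate is None:
            self.sampling_rate = self.design.sampling_rate
        for pid, trials in self.data.items():
            if len(trials) != len(self.condition[pid]):
                raise ValueError(f"participant {pid}: data/condition length mismatch")
            for ep in trials:
                if ep.shape != (len(self.design.channel_labels), len(self.time_axis)):
                    raise ValueError(
                        f"participant {pid}: epoch shape {ep.shape} inconsistent with "
                        f"{len(self.design.channel_labels)} channels x {len(self.time_axis)} samples"
                    )

    @property
    def participants(self) -> list[str]:
        return list(self.data)

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return self.design.channel_labels

    @property
    def n_trials(self) -> int:
        return sum(len(v) for v in self.data.values())

    def iter_trials(self) -> Iterator[tuple[str, int, Cell, np.ndarray]]:
        for pid, trials in self.data.items():
            for idx, ep in enumerate(trials):
                yield pid, idx, self.condition[pid][idx], ep

    def filtered(self, keep: set[tuple[str, int]]) -> "EpochSet":
        """Return a copy retaining only the (participant, trial-index) pairs in `keep`."""
        data: dict[str, list[np.ndarray]] = {}
        cond: dict[str, list[Cell]] = {}
        for pid, trials in self.data.items():
            data[pid] = [ep for i, ep in enumerate(trials) if (pid, i) in keep]
            cond[pid] = [c for i, c in enumerate(self.condition[pid]) if (pid, i) in keep]
        return EpochSet(self.design, data, cond, self.time_axis, self.sampling_rate)


def effect_waveform(
    effect: EffectSpec,
    level: str,
    time_axis: np.ndarray,
    channel_labels: Sequence[str],
    latency_shift_ms: float = 0.0,
) -> np.ndarray:
    """Evaluate one effect level as a channels x samples matrix.

    The waveform is ``amplitude(level) * topography (x) Gaussian(peak, sd)``
    on the given time axis; doubling the amplitude doubles every entry.
    """
    if level not in effect.amplitude:
        raise KeyError(
            f"unknown level {level!r} for check {effect.check!r}; "
            f"levels: {sorted(effect.amplitude)}"
        )
    t = np.asarray(time_axis, dtype=float)
    topo = np.array([effect.channel_topography.get(ch, 0.0) for ch in channel_labels])
    peak = effect.peak_latency_ms[level] + latency_shift_ms
    bump = np.exp(-0.5 * ((t - peak) / effect.temporal_sd_ms) ** 2)
    return effect.amplitude[level] * np.outer(topo, bump)


def powerlaw_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    exponent: float,
    rms: float,
) -> np.ndarray:
    """1/f^beta background: white spectra shaped by f^(-beta/2), unit-RMS per channel."""
    if rms == 0.0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = shape * (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    )
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return rms * x / sd


def _effects_for_design(design: DesignSpec, effects: Sequence[EffectSpec]) -> None:
    for eff in effects:
        if eff.check not in design.check_names:
            raise ValueError(
                f"effect references check {eff.check!r} not in design "
                f"{list(design.check_names)}"
            )
        if set(eff.amplitude) != set(design.levels(eff.check)):
            raise ValueError(
                f"effect for {eff.check!r} lists levels {sorted(eff.amplitude)}, "
                f"design has {sorted(design.levels(eff.check))}"
            )
        unknown = set(eff.channel_topography) - set(design.channel_labels)
        if unknown:
            raise ValueError(f"effect topography names unknown channels: {sorted(unknown)}")


def generate_epochs(
    design: DesignSpec,
    effects: Sequence[EffectSpec],
    noise: NoiseSpec,
    seed: int,
) -> EpochSet:
    """Generate a full EpochSet for `design`; deterministic given `seed`.

    Each trial is the sum over effects of the cell-level component (with a
    per-trial latency jitter shared across channels and a per-participant
    multiplicative gain), a 1/f background, and white noise.  EMG epochs are
    emitted in rectified style: the noise floor is folded to be non-negative
    before the (non-negative) burst components are added.
    """
    _effects_for_design(design, effects)
    rng = np.random.default_rng(seed)
    t = design.time_axis
    n_ch = len(design.channel_labels)
    n_s = design.n_samples
    emg = design.modality == "EMG"

    data: dict[str, list[np.ndarray]] = {}
    condition: dict[str, list[Cell]] = {}
    for pid in design.participant_ids:
        gain = max(1.0 + noise.participant_gain_sd * rng.standard_normal(), 0.05)
        trials: list[np.ndarray] = []
        cells: list[Cell] = []
        for cell in design.cells:
            for _ in range(design.trials_per_cell[cell]):
                jitter = noise.latency_jitter_sd_ms * rng.standard_normal()
                component = np.zeros((n_ch, n_s))
                for eff in effects:
                    level = design.cell_level(cell, eff.check)
                    component += effect_waveform(
                        eff, level, t, design.channel_labels, latency_shift_ms=jitter
                    )
                bg = powerlaw_noise(rng, n_ch, n_s, noise.background_exponent, noise.background_scale)
                white = noise.white_sd * rng.standard_normal((n_ch, n_s))
                floor = np.abs(bg + white) if emg else bg + white
                trials.append(gain * component + floor)
                cells.append(cell)
        data[pid] = trials
        condition[pid] = cells
    return EpochSet(design, data, condition, t, design.sampling_rate)


def generate_raw_emg(
    design: DesignSpec,
    effects: Sequence[EffectSpec],
    noise: NoiseSpec,
    seed: int,
    fs_raw: float = 1024.0,
) -> EpochSet:
    """Raw-mode EMG: oscillatory 20-400 Hz carrier amplitude-modulated by the
    burst envelope, sampled at `fs_raw`, for exercising the conditioning chain.
    """
    if design.modality != "EMG":
        raise ValueError("raw mode is defined for EMG designs only")
    _effects_for_design(design, effects)
    rng = np.random.default_rng(seed)
    start, end = design.epoch_window
    i0 = int(np.ceil(start * fs_raw / 1000.0 - 1e-9))
    i1 = int(round(end * fs_raw / 1000.0))
    n_s = i1 - i0
    t = np.arange(i0, i1) * 1000.0 / fs_raw
    n_ch = len(design.channel_labels)
    sos = sps.butter(4, [20.0, 400.0], btype="bandpass", fs=fs_raw, output="sos")

    data: dict[str, list[np.ndarray]] = {}
    condition: dict[str, list[Cell]] = {}
    for pid in design.participant_ids:
        gain = max(1.0 + noise.participant_gain_sd * rng.standard_normal(), 0.05)
        trials: list[np.ndarray] = []
        cells: list[Cell] = []
        for cell in design.cells:
            for _ in range(design.trials_per_cell[cell]):
                jitter = noise.latency_jitter_sd_ms * rng.standard_normal()
                envelope = np.full((n_ch, n_s), noise.background_scale)
                for eff in effects:
                    level = design.cell_level(cell, eff.check)
                    envelope += gain * np.abs(
                        effect_waveform(eff, level, t, design.channel_labels, jitter)
                    )
                carrier = sps.sosfiltfilt(sos, rng.standard_normal((n_ch, n_s)), axis=1)
                sd = carrier.std(axis=1, keepdims=True)
                sd[sd == 0] = 1.0
                trials.append(envelope * carrier / sd)
                cells.append(cell)
        data[pid] = trials
        condition[pid] = cells
    return EpochSet(design, data, condition, t, fs_raw)
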
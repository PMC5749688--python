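"""Packaged factorial designs mirroring the two reference studies.

The designs reproduce the cell structures and class imbalances of the
oddball study (2 novelty x 3 pleasantness, 25 participants, novelty classes
~1:3.5) and the gambling study (2x2x2 goal conduciveness x control x power,
24 participants, control classes ~1:3) at reduced per-cell trial counts.
Component amplitudes are free parameters: synthetic accuracies are not
comparable to values measured on the original recordings.
"""

from __future__ import annotations

from appraisal_decode.montage import EEG_64, EMG_REGIONS
from appraisal_decode.synthgen import DesignSpec, EffectSpec, NoiseSpec


def study1_design(
    modality: str = "EEG",
    participants: int = 25,
    novel_trials: int = 4,
    channel_labels=None,
) -> DesignSpec:
    """Oddball-style design: novelty {novel, familiar} x pleasantness
    {unpleasant, neutral, pleasant}; familiar cells carry 3.5x the trials of
    novel cells."""
    checks = (
        ("novelty", ("novel", "familiar")),
        ("pleasantness", ("unpleasant", "neutral", "pleasant")),
    )
    familiar_trials = int(round(3.5 * novel_trials))
    tpc = {}
    for nov in ("novel", "familiar"):
        for pls in ("unpleasant", "neutral", "pleasant"):
            tpc[(nov, pls)] = novel_trials if nov == "novel" else familiar_trials
    if modality == "EEG":
        window, labels = (-200.0, 1000.0), EEG_64
    else:
        window, labels = (-100.0, 1500.0), EMG_REGIONS
    return DesignSpec(
        study_label="study1",
        modality=modality,
        participants=participants,
        checks=checks,
        trials_per_cell=tpc,
        epoch_window=window,
        channel_labels=tuple(channel_labels) if channel_labels is not None else labels,
    )


def study2_design(
    modality: str = "EEG",
    participants: int = 24,
    low_control_trials: int = 3,
    channel_labels=None,
) -> DesignSpec:
    """Gambling-style design: goal conduciveness x control x power, all
    binary; high-control cells carry 3x the trials of low-control cells."""
    checks = (
        ("goal_conduciveness", ("high", "low")),
        ("control", ("high", "low")),
        ("power", ("high", "low")),
    )
    tpc = {}
    for gc in ("high", "low"):
        for ctrl in ("high", "low"):
            for pw in ("high", "low"):
                tpc[(gc, ctrl, pw)] = (
                    3 * low_control_trials if ctrl == "high" else low_control_trials
                )
    if modality == "EEG":
        window, labels = (-200.0, 1500.0), EEG_64
    else:
        window, labels = (-100.0, 1500.0), EMG_REGIONS
    return DesignSpec(
        study_label="study2",
        modality=modality,
        participants=participants,
        checks=checks,
        trials_per_cell=tpc,
        epoch_window=window,
        channel_labels=tuple(channel_labels) if channel_labels is not None else labels,
    )


def study1_effects(amplitude: float = 2.0) -> list[EffectSpec]:
    """Late-positivity-style midline components differing across novelty and
    pleasantness levels."""
    midline = {"Fz": 0.5, "Cz": 0.8, "Pz": 1.0, "CPz": 0.9, "POz": 0.7}
    return [
        EffectSpec(
            check="novelty",
            channel_topography=midline,
            peak_latency_ms={"novel": 350.0, "familiar": 350.0},
            temporal_sd_ms=80.0,
            amplitude={"novel": amplitude, "familiar": 0.3 * amplitude},
        ),
        EffectSpec(
            check="pleasantness",
            channel_topography={"Pz": 1.0, "POz": 0.8, "CPz": 0.6},
            peak_latency_ms={"unpleasant": 600.0, "neutral": 600.0, "pleasant": 600.0},
            temporal_sd_ms=120.0,
            amplitude={
                "unpleasant": 0.6 * amplitude,
                "neutral": 0.0,
                "pleasant": 0.5 * amplitude,
            },
        ),
    ]


def study2_effects(amplitude: float = 2.0) -> list[EffectSpec]:
    frontal = {"Fz": 1.0, "FCz": 1.0, "F1": 0.6, "F2": 0.6, "Cz": 0.5}
    parietal = {"Pz": 1.0, "POz": 0.9, "CPz": 0.7, "P1": 0.5, "P2": 0.5}
    return [
        EffectSpec(
            check="goal_conduciveness",
            channel_topography=frontal,
            peak_latency_ms={"high": 250.0, "low": 270.0},
            temporal_sd_ms=60.0,
            amplitude={"high": 0.2 * amplitude, "low": 0.6 * amplitude},
        ),
        EffectSpec(
            check="control",
            channel_topography=parietal,
            peak_latency_ms={"high": 400.0, "low": 400.0},
            temporal_sd_ms=90.0,
            amplitude={"high": 0.4 * amplitude, "low": 0.2 * amplitude},
        ),
        EffectSpec(
            check="power",
            channel_topography=parietal,
            peak_latency_ms={"high": 450.0, "low": 500.0},
            temporal_sd_ms=90.0,
            amplitude={"high": 0.7 * amplitude, "low": 0.2 * amplitude},
        ),
    ]


def default_noise() -> NoiseSpec:
    return NoiseSpec(
        background_exponent=1.0,
        background_scale=1.0,
        white_sd=0.3,
        participant_gain_sd=0.15,
        latency_jitter_sd_ms=20.0,
    )


def probe_design(
    participants: int = 12,
    trials_per_cell: int = 60,
    n_channels: int = 8,
    modality: str = "EEG",
) -> DesignSpec:
    """Small single-check binary design for calibration and recovery checks."""
    labels = EEG_64[:n_channels] if modality == "EEG" else EMG_REGIONS[:n_channels]
    return DesignSpec(
        study_label="probe",
        modality=modality,
        participants=participants,
        checks=(("target", ("a", "b")),),
        trials_per_cell={("a",): trials_per_cell, ("b",): trials_per_cell},
        epoch_window=(-200.0, 1000.0) if modality == "EEG" else (-100.0, 1500.0),
        channel_labels=labels,
    )


def probe_effect(design: DesignSpec, amplitude: float) -> EffectSpec:
    """One-check effect present for level 'a' only, spread over all channels
    with linearly decaying topography."""
    n = len(design.channel_labels)
    topo = {ch: 1.0 - 0.5 * i / max(n - 1, 1) for i, ch in enumerate(design.channel_labels)}
    return EffectSpec(
        check="target",
        channel_topography=topo,
        peak_latency_ms={"a": 350.0, "b": 350.0},
        temporal_sd_ms=80.0,
        amplitude={"a": amplitude, "b": 0.0},
    )
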
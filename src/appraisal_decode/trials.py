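"""Relabeling of factorial cells, trial averaging, and channel selection."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence, Union

import numpy as np

from appraisal_decode.montage import EEG_64
from appraisal_decode.synthgen import EpochSet

logger = logging.getLogger(__name__)

AVERAGING_CHOICES = (1, 2, 3, 4, 5, 10, 20, "all")

# Named channel sets: region-of-interest channels, the same plus immediate
# neighbours, and the full montage.
CHANNEL_SETS: dict[str, tuple[str, ...]] = {
    "study1-set1": ("Fz", "Cz", "Pz"),
    "study1-set2": (
        "Fz", "Cz", "Pz", "FCz", "F1", "F2", "AFz", "C1", "C2", "CPz", "P1", "P2", "POz",
    ),
    "study1-set3": EEG_64,
    "study2-set1": ("Fz", "FCz", "Pz", "POz"),
    "study2-set2": (
        "Fz", "FCz", "Pz", "POz", "F1", "F2", "AFz", "FC1", "FC2", "Cz",
        "P1", "P2", "CPz", "PO3", "PO4", "Oz",
    ),
    "study2-set3": EEG_64,
}


@dataclass
class Instance:
    participant: str
    label: str
    signal: np.ndarray  # channels x samples


@dataclass
class InstanceSet:
    """Labeled instances (single or averaged epochs) grouped by participant."""

    instances: list[Instance]
    check: str
    n_averaged: Union[int, str]
    channel_labels: tuple[str, ...]
    levels: tuple[str, ...]
    sampling_rate: float = 256.0
    time_axis: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def labels(self) -> list[str]:
        return [inst.label for inst in self.instances]

    @property
    def participants(self) -> list[str]:
        return [inst.participant for inst in self.instances]


def relabel(epochs: EpochSet, check: str) -> InstanceSet:
    """Label every trial by its cell's level on `check`; trial counts and
    signals are untouched."""
    design = epochs.design
    if check not in design.check_names:
        raise KeyError(
            f"unknown check {check!r}; available checks: {list(design.check_names)}"
        )
    instances = [
        Instance(pid, design.cell_level(cell, check), ep)
        for pid, _, cell, ep in epochs.iter_trials()
    ]
    return InstanceSet(
        instances=instances,
        check=check,
        n_averaged=1,
        channel_labels=design.channel_labels,
        levels=design.levels(check),
        sampling_rate=epochs.sampling_rate,
        time_axis=epochs.time_axis,
    )


def _grouped_means(signals: list[np.ndarray], t: Union[int, str]) -> list[np.ndarray]:
    if t == "all":
        return [np.mean(signals, axis=0)] if signals else []
    n_groups = len(signals) // t
    return [
        np.mean(signals[i * t:(i + 1) * t], axis=0) for i in range(n_groups)
    ]


def average_trials(
    instances: InstanceSet,
    t: Union[int, str],
    rng: np.random.Generator | None = None,
) -> InstanceSet:
    """Average groups of `t` same-class trials within each participant.

    For numeric `t`, consecutive groups of `t` trials (in original trial
    order, or seeded-shuffled order when `rng` is given) are averaged and any
    remainder is discarded; ``t="all"`` averages all trials of a
    participant-class group into a single instance; ``t=1`` is the identity.
    """
    if t not in AVERAGING_CHOICES:
        raise ValueError(f"t must be one of {AVERAGING_CHOICES}, got {t!r}")
    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    order: list[tuple[str, str]] = []
    for inst in instances.instances:
        key = (inst.participant, inst.label)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(inst.signal)

    out: list[Instance] = []
    for key in order:
        signals = groups[key]
        if rng is not None and t != 1:
            signals = [signals[i] for i in rng.permutation(len(signals))]
        if t != "all" and len(signals) < t:
            logger.warning(
                "participant %s class %s: %d trials < T=%d, zero instances emitted",
                key[0], key[1], len(signals), t,
            )
        out.extend(Instance(key[0], key[1], m) for m in _grouped_means(signals, t))
    return replace(instances, instances=out, n_averaged=t)


def average_all_by_cell(epochs: EpochSet) -> list[tuple[str, tuple[str, ...], np.ndarray]]:
    """Average all trials within each participant x condition-cell group.

    This is the grouping that reproduces the published all-trials instance
    counts (participants x cells); check-specific classification uses
    :func:`average_trials` on relabeled instances instead.
    """
    out: list[tuple[str, tuple[str, ...], np.ndarray]] = []
    for pid in epochs.participants:
        by_cell: dict[tuple[str, ...], list[np.ndarray]] = {}
        for cell, ep in zip(epochs.condition[pid], epochs.data[pid]):
            by_cell.setdefault(cell, []).append(ep)
        for cell in epochs.design.cells:
            if by_cell.get(cell):
                out.append((pid, cell, np.mean(by_cell[cell], axis=0)))
    return out


def select_channels(
    instances: InstanceSet, channels: Union[str, Sequence[str]]
) -> InstanceSet:
    """Restrict (and reorder) the channel dimension to a named set or an
    explicit label list."""
    if isinstance(channels, str):
        if channels not in CHANNEL_SETS:
            raise KeyError(
                f"unknown channel set {channels!r}; available: {sorted(CHANNEL_SETS)}"
            )
        wanted = CHANNEL_SETS[channels]
    else:
        wanted = tuple(channels)
    missing = [ch for ch in wanted if ch not in instances.channel_labels]
    if missing:
        raise KeyError(f"channel label(s) not present: {missing}")
    idx = [instances.channel_labels.index(ch) for ch in wanted]
    out = [
        Instance(inst.participant, inst.label, inst.signal[idx, :])
        for inst in instances.instances
    ]
    return replace(instances, instances=out, channel_labels=wanted)
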
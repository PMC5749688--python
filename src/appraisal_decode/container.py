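"""Hierarchical on-disk container for epoch sets and related manifests.

Layout of one HDF5 file per study::

    /data/<participant>/<trial index>   channels x samples float64
    /meta                               scalar JSON string: design, condition
                                        labels, time axis, sampling rate

A flat TSV manifest (participant, trial, cell) can be written alongside.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from appraisal_decode.synthgen import DesignSpec, EpochSet


def design_to_dict(design: DesignSpec) -> dict:
    return {
        "study_label": design.study_label,
        "modality": design.modality,
        "participants": design.participants,
        "checks": [[name, list(levels)] for name, levels in design.checks],
        "trials_per_cell": {"|".join(cell): n for cell, n in design.trials_per_cell.items()},
        "sampling_rate": design.sampling_rate,
        "epoch_window": list(design.epoch_window),
        "channel_labels": list(design.channel_labels),
    }


def design_from_dict(d: dict) -> DesignSpec:
    return DesignSpec(
        study_label=d["study_label"],
        modality=d["modality"],
        participants=int(d["participants"]),
        checks=tuple((name, tuple(levels)) for name, levels in d["checks"]),
        trials_per_cell={tuple(k.split("|")): int(v) for k, v in d["trials_per_cell"].items()},
        sampling_rate=float(d["sampling_rate"]),
        epoch_window=tuple(d["epoch_window"]),
        channel_labels=tuple(d["channel_labels"]),
    )


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "design": design_to_dict(epochs.design),
        "condition": {pid: ["|".join(c) for c in cells] for pid, cells in epochs.condition.items()},
        "time_axis": epochs.time_axis.tolist(),
        "sampling_rate": epochs.sampling_rate,
    }
    with h5py.File(path, "w") as f:
        grp = f.create_group("data")
        for pid, trials in epochs.data.items():
            pg = grp.create_group(pid)
            for i, ep in enumerate(trials):
                pg.create_dataset(str(i), data=ep)
        f.create_dataset("meta", data=json.dumps(meta))


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        meta = json.loads(f["meta"][()])
        design = design_from_dict(meta["design"])
        data: dict[str, list[np.ndarray]] = {}
        for pid in meta["condition"]:
            pg = f["data"][pid]
            data[pid] = [pg[str(i)][()] for i in range(len(pg))]
    condition = {
        pid: [tuple(c.split("|")) for c in cells]
        for pid, cells in meta["condition"].items()
    }
    return EpochSet(
        design,
        data,
        condition,
        np.asarray(meta["time_axis"]),
        float(meta["sampling_rate"]),
    )


def write_manifest(epochs: EpochSet, path: str | Path) -> None:
    """Flat TSV manifest: participant, trial index, condition cell."""
    lines = ["participant\ttrial\tcell"]
    for pid, idx, cell, _ in epochs.iter_trials():
        lines.append(f"{pid}\t{idx}\t{'|'.join(cell)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_instance_manifest(instances, path: str | Path) -> None:
    """TSV manifest for an InstanceSet: participant, class, averaged-T, index."""
    lines = ["participant\tclass\tn_averaged\tindex"]
    for i, inst in enumerate(instances.instances):
        lines.append(f"{inst.participant}\t{inst.label}\t{instances.n_averaged}\t{i}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_rejection_report(report: list[tuple[str, int, list[str]]], path: str | Path) -> None:
    """TSV rejection report: participant, trial, comma-joined violated rules."""
    lines = ["participant\ttrial\trules"]
    for pid, idx, rules in report:
        lines.append(f"{pid}\t{idx}\t{','.join(rules)}")
    Path(path).write_text("\n".join(lines) + "\n")
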
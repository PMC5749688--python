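"""End-to-end glue: epochs -> relabel -> average -> channels -> features ->
nested cross-validation -> evaluation report."""

from __future__ import annotations

from typing import Optional, Sequence, Union

from appraisal_decode import decode, stats
from appraisal_decode.features import FeatureParams, FeatureTable, build_feature_table
from appraisal_decode.preprocess import baseline_correct
from appraisal_decode.synthgen import EpochSet
from appraisal_decode.trials import average_trials, relabel, select_channels


def prepare_instances(
    epochs: EpochSet,
    check: str,
    t: Union[int, str] = 1,
    channels: Union[str, Sequence[str], None] = None,
    baseline_window: Optional[tuple[float, float]] = None,
):
    """Relabel, optionally baseline-correct, average, and restrict channels."""
    if baseline_window is not None:
        data = {
            pid: [
                baseline_correct(ep, baseline_window, epochs.time_axis)
                for ep in eps
            ]
            for pid, eps in epochs.data.items()
        }
        epochs = EpochSet(
            epochs.design, data, epochs.condition, epochs.time_axis, epochs.sampling_rate
        )
    instances = relabel(epochs, check)
    instances = average_trials(instances, t)
    if channels is not None:
        instances = select_channels(instances, channels)
    return instances


def run_pipeline(
    epochs: EpochSet,
    check: str,
    t: Union[int, str] = 1,
    channels: Union[str, Sequence[str], None] = None,
    params: Optional[FeatureParams] = None,
    seed: int = 0,
    alpha: float = stats.ALPHA_DEFAULT,
    baseline_window: Optional[tuple[float, float]] = None,
) -> tuple[stats.EvalReport, decode.SicvResult, FeatureTable]:
    """Run one classification configuration end to end."""
    if params is None:
        params = (
            FeatureParams.eeg_default()
            if epochs.design.modality == "EEG"
            else FeatureParams.emg_default()
        )
    instances = prepare_instances(epochs, check, t, channels, baseline_window)
    table = build_feature_table(instances, params)
    result = decode.run_sicv(table, seed=seed)
    report = stats.evaluate(
        result,
        alpha=alpha,
        config={
            "check": check,
            "n_averaged": t,
            "channels": list(instances.channel_labels),
            "seed": seed,
        },
    )
    return report, result, table
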
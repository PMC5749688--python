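import numpy as np
import pytest

from appraisal_decode.montage import EMG_REGIONS
from appraisal_decode.synthgen import DesignSpec, EffectSpec, NoiseSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_design():
    """3 participants, one binary check, 2 channels, short epochs."""
    return DesignSpec(
        study_label="tiny",
        modality="EEG",
        participants=3,
        checks=(("target", ("a", "b")),),
        trials_per_cell={("a",): 5, ("b",): 5},
        epoch_window=(-100.0, 400.0),
        channel_labels=("Fz", "Pz"),
    )


@pytest.fixture
def two_check_design():
    """4 participants, 2x3 factorial, 2 channels."""
    return DesignSpec(
        study_label="factorial",
        modality="EEG",
        participants=4,
        checks=(
            ("novelty", ("novel", "familiar")),
            ("pleasantness", ("unpleasant", "neutral", "pleasant")),
        ),
        trials_per_cell={
            (n, p): (2 if n == "novel" else 7)
            for n in ("novel", "familiar")
            for p in ("unpleasant", "neutral", "pleasant")
        },
        epoch_window=(-100.0, 400.0),
        channel_labels=("Fz", "Pz"),
    )


@pytest.fixture
def emg_design():
    return DesignSpec(
        study_label="emg",
        modality="EMG",
        participants=4,
        checks=(("target", ("a", "b")),),
        trials_per_cell={("a",): 6, ("b",): 6},
        epoch_window=(-100.0, 1500.0),
        channel_labels=EMG_REGIONS,
    )


@pytest.fixture
def quiet_noise():
    return NoiseSpec(
        background_exponent=1.0,
        background_scale=0.5,
        white_sd=0.1,
        participant_gain_sd=0.05,
        latency_jitter_sd_ms=5.0,
    )


@pytest.fixture
def tiny_effect():
    return EffectSpec(
        check="target",
        channel_topography={"Fz": 0.5, "Pz": 1.0},
        peak_latency_ms={"a": 200.0, "b": 200.0},
        temporal_sd_ms=50.0,
        amplitude={"a": 2.0, "b": 0.0},
    )
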
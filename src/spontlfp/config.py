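"""Experiment configuration: one YAML-serializable object drives the
whole pipeline, and one master seed drives every random stream."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class ExperimentConfig:
    # master seed: all stage streams are spawned from it
    seed: int = 0

    # protocol (per-block stimulus counts follow the standard design:
    # airflow 11 x 10 = 110, touch 20 x 5 = 100)
    n_block_pairs: int = 1
    inter_block_gap_s: float = 120.0
    airflow_sequence_length: int = 11
    airflow_repetitions: int = 10
    touch_sequence_length: int = 20
    touch_repetitions: int = 5
    stimulus_duration_s: float = 1.0
    stimulus_gap_s: float = 4.0
    touch_jitter_s: float = 0.75

    # recording / effect
    fs: float = 1000.0
    channels_per_nucleus: dict = field(default_factory=lambda: {"central": 1, "basal": 2})
    band_lo: float = 10.0
    band_hi: float = 25.0
    power_ratio: float = 1.5
    background_exponent: float = 1.0
    noise_sd: float = 1.0
    shared_fraction: float = 0.5

    # window selection
    window_length_s: float = 0.5
    fallback_length_s: float = 0.4

    # spectrograms
    cwt_f0: float = 5.0
    freq_lo: float = 1.0
    freq_hi: float = 50.0
    freq_step: float = 1.0
    scale_rule: str = "central"
    time_decim: int = 25
    restrict_band: list | None = None     # [lo, hi] or None

    # decoding
    classifier: str = "cnn"               # "cnn" | "svm"
    nucleus: str | None = None            # None -> every simulated nucleus
    batch_size: int = 20
    epochs: int = 40
    learning_rate: float = 1.0e-3
    n_repetitions: int = 50
    n_shuffles: int = 20

    # autonomic
    mean_hr_bpm: float = 100.0
    resp_freq_hz: float = 0.3
    resp_depth_touch: float = 0.1
    resp_depth_airflow: float = 0.0
    artifact_rate: float = 0.0
    rsa_window_s: float = 60.0
    rsa_overlap_s: float = 3.0

    out_dir: str = "spontlfp_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
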
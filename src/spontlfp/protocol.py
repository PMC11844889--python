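"""Block-structured stimulus protocols.

A session alternates blocks of two tactile modalities: computer-controlled
airflow (sequences of 11 one-second presentations at fixed spacing, a
sequence repeated 10 times for 110 presentations per block) and social
grooming touch (sequences of 20 presentations with jittered ~4 s spacing,
repeated 5 times for 100 presentations per block).  Blocks are separated
by a configurable quiet gap (a few minutes by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AIRFLOW = "airflow"
TOUCH = "touch"
MODALITIES = (AIRFLOW, TOUCH)


@dataclass(frozen=True)
class StimulusEvent:
    onset: float          # seconds from session start
    duration: float       # seconds
    modality: str         # "airflow" | "touch"
    block_index: int
    within_block_index: int

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class StimulusTrainConfig:
    """One modality's block layout.

    ``gap`` is the offset-to-onset spacing between consecutive stimuli
    (so onset-to-onset spacing is ``gap + duration`` under the default
    convention).  Set ``spacing_convention="onset"`` to interpret ``gap``
    as onset-to-onset instead.  ``jitter`` (seconds) is the half-width of
    the uniform spacing jitter (0 for rigid spacing).
    """

    sequence_length: int
    repetitions: int
    duration: float = 1.0
    gap: float = 4.0
    jitter: float = 0.0
    spacing_convention: str = "offset"  # "offset" (gap after stimulus) | "onset"

    def __post_init__(self):
        if self.sequence_length < 0 or self.repetitions < 0:
            raise ValueError("sequence length and repetitions must be >= 0")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        base = self.gap if self.spacing_convention == "offset" else self.gap - self.duration
        if base - self.jitter <= 0:
            raise ValueError("spacing must exceed duration (after jitter)")
        if self.spacing_convention not in ("offset", "onset"):
            raise ValueError("spacing_convention must be 'offset' or 'onset'")

    @property
    def n_events(self) -> int:
        return self.sequence_length * self.repetitions


def default_airflow_config() -> StimulusTrainConfig:
    """11 presentations x 10 repetitions, 1 s stimuli at fixed 4 s gaps."""
    return StimulusTrainConfig(sequence_length=11, repetitions=10,
                               duration=1.0, gap=4.0, jitter=0.0)


def default_touch_config() -> StimulusTrainConfig:
    """20 grooming sweeps x 5 repetitions, ~4 s jittered gaps."""
    return StimulusTrainConfig(sequence_length=20, repetitions=5,
                               duration=1.0, gap=4.0, jitter=0.75)


@dataclass
class BlockProtocol:
    events: list = field(default_factory=list)          # ordered StimulusEvent
    block_types: list = field(default_factory=list)     # modality per block

    @property
    def n_blocks(self) -> int:
        return len(self.block_types)

    def block_events(self, block_index: int) -> list:
        return [e for e in self.events if e.block_index == block_index]

    def block_span(self, block_index: int) -> tuple:
        ev = self.block_events(block_index)
        return (ev[0].onset, ev[-1].offset)

    @property
    def end_time(self) -> float:
        return max((e.offset for e in self.events), default=0.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "onset_s": [e.onset for e in self.events],
                "duration_s": [e.duration for e in self.events],
                "modality": [e.modality for e in self.events],
                "block_index": [e.block_index for e in self.events],
                "within_block_index": [e.within_block_index for e in self.events],
            }
        )

    @classmethod
    def from_frame(cls, df) -> "BlockProtocol":
        events = [
            StimulusEvent(
                onset=float(r.onset_s),
                duration=float(r.duration_s),
                modality=str(r.modality),
                block_index=int(r.block_index),
                within_block_index=int(r.within_block_index),
            )
            for r in df.itertuples()
        ]
        block_types = []
        for e in events:
            if e.block_index == len(block_types):
                block_types.append(e.modality)
        return cls(events=events, block_types=block_types)


def generate_protocol(
    airflow_cfg: StimulusTrainConfig | None = None,
    touch_cfg: StimulusTrainConfig | None = None,
    n_block_pairs: int = 1,
    inter_block_gap: float = 120.0,
    start_time: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> BlockProtocol:
    """Build an alternating airflow/touch block protocol.

    Airflow blocks come first in each pair.  Spacing within an airflow
    block is rigid; touch spacing is jittered uniformly by ``±jitter``.
    """
    if airflow_cfg is None:
        airflow_cfg = default_airflow_config()
    if touch_cfg is None:
        touch_cfg = default_touch_config()
    if n_block_pairs < 0:
        raise ValueError("n_block_pairs must be >= 0")
    if inter_block_gap < 0:
        raise ValueError("inter_block_gap must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    events: list = []
    block_types: list = []
    t = start_time
    for _ in range(n_block_pairs):
        for modality, cfg in ((AIRFLOW, airflow_cfg), (TOUCH, touch_cfg)):
            block_index = len(block_types)
            block_types.append(modality)
            onset = t
            for i in range(cfg.n_events):
                events.append(
                    StimulusEvent(onset=onset, duration=cfg.duration,
                                  modality=modality, block_index=block_index,
                                  within_block_index=i)
                )
                base = cfg.gap if cfg.spacing_convention == "offset" else cfg.gap - cfg.duration
                jit = rng.uniform(-cfg.jitter, cfg.jitter) if cfg.jitter > 0 else 0.0
                onset = onset + cfg.duration + base + jit
            if cfg.n_events:
                t = events[-1].offset + inter_block_gap
    return BlockProtocol(events=events, block_types=block_types)
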
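"""Inter-stimulus segments and stable spontaneous-activity windows.

The decodable substrate is spontaneous activity between two stimuli of
the same type: each inter-stimulus interval (ISI) runs from 200 ms after
one stimulus' offset to 200 ms before the next onset, within one block
(no segment before a block's first stimulus, none across block gaps).

Because touch spacing is jittered, ISIs vary in length; a single fixed
window offset per label is chosen by minimizing the across-trial
variability of the trial-aligned signal — a reproducible surrogate for
picking the "stable" gray-box window by eye.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .protocol import MODALITIES

logger = logging.getLogger(__name__)

BUFFER_S = 0.2
DEFAULT_WINDOW_S = 0.5
FALLBACK_WINDOW_S = 0.4


class NoStableWindowError(RuntimeError):
    def __init__(self, label: str, reason: str = "no segment long enough"):
        super().__init__(f"no stable window for label '{label}': {reason}")
        self.label = label


@dataclass(frozen=True)
class ISISegment:
    channel: int
    start: float
    end: float
    label: str
    trial_index: int

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SpontaneousWindow:
    channel: int
    start: float
    length: float
    label: str
    trial_index: int

    @property
    def end(self) -> float:
        return self.start + self.length


def extract_isi_segments(session, buffer_s: float = BUFFER_S) -> list:
    """One segment per consecutive same-block stimulus pair, per channel.

    Segment boundaries apply ``buffer_s`` after the leading stimulus'
    offset and before the trailing stimulus' onset, excluding evoked
    activity.  Cross-block gaps produce no segment.
    """
    events = session.protocol.events
    segments = []
    trial_counter = dict.fromkeys(MODALITIES, 0)
    spans = []
    for prev, nxt in zip(events, events[1:]):
        if prev.block_index != nxt.block_index:
            continue
        start = prev.offset + buffer_s
        end = nxt.onset - buffer_s
        if end <= start:
            continue
        idx = trial_counter[prev.modality]
        trial_counter[prev.modality] += 1
        spans.append((start, end, prev.modality, idx))
    for ch in range(session.n_channels):
        for start, end, label, idx in spans:
            segments.append(ISISegment(channel=ch, start=start, end=end,
                                       label=label, trial_index=idx))
    return segments


def _segment_matrix(session, segs: list, max_len_s: float):
    """Aligned (trial, channel, time) array of segment-start-locked LFP."""
    fs = session.fs
    n_t = int(np.floor(max_len_s * fs))
    by_trial = {}
    for s in segs:
        by_trial.setdefault(s.trial_index, {})[s.channel] = s
    trials = sorted(by_trial)
    channels = sorted({s.channel for s in segs})
    out = np.empty((len(trials), len(channels), n_t), dtype=np.float64)
    for ti, trial in enumerate(trials):
        for ci, ch in enumerate(channels):
            seg = by_trial[trial][ch]
            i0 = int(round(seg.start * fs))
            out[ti, ci] = session.lfp[ch, i0:i0 + n_t]
    return out


def select_stable_window(
    session,
    segments: list,
    window_length: float,
    label: str,
    grid_step: float = 0.01,
) -> list:
    """Pick one window offset for a label by minimizing trial-wise variability.

    Segments of the label are aligned on their start (stimulus offset +
    buffer) and truncated to the shortest surviving segment.  The
    per-timepoint standard deviation across trials is computed per
    channel, normalized by its own mean (so the criterion is invariant
    to channel amplitude rescaling), and averaged over channels.  The
    window offset, on a ``grid_step`` grid, minimizing the mean of that
    aggregate over the window is applied to every trial; ties break to
    the earliest admissible offset.
    """
    segs = [s for s in segments if s.label == label]
    if not segs:
        raise NoStableWindowError(label, "no segments")
    long_enough = [s for s in segs if s.length >= window_length]
    n_dropped = len({(s.trial_index) for s in segs}) - len({s.trial_index for s in long_enough})
    if n_dropped:
        logger.warning("select_stable_window(%s): dropped %d trials shorter than %.3f s",
                       label, n_dropped, window_length)
    if not long_enough:
        raise NoStableWindowError(label)
    min_len = min(s.length for s in long_enough)

    aligned = _segment_matrix(session, long_enough, min_len)   # trial x ch x t
    sd = aligned.std(axis=0)                                   # ch x t
    scale = sd.mean(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    agg = (sd / scale).mean(axis=0)                            # t

    fs = session.fs
    wl_samp = int(round(window_length * fs))
    step_samp = max(int(round(grid_step * fs)), 1)
    max_off = agg.size - wl_samp
    if max_off < 0:
        raise NoStableWindowError(label, "window longer than shortest segment")
    offsets = np.arange(0, max_off + 1, step_samp)
    csum = np.concatenate([[0.0], np.cumsum(agg)])
    scores = (csum[offsets + wl_samp] - csum[offsets]) / wl_samp
    best = offsets[int(np.argmin(scores))] / fs                # first minimum wins

    return [
        SpontaneousWindow(channel=s.channel, start=s.start + best,
                          length=window_length, label=label,
                          trial_index=s.trial_index)
        for s in long_enough
    ]


def select_windows(
    session,
    window_length: float = DEFAULT_WINDOW_S,
    fallback_length: float = FALLBACK_WINDOW_S,
    grid_step: float = 0.01,
) -> tuple:
    """Stable windows for both labels at a uniform length.

    Tries ``window_length`` first; if either label has no admissible
    segment, falls back to ``fallback_length`` for both labels (window
    length is uniform within one session analysis).  Returns
    ``(windows, used_length)`` with windows of both labels combined.
    """
    for wl in (window_length, fallback_length):
        segments = extract_isi_segments(session)
        try:
            out = []
            for label in MODALITIES:
                if any(s.label == label for s in segments):
                    out.extend(select_stable_window(session, segments, wl, label,
                                                    grid_step=grid_step))
            if wl != window_length:
                logger.warning("select_windows: fell back to %.3f s windows", wl)
            return out, wl
        except NoStableWindowError:
            if wl == fallback_length:
                raise
    raise NoStableWindowError("any")  # pragma: no cover


def windows_to_frame(windows: list):
    import pandas as pd

    return pd.DataFrame({
        "channel": [w.channel for w in windows],
        "start_s": [w.start for w in windows],
        "length_s": [w.length for w in windows],
        "label": [w.label for w in windows],
        "trial_index": [w.trial_index for w in windows],
    })
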
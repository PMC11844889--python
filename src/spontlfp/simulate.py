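"""Synthetic session generator with known ground truth.

Emulates the statistical structure the decoding analysis assumes:

* a block protocol of alternating airflow / grooming-touch stimuli,
* multi-channel LFP built from 1/f background noise (partially shared
  within a nucleus), whose band-limited power in a chosen band is
  multiplied by ``power_ratio`` throughout touch blocks — the context
  effect is a latent block-long state, present between stimuli as well,
* brief stimulus-evoked transients (so stable-window selection is
  non-trivial),
* optional spike trains, optionally phase-locked to an LFP band,
* heartbeat (inter-beat-interval) series with respiratory modulation.

All randomness flows from one integer seed through a documented
``SeedSequence`` hierarchy: child streams, in order, are (0) protocol,
(1) LFP noise, (2) evoked transients, (3) spikes, (4) heartbeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .autonomic import IBISeries
from .protocol import (AIRFLOW, TOUCH, BlockProtocol, StimulusTrainConfig,
                       default_airflow_config, default_touch_config,
                       generate_protocol)

NUCLEI = ("central", "basal", "accessory_basal", "lateral")


@dataclass
class EffectSpec:
    """Context effect and background-noise parameters of the simulator."""

    band_lo: float = 10.0          # Hz
    band_hi: float = 25.0          # Hz
    power_ratio: float = 1.5       # touch / airflow band-power ratio
    background_exponent: float = 1.0   # 1/f^beta background slope
    noise_sd: float = 1.0          # amplitude units (a.u., think uV)
    shared_fraction: float = 0.5   # within-nucleus common-signal variance fraction

    def validate(self, fs: float) -> None:
        if not (0 < self.band_lo < self.band_hi < fs / 2):
            raise ValueError(
                f"band [{self.band_lo}, {self.band_hi}] Hz invalid for fs={fs}")
        if self.power_ratio <= 0:
            raise ValueError("power_ratio must be > 0")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")


@dataclass
class SessionRecording:
    lfp: np.ndarray                    # channels x samples
    fs: float
    nucleus_of_channel: list           # one nucleus label per channel
    protocol: BlockProtocol
    spikes: list | None = None         # per-unit spike-time arrays (s)
    heartbeats: IBISeries | None = None
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]

    @property
    def duration(self) -> float:
        return self.lfp.shape[1] / self.fs

    def channels_in(self, nucleus: str) -> list:
        return [i for i, n in enumerate(self.nucleus_of_channel) if n == nucleus]

    @property
    def nuclei(self) -> list:
        seen = []
        for n in self.nucleus_of_channel:
            if n not in seen:
                seen.append(n)
        return seen


def one_over_f_noise(n: int, exponent: float, rng: np.random.Generator,
                     fs: float, f_floor: float = 0.5) -> np.ndarray:
    """Unit-variance 1/f^exponent noise by spectral shaping of white noise.

    The amplitude profile is flattened below ``f_floor`` Hz to keep the
    variance finite and the traces free of huge infra-slow excursions.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f_eff = np.maximum(f, f_floor)
    spec *= f_eff ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _extract_band(x: np.ndarray, effect: EffectSpec, fs: float,
                  transition_hz: float = 1.0) -> np.ndarray:
    """Zero-phase band extraction with unit gain on [band_lo, band_hi].

    Uses an FFT mask with cosine transitions placed entirely *outside*
    the band, so the band content of the result is exactly that of the
    input — the simulated context gain then scales measured band power
    by exactly ``power_ratio``.
    """
    n = x.size
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    lo, hi, tr = effect.band_lo, effect.band_hi, transition_hz
    mask = np.zeros_like(f)
    mask[(f >= lo) & (f <= hi)] = 1.0
    rise = (f >= lo - tr) & (f < lo)
    mask[rise] = 0.5 * (1 + np.cos(np.pi * (lo - f[rise]) / tr))
    fall = (f > hi) & (f <= hi + tr)
    mask[fall] = 0.5 * (1 + np.cos(np.pi * (f[fall] - hi) / tr))
    return np.fft.irfft(np.fft.rfft(x) * mask, n=n)


def context_gain(protocol: BlockProtocol, n: int, fs: float,
                 power_ratio: float, lead: float = 2.0) -> np.ndarray:
    """Amplitude gain vs. time: sqrt(power_ratio) inside touch blocks."""
    g = np.ones(n)
    amp = np.sqrt(power_ratio)
    for b, btype in enumerate(protocol.block_types):
        if btype != TOUCH:
            continue
        t0, t1 = protocol.block_span(b)
        i0 = max(0, int((t0 - lead) * fs))
        i1 = min(n, int((t1 + lead) * fs))
        g[i0:i1] = amp
    return g


def simulate_lfp_session(
    protocol: BlockProtocol,
    channels_per_nucleus: dict,
    effect: EffectSpec | None = None,
    fs: float = 1000.0,
    seed: int = 0,
    evoked_amp: float = 2.0,
    rebound_amp: float = 1.5,
    tail_s: float = 10.0,
) -> SessionRecording:
    """Simulate a multi-channel LFP session for a given protocol.

    Each channel is ``noise_sd`` times a mixture of a within-nucleus shared
    1/f process and a private 1/f process; the band content of that mixture
    is multiplied by ``sqrt(power_ratio)`` throughout touch blocks, so the
    measured band-power ratio between contexts equals ``power_ratio``.
    Deterministic evoked transients are added at stimulus onsets, and
    rebound transients with per-trial random amplitude decay into the early
    inter-stimulus interval (they are what makes the stable-window search
    meaningful).
    """
    effect = effect or EffectSpec()
    effect.validate(fs)
    if fs < 4 * effect.band_hi:
        raise ValueError(f"fs={fs} too low; need >= 4 x band_hi = {4 * effect.band_hi}")
    if not channels_per_nucleus or sum(channels_per_nucleus.values()) < 1:
        raise ValueError("need at least one channel")

    ss = np.random.SeedSequence(seed)
    _, s_noise, s_evoked, *_ = ss.spawn(5)
    rng_noise = np.random.default_rng(s_noise)
    rng_ev = np.random.default_rng(s_evoked)

    n = int(np.ceil((protocol.end_time + tail_s) * fs))
    gain = context_gain(protocol, n, fs, effect.power_ratio)

    nucleus_of_channel: list = []
    rows = []
    for nucleus, n_ch in channels_per_nucleus.items():
        shared = one_over_f_noise(n, effect.background_exponent, rng_noise, fs)
        for _ in range(int(n_ch)):
            private = one_over_f_noise(n, effect.background_exponent, rng_noise, fs)
            base = effect.noise_sd * (
                np.sqrt(effect.shared_fraction) * shared
                + np.sqrt(1.0 - effect.shared_fraction) * private
            )
            band = _extract_band(base, effect, fs)
            rows.append(base + (gain - 1.0) * band)
            nucleus_of_channel.append(nucleus)
    lfp = np.asarray(rows, dtype=np.float32)

    # stimulus-evoked transients: deterministic onset response plus a
    # post-offset rebound whose amplitude varies trial to trial, decaying
    # ~400 ms into the ISI
    t_on = np.arange(int(0.15 * fs)) / fs
    onset_wave = evoked_amp * effect.noise_sd * np.exp(-t_on / 0.05) * np.sin(2 * np.pi * 10 * t_on)
    t_rb = np.arange(int(0.5 * fs)) / fs
    rebound_shape = np.exp(-t_rb / 0.15) * np.sin(2 * np.pi * 10 * t_rb)
    for ev in protocol.events:
        i_on = int(ev.onset * fs)
        i_off = int(ev.offset * fs)
        amp = rng_ev.uniform(0.0, rebound_amp) * effect.noise_sd
        sl_on = slice(i_on, min(i_on + onset_wave.size, n))
        sl_off = slice(i_off, min(i_off + rebound_shape.size, n))
        lfp[:, sl_on] += onset_wave[: sl_on.stop - sl_on.start]
        lfp[:, sl_off] += amp * rebound_shape[: sl_off.stop - sl_off.start]

    gt = {
        "seed": seed,
        "fs": fs,
        "effect": vars(effect).copy(),
        "evoked_amp": evoked_amp,
        "rebound_amp": rebound_amp,
    }
    return SessionRecording(lfp=lfp, fs=fs, nucleus_of_channel=nucleus_of_channel,
                            protocol=protocol, ground_truth=gt)


def simulate_spike_trains(
    session: SessionRecording,
    rate_hz: float,
    band_locking: float = 0.0,
    seed: int = 0,
    band: tuple = (10.0, 25.0),
    n_units: int = 4,
) -> list:
    """Attach inhomogeneous-Poisson spike trains to a session.

    Intensity is ``rate_hz * (1 + band_locking * cos(phi(t)))`` where
    ``phi`` is the Hilbert phase of the band-passed LFP of the unit's
    reference channel (units are assigned to channels round-robin).
    ``band_locking = 0`` gives homogeneous Poisson trains.  Spikes are
    drawn by thinning.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be > 0")
    if not -1 <= band_locking <= 1:
        raise ValueError("band_locking must be in [-1, 1]")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(5)[3])
    duration = session.duration
    if session.n_channels == 0 or duration <= 0:
        session.spikes = []
        return []
    fs = session.fs
    trains = []
    phases = {}
    for u in range(n_units):
        ch = u % session.n_channels
        lam_max = rate_hz * (1.0 + abs(band_locking))
        n_cand = rng.poisson(lam_max * duration)
        cand = np.sort(rng.uniform(0, duration, size=n_cand))
        if band_locking == 0:
            trains.append(cand)
            continue
        if ch not in phases:
            sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
            bp = signal.sosfiltfilt(sos, session.lfp[ch].astype(np.float64))
            phases[ch] = np.angle(signal.hilbert(bp))
        phi = phases[ch][np.minimum((cand * fs).astype(int), phases[ch].size - 1)]
        lam = rate_hz * (1.0 + band_locking * np.cos(phi))
        keep = rng.uniform(0, lam_max, size=cand.size) < lam
        trains.append(cand[keep])
    session.spikes = trains
    return trains


def simulate_ibi_series(
    duration_s: float,
    mean_hr_bpm: float = 100.0,
    resp_freq_hz: float = 0.3,
    resp_depth: float = 0.1,
    artifact_rate: float = 0.0,
    seed: int = 0,
    depth_fn=None,
    ibi_noise: float = 0.0,
) -> IBISeries:
    """Simulate heartbeat times with sinusoidal respiratory modulation.

    Inter-beat intervals follow ``ibi0 * (1 + d(t) sin(2 pi f_resp t))``
    with ``ibi0 = 60 / mean_hr_bpm``; ``d(t)`` is ``resp_depth`` unless a
    ``depth_fn(t)`` override is supplied (used for context-dependent
    sessions).  ``ibi_noise`` adds relative white Gaussian beat-to-beat
    variability (real heart rate is never perfectly rigid).
    ``artifact_rate`` (events/s) inserts spurious extra beats 100 ms after
    randomly chosen beats, producing intervals that violate the
    250–1500 ms physiological limits and must be cleaned downstream.
    """
    if not 40 < mean_hr_bpm < 240:
        raise ValueError("mean_hr_bpm must be in (40, 240)")
    if not 0 <= resp_depth < 1:
        raise ValueError("resp_depth must be in [0, 1)")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(5)[4])
    ibi0 = 60.0 / mean_hr_bpm
    beats = [0.0]
    t = 0.0
    while True:
        d = depth_fn(t) if depth_fn is not None else resp_depth
        ibi = ibi0 * (1.0 + d * np.sin(2 * np.pi * resp_freq_hz * t))
        if ibi_noise > 0:
            ibi *= max(1.0 + ibi_noise * rng.standard_normal(), 0.2)
        t += ibi
        if t > duration_s:
            break
        beats.append(t)
    beats = np.asarray(beats)
    if artifact_rate > 0 and beats.size > 2:
        n_art = rng.poisson(artifact_rate * duration_s)
        n_art = max(n_art, 1)
        hosts = rng.choice(beats.size - 1, size=min(n_art, beats.size - 1), replace=False)
        beats = np.sort(np.concatenate([beats, beats[hosts] + 0.1]))
    series = IBISeries.from_beats(beats)
    series.ground_truth = {
        "mean_hr_bpm": mean_hr_bpm,
        "resp_freq_hz": resp_freq_hz,
        "resp_depth": resp_depth,
        "artifact_rate": artifact_rate,
        "seed": seed,
    }
    return series


def simulate_context_ibi(
    protocol: BlockProtocol,
    mean_hr_bpm: float = 100.0,
    resp_freq_hz: float = 0.3,
    depth_touch: float = 0.1,
    depth_airflow: float = 0.0,
    artifact_rate: float = 0.0,
    seed: int = 0,
    tail_s: float = 10.0,
    ibi_noise: float = 0.02,
) -> IBISeries:
    """Heartbeat series whose respiratory modulation depth depends on the
    block context (touch vs. airflow), emulating stronger RSA during
    grooming.  A 2% beat-to-beat IBI jitter emulates the broadband
    variability real heart rate always carries."""
    spans = [(protocol.block_span(b), bt) for b, bt in enumerate(protocol.block_types)]

    def depth(t: float) -> float:
        for (t0, t1), btype in spans:
            if t0 - 2.0 <= t <= t1 + 2.0:
                return depth_touch if btype == TOUCH else depth_airflow
        return depth_airflow

    return simulate_ibi_series(
        protocol.end_time + tail_s, mean_hr_bpm, resp_freq_hz,
        resp_depth=max(depth_touch, depth_airflow), artifact_rate=artifact_rate,
        seed=seed, depth_fn=depth, ibi_noise=ibi_noise)
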
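"""Heart-rate cleaning, interpolation and respiratory sinus arrhythmia.

The RSA statistic quantifies respiratory-frequency (0.25–0.5 Hz, i.e.
15–30 breaths/min) modulation of the instantaneous heart rate.  Per
60-second sliding window, a multitaper (Slepian) power spectral density
of the interpolated heart-rate series is normalized to unit area on the
respiratory band; raw RSA strength ``P_rsa`` is the mean normalized
power within one half-bandwidth of the largest in-band spectral peak
(the in-band mean when no peak exists), and normalized strength is

    P~_rsa = (P_rsa - mu) / mu,   mu = median over windows,

so the median normalized strength is zero by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from scipy.interpolate import Akima1DInterpolator

from typing import Optional

logger = logging.getLogger(__name__)

IBI_MIN_MS = 250.0    # 240 BPM ceiling
IBI_MAX_MS = 1500.0   # 40 BPM floor
RESP_BAND = (0.25, 0.5)   # Hz


class AutonomicError(ValueError):
    pass


@dataclass
class IBISeries:
    """Heartbeat times (s) with aligned inter-beat intervals (ms).

    ``ibis[i]`` is the interval ending at ``beat_times[i + 1]``.  After
    cleaning, removed interval entries take their terminating beat with
    them, so the alignment (and ``len(ibis) == len(beat_times) - 1``)
    is preserved even though ``ibis`` is no longer literally the
    difference of consecutive retained beats.
    """

    beat_times: np.ndarray
    ibis: np.ndarray                  # milliseconds
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.ibis = np.asarray(self.ibis, dtype=float)
        if self.beat_times.size >= 2 and np.any(np.diff(self.beat_times) <= 0):
            raise AutonomicError("beat times must be strictly increasing")
        if self.ibis.size != max(self.beat_times.size - 1, 0):
            raise AutonomicError("ibis length must equal number of beats - 1")

    @classmethod
    def from_beats(cls, beat_times) -> "IBISeries":
        beat_times = np.asarray(beat_times, dtype=float)
        return cls(beat_times=beat_times, ibis=np.diff(beat_times) * 1000.0)

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"beat_time_s": self.beat_times})


def clean_ibi(raw: "IBISeries | np.ndarray") -> IBISeries:
    """Remove physiologically impossible intervals (outside 250–1500 ms).

    Accepts raw beat times or an existing series.  Each out-of-range
    interval entry is dropped together with its terminating beat; the
    number removed is logged.
    """
    series = raw if isinstance(raw, IBISeries) else IBISeries.from_beats(raw)
    if series.n_beats < 2:
        raise AutonomicError("need at least 2 beats")
    valid = (series.ibis >= IBI_MIN_MS) & (series.ibis <= IBI_MAX_MS)
    n_removed = int((~valid).sum())
    if n_removed:
        logger.info("clean_ibi: removed %d of %d intervals", n_removed, valid.size)
    beats = np.concatenate([[series.beat_times[0]], series.beat_times[1:][valid]])
    if beats.size < 2:
        raise AutonomicError("fewer than 2 valid beats remain after cleaning")
    out = IBISeries(beat_times=beats, ibis=series.ibis[valid],
                    ground_truth=dict(series.ground_truth))
    out.n_removed = n_removed
    return out


def interpolate_hr(ibi: IBISeries, grid_step_s: float = 0.001):
    """Instantaneous heart rate (BPM) on a regular grid.

    Per-interval HR values ``60000 / IBI`` are placed at each interval's
    terminating beat time and interpolated with the modified Akima cubic
    Hermite polynomial (shape-preserving, no spurious overshoot) onto a
    1 ms grid spanning the valid range.  Returns ``(times, hr_bpm)``.
    """
    if ibi.ibis.size < 4:
        raise AutonomicError("need at least 4 intervals for cubic interpolation")
    t_knots = ibi.beat_times[1:]
    hr_knots = 60000.0 / ibi.ibis
    interp = Akima1DInterpolator(t_knots, hr_knots, method="makima")
    n = int(np.floor((t_knots[-1] - t_knots[0]) / grid_step_s)) + 1
    t = t_knots[0] + np.arange(n) * grid_step_s
    return t, interp(t)


@dataclass
class TaperSet:
    tapers: np.ndarray       # k x N, orthonormal
    eigenvalues: np.ndarray  # concentration ratios, descending
    half_bandwidth: float    # Hz


def slepian_tapers(n: int, half_bandwidth: float, fs: float, k: int = 7) -> TaperSet:
    """First ``k`` discrete prolate spheroidal sequences for a window of
    ``n`` samples at rate ``fs`` with half-bandwidth ``half_bandwidth`` Hz."""
    if half_bandwidth >= fs / 2:
        raise AutonomicError("half-bandwidth must be below the Nyquist frequency")
    nw = half_bandwidth * n / fs       # time-bandwidth product N*W*dt
    if k > 2 * nw - 1:
        warnings.warn(
            f"k={k} tapers exceeds the 2NW-1={2 * nw - 1:.1f} guideline for "
            f"W={half_bandwidth} Hz over {n / fs:.0f} s; higher-order tapers "
            "have poor concentration", stacklevel=2)
    tapers, ratios = signal.windows.dpss(n, nw, Kmax=k, sym=True,
                                         norm=2, return_ratios=True)
    return TaperSet(tapers=tapers, eigenvalues=ratios, half_bandwidth=half_bandwidth)


def multitaper_psd(x: np.ndarray, fs: float, half_bandwidth: float = 0.07,
                   k: int = 7, tapers: Optional[TaperSet] = None):
    """Multitaper PSD: mean of the k taper eigenspectra.

    Each eigenspectrum is ``dt * |FFT(g_k * x)|**2`` of the demeaned
    signal.  Returns ``(freqs, psd)`` on the one-sided rfft grid.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if tapers is None:
        tapers = slepian_tapers(n, half_bandwidth, fs, k)
    x = x - x.mean()
    spec = np.fft.rfft(tapers.tapers * x[None, :], axis=1)
    psd = (np.abs(spec) ** 2).mean(axis=0) / fs
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, psd


@dataclass
class RSASeries:
    window_centers: np.ndarray
    raw: np.ndarray          # P_rsa per window
    normalized: np.ndarray   # P~_rsa per window
    labels: list             # block label per window (or None)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "window_center_s": self.window_centers,
            "p_rsa": self.raw,
            "p_rsa_norm": self.normalized,
            "block": [lb if lb is not None else "" for lb in self.labels],
        })

    def context_means(self) -> dict:
        out = {}
        for lb in ("airflow", "touch"):
            vals = [v for v, w in zip(self.normalized, self.labels) if w == lb]
            out[lb] = float(np.mean(vals)) if vals else np.nan
        return out


def _label_of(t: float, protocol) -> Optional[str]:
    if protocol is None:
        return None
    for b, btype in enumerate(protocol.block_types):
        t0, t1 = protocol.block_span(b)
        if t0 - 2.0 <= t <= t1 + 2.0:
            return btype
    return None


def rsa_strength(
    hr_times: np.ndarray,
    hr_values: np.ndarray,
    window_s: float = 60.0,
    overlap_s: float = 3.0,
    step_mode: str = "overlap",
    psd_fs: float = 4.0,
    half_bandwidth: float = 0.07,
    k: int = 7,
    band: tuple = RESP_BAND,
    peak_prominence: float = 0.1,
    protocol=None,
) -> RSASeries:
    """Windowed, normalized RSA strength of an instantaneous-HR series.

    ``step_mode="overlap"`` (default): consecutive windows share
    ``overlap_s`` seconds, i.e. the hop is ``window_s - overlap_s``;
    ``step_mode="step"`` treats ``overlap_s`` as the hop itself.  The HR
    grid is decimated to ``psd_fs`` Hz (anti-aliased) before spectral
    estimation — ample for a 0.5 Hz band.  Peaks are local maxima of the
    unit-area normalized PSD with prominence above ``peak_prominence``
    (normalized-density units).
    """
    hr_times = np.asarray(hr_times, dtype=float)
    hr_values = np.asarray(hr_values, dtype=float)
    span = hr_times[-1] - hr_times[0]
    if span < window_s:
        raise AutonomicError(f"HR span {span:.1f} s shorter than window {window_s} s")
    if not band[0] < band[1]:
        raise AutonomicError("empty respiratory band")
    step = window_s - overlap_s if step_mode == "overlap" else overlap_s
    if step <= 0:
        raise AutonomicError("window step must be positive")

    fs_in = 1.0 / np.median(np.diff(hr_times))
    q = max(int(round(fs_in / psd_fs)), 1)
    hr = signal.resample_poly(hr_values, up=1, down=q) if q > 1 else hr_values.copy()
    fs = fs_in / q
    t0 = hr_times[0]

    n_win = int(np.floor((span - window_s) / step)) + 1
    nper = int(round(window_s * fs))
    taper_set = slepian_tapers(nper, half_bandwidth, fs, k)

    centers, raws, labels = [], [], []
    for i in range(n_win):
        start = i * step
        i0 = int(round(start * fs))
        seg = hr[i0:i0 + nper]
        if seg.size < nper:
            break
        freqs, psd = multitaper_psd(seg, fs, tapers=taper_set)
        in_band = (freqs >= band[0]) & (freqs <= band[1])
        if not np.any(in_band):
            raise AutonomicError("no spectral bins in the respiratory band")
        area = np.trapezoid(psd[in_band], freqs[in_band])
        if area <= 0:
            raise AutonomicError("degenerate PSD: zero area in the respiratory band")
        npsd = psd / area
        band_idx = np.flatnonzero(in_band)
        peaks, _ = signal.find_peaks(npsd[band_idx], prominence=peak_prominence)
        if peaks.size:
            heights = npsd[band_idx][peaks]
            f_peak = freqs[band_idx][peaks[np.argmax(heights)]]
            sel = (freqs >= f_peak - half_bandwidth) & (freqs <= f_peak + half_bandwidth)
            p = float(npsd[sel].mean())
        else:
            p = float(npsd[in_band].mean())
        centers.append(t0 + start + window_s / 2.0)
        raws.append(p)
        labels.append(_label_of(centers[-1], protocol))

    raws = np.asarray(raws)
    mu = np.median(raws)
    normalized = (raws - mu) / mu
    return RSASeries(window_centers=np.asarray(centers), raw=raws,
                     normalized=normalized, labels=labels)


def compare_contexts(rsa_by_session, alternative: str = "greater"):
    """Paired one-sided t-test of per-session touch vs. airflow RSA means.

    ``rsa_by_session`` is a sequence whose elements are either
    ``RSASeries`` (labelled windows) or ``(touch_mean, airflow_mean)``
    pairs.  Tests touch > airflow by default.  With zero-variance paired
    differences the test is degenerate: p is reported as 0.0 when every
    difference favours the alternative, 1.0 when every difference opposes
    it, and 0.5 when all differences are zero (t = 0).
    """
    touch, airflow = [], []
    for item in rsa_by_session:
        if isinstance(item, RSASeries):
            means = item.context_means()
            touch.append(means["touch"])
            airflow.append(means["airflow"])
        else:
            touch.append(float(item[0]))
            airflow.append(float(item[1]))
    touch = np.asarray(touch)
    airflow = np.asarray(airflow)
    if touch.size < 2:
        raise AutonomicError("need at least 2 sessions")
    d = touch - airflow
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 0.5
        favours = d[0] > 0 if alternative == "greater" else d[0] < 0
        warnings.warn("zero-variance paired differences: degenerate t-test",
                      stacklevel=2)
        return (np.inf if favours else -np.inf), (0.0 if favours else 1.0)
    res = stats.ttest_rel(touch, airflow, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
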
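"""Continuous wavelet spectrograms and spike-triggered diagnostics.

Single-trial spectrograms are the magnitude of the continuous wavelet
transform

    x^(f, t) = (1/a) * integral x(tau) conj(psi((tau - t)/a)) dtau

against the complex Morlet wavelet

    psi(t) = (pi * fb)^(-1/2) * exp(-t^2 / fb) * exp(2j pi fc t)

evaluated on a 1–50 Hz grid.  ``f0`` is the dimensionless central
frequency in the standard (radian) Morlet convention — the default 5
matches the common "central frequency of 5" setting — so the cycle
frequency of the mother wavelet is ``fc = f0 / (2 pi)``.

Two frequency→scale rules are provided:

* ``"central"`` (default): a = fc * Fs / f, placing the wavelet's
  spectral peak exactly at the grid frequency;
* ``"printed"``: a = 2 * Fs / f, an alternative fixed rule.

The rule in force is recorded in each spectrogram's metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal


class TimeFreqError(ValueError):
    pass


@dataclass
class CWTParams:
    f0: float = 5.0                      # dimensionless central frequency
    fb: Optional[float] = None           # bandwidth; default from f0
    freqs: np.ndarray = field(default_factory=lambda: np.arange(1.0, 51.0, 1.0))
    scale_rule: str = "central"          # "central" | "printed"
    magnitude: bool = True               # |x^| images; False -> power |x^|^2

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.f0 <= 0:
            raise TimeFreqError("f0 must be > 0")
        if self.fb is None:
            # ~f0 cycles within the Gaussian envelope
            self.fb = 2.0 * (self.f0 / (2.0 * np.pi)) ** 2
        if self.fb <= 0:
            raise TimeFreqError("fb must be > 0")
        if self.scale_rule not in ("central", "printed"):
            raise TimeFreqError("scale_rule must be 'central' or 'printed'")

    @property
    def fc(self) -> float:
        """Cycle frequency of the mother wavelet (cycles per unit time)."""
        return self.f0 / (2.0 * np.pi)

    def scale(self, freq_hz: float, fs: float) -> float:
        if self.scale_rule == "central":
            return self.fc * fs / freq_hz
        return 2.0 * fs / freq_hz


@dataclass
class Spectrogram:
    values: np.ndarray               # freq x time, >= 0
    freqs: np.ndarray                # Hz
    times: np.ndarray                # s relative to window start
    label: Optional[str] = None
    channel: Optional[int] = None
    nucleus: Optional[str] = None
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.values.shape


def morlet_kernel(params: CWTParams, scale: float) -> np.ndarray:
    """Complex Morlet sampled at integer lags for a given scale (samples).

    Support is truncated at ±5 envelope standard deviations; odd length,
    centered at lag 0.
    """
    sigma = np.sqrt(params.fb / 2.0) * scale   # envelope sd in samples
    half = max(int(np.ceil(5.0 * sigma)), 1)
    k = np.arange(-half, half + 1)
    t = k / scale
    return (np.pi * params.fb) ** -0.5 * np.exp(-(t ** 2) / params.fb) \
        * np.exp(2j * np.pi * params.fc * t)


def cwt_row(x: np.ndarray, params: CWTParams, freq_hz: float, fs: float) -> np.ndarray:
    """Complex CWT coefficients at one frequency (length of ``x``)."""
    a = params.scale(freq_hz, fs)
    h = morlet_kernel(params, a)
    # conj(psi((tau - t)/a)) as a convolution kernel reduces to psi itself
    # (even Gaussian envelope, odd phase), so conv(x, psi) is the integral
    return signal.fftconvolve(x, h, mode="same") / (a * fs)


def compute_spectrogram(window_signal: np.ndarray, fs: float,
                        params: Optional[CWTParams] = None, **meta) -> Spectrogram:
    """Morlet-CWT magnitude spectrogram of one spontaneous window.

    Linear in the input amplitude (magnitude output).  Frequencies at or
    above Nyquist raise; windows shorter than two cycles of the lowest
    grid frequency warn but proceed (edge effects dominate there — the
    cone of influence is deliberately not masked).
    """
    params = params or CWTParams()
    x = np.asarray(window_signal, dtype=float)
    if x.ndim != 1:
        raise TimeFreqError("window_signal must be 1-D")
    if np.any(params.freqs >= fs / 2):
        raise TimeFreqError("frequency grid exceeds the Nyquist frequency")
    if x.size / fs < 2.0 / params.freqs.min():
        warnings.warn("window shorter than two cycles of the lowest frequency",
                      stacklevel=2)
    rows = np.empty((params.freqs.size, x.size))
    for i, f in enumerate(params.freqs):
        c = cwt_row(x, params, f, fs)
        rows[i] = np.abs(c) if params.magnitude else np.abs(c) ** 2
    return Spectrogram(values=rows, freqs=params.freqs.copy(),
                       times=np.arange(x.size) / fs,
                       meta={"f0": params.f0, "fb": params.fb,
                             "scale_rule": params.scale_rule,
                             "magnitude": params.magnitude, **meta})


def restrict_band(spec: Spectrogram, lo_hz: float, hi_hz: float) -> Spectrogram:
    """Keep only spectrogram rows with lo_hz <= f <= hi_hz."""
    mask = (spec.freqs >= lo_hz) & (spec.freqs <= hi_hz)
    if not np.any(mask):
        raise TimeFreqError(f"band [{lo_hz}, {hi_hz}] Hz does not intersect the grid")
    return Spectrogram(values=spec.values[mask], freqs=spec.freqs[mask],
                       times=spec.times.copy(), label=spec.label,
                       channel=spec.channel, nucleus=spec.nucleus,
                       meta={**spec.meta, "band": (lo_hz, hi_hz)})


@dataclass
class STAResult:
    lags: np.ndarray                  # s, symmetric about 0
    unit_traces: dict                 # context -> (units x lags) array
    msta: dict                        # context -> mean trace across units
    spectra: dict                     # context -> (freqs, power)
    candidate_bands: list             # [(lo_hz, hi_hz), ...] ranked
    n_spikes: dict                    # context -> eligible spikes per unit


def spike_triggered_average(
    lfp_channel: np.ndarray,
    spike_trains: list,
    windows: list,
    fs: float,
    half_width_s: float = 0.08,
    band_range: tuple = (1.0, 50.0),
) -> STAResult:
    """Spike-triggered LFP averages within spontaneous windows, by context.

    Only spikes whose full ±``half_width_s`` neighbourhood lies inside a
    window are eligible; snippets are grouped by the window's label.
    The mean STA (mSTA) per context averages unit STAs; their power
    spectra are compared and contiguous frequency ranges of largest
    band-integrated absolute difference are returned, ranked.
    """
    lfp = np.asarray(lfp_channel, dtype=float)
    half = int(round(half_width_s * fs))
    lags = np.arange(-half, half + 1) / fs
    spans = {}
    for w in windows:
        spans.setdefault(w.label, []).append((w.start, w.end))

    unit_traces: dict = {}
    n_spikes: dict = {}
    for train in spike_trains:
        train = np.asarray(train, dtype=float)
        for label, intervals in spans.items():
            snips = []
            for t0, t1 in intervals:
                sel = train[(train - half_width_s >= t0) & (train + half_width_s <= t1)]
                for s in sel:
                    i = int(round(s * fs))
                    if i - half >= 0 and i + half + 1 <= lfp.size:
                        snips.append(lfp[i - half:i + half + 1])
            n_spikes.setdefault(label, []).append(len(snips))
            if snips:
                unit_traces.setdefault(label, []).append(np.mean(snips, axis=0))

    if not any(unit_traces.values()):
        raise TimeFreqError("no eligible spikes inside any spontaneous window")

    msta = {}
    spectra = {}
    for label, traces in unit_traces.items():
        unit_traces[label] = np.asarray(traces)
        msta[label] = unit_traces[label].mean(axis=0)
        f, p = signal.periodogram(msta[label], fs=fs, detrend="constant")
        spectra[label] = (f, p)

    candidate_bands: list = []
    if "airflow" in spectra and "touch" in spectra:
        f = spectra["airflow"][0]
        diff = np.abs(spectra["touch"][1] - spectra["airflow"][1])
        in_range = (f >= band_range[0]) & (f <= band_range[1])
        thresh = np.median(diff[in_range])
        above = in_range & (diff > thresh)
        runs = []
        start = None
        for i, flag in enumerate(above):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, above.size - 1))
        runs.sort(key=lambda r: -diff[r[0]:r[1] + 1].sum())
        candidate_bands = [(float(f[i0]), float(f[i1])) for i0, i1 in runs]

    return STAResult(lags=lags, unit_traces=unit_traces, msta=msta,
                     spectra=spectra, candidate_bands=candidate_bands,
                     n_spikes=n_spikes)
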
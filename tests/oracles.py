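"""Independent reference implementations (oracles) shared by tests.

Each function re-derives a quantity by a route independent of the
package implementation it is used to check: direct O(N^2) convolution
for the CWT, exhaustive offset search for stable-window selection, and
periodogram band integration for the simulated context effect.
"""

import numpy as np
from scipy.signal import periodogram

import spontlfp as sl


def direct_cwt_oracle(x, freqs, fs, f0=5.0, fb=None):
    """O(N^2) direct-sum CWT against the analytically sampled complex
    Morlet; independently re-derived from the wavelet definition."""
    fb = fb if fb is not None else 2.0 * (f0 / (2 * np.pi)) ** 2
    fc = f0 / (2 * np.pi)
    out = np.empty((len(freqs), len(x)), dtype=complex)
    n = len(x)
    for fi, f in enumerate(freqs):
        a = fc * fs / f
        sigma = np.sqrt(fb / 2.0) * a
        half = max(int(np.ceil(5 * sigma)), 1)
        for t in range(n):
            acc = 0.0 + 0.0j
            lo = max(t - half, 0)
            hi = min(t + half, n - 1)
            taus = np.arange(lo, hi + 1)
            u = (taus - t) / a
            psi = (np.pi * fb) ** -0.5 * np.exp(-u ** 2 / fb) * np.exp(2j * np.pi * fc * u)
            acc = np.sum(x[taus] * np.conj(psi))
            out[fi, t] = acc / (a * fs)
    return np.abs(out)


def brute_force_offset(session, segments, window_length, label):
    """Exhaustive-search oracle over every admissible sample offset."""
    segs = [s for s in segments if s.label == label and s.length >= window_length]
    fs = session.fs
    min_len = min(s.length for s in segs)
    n_t = int(np.floor(min_len * fs))
    trials = {}
    for s in segs:
        i0 = int(round(s.start * fs))
        trials.setdefault(s.trial_index, {})[s.channel] = \
            session.lfp[s.channel, i0:i0 + n_t].astype(float)
    chans = sorted({s.channel for s in segs})
    arr = np.array([[trials[t][c] for c in chans] for t in sorted(trials)])
    sd = arr.std(axis=0)
    sd = sd / sd.mean(axis=1, keepdims=True)
    agg = sd.mean(axis=0)
    wl = int(round(window_length * fs))
    step = int(round(0.01 * fs))
    best, best_score = None, np.inf
    for off in range(0, agg.size - wl + 1, step):
        score = agg[off:off + wl].mean()
        if score < best_score - 1e-15:
            best, best_score = off, score
    return best / fs


def band_power_ratio(session, lo=10.0, hi=25.0, skip_s=0.5, channel=0):
    """Independent periodogram oracle: mean band-integrated power of the
    late portion of each ISI segment, touch / airflow."""
    fs = session.fs
    power = {"airflow": [], "touch": []}
    for seg in sl.extract_isi_segments(session):
        if seg.channel != channel:
            continue
        i0 = int(round((seg.start + skip_s) * fs))
        i1 = int(round(seg.end * fs))
        if i1 - i0 < 2 * fs:
            continue
        f, p = periodogram(session.lfp[channel, i0:i1].astype(float), fs=fs,
                           detrend="linear")
        m = (f >= lo) & (f <= hi)
        power[seg.label].append(np.trapezoid(p[m], f[m]))
    return np.mean(power["touch"]) / np.mean(power["airflow"])
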
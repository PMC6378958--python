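"""Spectral estimation, filtering, referencing and resampling.

All filters are applied with zero phase lag. The evoked-response low-pass is
a linear-phase FIR designed by frequency sampling with a squared-cosine
rolloff; its two design constants (transition width as a fraction of the
upper passband edge, and the duration-bandwidth product fixing the filter
length) are frozen so that the default 0-32 Hz, 60 dB design at 1100 Hz
reports a 1135 ms full transient and a 92 ms 99%-energy transient. The
filter transients are first-class metadata: epoching and averaging can
refuse edge-contaminated samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core_io import ChannelKind, Recording, logger

# frozen FIR design constants (see design_fir)
_TRANSITION_FRACTION = 0.0672   # transition band / upper passband edge
_TIME_BANDWIDTH = 4.884         # filter duration (s) × transition width (Hz)


# ---------------------------------------------------------------------------
# Welch power spectral density
# ---------------------------------------------------------------------------

@dataclass
class PSDResult:
    """Welch periodogram average: channel × frequency power density."""

    psd: np.ndarray            # (n_channels, n_freqs), unit²/Hz
    freqs: np.ndarray          # Hz
    ch_names: list
    window_s: float
    overlap: float
    n_segments: int

    def to_tsv(self, path) -> None:
        lines = ["channel\tfrequency\tpower"]
        for i, name in enumerate(self.ch_names):
            for f, p in zip(self.freqs, self.psd[i]):
                lines.append(f"{name}\t{f:.6f}\t{p:.10e}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def welch_psd(rec: Recording, window_s: float = 3.0, overlap: float = 0.5,
              exclude_bad: bool = True) -> PSDResult:
    """Welch PSD (Hann window) over segments fully inside good data.

    Bad segments split the recording into good spans; spans shorter than one
    window are skipped; spans are combined weighting by their segment counts.
    Density scaling: the integral of the PSD over frequency approximates the
    signal variance.
    """
    nperseg = int(round(window_s * rec.sfreq))
    noverlap = int(round(nperseg * overlap))
    picks = rec.picks((ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD, ChannelKind.EEG,
                       ChannelKind.EOG, ChannelKind.ECG), good_only=exclude_bad)
    if len(picks) == 0:
        raise ValueError("no channels to estimate")
    mask = rec.good_sample_mask() if exclude_bad else np.ones(rec.n_samples, bool)
    # contiguous good spans
    spans = []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(rec.n_samples)
    acc = None
    total_segments = 0
    freqs = None
    step = nperseg - noverlap
    for s, e in zip(starts, ends):
        if e - s < nperseg:
            continue
        n_seg = (e - s - noverlap) // step
        freqs, p = signal.welch(rec.data[picks, s:e], fs=rec.sfreq, window="hann",
                                nperseg=nperseg, noverlap=noverlap, axis=1)
        acc = p * n_seg if acc is None else acc + p * n_seg
        total_segments += n_seg
    if acc is None:
        raise ValueError("no good span longer than one window")
    return PSDResult(acc / total_segments, freqs, [rec.ch_names[i] for i in picks],
                     window_s, overlap, total_segments)


# ---------------------------------------------------------------------------
# notch filtering
# ---------------------------------------------------------------------------

def notch_filter(rec: Recording, freqs=(50.0, 100.0, 150.0, 200.0),
                 bandwidth: float = 1.0) -> Recording:
    """Zero-phase 4th-order IIR notch at each frequency (power line + harmonics).

    Each notch is a cascade of two identical biquads (total order 4, -3 dB
    bandwidth ``bandwidth``) applied forward-backward. Bad channels and
    non-data channels pass through untouched.
    """
    out = rec.copy()
    nyq = rec.sfreq / 2
    picks = rec.picks((ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD, ChannelKind.EEG,
                       ChannelKind.EOG, ChannelKind.ECG), good_only=True)
    if len(picks) == 0:
        return out
    for f0 in freqs:
        if f0 >= nyq:
            raise ValueError(f"notch frequency {f0} above Nyquist {nyq}")
        b, a = signal.iirnotch(f0, f0 / bandwidth, fs=rec.sfreq)
        sos = np.vstack([signal.tf2sos(b, a)] * 2)  # order 4 total
        out.data[picks] = signal.sosfiltfilt(sos, out.data[picks], axis=1)
    return out


# ---------------------------------------------------------------------------
# FIR design / application
# ---------------------------------------------------------------------------

@dataclass
class FilterSpec:
    """A linear-phase FIR with its transient-duration metadata."""

    kind: str                   # lowpass | highpass | bandpass | bandstop
    edges: tuple                # passband edges, Hz
    attenuation_db: float
    sfreq: float
    coefficients: np.ndarray = field(repr=False)
    order: int = 0
    transient_full: float = 0.0  # seconds, one-sided (= group delay)
    transient_99: float = 0.0    # seconds, one-sided 99%-energy half-width

    def to_dict(self) -> dict:
        return {"kind": self.kind, "edges": list(self.edges),
                "attenuation_db": self.attenuation_db, "sfreq": self.sfreq,
                "order": self.order, "transient_full": self.transient_full,
                "transient_99": self.transient_99}


def _freq_sampled_fir(numtaps: int, sfreq: float, response) -> np.ndarray:
    """Linear-phase FIR from a zero-phase target magnitude response."""
    n = 1 << int(np.ceil(np.log2(numtaps * 8)))
    f = np.fft.rfftfreq(n, 1.0 / sfreq)
    H = response(f)
    h = np.fft.irfft(H)
    return np.roll(h, numtaps // 2)[:numtaps]


def _rolloff(f, edge, trans, rising):
    """Squared-cosine transition ramp over [edge, edge+trans] (or mirrored)."""
    H = np.zeros_like(f)
    if rising:  # high-pass edge: 0 below, 1 above
        H[f >= edge + trans] = 1.0
        m = (f > edge) & (f < edge + trans)
        H[m] = np.sin(0.5 * np.pi * (f[m] - edge) / trans) ** 2
    else:       # low-pass edge: 1 below, 0 above
        H[f <= edge] = 1.0
        m = (f > edge) & (f < edge + trans)
        H[m] = np.cos(0.5 * np.pi * (f[m] - edge) / trans) ** 2
    return H


def design_fir(kind: str, passband, attenuation_db: float = 60.0,
               sfreq: float = 1100.0) -> FilterSpec:
    """Design the pipeline's even-order linear-phase FIR.

    ``passband`` is ``(0, f_hi)`` for lowpass, ``(f_lo, None)`` for highpass,
    ``(f_lo, f_hi)`` for bandpass. The transition band is a frozen fraction
    of the governing edge and fixes the filter length through a frozen
    duration-bandwidth product scaled by the requested attenuation (lower
    attenuation → shorter filter). Reports ``transient_full`` (group delay)
    and ``transient_99`` (half-width of the centered interval holding 99% of
    the impulse-response energy).
    """
    nyq = sfreq / 2
    lo, hi = passband
    lo = None if (lo is None or lo <= 0) else float(lo)
    hi = None if hi is None else float(hi)
    if hi is not None and hi >= nyq:
        raise ValueError(f"passband edge {hi} at or above Nyquist {nyq}")
    governing = hi if hi is not None else lo
    if governing is None:
        raise ValueError("at least one passband edge required")
    trans = _TRANSITION_FRACTION * governing
    if trans <= 0:
        raise ValueError("transition band collapsed to zero")
    if hi is not None and hi + trans >= nyq:
        raise ValueError("transition band exceeds Nyquist; lower the edge")
    numtaps = int(np.ceil(_TIME_BANDWIDTH * (attenuation_db / 60.0) * sfreq / trans))
    if numtaps % 2 == 0:
        numtaps += 1  # even order, type I
    if lo is None:
        name = "lowpass"
        resp = lambda f: _rolloff(f, hi, trans, rising=False)
    elif hi is None:
        name = "highpass"
        resp = lambda f: _rolloff(f, lo - trans, trans, rising=True)
    else:
        name = "bandpass"
        lo_trans = _TRANSITION_FRACTION * lo
        resp = lambda f: (_rolloff(f, lo - lo_trans, lo_trans, rising=True)
                          * _rolloff(f, hi, trans, rising=False))
    if kind not in (name, "auto"):
        raise ValueError(f"passband {passband} implies {name!r}, not {kind!r}")
    h = _freq_sampled_fir(numtaps, sfreq, resp)
    order = numtaps - 1
    # shortest centered interval with 99% of the energy, one-sided half-width
    e = h * h
    c = numtaps // 2
    total = e.sum()
    cum, k = e[c], 0
    while cum < 0.99 * total and k < c:
        k += 1
        cum += e[c - k] + e[c + k]
    return FilterSpec(name, tuple(x for x in (lo, hi) if x is not None),
                      attenuation_db, sfreq, h, order,
                      (order / 2) / sfreq, k / sfreq)


def apply_fir(data: np.ndarray, spec: FilterSpec, edge_flag: str = "energy99"):
    """Zero-phase FIR application with edge-contamination metadata.

    Returns ``(filtered, valid_mask)``: the linear-phase delay is compensated
    (symmetric kernel, 'same' convolution) and samples within the transient
    of either edge are masked out. ``edge_flag`` picks which transient is
    flagged: ``energy99`` (default; the 99%-energy half-width governs what
    epoch cropping must discard) or ``full``.
    """
    data = np.asarray(data, float)
    squeeze = data.ndim == 1
    data = np.atleast_2d(data)
    n = data.shape[-1]
    if n <= spec.order // 2:
        raise ValueError(f"data length {n} <= half filter length {spec.order // 2}; "
                         "pad or filter the continuous data before epoching")
    out = signal.fftconvolve(data, spec.coefficients[None, :], mode="same", axes=-1)
    if squeeze:
        out = out[0]
    t_edge = spec.transient_99 if edge_flag == "energy99" else spec.transient_full
    k = int(np.ceil(t_edge * spec.sfreq))
    valid = np.ones(n, bool)
    valid[:k] = False
    if k > 0:
        valid[-k:] = False
    return out, valid


def lowpass_recording(rec: Recording, f_hi: float = 32.0,
                      attenuation_db: float = 60.0) -> tuple[Recording, FilterSpec]:
    """Low-pass the data channels of a recording; flag transient edges as bad."""
    from .core_io import BadSegment
    spec = design_fir("lowpass", (0, f_hi), attenuation_db, rec.sfreq)
    out = rec.copy()
    picks = rec.picks((ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD, ChannelKind.EEG),
                      good_only=True)
    filt, valid = apply_fir(rec.data[picks], spec)
    out.data[picks] = filt
    k = int(np.ceil(spec.transient_99 * rec.sfreq))
    t0 = rec.first_sample_time
    out.bad_segments.append(BadSegment(t0, t0 + k / rec.sfreq, "filter_edge_bad"))
    out.bad_segments.append(BadSegment(t0 + (rec.n_samples - k) / rec.sfreq,
                                       t0 + rec.duration, "filter_edge_bad"))
    return out, spec


# ---------------------------------------------------------------------------
# DC offset, referencing, resampling
# ---------------------------------------------------------------------------

def remove_dc_offset(data: np.ndarray, times: np.ndarray,
                     baseline=(-0.5, -0.0009)) -> np.ndarray:
    """Subtract the per-channel mean over the baseline latency window."""
    times = np.asarray(times)
    sel = (times >= baseline[0]) & (times <= baseline[1])
    if not sel.any():
        raise ValueError(f"baseline {baseline} contains no samples")
    data = np.asarray(data, float)
    return data - data[..., sel].mean(axis=-1, keepdims=True)


def rereference_average(rec: Recording):
    """Build (not apply) the average-reference projector over good EEG channels.

    Returned as a :class:`megevoke.ssp.Projector` whose matrix is
    ``I - 11ᵀ/n`` on the good EEG subset and identity elsewhere; removing it
    from the projector list recovers the original reference exactly.
    """
    from .ssp import Projector
    picks = rec.picks(ChannelKind.EEG, good_only=True)
    if len(picks) < 2:
        raise ValueError("average reference needs at least 2 good EEG channels")
    names = [rec.ch_names[i] for i in picks]
    n = len(picks)
    u = np.full((n, 1), 1.0 / np.sqrt(n))
    proj = Projector(name="eeg_average_reference", kind=ChannelKind.EEG,
                     ch_names=names, components=u, singular_values=np.array([1.0]),
                     active=[True])
    rec.projectors.append(proj)
    return proj


def resample(rec: Recording, new_sfreq: float = 275.0, max_denom: int = 1000) -> Recording:
    """Polyphase anti-aliased downsampling; event onsets (in seconds) unchanged."""
    if new_sfreq >= rec.sfreq:
        raise ValueError("new_sfreq must be below the current rate")
    from fractions import Fraction
    frac = Fraction(new_sfreq / rec.sfreq).limit_denominator(max_denom)
    if abs(float(frac) - new_sfreq / rec.sfreq) > 1e-9:
        raise ValueError("resampling ratio is not a manageable rational number")
    up, down = frac.numerator, frac.denominator
    out = rec.copy()
    out.data = signal.resample_poly(rec.data, up, down, axis=1)
    out.sfreq = new_sfreq
    return out
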
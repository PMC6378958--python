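"""Morlet-wavelet time-frequency decomposition with edge masking and ERS/ERD.

Power is the squared modulus of the convolution with complex Morlet wavelets
on a log-spaced frequency grid. The mother wavelet is parameterized by its
center frequency fc (default 1 Hz) and temporal FWHM at fc (default 3 s);
at analysis frequency f the envelope scales by fc/f, trading temporal for
spectral resolution. Samples closer to an epoch edge than the wavelet
half-support (the point where the Gaussian envelope has decayed to e⁻¹ of
its peak, i.e. √2·σ_t) are masked invalid: for a [-500, 1200] ms epoch
analyzed down to 6 Hz this leaves the [-200, 900] ms window reliable.
ERS/ERD normalization expresses power as percent change from the
per-frequency baseline mean, which also flattens the 1/f background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class TFMap:
    """channels × frequencies × samples power with validity mask."""

    power: np.ndarray
    freqs: np.ndarray
    latencies: np.ndarray
    valid: np.ndarray              # (n_freqs, n_samples) edge-effect mask
    ch_names: list
    normalization: str = "none"    # none | ersd
    n_trials: int = 1

    def copy(self) -> "TFMap":
        return TFMap(self.power.copy(), self.freqs.copy(), self.latencies.copy(),
                     self.valid.copy(), list(self.ch_names), self.normalization,
                     self.n_trials)

    def to_tsv(self, path) -> None:
        lines = ["channel\tfrequency\tlatency\tpower\tvalid"]
        for c, name in enumerate(self.ch_names):
            for fi, f in enumerate(self.freqs):
                for ti, t in enumerate(self.latencies):
                    lines.append(f"{name}\t{f:.4f}\t{t:.6f}\t"
                                 f"{self.power[c, fi, ti]:.8e}\t{int(self.valid[fi, ti])}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def make_freq_grid(fmin: float = 6.0, fmax: float = 60.0, n: int = 20,
                   sfreq: float | None = None) -> np.ndarray:
    """n log-spaced analysis frequencies, endpoints inclusive."""
    if not 0 < fmin < fmax:
        raise ValueError("need 0 < fmin < fmax")
    if n < 2:
        raise ValueError("need at least 2 frequency bins")
    if sfreq is not None and fmax >= sfreq / 2:
        raise ValueError(f"fmax {fmax} at or above Nyquist {sfreq / 2}")
    return np.geomspace(fmin, fmax, n)


def _morlet(f: float, sfreq: float, fc: float, fwhm_tc: float):
    """Unit-energy complex Morlet at frequency f; returns (wavelet, sigma_t)."""
    sigma = fwhm_tc * _FWHM_TO_SIGMA * fc / f
    half = int(np.ceil(5 * sigma * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(2j * np.pi * f * t) * np.exp(-t ** 2 / (2 * sigma ** 2))
    w /= np.sqrt(np.sum(np.abs(w) ** 2) / sfreq)
    return w, sigma


def morlet_tf(data: np.ndarray, latencies: np.ndarray, grid: np.ndarray,
              sfreq: float, fc: float = 1.0, fwhm_tc: float = 3.0,
              ch_names: list | None = None) -> TFMap:
    """Morlet power of a channels × samples epoch on the frequency grid.

    The validity mask excludes samples within √2·σ_t(f) of either epoch
    edge; frequencies whose wavelet outlasts the whole epoch come back
    fully masked (with a warning) rather than failing.
    """
    from .core_io import logger
    data = np.atleast_2d(np.asarray(data, float))
    n_ch, n_s = data.shape
    power = np.empty((n_ch, len(grid), n_s))
    valid = np.zeros((len(grid), n_s), bool)
    t0, t1 = latencies[0], latencies[-1]
    for fi, f in enumerate(np.asarray(grid, float)):
        w, sigma = _morlet(f, sfreq, fc, fwhm_tc)
        half_support = np.sqrt(2.0) * sigma
        coef = signal.fftconvolve(data, w[None, :], mode="same", axes=1)
        power[:, fi] = np.abs(coef) ** 2
        valid[fi] = (latencies >= t0 + half_support) & (latencies <= t1 - half_support)
        if not valid[fi].any():
            logger.warning("epoch too short for %.2f Hz wavelet: bin fully masked", f)
    return TFMap(power, np.asarray(grid, float), np.asarray(latencies, float),
                 valid, ch_names or [f"ch{i}" for i in range(n_ch)])


def average_tf(tfmaps: list) -> TFMap:
    """Mean power across trials; masks intersect, trial count recorded."""
    ref = tfmaps[0]
    for m in tfmaps[1:]:
        if (m.power.shape != ref.power.shape
                or not np.allclose(m.freqs, ref.freqs)
                or not np.allclose(m.latencies, ref.latencies)):
            raise ValueError("TF maps have mismatched grids")
        if m.normalization != ref.normalization:
            raise ValueError("cannot average maps with different normalizations")
    out = ref.copy()
    out.power = np.mean([m.power for m in tfmaps], axis=0)
    out.valid = np.logical_and.reduce([m.valid for m in tfmaps])
    out.n_trials = sum(m.n_trials for m in tfmaps)
    return out


def ersd_normalize(tf: TFMap, baseline=(-0.2, -0.005)) -> TFMap:
    """Event-related (de)synchronization: percent power change from baseline.

    Per channel and frequency: 100·(P(t,f) − μ_base(f))/μ_base(f), with the
    baseline mean taken over valid baseline samples only.
    """
    lat = tf.latencies
    sel = (lat >= baseline[0]) & (lat <= baseline[1])
    if not sel.any():
        raise ValueError(f"baseline {baseline} outside the epoch")
    out = tf.copy()
    for fi in range(len(tf.freqs)):
        use = sel & tf.valid[fi]
        if not use.any():
            raise ValueError(f"baseline entirely masked at {tf.freqs[fi]:.2f} Hz")
        mu = tf.power[:, fi, use].mean(axis=1, keepdims=True)
        if (mu == 0).any():
            raise ValueError("zero baseline mean power")
        out.power[:, fi, :] = 100.0 * (tf.power[:, fi, :] - mu) / mu
    out.normalization = "ersd"
    return out
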
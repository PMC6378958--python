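"""Noise covariance and minimum-norm source estimation.

The weighted minimum-norm estimate (WMNE) is the Tikhonov-regularized linear
inverse K = R Gᵀ (G R Gᵀ + λ²C)⁻¹ with a diagonal depth prior
R_jj = ‖g_j‖^(−2γ) (clipped at a maximum ratio) and λ² set from an assumed
amplitude SNR via the trace convention λ² = tr(G R Gᵀ)/(snr²·tr(C)).
Internally the computation is whitened by the Cholesky factor of the
regularized covariance, which is algebraically identical to the stated
formula. dSPM and sLORETA rescale the kernel rows into dimensionless
statistical maps: dSPM by the estimated noise standard deviation of each
source (unit variance on pure noise), sLORETA by the square root of the
resolution-weighted variance diag(K G R) (zero localization error for a
single noiseless source). The source estimate is always a pure linear
operator applied to the sensor traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .core_io import ChannelKind, Recording, logger
from .epoch_average import EpochSet
from .head_model import GainMatrix
from .ssp import apply_projectors

DEPTH_CLIP_RATIO = 10.0  # max R_jj relative to the smallest prior weight


@dataclass
class NoiseCovariance:
    """Sensor noise second-order statistics (channels × channels)."""

    matrix: np.ndarray
    ch_names: list
    source: str                 # empty_room | baseline
    n_samples: int
    regularization: float = 0.0

    def __post_init__(self):
        m = self.matrix
        if not np.allclose(m, m.T, atol=1e-12 * max(1.0, np.abs(m).max())):
            raise ValueError("covariance must be symmetric")


def estimate_noise_cov(source, mode: str, picks=None) -> NoiseCovariance:
    """Sample covariance of noise-only data, mean removed.

    ``mode="empty_room"``: good samples of an empty-room :class:`Recording`.
    ``mode="baseline"``: per-trial pre-stimulus baselines of an
    :class:`EpochSet` concatenated across good trials.
    """
    if mode == "empty_room":
        rec: Recording = source
        if picks is None:
            picks = rec.picks((ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD,
                               ChannelKind.EEG), good_only=True)
        data = rec.data[np.ix_(picks, np.flatnonzero(rec.good_sample_mask()))]
        names = [rec.ch_names[i] for i in picks]
    elif mode == "baseline":
        epochs: EpochSet = source
        sel = epochs.latencies < 0
        block = epochs.good_data()[:, :, sel]          # trials × ch × samples
        data = np.concatenate(list(block), axis=1)
        names = list(epochs.ch_names)
        if picks is not None:
            data = data[picks]
            names = [names[i] for i in picks]
    else:
        raise ValueError(f"unknown noise-covariance mode {mode!r}")
    n = data.shape[1]
    if n < data.shape[0]:
        logger.warning("fewer noise samples (%d) than channels (%d): "
                       "regularization is mandatory", n, data.shape[0])
    data = data - data.mean(axis=1, keepdims=True)
    C = data @ data.T / (n - 1)
    return NoiseCovariance(C, names, mode, n)


def regularize_cov(cov: NoiseCovariance, fraction: float = 0.1,
                   kinds_of: dict | None = None) -> NoiseCovariance:
    """Diagonal loading per channel kind.

    Adds ``fraction × mean(diagonal of that kind)`` to each diagonal entry so
    heterogeneous sensor units (T, T/m, V) are each loaded on their own scale.
    ``kinds_of`` maps channel name → kind string; one pooled group otherwise.
    """
    if fraction < 0:
        raise ValueError("regularization fraction must be nonnegative")
    C = cov.matrix.copy()
    if fraction > 0:
        diag = np.diag(C).copy()
        if kinds_of:
            groups: dict[str, list[int]] = {}
            for i, name in enumerate(cov.ch_names):
                groups.setdefault(str(kinds_of.get(name, "all")), []).append(i)
        else:
            groups = {"all": list(range(len(cov.ch_names)))}
        for idxs in groups.values():
            load = fraction * diag[idxs].mean()
            C[idxs, idxs] += load
    return NoiseCovariance(C, list(cov.ch_names), cov.source, cov.n_samples, fraction)


@dataclass
class InverseKernel:
    """Pre-computed linear inverse: source estimate = K · sensor data."""

    kernel: np.ndarray            # (n_sources, n_channels)
    ch_names: list
    method: str                   # wmne | dspm | sloreta
    depth_gamma: float
    lambda2: float
    snr: float
    constrained: bool = True
    extras: dict = field(default_factory=dict)

    def apply(self, data: np.ndarray) -> np.ndarray:
        return self.kernel @ data


@dataclass
class SourceEstimate:
    """Sources × samples currents (A·m) or dimensionless statistic maps."""

    data: np.ndarray
    latencies: np.ndarray
    method: str
    units: str = "Am"
    standardization: str = "none"


def _depth_prior(G: np.ndarray, gamma: float, clip_ratio: float = DEPTH_CLIP_RATIO):
    power = (G ** 2).sum(axis=0)
    if (power <= 0).all():
        raise ValueError("all gain columns are zero")
    if (power <= 0).any():
        # e.g. near-radial sources in a spherical MEG model: the clip keeps
        # their prior finite instead of excluding them from the source space
        logger.warning("%d zero-norm gain columns; prior clipped",
                       int((power <= 0).sum()))
    if gamma <= 0:
        return np.ones_like(power)
    with np.errstate(divide="ignore"):
        R = power ** (-gamma)
    return np.minimum(R, clip_ratio * power.max() ** (-gamma))


def compute_wmne_kernel(gain: GainMatrix, cov: NoiseCovariance,
                        depth_gamma: float = 0.5, snr: float = 3.0,
                        lambda2: float | None = None) -> InverseKernel:
    """Depth-weighted, regularized minimum-norm inverse kernel.

    Whitened evaluation of K = R Gᵀ (G R Gᵀ + λ²C)⁻¹ with
    λ² = tr(G R Gᵀ)/(snr²·tr(C)) unless given explicitly.
    """
    G = gain.matrix
    if not gain.constrained:
        raise ValueError("use a constrained (fixed-orientation) gain")
    if list(gain.ch_names) != list(cov.ch_names):
        raise ValueError("gain rows and covariance channels do not match")
    C = cov.matrix
    R = _depth_prior(G, depth_gamma)
    if lambda2 is None:
        lambda2 = float(np.trace((G * R) @ G.T) / (snr ** 2 * np.trace(C)))
    # whiten: C = L Lᵀ; Gw = L⁻¹G; K = R Gwᵀ (Gw R Gwᵀ + λ²I)⁻¹ L⁻¹
    L = scipy.linalg.cholesky(C, lower=True)
    Gw = scipy.linalg.solve_triangular(L, G, lower=True)
    M = (Gw * R) @ Gw.T + lambda2 * np.eye(G.shape[0])
    Kw = np.linalg.solve(M.T, (Gw * R)).T            # R Gwᵀ M⁻¹
    K = scipy.linalg.solve_triangular(L, Kw.T, lower=True, trans="T").T
    return InverseKernel(K, list(gain.ch_names), "wmne", depth_gamma,
                         lambda2, snr, True, {"R": R})


def standardize_kernel(kernel: InverseKernel, cov: NoiseCovariance,
                       method: str, gain: GainMatrix | None = None) -> InverseKernel:
    """Rescale WMNE rows into a dimensionless dSPM or sLORETA kernel."""
    K = kernel.kernel
    if method == "dspm":
        denom = np.einsum("ij,jk,ik->i", K, cov.matrix, K)
    elif method == "sloreta":
        if gain is None:
            raise ValueError("sLORETA needs the gain matrix")
        R = kernel.extras["R"]
        denom = np.einsum("ij,ji->i", K, gain.matrix * R)
    else:
        raise ValueError(f"unknown standardization {method!r}")
    zero_rows = ~K.any(axis=1)
    if ((denom <= 0) & ~zero_rows).any():
        raise ValueError("non-positive variance in kernel standardization")
    denom = np.where(zero_rows, 1.0, denom)  # silent sources stay zero
    Ks = K / np.sqrt(denom)[:, None]
    return InverseKernel(Ks, list(kernel.ch_names), method, kernel.depth_gamma,
                         kernel.lambda2, kernel.snr, kernel.constrained,
                         dict(kernel.extras))


def apply_inverse(kernel: InverseKernel, data: np.ndarray, latencies: np.ndarray,
                  projectors=(), ch_names=None) -> SourceEstimate:
    """Project sensor data through the inverse kernel (projectors first)."""
    if projectors:
        data = apply_projectors(data, projectors, ch_names or kernel.ch_names)
    units = "Am" if kernel.method == "wmne" else "dimensionless"
    return SourceEstimate(kernel.apply(data), np.asarray(latencies), kernel.method,
                          units, "none" if kernel.method == "wmne" else kernel.method)


def zscore_baseline(est: SourceEstimate, baseline=(-0.2, -0.005)) -> SourceEstimate:
    """Standardize each source trace by its pre-stimulus mean and s.d. over time."""
    lat = est.latencies
    sel = (lat >= baseline[0]) & (lat <= baseline[1])
    if not sel.any():
        raise ValueError(f"baseline {baseline} outside the latency grid")
    mu = est.data[:, sel].mean(axis=1, keepdims=True)
    sd = est.data[:, sel].std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd[:, 0] == 0)
    if zero.size:
        raise ValueError(f"zero baseline variance for sources {zero[:10].tolist()}")
    return SourceEstimate((est.data - mu) / sd, lat.copy(), est.method,
                          "dimensionless", "zscore")
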
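"""Minimum-norm inversion: dense-formula oracles and statistical properties."""

import numpy as np
import pytest

from megevoke.core_io import ChannelKind
from megevoke.epoch_average import make_epochs
from megevoke.head_model import GainMatrix, SphereModel, icosphere
from megevoke.inverse import (InverseKernel, NoiseCovariance, SourceEstimate,
                              apply_inverse, compute_wmne_kernel,
                              estimate_noise_cov, regularize_cov,
                              standardize_kernel, zscore_baseline)
from conftest import make_recording


def toy_gain(n_ch=16, n_src=30, seed=0, mesh=None):
    rng = np.random.default_rng(seed)
    if mesh is None:
        mesh = icosphere(1, radius=0.05)
    G = rng.standard_normal((n_ch, n_src))
    # give sources distinct "depths" (column norms)
    G *= rng.uniform(0.2, 2.0, n_src)
    return GainMatrix(G, [f"CH{i:03d}" for i in range(n_ch)], mesh, True)


def toy_cov(n_ch=16, seed=1, sigma=1.0):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n_ch, 2 * n_ch))
    C = sigma ** 2 * (A @ A.T) / (2 * n_ch)
    return NoiseCovariance(C, [f"CH{i:03d}" for i in range(n_ch)], "empty_room",
                           10000)


class TestNoiseCovariance:
    def test_white_noise_diagonal(self):
        rng = np.random.default_rng(0)
        n, T = 6, 50000
        rec = make_recording(2.0 * rng.standard_normal((n, T)), 600.0,
                             [ChannelKind.MEG_MAG] * n)
        cov = estimate_noise_cov(rec, "empty_room")
        se = 4.0 * np.sqrt(2.0 / T)
        assert np.abs(np.diag(cov.matrix) - 4.0).max() < 3 * se
        off = cov.matrix[~np.eye(n, dtype=bool)]
        assert np.abs(off).max() < 3 * 4.0 / np.sqrt(T)

    def test_correlated_channels_rank_deficient(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(5000)
        rec = make_recording(np.vstack([x, x]), 600.0, [ChannelKind.MEG_MAG] * 2)
        cov = estimate_noise_cov(rec, "empty_room")
        assert np.linalg.matrix_rank(cov.matrix, tol=1e-10) == 1

    def test_baseline_mode_equals_direct_formula(self):
        rng = np.random.default_rng(2)
        rec = make_recording(rng.standard_normal((3, 40000)), 600.0,
                             [ChannelKind.EEG] * 3)
        from megevoke.core_io import Event, EventList
        events = EventList([Event("A", t) for t in [10.0, 20.0, 30.0]])
        epochs = make_epochs(rec, events)
        cov = estimate_noise_cov(epochs, "baseline")
        sel = epochs.latencies < 0
        block = np.concatenate(list(epochs.good_data()[:, :, sel]), axis=1)
        block = block - block.mean(axis=1, keepdims=True)
        expected = block @ block.T / (block.shape[1] - 1)
        assert np.abs(cov.matrix - expected).max() < 1e-12

    def test_regularize_fraction_zero_identity(self):
        cov = toy_cov()
        out = regularize_cov(cov, 0.0)
        assert np.array_equal(out.matrix, cov.matrix)

    def test_singular_becomes_invertible(self):
        C = np.ones((3, 3))
        cov = NoiseCovariance(C, ["A", "B", "C"], "empty_room", 100)
        out = regularize_cov(cov, 0.1)
        assert np.linalg.cond(out.matrix) < 1e3
        assert np.linalg.eigvalsh(out.matrix).min() >= 0.1 * 1.0 - 1e-12

    def test_per_kind_loading_scales(self):
        C = np.diag([1.0, 1.0, 1e6, 1e6])
        cov = NoiseCovariance(C, ["M1", "M2", "G1", "G2"], "empty_room", 100)
        kinds = {"M1": "MAG", "M2": "MAG", "G1": "GRAD", "G2": "GRAD"}
        out = regularize_cov(cov, 0.1, kinds)
        assert out.matrix[0, 0] == pytest.approx(1.1)
        assert out.matrix[2, 2] == pytest.approx(1.1e6)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            regularize_cov(toy_cov(), -0.1)


class TestWMNE:
    def test_exact_inverse_limit(self):
        """γ=0, λ²→0, square well-conditioned gain: K → G⁻¹."""
        rng = np.random.default_rng(3)
        n = 10
        G = rng.standard_normal((n, n)) + 3 * np.eye(n)
        gain = GainMatrix(G, [f"CH{i:03d}" for i in range(n)],
                          icosphere(0, radius=0.05), True)
        cov = NoiseCovariance(np.eye(n), gain.ch_names, "empty_room", 1000)
        kern = compute_wmne_kernel(gain, cov, depth_gamma=0.0, lambda2=1e-12)
        assert np.abs(kern.kernel @ G - np.eye(n)).max() < 1e-6

    def test_matches_dense_formula(self):
        """Whitened computation equals brute-force R Gᵀ (G R Gᵀ + λ²C)⁻¹."""
        gain, cov = toy_gain(), toy_cov()
        kern = compute_wmne_kernel(gain, cov, depth_gamma=0.5, snr=3.0)
        G, C = gain.matrix, cov.matrix
        R = kern.extras["R"]
        lam2 = kern.lambda2
        dense = (R[:, None] * G.T) @ np.linalg.inv((G * R) @ G.T + lam2 * C)
        assert np.abs(kern.kernel - dense).max() < 1e-10 * np.abs(dense).max()
        assert lam2 == pytest.approx(np.trace((G * R) @ G.T) / (9.0 * np.trace(C)))

    def test_depth_weighting_monotone(self):
        gain = toy_gain(seed=4)
        cov = toy_cov(seed=5)
        kern = compute_wmne_kernel(gain, cov, depth_gamma=0.5)
        R = kern.extras["R"]
        norms = np.linalg.norm(gain.matrix, axis=0)
        # stronger (shallower) source -> smaller prior weight, up to the clip
        i, j = np.argmax(norms), np.argmin(norms)
        assert R[i] < R[j]

    def test_kernel_linearity(self):
        gain, cov = toy_gain(), toy_cov()
        kern = compute_wmne_kernel(gain, cov)
        rng = np.random.default_rng(6)
        y1, y2 = rng.standard_normal((2, 16, 40))
        lhs = kern.apply(2.0 * y1 + y2)
        rhs = 2.0 * kern.apply(y1) + kern.apply(y2)
        assert np.abs(lhs - rhs).max() < 1e-9 * np.abs(lhs).max()

    def test_channel_mismatch_rejected(self):
        gain = toy_gain()
        cov = toy_cov(n_ch=12)
        with pytest.raises(ValueError, match="do not match"):
            compute_wmne_kernel(gain, cov)


def sphere_meg_setup(subdiv=1, seed=0, tangential=True):
    """Constrained tangential source space in a sphere with a MAG helmet."""
    from megevoke.head_model import assemble_gain
    from megevoke.core_io import ChannelInfo
    cortex = icosphere(subdiv, radius=0.055)
    # tangential unit orientations (rotate radial by 90° about a fixed axis)
    radial = cortex.vertices / np.linalg.norm(cortex.vertices, axis=1, keepdims=True)
    helper = np.array([0.3, 0.5, 0.8])
    tang = np.cross(radial, helper)
    cortex.normals = tang / np.linalg.norm(tang, axis=1, keepdims=True)
    sphere = SphereModel([0, 0, 0], 0.09)
    rng = np.random.default_rng(seed)
    channels = []
    from megevoke.simulate import _fibonacci_cap
    for i, p in enumerate(_fibonacci_cap(40, 0.12, -0.06)):
        channels.append(ChannelInfo(f"MEG{i:03d}", ChannelKind.MEG_MAG, "T", p,
                                    p / np.linalg.norm(p)))
    gain = assemble_gain(cortex, channels, meg_sphere=sphere, constrained=True)
    return gain, cortex


class TestStandardization:
    def test_dspm_unit_variance_on_noise(self):
        """dSPM maps pure noise with covariance C to unit-variance sources."""
        gain, cov = toy_gain(), toy_cov(seed=7)
        kern = compute_wmne_kernel(gain, cov)
        dspm = standardize_kernel(kern, cov, "dspm")
        rng = np.random.default_rng(8)
        L = np.linalg.cholesky(cov.matrix)
        noise = L @ rng.standard_normal((16, 60000))
        est = dspm.kernel @ noise
        v = est.var(axis=1)
        assert np.abs(v - 1.0).max() < 0.05

    def test_sloreta_zero_localization_error(self):
        """Noiseless single-source sweep: the sLORETA maximum sits exactly at
        the active source (its defining property)."""
        gain, _ = sphere_meg_setup()
        n_ch = gain.matrix.shape[0]
        cov = NoiseCovariance(np.eye(n_ch) * 1e-26, gain.ch_names, "empty_room", 1000)
        kern = compute_wmne_kernel(gain, cov, depth_gamma=0.0, snr=1e4)
        slor = standardize_kernel(kern, cov, "sloreta", gain)
        misses = 0
        for j in range(gain.n_sources):
            y = gain.matrix[:, [j]] * 1e-8
            est = np.abs(slor.kernel @ y)[:, 0]
            misses += int(np.argmax(est) != j)
        assert misses == 0

    def test_dspm_scaling_linearity(self):
        gain, cov = toy_gain(), toy_cov()
        dspm = standardize_kernel(compute_wmne_kernel(gain, cov), cov, "dspm")
        y = np.random.default_rng(9).standard_normal((16, 5))
        assert np.allclose(dspm.kernel @ (10 * y), 10 * (dspm.kernel @ y))

    def test_wmne_single_source_recovery(self):
        """Median peak-localization error ≤ 2 mesh edges over 20 sims at SNR 3;
        dSPM never (median-)worse than WMNE on the same simulations."""
        gain, cortex = sphere_meg_setup()
        n_ch = gain.matrix.shape[0]
        rng = np.random.default_rng(10)
        sigma = 1.0
        cov = NoiseCovariance(np.eye(n_ch) * sigma ** 2, gain.ch_names,
                              "empty_room", 10000)
        kern = compute_wmne_kernel(gain, cov, depth_gamma=0.5, snr=3.0)
        dspm = standardize_kernel(kern, cov, "dspm")
        edge = cortex.mean_edge_length()
        verts = cortex.vertices
        errs_w, errs_d = [], []
        for _ in range(20):
            j = rng.integers(gain.n_sources)
            y_clean = gain.matrix[:, [j]]
            scale = 3.0 * sigma / np.linalg.norm(y_clean) * np.sqrt(n_ch)
            y = scale * y_clean + sigma * rng.standard_normal((n_ch, 1))
            for K, errs in ((kern.kernel, errs_w), (dspm.kernel, errs_d)):
                peak = np.argmax(np.abs(K @ y)[:, 0])
                errs.append(np.linalg.norm(verts[peak] - verts[j]))
        assert np.median(errs_w) <= 2 * edge
        assert np.median(errs_d) <= np.median(errs_w) + 1e-12


class TestZScore:
    def _est(self, seed=0):
        rng = np.random.default_rng(seed)
        lat = np.arange(int(-0.2 * 600), int(0.9 * 600)) / 600.0
        data = rng.standard_normal((5, len(lat)))
        return SourceEstimate(data, lat, "wmne")

    def test_baseline_mean_zero_sd_one(self):
        z = zscore_baseline(self._est(), (-0.2, -0.005))
        sel = (z.latencies >= -0.2) & (z.latencies <= -0.005)
        assert np.abs(z.data[:, sel].mean(axis=1)).max() < 1e-12
        assert np.abs(z.data[:, sel].std(axis=1, ddof=1) - 1).max() < 1e-12

    def test_constant_shift_maps_to_delta_over_sigma(self):
        est = self._est(seed=1)
        sel = est.latencies >= 0
        base = (est.latencies >= -0.2) & (est.latencies <= -0.005)
        mu = est.data[:, base].mean(axis=1)
        sd = est.data[:, base].std(axis=1, ddof=1)
        est.data[:, sel] = (mu + 3.0 * sd)[:, None]
        z = zscore_baseline(est, (-0.2, -0.005))
        assert np.abs(z.data[:, sel] - 3.0).max() < 1e-9

    def test_matches_two_pass_oracle(self):
        est = self._est(seed=2)
        z = zscore_baseline(est, (-0.2, -0.005))
        sel = (est.latencies >= -0.2) & (est.latencies <= -0.005)
        mu = est.data[:, sel].mean(axis=1, keepdims=True)
        sd = est.data[:, sel].std(axis=1, ddof=1, keepdims=True)
        assert np.abs(z.data - (est.data - mu) / sd).max() < 1e-12

    def test_zero_variance_trace_errors(self):
        est = self._est()
        est.data[2] = 5.0
        with pytest.raises(ValueError, match="zero baseline variance"):
            zscore_baseline(est, (-0.2, -0.005))


class TestApplyInverse:
    def test_projector_applied_before_kernel(self):
        from megevoke.ssp import Projector
        gain, cov = toy_gain(), toy_cov()
        kern = compute_wmne_kernel(gain, cov)
        rng = np.random.default_rng(11)
        u = rng.standard_normal((16, 1))
        u /= np.linalg.norm(u)
        proj = Projector("p", ChannelKind.MEG_MAG, kern.ch_names, u,
                         np.array([1.0]), [True])
        y = u @ rng.standard_normal((1, 20))  # lies entirely in the subspace
        est = apply_inverse(kern, y, np.arange(20) / 600.0, projectors=[proj])
        assert np.abs(est.data).max() < 1e-12
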
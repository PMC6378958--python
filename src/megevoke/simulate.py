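"""Synthetic multi-subject MEG/EEG datasets with known ground truth.

Emulates a face-perception evoked-response study: bit-coded stimulus
triggers (Familiar 5, Unfamiliar 13, Scrambled 17) with a 34.5 ms
presentation delay, an occipital dipolar source peaking ~100 ms in every
condition, a ventral face-sensitive source peaking ~155 ms with larger
amplitude for faces than scrambled images, blink and cardiac artifacts
mirrored on EOG/ECG channels, 1/f + line-frequency + white sensor noise,
optional cHPI sinusoids, several runs per subject and between-subject
amplitude/latency variability. Every injected quantity is recorded in a
:class:`GroundTruth` sufficient to predict the expected value of each
downstream estimate.

Sensor noise is scaled per channel kind so that the subject-average evoked
response reaches a configurable amplitude SNR (default 3) at the best
channel, matching the SNR assumption of the inverse operator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core_io import (BadSegment, ChannelInfo, ChannelKind, Event, EventList,
                      Recording)
from .head_model import (DEFAULT_CONDUCTIVITIES, GainMatrix, SphereModel,
                         SurfaceMesh, assemble_gain, icosphere)

CONDITION_CODES = {"Familiar": 5, "Unfamiliar": 13, "Scrambled": 17}


@dataclass
class SubjectSpec:
    """Generator parameters for one synthetic subject (desk scale defaults)."""

    n_runs: int = 3
    n_trials: int = 40                      # per condition per run
    conditions: tuple = ("Familiar", "Scrambled")
    sfreq: float = 1100.0
    n_meg_mag: int = 40
    n_meg_grad: int = 20
    n_eeg: int = 20
    cortex_subdiv: int = 2                  # icosphere level: 1→42, 2→162, 3→642
    isi_s: tuple = (1.1, 1.5)               # uniform inter-stimulus interval
    trigger_delay: float = 0.0345           # trigger-to-screen hardware delay
    trigger_pulse_s: float = 0.05
    evoked_snr: float = 3.0                 # single-trial peak amplitude SNR
    occipital_amp: float = 30e-9            # A·m
    occipital_latency: float = 0.100
    face_amp: float = 40e-9                 # face conditions
    scrambled_amp: float = 15e-9
    face_latency: float = 0.155
    blink_rate: float = 0.05                # Hz (Poisson)
    heart_rate: float = 1.2                 # Hz
    line_freq: float = 50.0
    chpi_start: float | None = None         # absolute seconds; None = no cHPI
    first_sample_time: float = 0.0
    amp_jitter_sd: float = 0.2              # between-subject, relative
    latency_jitter_sd: float = 0.010        # between-subject, seconds
    trial_jitter_sd: float = 0.1            # within-subject, relative
    bad_channels: tuple = ()                # names marked bad in every run
    pad_s: float = 3.0

    def run_duration(self) -> float:
        n = self.n_trials * len(self.conditions)
        return 2 * self.pad_s + n * self.isi_s[1]


@dataclass
class GroundTruth:
    """Everything injected: geometry, sources, schedules, artifacts, noise."""

    seed: int
    spec: dict
    source_vertices: dict = field(default_factory=dict)
    source_amplitudes: dict = field(default_factory=dict)
    source_latencies: dict = field(default_factory=dict)
    schedules: list = field(default_factory=list)        # per run: [(label, t_trigger)]
    blink_times: list = field(default_factory=list)      # per run
    heartbeat_times: list = field(default_factory=list)  # per run
    noise_sd: dict = field(default_factory=dict)
    bad_channels: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# geometry and sensors
# ---------------------------------------------------------------------------

def make_head_geometry(cortex_subdiv: int = 2):
    """Scalp sphere mesh (r=9 cm), shell model and an ellipsoidal cortex.

    The cortex is an icosphere squashed to (6.0, 5.5, 5.0) cm semi-axes so
    vertex normals are not purely radial (radial dipoles are MEG-silent in a
    spherical conductor).
    """
    scalp = icosphere(3, radius=0.09)
    cortex = icosphere(cortex_subdiv, radius=1.0)
    axes = np.array([0.060, 0.055, 0.050])
    cortex.vertices = cortex.vertices * axes
    # analytic ellipsoid normals
    n = cortex.vertices / axes ** 2
    cortex.normals = n / np.linalg.norm(n, axis=1, keepdims=True)
    sphere = SphereModel(np.zeros(3), 0.09, shell_radii=(0.07, 0.08, 0.09),
                         conductivities=DEFAULT_CONDUCTIVITIES)
    return scalp, cortex, sphere


def _fibonacci_cap(n: int, radius: float, z_min: float) -> np.ndarray:
    """n roughly uniform points on the upper spherical cap above z_min."""
    i = np.arange(n)
    frac_cap = (1 - z_min / radius) / 2          # cap area fraction of sphere
    z = radius * (1 - 2 * frac_cap * (i + 0.5) / n)
    phi = np.pi * (1 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.maximum(radius ** 2 - z ** 2, 0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_sensor_array(spec: SubjectSpec) -> list[ChannelInfo]:
    """MEG helmet (radial magnetometers + planar gradiometers at 13 cm),
    EEG montage on the scalp sphere, plus EOG/ECG/STIM channels."""
    channels: list[ChannelInfo] = []
    meg_pos = _fibonacci_cap(spec.n_meg_mag + spec.n_meg_grad, 0.13, -0.02)
    for i, p in enumerate(meg_pos):
        orient = p / np.linalg.norm(p)
        if i < spec.n_meg_mag:
            channels.append(ChannelInfo(f"MEG{i + 1:03d}", ChannelKind.MEG_MAG, "T",
                                        p, orient))
        else:
            channels.append(ChannelInfo(f"MEG{i + 1:03d}", ChannelKind.MEG_GRAD, "T/m",
                                        p, orient))
    eeg_pos = _fibonacci_cap(spec.n_eeg, 0.09, -0.01)
    for i, p in enumerate(eeg_pos):
        channels.append(ChannelInfo(f"EEG{i + 1:03d}", ChannelKind.EEG, "V", p))
    channels.append(ChannelInfo("EOG062", ChannelKind.EOG, "V",
                                np.array([0.08, 0.0, 0.03])))
    channels.append(ChannelInfo("ECG063", ChannelKind.ECG, "V"))
    channels.append(ChannelInfo("STI101", ChannelKind.STIM, ""))
    for c in channels:
        if c.name in spec.bad_channels:
            c.is_bad = True
    return channels


def _pick_source_vertices(cortex: SurfaceMesh) -> dict:
    """Occipital (-X) and ventral (-Z, posterior) vertices with usefully
    tangential normals (MEG-visible)."""
    v, n = cortex.vertices, cortex.normals
    radial = v / np.linalg.norm(v, axis=1, keepdims=True)
    tangential = 1 - np.abs((n * radial).sum(1))
    # exclude near-radial vertices outright: they are MEG-silent in a sphere
    ok = tangential >= 0.5 * tangential.max()
    occ_score = np.where(ok, -v[:, 0] / np.abs(v[:, 0]).max(), -np.inf)
    ventral_score = np.where(ok, (-v[:, 2] - 0.5 * v[:, 0]) / np.abs(v[:, 2]).max(),
                             -np.inf)
    occ = int(np.argmax(occ_score))
    ventral_score[occ] = -np.inf  # two distinct sources
    return {"occipital": occ, "ventral": int(np.argmax(ventral_score))}


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def _gauss_bump(t: np.ndarray, peak: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - peak) / width) ** 2)


def _qrs_template(sfreq: float) -> np.ndarray:
    """Synthetic QRS complex, ~120 ms, unit R-peak amplitude at the center."""
    t = np.arange(int(0.12 * sfreq)) / sfreq - 0.06
    return (-0.25 * _gauss_bump(t, -0.025, 0.008)
            + 1.0 * _gauss_bump(t, 0.0, 0.006)
            - 0.3 * _gauss_bump(t, 0.025, 0.009))


def _one_over_f_noise(rng: np.random.Generator, n_ch: int, n_s: int, sfreq: float,
                      corner: float = 2.0) -> np.ndarray:
    """Unit-variance noise with 1/(f+corner) amplitude spectrum per channel."""
    white = rng.standard_normal((n_ch, n_s))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_s, 1 / sfreq)
    spec *= 1.0 / (f + corner)
    out = np.fft.irfft(spec, n=n_s, axis=1)
    return out / out.std(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# subject simulation
# ---------------------------------------------------------------------------

_GAIN_CACHE: dict = {}


def _cached_gain(spec: SubjectSpec, cortex, channels, sphere) -> GainMatrix:
    """The forward model depends only on the array geometry, not the seed."""
    key = (spec.cortex_subdiv, spec.n_meg_mag, spec.n_meg_grad, spec.n_eeg,
           tuple(spec.bad_channels))
    if key not in _GAIN_CACHE:
        _GAIN_CACHE[key] = assemble_gain(cortex, channels, meg_sphere=sphere,
                                         eeg_sphere=sphere, constrained=True)
    return _GAIN_CACHE[key]


def simulate_subject(spec: SubjectSpec | None = None, seed: int = 0,
                     subject_scale: dict | None = None):
    """Generate one subject's runs plus the ground truth.

    ``subject_scale`` optionally overrides the per-subject amplitude factors
    and latency shifts (used by :func:`simulate_group`); otherwise they are
    drawn here from the stated between-subject distributions.
    """
    spec = spec or SubjectSpec()
    rng = np.random.default_rng(seed)
    if spec.n_trials * len(spec.conditions) * spec.isi_s[1] <= 0:
        raise ValueError("empty trial schedule")
    scalp, cortex, sphere = make_head_geometry(spec.cortex_subdiv)
    channels = make_sensor_array(spec)
    gain = _cached_gain(spec, cortex, channels, sphere)
    src = _pick_source_vertices(cortex)
    if subject_scale is None:
        subject_scale = {
            "amp": {name: max(0.2, 1 + rng.normal(0, spec.amp_jitter_sd))
                    for name in ("occipital", "ventral")},
            "latency": {name: rng.normal(0, spec.latency_jitter_sd)
                        for name in ("occipital", "ventral")},
        }
    truth = GroundTruth(seed=seed, spec=asdict(spec), source_vertices=src,
                        bad_channels=list(spec.bad_channels))
    truth.source_amplitudes = {
        cond: {"occipital": spec.occipital_amp * subject_scale["amp"]["occipital"],
               "ventral": (spec.face_amp if cond != "Scrambled" else spec.scrambled_amp)
               * subject_scale["amp"]["ventral"]}
        for cond in spec.conditions}
    truth.source_latencies = {
        "occipital": spec.occipital_latency + subject_scale["latency"]["occipital"],
        "ventral": spec.face_latency + subject_scale["latency"]["ventral"]}

    runs = []
    for run in range(spec.n_runs):
        rec = _simulate_run(spec, rng, channels, gain, src, truth, run)
        runs.append(rec)
    return runs, truth


def _simulate_run(spec, rng, channels, gain: GainMatrix, src, truth: GroundTruth,
                  run: int) -> Recording:
    sf = spec.sfreq
    n_s = int(round(spec.run_duration() * sf))
    t0 = spec.first_sample_time
    times = t0 + np.arange(n_s) / sf
    data = np.zeros((len(channels), n_s))
    name_index = {c.name: i for i, c in enumerate(channels)}
    gain_rows = {n: i for i, n in enumerate(gain.ch_names)}

    # --- stimulus schedule and trigger channel ---------------------------
    schedule = []
    labels = [c for c in spec.conditions for _ in range(spec.n_trials)]
    rng.shuffle(labels)
    t_cursor = t0 + spec.pad_s
    stim_idx = name_index["STI101"]
    for label in labels:
        t_trig = t_cursor
        schedule.append([label, float(t_trig)])
        i0 = int(round((t_trig - t0) * sf))
        i1 = min(n_s, i0 + int(round(spec.trigger_pulse_s * sf)))
        data[stim_idx, i0:i1] = CONDITION_CODES[label]
        t_cursor += rng.uniform(*spec.isi_s)
    truth.schedules.append(schedule)

    # --- evoked sources ---------------------------------------------------
    clean = np.zeros((len(gain.ch_names), n_s))
    for label, t_trig in schedule:
        t_stim = t_trig + spec.trigger_delay
        trial_gain = max(0.2, 1 + rng.normal(0, spec.trial_jitter_sd))
        for sname, width in (("occipital", 0.020), ("ventral", 0.025)):
            amp = truth.source_amplitudes[label][sname] * trial_gain
            lat = truth.source_latencies[sname]
            tc = amp * _gauss_bump(times, t_stim + lat, width)
            clean += np.outer(gain.matrix[:, src[sname]], tc)
    for n, i in gain_rows.items():
        data[name_index[n]] += clean[i]

    # --- noise scaled per channel kind to the single-trial peak SNR -------
    # the N-trial average then has amplitude SNR ≈ evoked_snr·sqrt(N), the
    # way averaging behaves in a real session
    noise_sd = {}
    for kind in (ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD, ChannelKind.EEG):
        rows = [i for i, c in enumerate(channels)
                if c.kind is kind and c.name in gain_rows]
        if not rows:
            continue
        peak = np.abs(clean[[gain_rows[channels[i].name] for i in rows]]).max()
        if peak == 0:
            peak = 1.0
        sd = peak / spec.evoked_snr
        noise_sd[kind.value] = float(sd)
        n_ch = len(rows)
        pink = _one_over_f_noise(rng, n_ch, n_s, sf)
        white = rng.standard_normal((n_ch, n_s))
        line = np.sin(2 * np.pi * spec.line_freq * times[None, :]
                      + rng.uniform(0, 2 * np.pi, (n_ch, 1)))
        mix = (np.sqrt(0.6) * pink + np.sqrt(0.3) * white
               + np.sqrt(0.2) * line * rng.uniform(0.5, 1.0, (n_ch, 1)))
        data[rows] += sd * mix
    truth.noise_sd[f"run{run}"] = noise_sd

    rec = Recording([c.copy() for c in channels], data, sf, t0)
    inject_artifacts(rec, spec, rng, truth)
    return rec


def inject_artifacts(rec: Recording, spec: SubjectSpec, rng: np.random.Generator,
                     truth: GroundTruth | None = None) -> dict:
    """Add blinks, heartbeats and (optionally) cHPI sinusoids in place.

    Blinks: ~400 ms raised-cosine bumps at Poisson times on an eye-dipole
    topography, 150-250 μV on the EOG channel. Heartbeats: QRS template at
    the configured rate (timing jitter s.d. 5 ms) on a fixed deep-source
    cardiac topography, ~1 mV on the ECG channel. cHPI: >290 Hz sinusoids
    on MEG channels from ``spec.chpi_start`` onward. Returns the injected
    event times.
    """
    sf = rec.sfreq
    n_s = rec.n_samples
    t0 = rec.first_sample_time
    duration = rec.duration
    scalp, cortex, sphere = make_head_geometry(1)
    meg = [c for c in rec.channels if c.kind in (ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD)]
    from .head_model import meg_forward_sphere, meg_forward_gradiometer

    def topography(dipole_pos, moment):
        out = {}
        for c in meg:
            fwd = (meg_forward_gradiometer if c.kind is ChannelKind.MEG_GRAD
                   else meg_forward_sphere)
            out[c.name] = fwd(dipole_pos, moment, c.position, c.orientation, sphere)
        return out

    # blinks
    blink_topo = topography(np.array([0.065, 0.015, 0.025]), np.array([0, 80e-9, 0]))
    n_blinks = rng.poisson(spec.blink_rate * duration)
    blink_times = np.sort(rng.uniform(t0 + 1.0, t0 + duration - 1.0, n_blinks))
    half = int(0.2 * sf)
    bump_t = np.arange(-half, half + 1) / sf
    bump = 0.5 * (1 + np.cos(np.pi * bump_t / 0.2))
    eog_idx = rec.picks(ChannelKind.EOG)
    for bt in blink_times:
        c = int(round((bt - t0) * sf))
        lo, hi = max(0, c - half), min(n_s, c + half + 1)
        seg = bump[lo - (c - half):hi - (c - half)]
        amp = rng.uniform(1.0, 1.7)
        if len(eog_idx):
            rec.data[eog_idx[0], lo:hi] += 150e-6 * amp * seg
        for name, v in blink_topo.items():
            rec.data[rec.index_of(name), lo:hi] += 3.0 * amp * v * seg
    # heartbeats
    beats = []
    if spec.heart_rate > 0:
        heart_topo = topography(np.array([0.0, 0.01, -0.055]),
                                np.array([40e-9, 0, 30e-9]))
        period = 1.0 / spec.heart_rate
        t = t0 + rng.uniform(0, period)
        while t < t0 + duration - 0.2:
            beats.append(t)
            t += period + rng.normal(0, 0.005)
    else:
        heart_topo = {}
    qrs = _qrs_template(sf)
    qh = len(qrs) // 2
    ecg_idx = rec.picks(ChannelKind.ECG)
    for bt in beats:
        c = int(round((bt - t0) * sf))
        lo, hi = max(0, c - qh), min(n_s, c - qh + len(qrs))
        seg = qrs[lo - (c - qh):hi - (c - qh)]
        if len(ecg_idx):
            rec.data[ecg_idx[0], lo:hi] += 1e-3 * seg
        for name, v in heart_topo.items():
            rec.data[rec.index_of(name), lo:hi] += 2.5 * v * seg
    # cHPI
    if spec.chpi_start is not None:
        freqs = [f for f in (293.0, 307.0, 314.0, 321.0) if f < 0.45 * sf]
        if freqs:
            start = int(round((spec.chpi_start - t0) * sf))
            start = max(0, start)
            tt = np.arange(n_s - start) / sf
            meg_rows = rec.picks((ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD))
            mag_scale = np.array([np.abs(rec.data[r]).std() for r in meg_rows])
            for f in freqs:
                phases = rng.uniform(0, 2 * np.pi, len(meg_rows))
                amp = 20.0 * mag_scale
                rec.data[meg_rows, start:] += (amp[:, None]
                                               * np.sin(2 * np.pi * f * tt[None, :]
                                                        + phases[:, None]))
    if truth is not None:
        truth.blink_times.append([float(x) for x in blink_times])
        truth.heartbeat_times.append([float(x) for x in beats])
    return {"blinks": list(blink_times), "heartbeats": beats}


# ---------------------------------------------------------------------------
# group simulation
# ---------------------------------------------------------------------------

@dataclass
class GroupDataset:
    subjects: list                       # list of (runs, truth) tuples
    template_cortex: SurfaceMesh
    vertex_mappings: list                # per subject (identity at desk scale)
    empty_rooms: list                    # per subject Recording

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def simulate_empty_room(spec: SubjectSpec, rng: np.random.Generator,
                        noise_sd: dict, duration_s: float = 30.0) -> Recording:
    """Subject-free MEG noise recording with the session's noise amplitudes."""
    channels = [c.copy() for c in make_sensor_array(spec)
                if c.kind in (ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD)]
    n_s = int(duration_s * spec.sfreq)
    data = np.zeros((len(channels), n_s))
    times = np.arange(n_s) / spec.sfreq
    for kind in (ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD):
        rows = [i for i, c in enumerate(channels) if c.kind is kind]
        if not rows or kind.value not in noise_sd:
            continue
        sd = noise_sd[kind.value]
        pink = _one_over_f_noise(rng, len(rows), n_s, spec.sfreq)
        white = rng.standard_normal((len(rows), n_s))
        line = np.sin(2 * np.pi * spec.line_freq * times[None, :]
                      + rng.uniform(0, 2 * np.pi, (len(rows), 1)))
        data[rows] = sd * (np.sqrt(0.6) * pink + np.sqrt(0.3) * white
                           + np.sqrt(0.2) * line * rng.uniform(0.5, 1.0, (len(rows), 1)))
    return Recording(channels, data, spec.sfreq)


def simulate_group(n_subjects: int = 16, spec: SubjectSpec | None = None,
                   seed: int = 0, between_subject_sd: float | None = None) -> GroupDataset:
    """Simulate a cohort sharing the template cortex (identity vertex maps)."""
    if n_subjects < 2:
        raise ValueError("a group needs at least 2 subjects")
    spec = spec or SubjectSpec()
    if between_subject_sd is not None:
        from dataclasses import replace
        spec = replace(spec, amp_jitter_sd=between_subject_sd)
    root = np.random.SeedSequence(seed)
    child_seeds = root.generate_state(2 * n_subjects)
    _, cortex, _ = make_head_geometry(spec.cortex_subdiv)
    import scipy.sparse as sp
    identity = sp.identity(cortex.n_vertices, format="csr")
    subjects, mappings, empty_rooms = [], [], []
    for s in range(n_subjects):
        runs, truth = simulate_subject(spec, seed=int(child_seeds[2 * s] % (2 ** 31)))
        subjects.append((runs, truth))
        mappings.append(identity)
        er_rng = np.random.default_rng(int(child_seeds[2 * s + 1] % (2 ** 31)))
        noise_sd = truth.noise_sd.get("run0", {})
        empty_rooms.append(simulate_empty_room(spec, er_rng, noise_sd))
    return GroupDataset(subjects, cortex, mappings, empty_rooms)
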
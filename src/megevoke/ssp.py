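"""Signal-space projection.

Artifact subspaces are estimated by PCA of band-passed data concatenated in
windows around artifact events (heartbeats, blinks), separately per sensor
type so magnetometer and gradiometer patterns never mix. Removing the
subspace is an orthogonal projection P = I - UUᵀ: idempotent, symmetric and
contracting. Projectors are carried lazily on the recording and applied by
every downstream multichannel estimate (averages, covariances, and the rows
of the forward gain before inversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .core_io import ChannelKind, EventList, Recording, logger

#: default artifact-locked windows and bands (seconds, Hz)
CARDIAC_WINDOW_S = 0.04
CARDIAC_BAND = (13.0, 40.0)
BLINK_WINDOW_S = 0.2
BLINK_BAND = (1.5, 15.0)


@dataclass
class Projector:
    """An orthonormal artifact subspace on a named channel subset."""

    name: str
    kind: ChannelKind
    ch_names: list
    components: np.ndarray               # (n_channels, k), orthonormal columns
    singular_values: np.ndarray          # variance fractions, descending
    active: list = field(default_factory=list)

    def __post_init__(self):
        U = self.components
        gram = U.T @ U
        if not np.allclose(gram, np.eye(U.shape[1]), atol=1e-9):
            raise ValueError("projector components are not orthonormal")
        if not self.active:
            self.active = [False] * U.shape[1]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def active_basis(self) -> np.ndarray:
        sel = np.asarray(self.active, bool)
        return self.components[:, sel]

    def matrix(self) -> np.ndarray:
        """P = I - UUᵀ over the projector's channel subset (active components)."""
        U = self.active_basis()
        return np.eye(len(self.ch_names)) - U @ U.T


def projector_to_dict(p: Projector) -> dict:
    return {"name": p.name, "kind": p.kind.value, "ch_names": list(p.ch_names),
            "components": p.components.tolist(),
            "singular_values": p.singular_values.tolist(),
            "active": [bool(a) for a in p.active]}


def projector_from_dict(d: dict) -> Projector:
    return Projector(d["name"], ChannelKind(d["kind"]), d["ch_names"],
                     np.asarray(d["components"], float),
                     np.asarray(d["singular_values"], float), d["active"])


def build_artifact_ssp(rec: Recording, events: EventList, window_s: float,
                       band_hz: tuple, channel_kind: ChannelKind,
                       name: str | None = None, n_active: int = 1) -> Projector:
    """PCA of artifact-locked, band-passed data on one channel kind.

    Windows of ±``window_s`` around each event onset are band-passed and
    concatenated; the left singular vectors of the channels × samples block
    give the artifact's spatial patterns, ordered by variance fraction. By
    default only the first component is marked active.
    """
    if channel_kind not in (ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD, ChannelKind.EEG):
        raise ValueError(f"SSP not defined for channel kind {channel_kind}")
    if len(events) == 0:
        raise ValueError("no artifact events to build SSP from")
    picks = rec.picks(channel_kind, good_only=True)
    if len(events) < max(10, len(picks) // 10):
        logger.warning("only %d artifact events for %d channels: SSP may be unstable",
                       len(events), len(picks))
    sos = _signal.butter(4, band_hz, btype="bandpass", fs=rec.sfreq, output="sos")
    filt = _signal.sosfiltfilt(sos, rec.data[picks], axis=1)
    half = int(round(window_s * rec.sfreq))
    blocks = []
    for ev in events:
        c = rec.time_to_sample(ev.onset)
        if c - half < 0 or c + half >= rec.n_samples:
            continue
        blocks.append(filt[:, c - half:c + half + 1])
    if not blocks:
        raise ValueError("no artifact window fits inside the recording")
    block = np.concatenate(blocks, axis=1)
    block = block - block.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(block, full_matrices=False)
    var = s ** 2
    var_frac = var / var.sum()
    active = [i < n_active for i in range(U.shape[1])]
    return Projector(name or f"ssp_{channel_kind.value.lower()}", channel_kind,
                     [rec.ch_names[i] for i in picks], U, var_frac, active)


def apply_projectors(data: np.ndarray, projectors, ch_names: list) -> np.ndarray:
    """Apply every active projector to a channels × samples (or gain) array.

    Rows are matched to each projector's channel subset by name; channels
    outside the subset are untouched. Idempotent by construction.
    """
    out = np.array(data, float, copy=True)
    index = {n: i for i, n in enumerate(ch_names)}
    for p in projectors:
        U = p.active_basis()
        if U.shape[1] == 0:
            continue
        rows = [index[n] for n in p.ch_names if n in index]
        if len(rows) != len(p.ch_names):
            missing = set(p.ch_names) - set(index)
            raise ValueError(f"projector {p.name}: channels missing from data: {sorted(missing)[:5]}")
        sub = out[rows]
        out[rows] = sub - U @ (U.T @ sub)
    return out


def projector_topography(proj: Projector, component: int) -> dict:
    """Component vector keyed by channel name, for reporting/QC displays."""
    if not 0 <= component < proj.n_components:
        raise IndexError(f"component {component} out of range (k={proj.n_components})")
    vec = proj.components[:, component]
    return dict(zip(proj.ch_names, vec.tolist()))
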
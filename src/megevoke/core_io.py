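"""Core data model and file formats.

Containers for continuous multichannel recordings (MEG/EEG sensor arrays
with per-channel geometry), event lists, bad-segment bookkeeping and linear
projectors, plus readers/writers for the on-disk formats: BIDS-style
``channels.tsv`` / ``events.tsv`` and a documented raw container (flat
little-endian float64 matrix + JSON sidecar) that round-trips bit-exactly.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

logger = logging.getLogger("megevoke")
if not logger.handlers:  # library default: warnings to stderr, no config forced
    logging.basicConfig(level=logging.WARNING, format="%(name)s:%(levelname)s: %(message)s")

MU0 = 4e-7 * np.pi  # vacuum permeability, T·m/A


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------

class ChannelKind(Enum):
    MEG_MAG = "MEG_MAG"
    MEG_GRAD = "MEG_GRAD"
    EEG = "EEG"
    EOG = "EOG"
    ECG = "ECG"
    STIM = "STIM"
    NOSIG = "NOSIG"


#: channels.tsv ``type`` column values accepted for each kind
_TSV_TYPE_MAP = {
    "MEGMAG": ChannelKind.MEG_MAG,
    "MEG_MAG": ChannelKind.MEG_MAG,
    "MEGGRADPLANAR": ChannelKind.MEG_GRAD,
    "MEGGRAD": ChannelKind.MEG_GRAD,
    "MEG_GRAD": ChannelKind.MEG_GRAD,
    "EEG": ChannelKind.EEG,
    "EOG": ChannelKind.EOG,
    "ECG": ChannelKind.ECG,
    "TRIG": ChannelKind.STIM,
    "STIM": ChannelKind.STIM,
    "NOSIG": ChannelKind.NOSIG,
}

MEG_KINDS = (ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD)
DATA_KINDS = (ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD, ChannelKind.EEG)


@dataclass
class ChannelInfo:
    """One sensor: identity, type, SI unit, and head-frame geometry."""

    name: str
    kind: ChannelKind
    unit: str = ""
    position: np.ndarray | None = None   # 3-vector, meters, head frame
    orientation: np.ndarray | None = None  # unit 3-vector (MEG only)
    is_bad: bool = False

    def __post_init__(self) -> None:
        if self.position is not None:
            self.position = np.asarray(self.position, float)
        if self.orientation is not None:
            self.orientation = np.asarray(self.orientation, float)
            n = np.linalg.norm(self.orientation)
            if abs(n - 1.0) > 1e-9:
                raise ValueError(f"channel {self.name}: orientation norm {n} != 1")

    def copy(self) -> "ChannelInfo":
        return ChannelInfo(
            self.name, self.kind, self.unit,
            None if self.position is None else self.position.copy(),
            None if self.orientation is None else self.orientation.copy(),
            self.is_bad,
        )


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

@dataclass
class Event:
    """A labeled point or extended event on the recording clock (seconds)."""

    label: str
    onset: float
    duration: float = 0.0
    value: float | None = None  # e.g. decoded trigger code

    @property
    def is_bad(self) -> bool:
        return "bad" in self.label

    @property
    def end(self) -> float:
        return self.onset + self.duration


class EventList:
    """Ordered event collection, sorted by onset, with per-label grouping."""

    def __init__(self, events: list[Event] | None = None):
        self.events: list[Event] = sorted(events or [], key=lambda e: e.onset)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.label, None)
        return list(seen)

    def by_label(self, label: str) -> "EventList":
        return EventList([e for e in self.events if e.label == label])

    def add(self, ev: Event) -> None:
        self.events.append(ev)
        self.events.sort(key=lambda e: e.onset)

    def extend(self, other: "EventList") -> "EventList":
        return EventList(self.events + list(other))

    def copy(self) -> "EventList":
        return EventList([Event(e.label, e.onset, e.duration, e.value) for e in self.events])


@dataclass
class BadSegment:
    """A [start, end] span of unusable data, in seconds on the recording clock."""

    start: float
    end: float
    label: str = "bad"

    def overlaps(self, t0: float, t1: float) -> bool:
        return self.start < t1 and t0 < self.end


# ---------------------------------------------------------------------------
# recording
# ---------------------------------------------------------------------------

class Recording:
    """Continuous channels × samples data in SI units with metadata.

    ``data[i, j]`` is channel i at time ``first_sample_time + j / sfreq``.
    Projectors attached to the recording are lazy: they are applied by
    downstream estimators (averaging, covariance, inversion), never
    destructively to ``data``.
    """

    def __init__(self, channels: list[ChannelInfo], data: np.ndarray, sfreq: float,
                 first_sample_time: float = 0.0, events: EventList | None = None,
                 bad_segments: list[BadSegment] | None = None,
                 projectors: list | None = None):
        data = np.asarray(data, float)
        if data.ndim != 2 or data.shape[0] != len(channels):
            raise ValueError("data must be channels × samples matching channel list")
        names = [c.name for c in channels]
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names")
        self.channels = channels
        self.data = data
        self.sfreq = float(sfreq)
        self.first_sample_time = float(first_sample_time)
        self.events = events or EventList()
        self.bad_segments = list(bad_segments or [])
        self.projectors = list(projectors or [])

    # -- basic geometry -----------------------------------------------------
    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return self.first_sample_time + np.arange(self.n_samples) / self.sfreq

    @property
    def ch_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def index_of(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def picks(self, kind: ChannelKind | tuple, good_only: bool = False) -> np.ndarray:
        kinds = kind if isinstance(kind, tuple) else (kind,)
        return np.array([i for i, c in enumerate(self.channels)
                         if c.kind in kinds and not (good_only and c.is_bad)], int)

    def time_to_sample(self, t: float) -> int:
        return int(round((t - self.first_sample_time) * self.sfreq))

    def add_bad_segment(self, seg: BadSegment) -> None:
        t0, t1 = self.first_sample_time, self.first_sample_time + self.duration
        if seg.end < t0 or seg.start > t1:
            raise ValueError("bad segment outside the recording span")
        self.bad_segments.append(seg)

    def good_sample_mask(self) -> np.ndarray:
        """Boolean per-sample mask, False inside any bad segment or bad event."""
        mask = np.ones(self.n_samples, bool)
        spans = [(s.start, s.end) for s in self.bad_segments]
        spans += [(e.onset, e.end) for e in self.events if e.is_bad]
        for start, end in spans:
            i0 = max(0, int(np.floor((start - self.first_sample_time) * self.sfreq)))
            i1 = min(self.n_samples, int(np.ceil((end - self.first_sample_time) * self.sfreq)) + 1)
            mask[i0:i1] = False
        return mask

    def copy(self) -> "Recording":
        return Recording([c.copy() for c in self.channels], self.data.copy(), self.sfreq,
                         self.first_sample_time, self.events.copy(),
                         [BadSegment(s.start, s.end, s.label) for s in self.bad_segments],
                         list(self.projectors))


# ---------------------------------------------------------------------------
# channels.tsv / events.tsv
# ---------------------------------------------------------------------------

def read_channels_tsv(path) -> list[ChannelInfo]:
    """Read a BIDS-style channels.tsv (name/type/units, optional status)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    for col in ("name", "type", "units"):
        if col not in header:
            raise ValueError(f"{path}: missing required column {col!r}")
    idx = {h: i for i, h in enumerate(header)}
    out: list[ChannelInfo] = []
    seen: set[str] = set()
    for line in lines[1:]:
        if not line.strip():
            continue
        row = line.split("\t")
        name = row[idx["name"]]
        if name in seen:
            raise ValueError(f"{path}: duplicate channel name {name!r}")
        seen.add(name)
        raw_type = row[idx["type"]].upper()
        kind = _TSV_TYPE_MAP.get(raw_type)
        if kind is None:
            logger.warning("channels.tsv: unknown type %r for %s, mapping to NOSIG", raw_type, name)
            kind = ChannelKind.NOSIG
        unit = row[idx["units"]]
        if unit == "n/a":
            unit = ""
        is_bad = "status" in idx and len(row) > idx["status"] and row[idx["status"]].lower() == "bad"
        out.append(ChannelInfo(name, kind, unit, is_bad=is_bad))
    return out


def write_channels_tsv(channels: list[ChannelInfo], path) -> None:
    rows = ["name\ttype\tunits\tstatus"]
    for c in channels:
        rows.append(f"{c.name}\t{c.kind.value}\t{c.unit or 'n/a'}\t{'bad' if c.is_bad else 'good'}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_events_tsv(path) -> tuple[EventList, list[BadSegment]]:
    """Read events.tsv; rows whose trial_type contains "bad" and have nonzero
    duration are returned separately as bad segments."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    idx = {h: i for i, h in enumerate(header)}
    for col in ("onset", "duration", "trial_type"):
        if col not in idx:
            raise ValueError(f"{path}: missing required column {col!r}")
    events, bads = [], []
    for line in lines[1:]:
        if not line.strip():
            continue
        row = line.split("\t")
        try:
            onset = float(row[idx["onset"]])
        except ValueError:
            raise ValueError(f"{path}: non-numeric onset {row[idx['onset']]!r}") from None
        dur_raw = row[idx["duration"]]
        duration = 0.0 if dur_raw == "n/a" else float(dur_raw)
        if duration < 0:
            raise ValueError(f"{path}: negative duration at onset {onset}")
        label = row[idx["trial_type"]]
        value = None
        if "value" in idx and len(row) > idx["value"] and row[idx["value"]] != "n/a":
            value = float(row[idx["value"]])
        if "bad" in label and duration > 0:
            bads.append(BadSegment(onset, onset + duration, label))
        else:
            events.append(Event(label, onset, duration, value))
    return EventList(events), bads


def write_events_tsv(events: EventList, path, bad_segments: list[BadSegment] | None = None) -> None:
    rows = ["onset\tduration\ttrial_type\tvalue"]
    items = [(e.onset, e.duration, e.label, e.value) for e in events]
    items += [(s.start, s.end - s.start, s.label, None) for s in (bad_segments or [])]
    for onset, duration, label, value in sorted(items):
        v = "n/a" if value is None else f"{value:g}"
        rows.append(f"{onset:.6f}\t{duration:.6f}\t{label}\t{v}")
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# raw container: <stem>.json sidecar + <stem>.dat float64 matrix
# ---------------------------------------------------------------------------

def _channel_to_dict(c: ChannelInfo) -> dict:
    return {
        "name": c.name, "type": c.kind.value, "units": c.unit,
        "position": None if c.position is None else list(map(float, c.position)),
        "orientation": None if c.orientation is None else list(map(float, c.orientation)),
        "status": "bad" if c.is_bad else "good",
    }


def _channel_from_dict(d: dict) -> ChannelInfo:
    return ChannelInfo(d["name"], ChannelKind(d["type"]), d.get("units", ""),
                       d.get("position"), d.get("orientation"),
                       d.get("status") == "bad")


def write_raw(rec: Recording, path) -> None:
    """Write a Recording as ``<stem>.dat`` (little-endian float64, C order,
    channels × samples) plus ``<stem>.json`` sidecar. Bit-exact round trip."""
    stem = Path(path).with_suffix("")
    from .ssp import projector_to_dict  # local import: avoid cycle
    sidecar = {
        "sfreq": rec.sfreq,
        "first_sample_time": rec.first_sample_time,
        "shape": list(rec.data.shape),
        "dtype": "<f8",
        "channels": [_channel_to_dict(c) for c in rec.channels],
        "events": [[e.label, e.onset, e.duration, e.value] for e in rec.events],
        "bad_segments": [[s.label, s.start, s.end] for s in rec.bad_segments],
        "projectors": [projector_to_dict(p) for p in rec.projectors],
    }
    rec.data.astype("<f8").tofile(stem.with_suffix(".dat"))
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_raw(path) -> Recording:
    stem = Path(path).with_suffix("")
    from .ssp import projector_from_dict
    try:
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        shape = tuple(sidecar["shape"])
        channels = [_channel_from_dict(d) for d in sidecar["channels"]]
    except (KeyError, json.JSONDecodeError) as err:
        raise ValueError(f"{stem}.json: corrupted sidecar ({err})") from None
    data = np.fromfile(stem.with_suffix(".dat"), dtype="<f8")
    if data.size != shape[0] * shape[1]:
        raise ValueError(f"{stem}.dat: matrix size {data.size} does not match sidecar shape {shape}")
    events = EventList([Event(lbl, on, du, val) for lbl, on, du, val in sidecar.get("events", [])])
    bads = [BadSegment(s, e, lbl) for lbl, s, e in sidecar.get("bad_segments", [])]
    projs = [projector_from_dict(d) for d in sidecar.get("projectors", [])]
    return Recording(channels, data.reshape(shape), sidecar["sfreq"],
                     sidecar["first_sample_time"], events, bads, projs)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: every stage parameter with its default; a config file may override any key.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "megevoke_out",
    "stages": ["simulate", "preprocess", "ssp", "epoch", "average",
               "forward", "inverse", "tf", "group"],
    "simulate": {
        "n_subjects": 2, "n_runs": 2, "n_trials": 20,
        "conditions": ["Familiar", "Scrambled"],
        "sfreq": 600.0, "n_meg_mag": 30, "n_meg_grad": 0, "n_eeg": 12,
        "cortex_subdiv": 1, "trigger_delay": 0.0345, "evoked_snr": 3.0,
        "blink_rate": 0.05, "heart_rate": 1.2, "line_freq": 50.0,
    },
    "preprocess": {
        "notch_freqs": [50.0, 100.0, 150.0, 200.0],
        "lowpass_hz": 32.0, "attenuation_db": 60.0,
        "psd_window_s": 3.0, "psd_overlap": 0.5,
        "blink_channel": "EOG061", "blink_threshold": 100e-6,
        "blink_band": [0.3, 20.0],
        "artifact_bands": [[1.0, 7.0], [40.0, 240.0]], "artifact_z": 5.0,
    },
    "ssp": {"cardiac_window_s": 0.04, "cardiac_band": [13.0, 40.0], "n_active": 1},
    "epoch": {"window_s": [-0.5, 1.2], "dc_baseline_s": [-0.5, -0.0009]},
    "average": {"crop_s": [-0.2, 0.9], "zscore_baseline_s": [-0.2, -0.005]},
    "forward": {"conductivities": [0.33, 0.0042, 0.33],
                "full_scale_n_vertices": 15000},
    "inverse": {"depth_gamma": 0.5, "snr": 3.0, "cov_regularization": 0.1,
                "methods": ["wmne", "dspm", "sloreta"]},
    "tf": {"fmin": 6.0, "fmax": 60.0, "n_freqs": 20, "fc": 1.0, "fwhm_tc": 3.0},
    "group": {"n_randomizations": 1000, "alpha": 0.05, "smooth_fwhm_m": 0.003,
              "correction": "fdr"},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        if key not in base:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise TypeError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


class PipelineConfig:
    """Validated key tree of all stage parameters.

    Every pipeline run is fully determined by (config, input data, seed).
    """

    def __init__(self, overrides: dict | None = None):
        self.tree = _merge(DEFAULT_CONFIG, overrides or {})
        if not isinstance(self.tree["seed"], int):
            raise TypeError("seed must be an integer")
        unknown = set(self.tree["stages"]) - set(DEFAULT_CONFIG["stages"])
        if unknown:
            raise KeyError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.tree[key]

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.tree, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# execution report
# ---------------------------------------------------------------------------

@dataclass
class StageEntry:
    stage: str
    parameters: dict
    started: float
    finished: float = 0.0
    warnings: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    snapshots: list = field(default_factory=list)


class ExecutionReport:
    """Ordered, lossless log of executed pipeline stages."""

    def __init__(self):
        self.entries: list[StageEntry] = []

    def start_stage(self, stage: str, parameters: dict | None = None) -> StageEntry:
        entry = StageEntry(stage, dict(parameters or {}), _time.time())
        self.entries.append(entry)
        return entry

    def finish_stage(self, entry: StageEntry, **summary) -> None:
        entry.finished = _time.time()
        entry.summary.update(summary)

    def __len__(self):
        return len(self.entries)

    def stage_names(self) -> list[str]:
        return [e.stage for e in self.entries]

    def get(self, stage: str) -> StageEntry | None:
        for e in self.entries:
            if e.stage == stage:
                return e
        return None

    def to_json(self, path=None) -> str:
        payload = [{"stage": e.stage, "parameters": e.parameters, "started": e.started,
                    "finished": e.finished, "warnings": e.warnings,
                    "summary": e.summary, "snapshots": e.snapshots}
                   for e in self.entries]
        text = json.dumps(payload, indent=1, default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path_or_text) -> "ExecutionReport":
        text = path_or_text
        p = Path(str(path_or_text))
        if p.exists():
            text = p.read_text()
        rep = cls()
        for d in json.loads(text):
            rep.entries.append(StageEntry(d["stage"], d["parameters"], d["started"],
                                          d["finished"], d["warnings"], d["summary"],
                                          d["snapshots"]))
        return rep

    def to_text(self) -> str:
        lines = []
        for e in self.entries:
            lines.append(f"[{e.stage}] {e.finished - e.started:.2f} s")
            for k, v in e.parameters.items():
                lines.append(f"    param {k} = {v}")
            for k, v in e.summary.items():
                lines.append(f"    {k}: {v}")
            for w in e.warnings:
                lines.append(f"    WARNING: {w}")
        return "\n".join(lines)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
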
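"""Event construction and artifact detection.

Decodes the bit-coded stimulus trigger channel into per-bit events, combines
coincident bits into labeled stimulus categories, and detects physiological
or instrumental artifacts: blinks (threshold on band-passed EOG), heartbeats
(R-peaks on ECG), cHPI activation (onset of high-frequency head-tracking
sinusoids) and band-limited artifact segments (movement 1-7 Hz, muscle
40-240 Hz).

Bit numbering is 1-based from the least significant bit, so trigger code 5 =
binary 00101 has bits 1 and 3 set; bit 3 codes "face", bit 4 "unfamiliar",
bit 5 "scrambled".
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core_io import BadSegment, ChannelKind, Event, EventList, Recording, logger

#: category → required bit values; bits not listed are "don't care"
STIMULUS_RULES: dict[str, dict[int, int]] = {
    "Familiar": {3: 1, 4: 0, 5: 0},
    "Unfamiliar": {3: 1, 4: 1, 5: 0},
    "Scrambled": {5: 1},
}

#: hardware delay between trigger pulse and image appearing on screen
PRESENTATION_DELAY_S = 0.0345


# ---------------------------------------------------------------------------
# trigger decoding
# ---------------------------------------------------------------------------

def decode_trigger_bits(rec: Recording, stim_channel: str, n_bits: int = 16) -> EventList:
    """One point event ``bit<b>`` per 0→1 transition of each trigger bit.

    The event's ``value`` carries the full integer code at the transition
    sample, so coincident bit events can be recombined into stimulus codes.
    """
    idx = rec.index_of(stim_channel)
    codes = np.asarray(np.round(rec.data[idx]), np.int64)
    if codes.min() < 0:
        raise ValueError("stim channel holds negative values")
    times = rec.times
    events = []
    for b in range(1, n_bits + 1):
        bit = (codes >> (b - 1)) & 1
        onsets = np.flatnonzero(np.diff(bit) == 1) + 1
        for i in onsets:
            events.append(Event(f"bit{b}", times[i], 0.0, value=float(codes[i])))
    return EventList(events)


def combine_bit_events(events: EventList, rules: dict[str, dict[int, int]] | None = None,
                       sfreq: float | None = None) -> EventList:
    """Merge coincident per-bit events into labeled stimulus events.

    ``rules`` maps label → {bit: required value}; unlisted bits are
    unconstrained. Onsets whose code matches no rule are dropped; an onset
    matching two rules is an error (rules must be mutually exclusive).
    """
    rules = STIMULUS_RULES if rules is None else rules
    tol = 0.5 / sfreq if sfreq else 1e-9
    # group bit events by onset (coincident within one sample)
    groups: list[tuple[float, float]] = []  # (onset, code)
    for e in events:
        if not e.label.startswith("bit"):
            continue
        if groups and abs(e.onset - groups[-1][0]) <= tol:
            continue  # same onset, code already captured
        groups.append((e.onset, e.value))
    out = []
    for onset, code in groups:
        code_int = int(code)
        matches = [lbl for lbl, req in rules.items()
                   if all(((code_int >> (b - 1)) & 1) == v for b, v in req.items())]
        if len(matches) > 1:
            raise ValueError(f"rules {matches} both match code {code_int} at onset {onset}")
        if matches:
            out.append(Event(matches[0], onset, 0.0, value=float(code_int)))
    return EventList(out)


def transform_events(events: EventList, op: str, **args) -> EventList:
    """Label-level event editing: rename, group_by_name, delete, add_offset."""
    evs = events.copy()
    if op == "rename":
        old, new = args["old"], args["new"]
        existing = set(evs.labels())
        if new in existing and new != old and not args.get("merge", False):
            raise ValueError(f"label {new!r} already exists (use group_by_name to merge)")
        for e in evs:
            if e.label == old:
                e.label = new
    elif op == "group_by_name":
        labels, new = set(args["labels"]), args["new"]
        for e in evs:
            if e.label in labels:
                e.label = new
    elif op == "delete":
        labels = set(args["labels"])
        return EventList([e for e in evs if e.label not in labels])
    elif op == "add_offset":
        offset = float(args["offset"])
        labels = args.get("labels")
        for e in evs:
            if labels is None or e.label in labels:
                e.onset += offset
    else:
        raise ValueError(f"unknown event transform {op!r}")
    return EventList(list(evs))


# ---------------------------------------------------------------------------
# threshold / blink detection
# ---------------------------------------------------------------------------

def _bandpass_sos(band: tuple[float, float], sfreq: float, order: int = 4):
    lo, hi = band
    nyq = sfreq / 2
    if not (0 < lo < hi) or hi >= nyq:
        raise ValueError(f"band {band} outside (0, {nyq})")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=sfreq, output="sos")


def detect_threshold_events(rec: Recording, channel: str, band: tuple[float, float],
                            threshold: float, min_gap: float = 0.5,
                            label: str = "blink", mark_bad: bool = True) -> EventList:
    """Events spanning each contiguous |band-passed signal| > threshold excursion.

    Excursions separated by less than ``min_gap`` seconds are merged. With
    ``mark_bad`` the label gets a ``_bad`` suffix so downstream epoching
    rejects co-occurring trials.
    """
    idx = rec.index_of(channel)
    if rec.channels[idx].is_bad:
        raise ValueError(f"channel {channel} is marked bad")
    x = rec.data[idx]
    if threshold <= 0:
        # degenerate: everything supra-threshold
        lbl = label + ("_bad" if mark_bad else "")
        return EventList([Event(lbl, rec.first_sample_time, rec.duration)])
    filt = signal.sosfiltfilt(_bandpass_sos(band, rec.sfreq), x)
    above = np.abs(filt) > threshold
    if not above.any():
        return EventList()
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    # merge close excursions
    merged: list[list[int]] = []
    gap = int(round(min_gap * rec.sfreq))
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    lbl = label + ("_bad" if mark_bad else "")
    t0, sf = rec.first_sample_time, rec.sfreq
    return EventList([Event(lbl, t0 + s / sf, (e - s) / sf) for s, e in merged])


# ---------------------------------------------------------------------------
# heartbeat detection
# ---------------------------------------------------------------------------

def detect_heartbeats(rec: Recording, ecg_channel: str | None = None,
                      band: tuple[float, float] = (8.0, 40.0)) -> EventList:
    """One point event per R-peak of the ECG trace.

    Local-maximum search on the rectified band-passed trace with an adaptive
    amplitude threshold and a 300 ms refractory period; polarity-invariant.
    Returns an empty list when no credible peaks exist.
    """
    if ecg_channel is None:
        picks = rec.picks(ChannelKind.ECG)
        if len(picks) == 0:
            raise ValueError("no ECG channel in recording")
        idx = picks[0]
    else:
        idx = rec.index_of(ecg_channel)
    x = rec.data[idx].astype(float)
    if np.ptp(x) == 0:
        return EventList()
    hi = min(band[1], 0.45 * rec.sfreq)
    env = np.abs(signal.sosfiltfilt(_bandpass_sos((band[0], hi), rec.sfreq), x))
    thr = 0.5 * np.percentile(env, 99.5)
    noise_floor = 5.0 * np.median(env)
    if thr < noise_floor:  # no QRS-like dynamics above the background
        return EventList()
    peaks, _ = signal.find_peaks(env, height=thr, distance=int(0.3 * rec.sfreq))
    times = rec.times
    return EventList([Event("cardiac", times[p]) for p in peaks])


# ---------------------------------------------------------------------------
# cHPI onset
# ---------------------------------------------------------------------------

def detect_chpi_onset(rec: Recording, chpi_band: tuple[float, float] = (250.0, None),
                      window_s: float = 1.0, hop_s: float = 0.1,
                      ratio: float = 10.0) -> BadSegment | None:
    """Mark [file start, cHPI activation) as one bad segment.

    Head-position-indicator coils emit strong sinusoids well above the
    physiological band; their activation is found as the first short window
    whose high-frequency band power exceeds ``ratio`` × the power at the
    start of the file. Returns ``None`` when the coils are already on at
    sample 0; flags the whole file (with a warning) when they never turn on.
    """
    picks = rec.picks((ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD), good_only=True)
    if len(picks) == 0:
        raise ValueError("no MEG channels for cHPI detection")
    nyq = rec.sfreq / 2
    lo = min(chpi_band[0], 0.8 * nyq)
    sos_hi = signal.butter(4, lo, btype="highpass", fs=rec.sfreq, output="sos")
    sos_lo = signal.butter(4, min(100.0, 0.5 * lo), btype="lowpass", fs=rec.sfreq,
                           output="sos")
    hp = signal.sosfiltfilt(sos_hi, rec.data[picks], axis=1)
    lp = signal.sosfiltfilt(sos_lo, rec.data[picks], axis=1)
    power = (hp ** 2).mean(axis=0)
    power_lo = (lp ** 2).mean(axis=0)
    win = int(round(window_s * rec.sfreq))
    hop = int(round(hop_s * rec.sfreq))
    if win > rec.n_samples:
        raise ValueError("window longer than recording")
    starts = np.arange(0, rec.n_samples - win + 1, hop)
    band_power = np.array([power[s:s + win].mean() for s in starts])
    band_power_lo = np.array([power_lo[s:s + win].mean() for s in starts])
    # HPI sinusoids dominate the physiological band by orders of magnitude:
    # a window is "HPI active" when its high-band power swamps its low band
    active = band_power > ratio * np.maximum(band_power_lo, 1e-300)
    if active[0]:
        return None  # HPI on from the start: nothing to mark
    if not active.any():
        logger.warning("cHPI never detected: flagging the whole file")
        return BadSegment(rec.first_sample_time, rec.first_sample_time + rec.duration,
                          "chpi_missing_bad")
    k = int(np.argmax(active))
    coarse = starts[k]
    # refine to near-sample precision with a short moving average of the
    # instantaneous band power around the coarse window
    fine_win = max(4, int(round(0.02 * rec.sfreq)))
    i0 = max(0, coarse - win)
    i1 = min(rec.n_samples, coarse + 2 * win)
    smooth = np.convolve(power[i0:i1], np.ones(fine_win) / fine_win, mode="same")
    fine_thresh = ratio * max(band_power_lo[k], 1e-300)
    cross = np.flatnonzero(smooth > fine_thresh)
    onset_sample = i0 + cross[0] if cross.size else coarse
    onset_t = rec.first_sample_time + onset_sample / rec.sfreq
    return BadSegment(rec.first_sample_time, onset_t, "chpi_onset_bad")


# ---------------------------------------------------------------------------
# band-limited artifact segments
# ---------------------------------------------------------------------------

_BAND_LABELS = {(1.0, 7.0): "movement_bad", (40.0, 240.0): "muscle_bad"}


def detect_band_artifacts(rec: Recording, bands=((1.0, 7.0), (40.0, 240.0)),
                          z_threshold: float = 5.0, window_s: float = 1.0,
                          hop_s: float = 0.25) -> EventList:
    """Robust-z sliding-window RMS detector for movement/muscle artifacts.

    Per band: band-limit the good data channels, compute RMS over sliding
    windows, z-score the windows robustly (median/MAD) and flag windows with
    z above threshold. Contiguous flagged windows merge into one event.
    """
    picks = rec.picks((ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD, ChannelKind.EEG),
                      good_only=True)
    win = int(round(window_s * rec.sfreq))
    hop = int(round(hop_s * rec.sfreq))
    if win > rec.n_samples:
        raise ValueError("window longer than recording")
    nyq = rec.sfreq / 2
    out: list[Event] = []
    t0, sf = rec.first_sample_time, rec.sfreq
    for band in bands:
        lo, hi = band
        hi_clip = min(hi, 0.95 * nyq)  # clip upper edge at Nyquist
        label = _BAND_LABELS.get(tuple(band), f"band{lo:g}-{hi:g}_bad")
        filt = signal.sosfiltfilt(_bandpass_sos((lo, hi_clip), rec.sfreq), rec.data[picks], axis=1)
        # skip windows inside the filter startup transient at either edge
        skip = int(round(2.0 * rec.sfreq / lo))
        starts = np.arange(0, rec.n_samples - win + 1, hop)
        starts = starts[(starts >= skip) & (starts + win <= rec.n_samples - skip)]
        if starts.size == 0:
            starts = np.arange(0, rec.n_samples - win + 1, hop)
        rms = np.array([np.sqrt(np.mean(filt[:, s:s + win] ** 2)) for s in starts])
        med = np.median(rms)
        mad = np.median(np.abs(rms - med)) * 1.4826
        if mad == 0:
            continue
        z = (rms - med) / mad
        flagged = z > z_threshold
        i = 0
        while i < len(flagged):
            if flagged[i]:
                j = i
                while j + 1 < len(flagged) and flagged[j + 1]:
                    j += 1
                s0, s1 = starts[i], starts[j] + win
                out.append(Event(label, t0 + s0 / sf, (s1 - s0) / sf))
                i = j + 1
            else:
                i += 1
    return EventList(out)
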
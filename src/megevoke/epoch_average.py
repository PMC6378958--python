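"""Epoch extraction, trial/run/subject averaging and condition contrasts.

Epochs are cut on a latency grid anchored at the exact event sample
(latency 0); trials overlapping any bad event/segment, or running off the
recording edge, are flagged bad with a reason and never enter averages.
Run averages combine into subject averages weighted by good-trial counts
(algebraically identical to the pooled-trial mean); subject averages combine
into unweighted grand averages. Contrasts implement both amplitude (A - B)
and magnitude (|A| - |B|) differences — for signed source currents these
answer different questions, e.g. A = -10, B = -5 gives A-B = -5 but
|A|-|B| = +5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import EventList, Recording
from .preprocess import remove_dc_offset
from .ssp import apply_projectors


@dataclass
class EpochSet:
    """Trial-segmented data for one condition: trials × channels × samples."""

    condition: str
    data: np.ndarray
    latencies: np.ndarray          # seconds, 0 = event onset
    ch_names: list
    good: np.ndarray               # per-trial flag
    bad_reason: list               # '' for good trials
    run_id: str = ""
    projectors: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_good(self) -> int:
        return int(self.good.sum())

    def good_data(self) -> np.ndarray:
        return self.data[self.good]

    def copy(self) -> "EpochSet":
        return EpochSet(self.condition, self.data.copy(), self.latencies.copy(),
                        list(self.ch_names), self.good.copy(), list(self.bad_reason),
                        self.run_id, list(self.projectors))


@dataclass
class Evoked:
    """Trial-averaged response with good-trial bookkeeping and provenance."""

    condition: str
    data: np.ndarray               # channels × samples
    latencies: np.ndarray
    ch_names: list
    n_good: int
    weighting: str = "unweighted"  # or "weighted"
    provenance: list = field(default_factory=list)

    def copy(self) -> "Evoked":
        return Evoked(self.condition, self.data.copy(), self.latencies.copy(),
                      list(self.ch_names), self.n_good, self.weighting,
                      list(self.provenance))


def make_epochs(rec: Recording, events: EventList, window=(-0.5, 1.2),
                dc_baseline=(-0.5, -0.0009), condition: str | None = None,
                picks: np.ndarray | None = None, run_id: str = "") -> EpochSet:
    """One trial per event; DC offset removed over the baseline window.

    A trial is flagged bad when it overlaps a bad segment or bad event
    (reason ``"artifact"``), or lies too close to the recording edge
    (reason ``"edge"``). Trial count always equals event count.
    """
    if len(events) == 0:
        raise ValueError("no events to epoch")
    if picks is None:
        picks = np.arange(rec.n_channels)
    sf = rec.sfreq
    i0 = int(round(window[0] * sf))
    i1 = int(round(window[1] * sf))
    latencies = np.arange(i0, i1 + 1) / sf
    if not ((latencies >= dc_baseline[0]) & (latencies <= dc_baseline[1])).any():
        raise ValueError("epoch window does not contain the DC baseline")
    bad_spans = [(s.start, s.end) for s in rec.bad_segments]
    bad_spans += [(e.onset, e.end) for e in rec.events if e.is_bad]
    n_lat = len(latencies)
    trials = np.zeros((len(events), len(picks), n_lat))
    good = np.ones(len(events), bool)
    reasons = [""] * len(events)
    for t, ev in enumerate(events):
        c = rec.time_to_sample(ev.onset)
        lo, hi = c + i0, c + i1
        if lo < 0 or hi >= rec.n_samples:
            good[t] = False
            reasons[t] = "edge"
            continue
        seg = rec.data[np.ix_(picks, np.arange(lo, hi + 1))]
        trials[t] = remove_dc_offset(seg, latencies, dc_baseline)
        t0, t1 = ev.onset + window[0], ev.onset + window[1]
        if any(s < t1 and t0 < e for s, e in bad_spans):
            good[t] = False
            reasons[t] = "artifact"
    return EpochSet(condition or (events[0].label if len(events) else ""), trials,
                    latencies, [rec.ch_names[i] for i in picks], good, reasons,
                    run_id, list(rec.projectors))


def average_condition(epochs: EpochSet, apply_proj: bool = True) -> Evoked:
    """Arithmetic mean over good trials of one condition within one run."""
    if epochs.n_good == 0:
        raise ValueError(f"condition {epochs.condition!r}: no good trials to average")
    mean = epochs.good_data().mean(axis=0)
    if apply_proj and epochs.projectors:
        mean = apply_projectors(mean, epochs.projectors, epochs.ch_names)
    return Evoked(epochs.condition, mean, epochs.latencies.copy(), list(epochs.ch_names),
                  epochs.n_good, "unweighted",
                  [{"run": epochs.run_id, "n_good": epochs.n_good}])


def weighted_average(evokeds: list, condition: str | None = None) -> Evoked:
    """Combine run-level averages weighted by their good-trial counts.

    Exactly equals the arithmetic mean of the pooled good trials:
    Σ nₖ·avgₖ / Σ nₖ with n_good = Σ nₖ.
    """
    _check_compatible(evokeds)
    n_total = sum(e.n_good for e in evokeds)
    data = sum(e.n_good * e.data for e in evokeds) / n_total
    prov = [p for e in evokeds for p in e.provenance]
    return Evoked(condition or evokeds[0].condition, data, evokeds[0].latencies.copy(),
                  list(evokeds[0].ch_names), n_total, "weighted", prov)


def grand_average(evokeds: list, subject_ids: list | None = None,
                  condition: str | None = None) -> Evoked:
    """Unweighted mean across subjects (each subject counts once)."""
    _check_compatible(evokeds)
    if subject_ids is not None and len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids in grand average")
    data = np.mean([e.data for e in evokeds], axis=0)
    prov = [{"subject": s if subject_ids else i, "n_good": e.n_good}
            for i, (e, s) in enumerate(zip(evokeds, subject_ids or [None] * len(evokeds)))]
    return Evoked(condition or evokeds[0].condition, data, evokeds[0].latencies.copy(),
                  list(evokeds[0].ch_names), len(evokeds), "unweighted", prov)


def contrast(ev_a: Evoked, ev_b: Evoked, mode: str = "amplitude") -> Evoked:
    """Condition contrast: ``amplitude`` → A−B; ``magnitude`` → |A|−|B|."""
    _check_compatible([ev_a, ev_b])
    if mode == "amplitude":
        data = ev_a.data - ev_b.data
    elif mode == "magnitude":
        data = np.abs(ev_a.data) - np.abs(ev_b.data)
    else:
        raise ValueError(f"unknown contrast mode {mode!r}")
    return Evoked(f"{ev_a.condition}-{ev_b.condition}[{mode}]", data,
                  ev_a.latencies.copy(), list(ev_a.ch_names),
                  min(ev_a.n_good, ev_b.n_good), "unweighted",
                  ev_a.provenance + ev_b.provenance)


def crop_time(obj, window=(-0.2, 0.9)):
    """Drop samples outside the latency window (works on Evoked or EpochSet)."""
    sel = (obj.latencies >= window[0] - 1e-12) & (obj.latencies <= window[1] + 1e-12)
    if not sel.any():
        raise ValueError(f"crop window {window} does not intersect the latency grid")
    out = obj.copy() if hasattr(obj, "copy") else obj
    out.data = obj.data[..., sel].copy()
    out.latencies = obj.latencies[sel].copy()
    return out


def _check_compatible(evokeds: list) -> None:
    if not evokeds:
        raise ValueError("empty evoked list")
    ref = evokeds[0]
    for e in evokeds[1:]:
        if e.data.shape != ref.data.shape or len(e.latencies) != len(ref.latencies):
            raise ValueError("incompatible shapes between evokeds")
        if not np.allclose(e.latencies, ref.latencies, atol=1e-9):
            raise ValueError("mismatched latency grids")
        if list(e.ch_names) != list(ref.ch_names):
            raise ValueError("mismatched channel sets")
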
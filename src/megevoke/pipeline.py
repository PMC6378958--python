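"""End-to-end scripted pipeline.

Runs the stages in fixed order (simulate → preprocess → ssp → epoch →
average → forward → inverse → tf → group), threading data in memory,
writing artifacts under the configured output directory and appending one
entry per executed stage to the execution report. Identical
(config, inputs, seed) produce identical numeric outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import events_artifacts as ea
from . import group_stats as gs
from .core_io import (ChannelKind, ExecutionReport, PipelineConfig, Recording,
                      write_channels_tsv, write_events_tsv, write_raw, logger)
from .epoch_average import (average_condition, contrast, crop_time, grand_average,
                            make_epochs, weighted_average)
from .inverse import (apply_inverse, compute_wmne_kernel, estimate_noise_cov,
                      regularize_cov, standardize_kernel, zscore_baseline)
from .preprocess import lowpass_recording, notch_filter, rereference_average, welch_psd
from .simulate import SubjectSpec, simulate_group
from .ssp import CARDIAC_BAND, CARDIAC_WINDOW_S, build_artifact_ssp
from .timefreq import ersd_normalize, make_freq_grid, morlet_tf


class PipelineState:
    """In-memory data shared between stages."""

    def __init__(self):
        self.dataset = None
        self.epochs = {}            # (subject, condition) -> list of EpochSet per run
        self.evokeds = {}           # (subject, condition) -> Evoked
        self.gains = {}
        self.kernels = {}
        self.source_maps = {}       # (subject, condition) -> np.ndarray
        self.stats = {}
        self.tf_maps = {}


def run_pipeline(config: PipelineConfig, seed: int | None = None,
                 out_dir: str | None = None) -> ExecutionReport:
    """Execute the configured stages; halt (raising) on stage failure."""
    seed = config["seed"] if seed is None else seed
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    report = ExecutionReport()
    state = PipelineState()
    stage_fns = {"simulate": _stage_simulate, "preprocess": _stage_preprocess,
                 "ssp": _stage_ssp, "epoch": _stage_epoch, "average": _stage_average,
                 "forward": _stage_forward, "inverse": _stage_inverse,
                 "tf": _stage_tf, "group": _stage_group}
    for stage in config["stages"]:
        params = dict(config[stage]) if stage in config.tree else {}
        entry = report.start_stage(stage, params)
        try:
            summary = stage_fns[stage](config, state, seed, out, entry)
        except Exception as err:
            entry.warnings.append(f"stage failed: {err}")
            report.finish_stage(entry, status="failed")
            report.to_json(out / "report.json")
            raise
        report.finish_stage(entry, **(summary or {}))
    report.to_json(out / "report.json")
    (out / "report.txt").write_text(report.to_text())
    return report


def _sim_spec(config: PipelineConfig) -> SubjectSpec:
    c = config["simulate"]
    return SubjectSpec(n_runs=c["n_runs"], n_trials=c["n_trials"],
                       conditions=tuple(c["conditions"]), sfreq=c["sfreq"],
                       n_meg_mag=c["n_meg_mag"], n_meg_grad=c["n_meg_grad"],
                       n_eeg=c["n_eeg"], cortex_subdiv=c["cortex_subdiv"],
                       trigger_delay=c["trigger_delay"], evoked_snr=c["evoked_snr"],
                       blink_rate=c["blink_rate"], heart_rate=c["heart_rate"],
                       line_freq=c["line_freq"])


def _stage_simulate(config, state, seed, out, entry):
    spec = _sim_spec(config)
    state.dataset = simulate_group(config["simulate"]["n_subjects"], spec, seed=seed)
    sub_dir = out / "sub-01" / "run-01"
    sub_dir.mkdir(parents=True, exist_ok=True)
    runs0, truth0 = state.dataset.subjects[0]
    write_raw(runs0[0], sub_dir / "raw.json")
    write_channels_tsv(runs0[0].channels, sub_dir / "channels.tsv")
    truth0.to_json(out / "sub-01" / "truth.json")
    return {"n_subjects": state.dataset.n_subjects,
            "n_runs": spec.n_runs, "sfreq": spec.sfreq}


def _stage_preprocess(config, state, seed, out, entry):
    c = config["preprocess"]
    n_bad_events = 0
    sfreq = config["simulate"]["sfreq"]
    notch = [f for f in c["notch_freqs"] if f < 0.95 * sfreq / 2]
    for runs, truth in state.dataset.subjects:
        for i, rec in enumerate(runs):
            runs[i] = rec = notch_filter(rec, notch)
            eog = rec.picks(ChannelKind.EOG)
            if len(eog):
                blinks = ea.detect_threshold_events(
                    rec, rec.ch_names[eog[0]], tuple(c["blink_band"]),
                    c["blink_threshold"], label="blink")
                rec.events = rec.events.extend(blinks)
                n_bad_events += len(blinks)
            beats = ea.detect_heartbeats(rec)
            rec.events = rec.events.extend(beats)
            arts = ea.detect_band_artifacts(rec, tuple(map(tuple, c["artifact_bands"])),
                                            c["artifact_z"])
            rec.events = rec.events.extend(arts)
            n_bad_events += len(arts)
            if len(rec.picks(ChannelKind.EEG, good_only=True)) >= 2:
                rereference_average(rec)
    psd = welch_psd(state.dataset.subjects[0][0][0], c["psd_window_s"], c["psd_overlap"])
    psd.to_tsv(out / "sub-01" / "psd.tsv")
    return {"bad_events_marked": n_bad_events}


def _stage_ssp(config, state, seed, out, entry):
    c = config["ssp"]
    n_proj = 0
    for runs, truth in state.dataset.subjects:
        for rec in runs:
            beats = rec.events.by_label("cardiac")
            if len(beats) < 10:
                continue
            for kind in (ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD):
                if len(rec.picks(kind, good_only=True)) == 0:
                    continue
                proj = build_artifact_ssp(rec, beats, c["cardiac_window_s"],
                                          tuple(c["cardiac_band"]), kind,
                                          n_active=c["n_active"])
                rec.projectors.append(proj)
                n_proj += 1
    return {"projectors_built": n_proj}


def _stage_epoch(config, state, seed, out, entry):
    c = config["epoch"]
    spec = _sim_spec(config)
    rejected = {}
    for s, (runs, truth) in enumerate(state.dataset.subjects):
        for r, rec in enumerate(runs):
            bits = ea.decode_trigger_bits(rec, "STI101")
            stim = ea.combine_bit_events(bits, sfreq=rec.sfreq)
            stim = ea.transform_events(stim, "add_offset", offset=spec.trigger_delay)
            for cond in spec.conditions:
                evs = stim.by_label(cond)
                if len(evs) == 0:
                    continue
                picks = rec.picks((ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD,
                                   ChannelKind.EEG), good_only=True)
                eset = make_epochs(rec, evs, tuple(c["window_s"]),
                                   tuple(c["dc_baseline_s"]), condition=cond,
                                   picks=picks, run_id=f"sub{s:02d}-run{r:02d}")
                state.epochs.setdefault((s, cond), []).append(eset)
                rejected[f"sub{s:02d}-run{r:02d}-{cond}"] = int((~eset.good).sum())
    return {"trials_rejected_per_run": rejected}


def _stage_average(config, state, seed, out, entry):
    spec = _sim_spec(config)
    counts = {}
    from .preprocess import apply_fir, design_fir
    lp = config["preprocess"]
    fir = design_fir("lowpass", (0, lp["lowpass_hz"]), lp["attenuation_db"], spec.sfreq)
    for (s, cond), esets in state.epochs.items():
        run_avgs = [average_condition(e) for e in esets if e.n_good > 0]
        ev = weighted_average(run_avgs, condition=cond)
        if ev.data.shape[1] > fir.order:  # low-pass the average, then crop the
            ev.data, _ = apply_fir(ev.data, fir)  # transient-contaminated edges
        ev = crop_time(ev, tuple(config["average"]["crop_s"]))
        state.evokeds[(s, cond)] = ev
        counts[f"sub{s:02d}-{cond}"] = ev.n_good
    # faces vs scrambled contrast per subject, when both present
    conds = set(spec.conditions)
    if {"Familiar", "Scrambled"} <= conds:
        for s in range(state.dataset.n_subjects):
            faces = [state.evokeds[(s, c)] for c in ("Familiar", "Unfamiliar")
                     if (s, c) in state.evokeds]
            if faces and (s, "Scrambled") in state.evokeds:
                face_ev = weighted_average(faces, condition="Faces")
                state.evokeds[(s, "Faces")] = face_ev
                state.evokeds[(s, "Faces-Scrambled")] = contrast(
                    face_ev, state.evokeds[(s, "Scrambled")], "amplitude")
    return {"good_trials": counts}


def _stage_forward(config, state, seed, out, entry):
    from .simulate import _cached_gain, make_head_geometry, make_sensor_array
    spec = _sim_spec(config)
    scalp, cortex, sphere = make_head_geometry(spec.cortex_subdiv)
    gain = _cached_gain(spec, cortex, make_sensor_array(spec), sphere)
    for s in range(state.dataset.n_subjects):
        state.gains[s] = gain
    return {"n_sources": gain.n_sources, "n_channels": len(gain.ch_names)}


def _stage_inverse(config, state, seed, out, entry):
    c = config["inverse"]
    meg_kinds = (ChannelKind.MEG_MAG, ChannelKind.MEG_GRAD)
    for s in range(state.dataset.n_subjects):
        er = state.dataset.empty_rooms[s]
        gain = state.gains[s]
        cov = estimate_noise_cov(er, "empty_room")
        kinds = {ch.name: ch.kind.value for ch in er.channels}
        cov = regularize_cov(cov, c["cov_regularization"], kinds)
        # restrict gain rows to the covariance channels (MEG-only inversion)
        rows = [i for i, n in enumerate(gain.ch_names) if n in set(cov.ch_names)]
        sub_gain = type(gain)(gain.matrix[rows], [gain.ch_names[i] for i in rows],
                              gain.source_space, gain.constrained)
        order = [sub_gain.ch_names.index(n) for n in cov.ch_names]
        sub_gain = type(gain)(sub_gain.matrix[order], list(cov.ch_names),
                              gain.source_space, gain.constrained)
        kern = compute_wmne_kernel(sub_gain, cov, c["depth_gamma"], c["snr"])
        kernels = {"wmne": kern}
        if "dspm" in c["methods"]:
            kernels["dspm"] = standardize_kernel(kern, cov, "dspm")
        if "sloreta" in c["methods"]:
            kernels["sloreta"] = standardize_kernel(kern, cov, "sloreta", sub_gain)
        state.kernels[s] = kernels
        for (ss, cond), ev in list(state.evokeds.items()):
            if ss != s or "-" in cond:
                continue
            picks = [ev.ch_names.index(n) for n in cov.ch_names]
            est = apply_inverse(kernels["wmne"], ev.data[picks], ev.latencies)
            try:
                est_z = zscore_baseline(est, tuple(config["average"]["zscore_baseline_s"]))
            except ValueError:
                est_z = est
            state.source_maps[(s, cond)] = est_z.data
    return {"methods": list(c["methods"]),
            "n_subjects_inverted": state.dataset.n_subjects}


def _stage_tf(config, state, seed, out, entry):
    c = config["tf"]
    spec = _sim_spec(config)
    grid = make_freq_grid(c["fmin"], min(c["fmax"], 0.45 * spec.sfreq), c["n_freqs"])
    for (s, cond), ev in state.evokeds.items():
        if "-" in cond:
            continue
        tf = morlet_tf(ev.data, ev.latencies, grid, spec.sfreq, c["fc"], c["fwhm_tc"],
                       ch_names=ev.ch_names)
        try:
            tf = ersd_normalize(tf, (-0.2, -0.005))
        except ValueError:
            pass  # short desk-scale epochs may mask the whole baseline at low f
        state.tf_maps[(s, cond)] = tf
    return {"n_tf_maps": len(state.tf_maps), "n_freqs": len(grid)}


def _stage_group(config, state, seed, out, entry):
    c = config["group"]
    spec = _sim_spec(config)
    conds = [cond for cond in ("Faces", "Familiar", "Scrambled")
             if all((s, cond) in state.evokeds for s in range(state.dataset.n_subjects))]
    summary = {}
    for cond in conds:
        evs = [state.evokeds[(s, cond)] for s in range(state.dataset.n_subjects)]
        ga = grand_average(evs, subject_ids=list(range(len(evs))))
        summary[f"grand_average_{cond}_peak"] = float(np.abs(ga.data).max())
    a_cond = "Faces" if "Faces" in conds else (conds[0] if conds else None)
    if a_cond and "Scrambled" in conds and a_cond != "Scrambled":
        A = np.stack([state.evokeds[(s, a_cond)].data
                      for s in range(state.dataset.n_subjects)])
        B = np.stack([state.evokeds[(s, "Scrambled")].data
                      for s in range(state.dataset.n_subjects)])
        res = gs.permutation_paired_ttest(A, B, c["n_randomizations"],
                                          seed=np.random.default_rng(seed + 1),
                                          alpha=c["alpha"])
        mask = gs.fdr_correct(res.p_map, c["alpha"])
        res.significant = mask
        res.correction = "fdr"
        res.to_tsv(out / f"group_{a_cond}_vs_Scrambled_fdr.tsv")
        state.stats["sensor_fdr"] = res
        summary["n_significant_fdr"] = int(mask.sum())
        # cluster test on sensor space
        from .simulate import make_sensor_array
        channels = make_sensor_array(spec)
        names = [ch.name for ch in channels]
        ev0 = state.evokeds[(0, a_cond)]
        pos = np.array([channels[names.index(n)].position for n in ev0.ch_names
                        if channels[names.index(n)].position is not None
                        and channels[names.index(n)].kind is ChannelKind.MEG_MAG])
        rows = [i for i, n in enumerate(ev0.ch_names)
                if channels[names.index(n)].kind is ChannelKind.MEG_MAG]
        if len(rows) >= 4:
            adj = gs.build_adjacency(pos, rule="delaunay")
            cres = gs.cluster_permutation(A[:, rows], B[:, rows], adj,
                                          n_rand=c["n_randomizations"],
                                          seed=np.random.default_rng(seed + 2),
                                          alpha=c["alpha"])
            state.stats["sensor_cluster"] = cres
            summary["n_significant_clusters"] = sum(1 for cl in cres.clusters
                                                    if cl["p"] <= c["alpha"])
    return summary
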
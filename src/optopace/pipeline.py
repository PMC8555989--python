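"""Stage driver: execute a configured stage and write outputs + provenance."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import ecg as ecg_mod
from . import gating, io, synth, vessel
from .config import RunConfig, write_provenance
from .exceptions import OptopaceError, PipelineError, ValidationError
from .trace import PulseTrain


def synth_ecg_stage(
    sampling_rate: float = 1000.0,
    duration: float = 30.0,
    heart_rate: float = 5.0,
    r_duration_unstim: float = 12.0,
    r_duration_stim: float = 18.0,
    pr_interval_unstim: float = 40.0,
    pr_interval_stim: float = 48.0,
    jitter_sd: float = 1.0,
    noise_sd: float = 0.02,
    pulse_rate: float = 5.0,
    pulse_length: float = 70.0,
    stim_latency: float = 20.0,
    stim_onset_time: float = 1e9,
    mode: str = "ventricular",
    dropout: float = 0.0,
    seed: int = 0,
):
    """Keyword facade over :func:`optopace.synth.synth_ecg` for config runs."""
    spec = synth.EcgSimSpec(
        sampling_rate=sampling_rate, duration=duration, heart_rate=heart_rate,
        r_duration_unstim=r_duration_unstim, r_duration_stim=r_duration_stim,
        pr_interval_unstim=pr_interval_unstim, pr_interval_stim=pr_interval_stim,
        jitter_sd=jitter_sd, noise_sd=noise_sd, pulse_rate=pulse_rate,
        pulse_length=pulse_length, stim_latency=stim_latency,
        stim_onset_time=stim_onset_time, mode=mode, dropout=dropout, seed=seed,
    )
    return synth.synth_ecg(spec)


def synth_vessel_stage(
    frame_rate: float = 10.0,
    n_frames: int = 100,
    pixel_size: float = 0.55,
    image_shape: tuple[int, int] = (96, 192),
    baseline_width: float = 50.0,
    width_timecourse: list | None = None,
    wall_profile_sd: float = 2.0,
    wall_intensity: float = 1000.0,
    background: float = 100.0,
    texture_amplitude: float = 100.0,
    noise_sd: float = 10.0,
    jitter_max: int = 3,
    laser_on: float = 2.0,
    laser_off: float = 8.0,
    seed: int = 0,
):
    spec = synth.VesselSimSpec(
        frame_rate=frame_rate, n_frames=n_frames, pixel_size=pixel_size,
        image_shape=tuple(image_shape), baseline_width=baseline_width,
        width_timecourse=width_timecourse, wall_profile_sd=wall_profile_sd,
        wall_intensity=wall_intensity, background=background,
        texture_amplitude=texture_amplitude, noise_sd=noise_sd,
        jitter_max=jitter_max, laser_on=laser_on, laser_off=laser_off, seed=seed,
    )
    return synth.synth_vessel_video(spec)


def synth_linescan_stage(
    n_lines_per_frame: int = 64,
    frame_rate: float = 30.0,
    cardiac_period: float = 0.15,
    resp_period: float = 0.63,
    modulation_depth: float = 0.3,
    n_frames: int = 30,
    n_cols: int = 32,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    return synth.synth_linescan(
        n_lines_per_frame, frame_rate, cardiac_period, resp_period,
        modulation_depth, seed=seed, n_frames=n_frames, n_cols=n_cols,
        noise_sd=noise_sd,
    )


def synth_fluor_stage(
    pulse_period_s: float = 0.5,
    n_pulses: int = 10,
    pulse_length_ms: float = 70.0,
    latency: float = 50.0,
    rise: float = 10.0,
    decay: float = 100.0,
    amplitude: float = 30.0,
    noise_sd: float = 0.5,
    sampling_rate: float = 1000.0,
    baseline: float = 100.0,
    seed: int = 0,
):
    rising = np.arange(n_pulses) * pulse_period_s
    pulses = PulseTrain(rising, rising + pulse_length_ms / 1000.0)
    trace, gt = synth.synth_fluor_trace(
        pulses, latency, rise, decay, amplitude, noise_sd, sampling_rate,
        seed=seed, baseline=baseline,
    )
    return trace, pulses, gt


def _json_safe(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    return obj


def _write_ground_truth(out: Path, gt: synth.GroundTruth) -> str:
    record = {}
    for name in (
        "seed", "beat_times", "beat_classes", "r_durations_ms", "p_times",
        "pr_intervals_ms", "matched_pulse_index", "pulse_rising",
        "pulse_falling", "shift_per_frame", "width_per_frame",
        "wall_centers_um", "phase_per_line", "line_times", "r_peak_times",
        "resp_peak_times", "transient_onset_times", "transient_peak",
    ):
        val = getattr(gt, name)
        if val is not None:
            record[name] = _json_safe(val)
    path = out / "ground_truth.json"
    path.write_text(json.dumps(record, indent=1, sort_keys=True))
    return path.name


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage; returns {output name: path}.

    Every output directory receives a ``provenance.json`` with the config,
    its hash, the seed, and every resolved parameter value.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.resolved_params()
    stage = config.stage
    try:
        outputs = _dispatch(stage, params, config, out)
    except OptopaceError as e:
        inputs = ", ".join(str(v) for v in config.inputs.values()) or "synthetic"
        raise type(e)(f"[stage {stage}; inputs: {inputs}] {e}") from e
    write_provenance(out, config, sorted(outputs.keys()))
    return {k: str(out / v) for k, v in outputs.items()}


def _dispatch(stage: str, params: dict, config: RunConfig, out: Path) -> dict:
    seed = config.seed
    if stage == "synth_ecg":
        ecg_t, ttl_t, gt = synth_ecg_stage(**params, seed=seed)
        io.write_time_trace(out / "ecg.csv", ecg_t)
        io.write_time_trace(out / "ttl.csv", ttl_t)
        gt_name = _write_ground_truth(out, gt)
        return {"ecg": "ecg.csv", "ttl": "ttl.csv", "ground_truth": gt_name}

    if stage == "synth_vessel":
        frames, gt = synth_vessel_stage(**params, seed=seed)
        fr = params.get("frame_rate", 10.0)
        px = params.get("pixel_size", 0.55)
        io.write_stack(out / "vessel.tiff", frames, fr, px)
        gt_name = _write_ground_truth(out, gt)
        return {"stack": "vessel.tiff", "ground_truth": gt_name}

    if stage == "synth_linescan":
        lines, ecg_t, resp_t, gt = synth_linescan_stage(**params, seed=seed)
        io.write_line_records(out / "lines.tiff", lines)
        io.write_time_trace(out / "ecg.csv", ecg_t)
        io.write_time_trace(out / "resp.csv", resp_t)
        gt_name = _write_ground_truth(out, gt)
        return {"lines": "lines.tiff", "ecg": "ecg.csv", "resp": "resp.csv",
                "ground_truth": gt_name}

    if stage == "synth_fluor":
        trace, pulses, gt = synth_fluor_stage(**params, seed=seed)
        io.write_time_trace(out / "fluor.csv", trace)
        n = trace.n
        ttl = np.zeros(n)
        t_axis = trace.times
        for r, f in zip(pulses.rising_edges, pulses.falling_edges):
            ttl[(t_axis >= r) & (t_axis < f)] = 1.0
        io.write_time_trace(out / "ttl.csv", type(trace)(trace.sampling_rate, ttl))
        gt_name = _write_ground_truth(out, gt)
        return {"fluor": "fluor.csv", "ttl": "ttl.csv", "ground_truth": gt_name}

    if stage == "ecg":
        ecg_raw = io.read_time_trace(config.inputs["ecg"])
        ttl = io.read_time_trace(config.inputs["ttl"])
        mode = params.pop("mode")
        beats = ecg_mod.analyze_ecg(ecg_raw, ttl, mode, **params)
        io.write_beat_table(out / "beats.csv", beats)
        return {"beats": "beats.csv"}

    if stage == "vessel":
        exclusion = params.pop("exclusion")
        stack = io.read_stack(config.inputs["stack"], exclusion=exclusion)
        p0 = params.pop("line_p0")
        p1 = params.pop("line_p1")
        if p0 is None or p1 is None:
            raise ValidationError("vessel stage requires line_p0 and line_p1")
        line = vessel.MeasureLine(tuple(p0), tuple(p1), params.pop("band_width"))
        stab, shifts = vessel.stabilize_stack(stack, params.pop("search_radius"))
        trace = vessel.diameter_series(
            stab, line, shifts, params.pop("max_fail_fraction"),
            params.pop("fit_halfwidth"),
        )
        trace = vessel.smooth_running_average(trace, params.pop("window"))
        io.write_diameter_trace(out / "diameter.csv", trace)
        outputs = {"diameter": "diameter.csv"}
        laser_on, laser_off = params.pop("laser_on"), params.pop("laser_off")
        if laser_on is not None and laser_off is not None:
            m = vessel.response_metrics(
                trace, laser_on, laser_off, params.pop("min_search"),
                params.pop("direction"),
            )
            (out / "response.json").write_text(json.dumps({
                "min_width_um": m.min_width, "max_width_um": m.max_width,
                "net_change_um": m.net_change, "pct_change": m.pct_change,
            }, indent=1, sort_keys=True))
            outputs["response"] = "response.json"
        return outputs

    if stage == "gate":
        lines = io.read_line_records(config.inputs["lines"])
        ecg_t = io.read_time_trace(config.inputs["ecg"])
        r_peaks = ecg_mod.detect_r_peaks(
            ecg_mod.preprocess_ecg(ecg_t), min_height=0.4)
        phases = gating.assign_cardiac_phase(lines.times, r_peaks)
        accept = None
        if "resp" in config.inputs:
            resp_t = io.read_time_trace(config.inputs["resp"])
            accept = gating.respiratory_gate(
                lines.times, resp_t, params.pop("exclusion_fraction"))
        pbs = gating.reconstruct_phase_bins(lines, phases, accept, params.pop("n_bins"))
        import tifffile

        tifffile.imwrite(out / "bins.tiff", np.nan_to_num(pbs.images).astype(np.float32))
        tifffile.imwrite(out / "counts.tiff", pbs.counts.astype(np.uint16))
        return {"bins": "bins.tiff", "counts": "counts.tiff"}

    if stage == "fluor":
        trace = io.read_time_trace(config.inputs["trace"])
        ttl = io.read_time_trace(config.inputs["ttl"])
        pulses = ecg_mod.binarize_pulses(ttl)
        res = gating.pacing_coupling(trace, pulses, **params)
        (out / "coupling.json").write_text(json.dumps({
            "coupling_fraction": res.coupling_fraction,
            "latencies_ms": _json_safe(res.latencies_ms),
            "onset_times_s": _json_safe(res.onset_times),
        }, indent=1, sort_keys=True))
        return {"coupling": "coupling.json"}

    raise ValidationError(f"unknown stage {stage!r}")
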
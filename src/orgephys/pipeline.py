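"""End-to-end orchestration: simulate/load -> preprocess -> evoked LFP ->
spectra -> MUA -> phase locking, from one config, with deterministic
per-stage seeds and a machine-readable JSON report.

Every stochastic stage derives its seed as a stable hash of (master seed,
stage name), so stage results do not depend on execution order and a rerun
with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import yaml
from fractions import Fraction
from scipy import signal as _signal

from . import __version__
from .data import Recording
from .evoked import delay_shuffle_test, epoch_trials, peak_map, trial_average
from .io import read_recording, write_events, write_recording
from .mua import detect_events, evoked_mua_snr, mua_power, overlap_shift_test
from .phase import (
    multitaper_phase,
    plv_bootstrap,
    plv_compare,
    plv_spatial_map,
    rayleigh_test,
    split_events_by_stimulus,
)
from .preprocess import exclude_channels, filter_lfp, filter_mua, remove_common_components
from .spectral import DEFAULT_BANDS, band_power, region_power_ratio
from .synth import SynthSpec, generate_recording

__all__ = ["PipelineConfig", "run_pipeline", "derive_seed", "resample_recording",
           "report_hash", "validate_report"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable, order-independent per-stage seed below 2^31."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


def resample_recording(rec: Recording, target_fs_hz: float) -> Recording:
    """Polyphase resampling of all channels to ``target_fs_hz``."""
    frac = Fraction(target_fs_hz / rec.fs_hz).limit_denominator(10000)
    data = _signal.resample_poly(rec.data, up=frac.numerator, down=frac.denominator, axis=1)
    out = dataclasses.replace(rec, data=data, fs_hz=rec.fs_hz * frac.numerator / frac.denominator)
    return out.with_data(data, f"resampled to {out.fs_hz:g} Hz")


@dataclass
class PipelineConfig:
    """One config for the whole pipeline.

    Either ``input_path`` (an HDF5 bundle) or ``synth`` (keyword arguments
    for :class:`orgephys.synth.SynthSpec`) provides the recording.  Stage
    blocks hold per-stage parameters; ``stages`` toggles them.
    """

    seed: int = 0
    outdir: str = "orgephys_out"
    input_path: Optional[str] = None
    synth: Optional[Dict[str, Any]] = None
    stages: Dict[str, bool] = field(
        default_factory=lambda: {
            "preprocess": True, "lfp": True, "spectra": True, "mua": True, "plv": True,
        }
    )
    preprocess: Dict[str, Any] = field(
        default_factory=lambda: {"max_impedance_ohm": 4e6, "uniformity_cv_max": 0.25,
                                 "run_ica": True}
    )
    lfp: Dict[str, Any] = field(
        default_factory=lambda: {"which_pulse": 0, "pre_s": 0.2, "post_s": 0.5,
                                 "search_window_s": [0.01, 0.08], "pair": [15, 0],
                                 "n_shuffles": 1000, "alternative": "two-sided"}
    )
    spectra: Dict[str, Any] = field(default_factory=lambda: {"working_fs_hz": 500.0})
    mua: Dict[str, Any] = field(
        default_factory=lambda: {"k": 3.5, "overlap_pair": [0, 15], "n_shifts": 10000,
                                 "response_window_s": [0.0, 0.3]}
    )
    plv: Dict[str, Any] = field(
        default_factory=lambda: {"target_channel": 0, "field_channel": 15,
                                 "working_fs_hz": 1000.0, "time_bandwidth": 3.0,
                                 "n_tapers": 5, "n_boot": 1000, "sample_size": 50,
                                 "band_hz": [4.0, 6.0], "spatial_map": True}
    )

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        for k, v in d.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            current = getattr(cfg, k)
            if isinstance(current, dict) and isinstance(v, dict):
                current.update(v)
            else:
                setattr(cfg, k, v)
        if cfg.input_path is None and cfg.synth is None:
            raise ValueError("config must provide input_path or synth")
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


def _jsonable(x: Any) -> Any:
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, (np.floating, float)):
        return float(x)
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, (np.bool_, bool)):
        return bool(x)
    return x


def report_hash(report: Dict[str, Any]) -> str:
    """SHA-256 of the canonical JSON serialization of a report.

    Wall time and the output location are excluded: two runs of the same
    analysis in different directories are the same result.
    """
    payload = {k: v for k, v in report.items() if k not in ("report_hash", "wall_time_s")}
    if isinstance(payload.get("config"), dict):
        payload["config"] = {k: v for k, v in payload["config"].items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(_jsonable(payload), sort_keys=True).encode()
    ).hexdigest()


_REQUIRED_REPORT_KEYS = {"version": str, "seed": int, "stages_run": list, "report_hash": str}


def validate_report(report: Dict[str, Any]) -> None:
    """Check a report against the published schema (schemas/report.schema.json)."""
    for key, typ in _REQUIRED_REPORT_KEYS.items():
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has type {type(report[key]).__name__}, "
                             f"expected {typ.__name__}")
    for stage in report["stages_run"]:
        if stage not in report:
            raise ValueError(f"report missing block for stage {stage!r}")


def run_pipeline(cfg: PipelineConfig) -> Dict[str, Any]:
    """Run all enabled stages; write stage outputs and report.json to outdir.

    A stage failure aborts with the stage name and cause; outputs of the
    stages already completed are retained on disk.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    report: Dict[str, Any] = {
        "version": __version__,
        "seed": int(cfg.seed),
        "stages_run": [],
        "config": _jsonable(dataclasses.asdict(cfg)),
    }
    log_lines = []

    def _log(stage: str, t0: float, **params):
        log_lines.append(f"{stage}: {time.time() - t0:.2f} s  params={_jsonable(params)}")

    def _run(stage_name, fn):
        t0 = time.time()
        try:
            fn()
        except Exception as e:
            report["failed_stage"] = stage_name
            report["error"] = str(e)
            (outdir / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
            raise RuntimeError(f"pipeline stage {stage_name!r} failed: {e}") from e
        report["stages_run"].append(stage_name)
        _log(stage_name, t0)

    state: Dict[str, Any] = {}

    def stage_input():
        if cfg.input_path is not None:
            state["rec"] = read_recording(cfg.input_path)
        else:
            spec = SynthSpec.from_dict({**cfg.synth, "seed": derive_seed(cfg.seed, "simulate")})
            rec, gt = generate_recording(spec)
            state["rec"], state["gt"] = rec, gt
            write_recording(rec, outdir / "recording.h5")
        report["input"] = {
            "n_channels": state["rec"].n_channels,
            "fs_hz": state["rec"].fs_hz,
            "duration_s": state["rec"].duration_s,
            "state": state["rec"].state,
        }

    _run("input", stage_input)

    def stage_preprocess():
        p = cfg.preprocess
        rec = exclude_channels(state["rec"], p["max_impedance_ohm"])
        block: Dict[str, Any] = {"n_included": int(rec.included_indices().size)}
        if p.get("run_ica", True):
            fit_mask = None
            if rec.stimulus is not None and p.get("fit_on_stimulus_free", True):
                # estimate the unmixing on background segments so evoked
                # transients do not leak into the artifact components
                fit_mask = np.ones(rec.n_samples, dtype=bool)
                pad = 0.5
                for onset in rec.stimulus.onsets_s:
                    i0 = int(onset * rec.fs_hz)
                    i1 = int((onset + rec.stimulus.train_duration_s + pad) * rec.fs_hz)
                    fit_mask[max(i0, 0) : min(i1, rec.n_samples)] = False
            rec, ica = remove_common_components(
                rec, uniformity_cv_max=p["uniformity_cv_max"],
                seed=derive_seed(cfg.seed, "ica"),
                strict_convergence=p.get("strict_convergence", False),
                fit_mask=fit_mask,
            )
            block["ica"] = {
                "n_components": ica.n_components,
                "removed": ica.removed_component_indices,
                "protected": ica.protected_component_indices,
                "converged": ica.converged,
                "mixing_uniformity": np.round(ica.mixing_uniformity, 6),
                "variance_removed_fraction": round(ica.variance_removed_fraction, 6),
            }
        state["rec"] = rec
        report["preprocess"] = _jsonable(block)

    if cfg.stages.get("preprocess", True):
        _run("preprocess", stage_preprocess)

    def stage_lfp():
        p = cfg.lfp
        lfp = filter_lfp(state["rec"])
        state["lfp"] = lfp
        tt = epoch_trials(lfp, p["which_pulse"], p["pre_s"], p["post_s"])
        mean, _sd = trial_average(tt)
        pm = peak_map(mean, tt.t_axis_s, tuple(p["search_window_s"]),
                      included=np.array([c.included for c in lfp.channels]))
        a, b = p["pair"]
        test = delay_shuffle_test(pm, a, b, n_shuffles=p["n_shuffles"],
                                  seed=derive_seed(cfg.seed, "lfp_shuffle"),
                                  alternative=p["alternative"])
        report["lfp"] = _jsonable({
            "n_trials": tt.n_trials,
            "peak_amp_uv": np.round(pm.peak_amp_uv, 4),
            "peak_delay_s": np.round(pm.peak_delay_s, 6),
            "delay_test": {**test, "pair": [a, b]},
        })

    if cfg.stages.get("lfp", True):
        _run("lfp", stage_lfp)

    def stage_spectra():
        work = resample_recording(state["rec"], cfg.spectra["working_fs_hz"])
        bp = band_power(work, DEFAULT_BANDS)
        block = {"band_power_uv2_per_hz": {c: np.round(bp[c].to_numpy(), 6) for c in bp.columns}}
        try:
            ratio = region_power_ratio(bp, work.channels)
            block["region_ratio"] = {
                b: {"organoid_ratio": round(float(r.organoid_ratio), 6),
                    "p_value": round(float(r.p_value), 6)}
                for b, r in ratio.iterrows()
            }
        except ValueError:
            block["region_ratio"] = None  # not enough labeled channels
        report["spectra"] = _jsonable(block)

    if cfg.stages.get("spectra", True):
        _run("spectra", stage_spectra)

    def stage_mua():
        p = cfg.mua
        mua = filter_mua(state["rec"])
        trains = detect_events(mua, k=p["k"])
        write_events(trains, outdir / "events.csv")
        state["trains"] = trains
        block: Dict[str, Any] = {
            "event_counts": [t.n_events for t in trains],
            "rates_hz": [round(t.n_events / mua.duration_s, 4) for t in trains],
        }
        if state["rec"].stimulus is not None:
            pw = mua_power(mua)
            snr = evoked_mua_snr(pw, state["rec"].stimulus.onsets_s,
                                 tuple(p["response_window_s"]))
            block["evoked_snr_db"] = np.round(snr, 3)
        a, b = p["overlap_pair"]
        ta = next(t for t in trains if t.channel_id == a)
        tb = next(t for t in trains if t.channel_id == b)
        block["overlap_test"] = {
            **overlap_shift_test(ta, tb, duration_s=mua.duration_s, n_shifts=p["n_shifts"],
                                 seed=derive_seed(cfg.seed, "mua_shift")),
            "pair": [a, b],
        }
        report["mua"] = _jsonable(block)

    if cfg.stages.get("mua", True):
        _run("mua", stage_mua)

    def stage_plv():
        p = cfg.plv
        lfp = state.get("lfp") or filter_lfp(state["rec"])
        work = resample_recording(lfp, p["working_fs_hz"])
        pf = multitaper_phase(work, time_bandwidth=p["time_bandwidth"],
                              n_tapers=p["n_tapers"])
        trains = state.get("trains")
        if trains is None:
            trains = detect_events(filter_mua(state["rec"]), k=cfg.mua["k"])
        target = next(t for t in trains if t.channel_id == p["target_channel"])
        seed = derive_seed(cfg.seed, "plv")
        block: Dict[str, Any] = {"target_channel": p["target_channel"],
                                 "field_channel": p["field_channel"]}
        if state["rec"].stimulus is not None:
            ev_stim, ev_ns = split_events_by_stimulus(target, state["rec"].stimulus)
            rs = plv_bootstrap(ev_stim, pf, p["field_channel"], n_boot=p["n_boot"],
                               sample_size=p["sample_size"], seed=seed, condition="stim")
            rn = plv_bootstrap(ev_ns, pf, p["field_channel"], n_boot=p["n_boot"],
                               sample_size=p["sample_size"], seed=seed + 1,
                               condition="no_stim")
            cmp_ = plv_compare(rs, rn)
            band = tuple(p["band_hz"])
            bmask = (pf.freqs_hz >= band[0]) & (pf.freqs_hz <= band[1])
            block.update({
                "freqs_hz": pf.freqs_hz,
                "plv_stim": np.round(rs.plv, 5),
                "plv_no_stim": np.round(rn.plv, 5),
                "significant": cmp_["significant"],
                "band_hz": list(band),
                "band_significant": bool(cmp_["significant"][bmask].any()),
            })
            ph = pf.lookup(p["field_channel"], ev_stim.event_times_s)
            centre = int(np.argmin(np.abs(pf.freqs_hz - np.mean(band))))
            block["rayleigh_stim_band_centre"] = rayleigh_test(ph[centre])
            if p.get("spatial_map", True):
                sm = plv_spatial_map(target, pf, state["rec"].stimulus, band_hz=band,
                                     n_boot=p["n_boot"], sample_size=p["sample_size"],
                                     seed=seed + 100)
                block["spatial_map"] = {k: v for k, v in sm.items()}
        else:
            r = plv_bootstrap(target, pf, p["field_channel"], n_boot=p["n_boot"],
                              sample_size=p["sample_size"], seed=seed)
            block.update({"freqs_hz": pf.freqs_hz, "plv": np.round(r.plv, 5)})
        report["plv"] = _jsonable(block)

    if cfg.stages.get("plv", True):
        _run("plv", stage_plv)

    report["wall_time_s"] = round(time.time() - t_start, 3)
    report["report_hash"] = report_hash(report)
    validate_report(report)
    (outdir / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return report
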
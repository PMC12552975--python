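"""Signal CSV I/O and run configuration.

Signal CSV contract: comma-separated, dot decimal, UTF-8, header required.
Columns ``time_s``, ``amplitude_mm``, ``xray_on`` (0/1) and optionally
``system``. Times are in seconds.
"""
from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

from .acquisition import AcquisitionConfig
from .experiment import RunConfig
from .prep import SignalTrace
from .surrogate import PredictorSpec, SurrogateSpec, preset
from .waveforms import TumorMotionSpec, WaveformSpec

REQUIRED_COLUMNS = ("time_s", "amplitude_mm", "xray_on")


def read_signal_csv(path) -> SignalTrace:
    """Read a signal trace; malformed rows are rejected with line numbers."""
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    numeric = {}
    # header is line 1, data starts at line 2
    bad_rows = set()
    for col in REQUIRED_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad_rows.update(int(i) + 2 for i in df.index[converted.isna()])
        numeric[col] = converted
    if bad_rows:
        raise ValueError(f"non-numeric values in {path} at line(s) {sorted(bad_rows)}")
    label = ""
    if "system" in df.columns and len(df) and not pd.isna(df["system"].iloc[0]):
        label = str(df["system"].iloc[0])
    return SignalTrace(
        numeric["time_s"].to_numpy(float),
        numeric["amplitude_mm"].to_numpy(float),
        numeric["xray_on"].to_numpy(float) > 0.5,
        label,
    )


def write_signal_csv(trace: SignalTrace, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.timestamps,
            "amplitude_mm": trace.amplitudes,
            "xray_on": trace.xray_on.astype(int),
        }
    )
    if trace.system_label:
        df["system"] = trace.system_label
    df.to_csv(path, index=False)


def _waveform_from_dict(d: dict) -> WaveformSpec:
    kw = dict(
        family=d.get("family", "cos6"),
        a_p2p_mm=float(d.get("a_p2p_mm", 15.0)),
        t_cycle_s=float(d.get("t_cycle_s", 4.0)),
        duration_s=float(d.get("duration_s", 120.0)),
        dt_s=float(d.get("dt_s", 0.02)),
        seed=int(d.get("seed", 0)),
    )
    if "a_range_mm" in d:
        kw["a_range_mm"] = tuple(float(v) for v in d["a_range_mm"])
    if "t_range_s" in d:
        kw["t_range_s"] = tuple(float(v) for v in d["t_range_s"])
    return WaveformSpec(**kw)


def _surrogate_from_dict(d: dict) -> SurrogateSpec:
    if "preset" in d:
        overrides = {k: v for k, v in d.items() if k not in ("preset", "name")}
        return preset(d["preset"], **overrides)
    return SurrogateSpec(
        latency_s=float(d.get("latency_ms", 0.0)) / 1000.0,
        noise_sd_mm=float(d.get("noise_sd_mm", 0.0)),
        scale=float(d.get("scale", 1.0)),
        baseline_offset_mm=float(d.get("baseline_offset_mm", 0.0)),
        table_coupling=float(d.get("table_coupling", 0.0)),
        name=str(d.get("name", "generic")),
    )


def load_config(path) -> RunConfig:
    """Load a YAML run configuration into a validated RunConfig."""
    raw = yaml.safe_load(pathlib.Path(path).read_text())
    waveforms = {
        str(w.get("name", f"waveform{i}")): _waveform_from_dict(w)
        for i, w in enumerate(raw.get("waveforms", []))
    }
    if not waveforms:
        raise ValueError("config must define at least one waveform")
    tumor_d = raw.get("tumor", {})
    tumor = TumorMotionSpec(
        a_si_mm=float(tumor_d.get("a_si_mm", 15.0)),
        a_ap_mm=float(tumor_d.get("a_ap_mm", 2.0)),
        a_lm_mm=float(tumor_d.get("a_lm_mm", 2.0)),
    )
    systems = {}
    for i, s in enumerate(raw.get("systems", [{"preset": "surface"}, {"preset": "marker"}])):
        name = str(s.get("name", s.get("preset", f"system{i}")))
        systems[name] = _surrogate_from_dict(s)
    pred = raw.get("prediction", {})
    acq_d = raw.get("acquisition", {})
    acq = AcquisitionConfig(
        n_couch_positions=int(acq_d.get("n_couch_positions", 4)),
        table_increment_mm=float(acq_d.get("table_increment_mm", 34.56)),
        rotation_time_s=float(acq_d.get("rotation_time_s", 0.5)),
        travel_time_s=float(acq_d.get("travel_time_s", 0.8)),
        start_time_s=float(acq_d.get("start_time_s", 2.0)),
    )
    return RunConfig(
        waveforms=waveforms,
        tumor=tumor,
        systems=systems,
        prediction_horizons_ms=[float(h) for h in pred.get("horizons_ms", [0.0])],
        predictor_order=int(pred.get("poly_order", 2)),
        predictor_window_s=float(pred.get("fit_window_s", 0.3)),
        acquisition=acq,
        n_repeats=int(raw.get("repeats", 3)),
        seed=int(raw.get("seed", 0)),
    )
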
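"""HDF5 / CSV / YAML interchange for sessions, results and configs.

Session container layout:
  /raw/<exp_id>/intensities   (wavelength, t, y, x) float32
  /dark/<gap_id>              (y, x) float32
  /events                     table: exp_id, time_s, session_time_s, kind, value
  /masks/{window,artery,vein,parenchyma,active}   optional boolean grids
  root attrs: seed, wavelengths_nm, frame_rate_hz, pixel_um, protocol (JSON),
              condition (JSON)

Result container layout:
  /roi/mask, /compartments/{artery,vein}
  /series/<exp_id>/<species>  fractional ROI series
  /concatenated/{values,times_s}
  /stats attrs: air baseline, stage log
"""

from __future__ import annotations

import dataclasses
import json
import types

import h5py
import pandas as pd
import yaml

from .errors import ValidationError
from .phantom import (
    ConditionSpec,
    ExperimentSpec,
    Protocol,
    SessionRecording,
)
from .spectra import BaselineState


def _protocol_to_json(protocol: Protocol) -> str:
    return json.dumps({
        "inter_experiment_gap_s": protocol.inter_experiment_gap_s,
        "experiments": [dataclasses.asdict(e) for e in protocol.experiments],
    })


def _protocol_from_json(s: str) -> Protocol:
    d = json.loads(s)
    return Protocol(
        experiments=tuple(ExperimentSpec(**e) for e in d["experiments"]),
        inter_experiment_gap_s=d["inter_experiment_gap_s"],
    )


def save_session(recording: SessionRecording, path) -> None:
    """Write a SessionRecording to an HDF5 container."""
    with h5py.File(path, "w") as f:
        raw = f.create_group("raw")
        for exp_id, movie in recording.intensities.items():
            raw.create_group(exp_id).create_dataset(
                "intensities", data=movie, compression="gzip",
                compression_opts=1)
        dark = f.create_group("dark")
        for gap_id, frame in recording.dark_frames.items():
            dark.create_dataset(gap_id, data=frame)
        ev = recording.events
        g = f.create_group("events")
        g.create_dataset("exp_id", data=ev["exp_id"].astype("S"))
        g.create_dataset("time_s", data=ev["time_s"].to_numpy(float))
        g.create_dataset("session_time_s",
                         data=ev["session_time_s"].to_numpy(float))
        g.create_dataset("kind", data=ev["kind"].astype("S"))
        g.create_dataset("value", data=ev["value"].astype("S"))
        if recording.phantom is not None:
            m = f.create_group("masks")
            ph = recording.phantom
            for name in ("window", "artery", "vein", "parenchyma", "active"):
                m.create_dataset(name, data=getattr(ph, f"{name}_mask"))
        f.attrs["wavelengths_nm"] = list(recording.wavelengths_nm)
        f.attrs["frame_rate_hz"] = recording.frame_rate_hz
        f.attrs["protocol"] = _protocol_to_json(recording.protocol)
        if recording.condition is not None:
            f.attrs["condition"] = json.dumps(
                dataclasses.asdict(recording.condition))
        for k, v in recording.meta.items():
            if isinstance(v, (int, float, str)):
                f.attrs[f"meta_{k}"] = v


def load_session(path) -> SessionRecording:
    """Read a SessionRecording container (no ground truth is stored)."""
    with h5py.File(path, "r") as f:
        intensities = {
            exp_id: f["raw"][exp_id]["intensities"][()]
            for exp_id in f["raw"]
        }
        dark = {gap_id: f["dark"][gap_id][()] for gap_id in f["dark"]}
        g = f["events"]
        events = pd.DataFrame({
            "exp_id": [s.decode() for s in g["exp_id"][()]],
            "time_s": g["time_s"][()],
            "session_time_s": g["session_time_s"][()],
            "kind": [s.decode() for s in g["kind"][()]],
            "value": [s.decode() for s in g["value"][()]],
        })
        protocol = _protocol_from_json(f.attrs["protocol"])
        condition = None
        if "condition" in f.attrs:
            condition = ConditionSpec(**json.loads(f.attrs["condition"]))
        phantom = None
        if "masks" in f:
            ns = types.SimpleNamespace()
            for name in ("window", "artery", "vein", "parenchyma", "active"):
                setattr(ns, f"{name}_mask", f["masks"][name][()].astype(bool))
            phantom = ns
        meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
        return SessionRecording(
            intensities=intensities,
            dark_frames=dark,
            events=events,
            wavelengths_nm=tuple(float(w) for w in f.attrs["wavelengths_nm"]),
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            protocol=protocol,
            condition=condition,
            phantom=phantom,
            truth=None,
            meta=meta,
        )


def save_results(result, path) -> None:
    """Write a SessionResult to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_group("roi").create_dataset("mask", data=result.roi.pixels)
        f["roi"].attrs["k_sd"] = result.roi.k_sd
        f["roi"].attrs["source_experiment"] = result.roi.source_experiment
        comp = f.create_group("compartments")
        if result.artery_mask is not None:
            comp.create_dataset("artery", data=result.artery_mask)
            comp.create_dataset("vein", data=result.vein_mask)
        ser = f.create_group("series")
        for exp_id, er in result.experiments.items():
            g = ser.create_group(exp_id)
            for sp, series in er.roi_series.items():
                g.create_dataset(sp, data=series)
            if er.magnitudes:
                for sp, m in er.magnitudes.items():
                    g.attrs[f"magnitude_{sp}"] = m
        cs = f.create_group("concatenated")
        cs.create_dataset("values", data=result.concatenated_hbt.values)
        cs.create_dataset("times_s", data=result.concatenated_hbt.times_s)
        st = f.create_group("stats")
        if result.air_baseline is not None:
            st.attrs["air_hbt_uM"] = result.air_baseline.hbt_uM
            st.attrs["air_so2"] = result.air_baseline.so2
        st.attrs["stage_log"] = "\n".join(result.stage_log)


def events_to_csv(events: pd.DataFrame, path) -> None:
    """Event-log interchange CSV with header time_s,kind,value."""
    events[["time_s", "kind", "value"]].to_csv(path, index=False)


def events_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = {"time_s", "kind", "value"} - set(df.columns)
    if missing:
        raise ValidationError(f"event CSV missing columns {sorted(missing)}")
    return df


def load_config(path) -> dict:
    """Read a YAML analysis-config mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config YAML must be a mapping")
    return cfg


def baseline_from_config(cfg: dict, key: str,
                         default: BaselineState) -> BaselineState:
    if key not in cfg:
        return default
    v = cfg[key]
    return BaselineState(hbt_uM=float(v["hbt_uM"]), so2=float(v["so2"]),
                         condition=v.get("condition", default.condition))
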
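"""Readers/writers for the pipeline's on-disk formats.

Traces are cells x time CSV (row index ``cell``), events are long-format
CSV (``trial,event,time_s``), videos are multi-page TIFF, everything else
is JSON.  All writers are deterministic (fixed float format, sorted JSON
keys) so reruns with the same seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from graftdyn.preprocess import SessionRecording, EVENT_NAMES

FLOAT_FMT = "%.10g"


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(path, obj):
    Path(path).write_text(json.dumps(_to_jsonable(obj), indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_table(path, df: pd.DataFrame, index=False):
    df.to_csv(path, index=index, float_format=FLOAT_FMT)


def write_traces(path, traces: np.ndarray):
    df = pd.DataFrame(np.asarray(traces))
    df.index.name = "cell"
    df.to_csv(path, float_format=FLOAT_FMT)


def read_traces(path) -> np.ndarray:
    df = pd.read_csv(path, index_col="cell")
    return df.to_numpy(dtype=float)


def write_events(path, events: pd.DataFrame):
    missing = {"trial", "event", "time_s"} - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    events.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"trial", "event", "time_s"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[df.time_s.isna() | ~df.event.isin(EVENT_NAMES)]
    if len(bad):
        raise ValueError(f"{path}: malformed event rows {bad.tolist()[:5]}")
    return df


def write_session(outdir, rec: SessionRecording):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_traces(outdir / "traces.csv", rec.traces)
    write_traces(outdir / "residuals.csv", rec.residuals)
    write_events(outdir / "events.csv", rec.events)
    write_json(outdir / "meta.json", {
        "rate_hz": rec.rate_hz, "session_label": rec.session_label,
        "success": rec.success, "attempt": rec.attempt})


def read_session(indir) -> SessionRecording:
    indir = Path(indir)
    for f in ("traces.csv", "residuals.csv", "events.csv", "meta.json"):
        if not (indir / f).exists():
            raise FileNotFoundError(f"missing input file: {indir / f}")
    meta = read_json(indir / "meta.json")
    return SessionRecording(
        traces=read_traces(indir / "traces.csv"),
        residuals=read_traces(indir / "residuals.csv"),
        rate_hz=meta["rate_hz"], events=read_events(indir / "events.csv"),
        success=np.asarray(meta["success"], dtype=bool),
        attempt=np.asarray(meta["attempt"], dtype=bool),
        session_label=meta["session_label"])


def write_tiff(path, frames: np.ndarray):
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
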
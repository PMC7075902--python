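"""Tabular I/O: trial tables and oxygen traces as plain CSV (+ JSON sidecars).

Round-trips are lossless for every analysis field and reads are schema
validated: missing columns, malformed or duplicate rows, and non-uniform
sampling are all reported with names / line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import O2Trace

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "read_trace",
    "write_trace",
    "SchemaError",
]

TRIAL_COLUMNS = (
    "animal_id", "session", "regime", "trial", "cue", "sound", "rewarded",
    "iti_s", "cue_onset_s", "outcome_onset_s", "pre_cue_rate", "cue_rate",
)


class SchemaError(ValueError):
    """A table or trace file failed validation."""


def write_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing required column(s): {missing}")
    trials.to_csv(path, index=False)
    return path


def read_trials(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {missing}")
    dup = df.duplicated(subset=["animal_id", "session", "trial"])
    if dup.any():
        # +2: header line plus 1-based numbering
        lines = (df.index[dup] + 2).tolist()
        raise SchemaError(
            f"{path.name}: duplicate (animal_id, session, trial) at line(s) {lines}"
        )
    bad_rew = ~df["rewarded"].isin((0, 1))
    if bad_rew.any():
        lines = (df.index[bad_rew] + 2).tolist()
        raise SchemaError(f"{path.name}: rewarded must be 0/1 at line(s) {lines}")
    for col in ("iti_s", "cue_onset_s", "outcome_onset_s", "pre_cue_rate", "cue_rate"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise SchemaError(f"{path.name}: column {col!r} is not numeric")
    return df


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_trace(
    trace: O2Trace, csv_path: str | Path, events: pd.DataFrame | None = None
) -> Path:
    """Write one electrode-session trace (CSV) plus its JSON sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": trace.time_s, "signal": trace.signal}).to_csv(
        csv_path, index=False
    )
    sidecar = {
        "animal_id": trace.animal_id,
        "region": trace.region,
        "electrode_id": trace.electrode_id,
        "session": int(trace.session),
        "events": [] if events is None else events.to_dict(orient="records"),
    }
    _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_trace(csv_path: str | Path) -> tuple[O2Trace, pd.DataFrame]:
    """Read a trace CSV and its sidecar; returns (trace, events frame)."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    for col in ("time_s", "signal"):
        if col not in df.columns:
            raise SchemaError(f"{csv_path.name}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) >= 2:
        dts = np.diff(t)
        if dts.max() - dts.min() > 1e-9:
            raise SchemaError(
                f"{csv_path.name}: non-uniform sampling, dt in "
                f"[{dts.min():.9g}, {dts.max():.9g}] s"
            )
    sidecar_file = _sidecar_path(csv_path)
    if not sidecar_file.exists():
        raise SchemaError(f"missing sidecar {sidecar_file.name}")
    meta = json.loads(sidecar_file.read_text())
    trace = O2Trace(
        time_s=t,
        signal=df["signal"].to_numpy(dtype=float),
        region=meta["region"],
        electrode_id=meta["electrode_id"],
        animal_id=meta["animal_id"],
        session=int(meta["session"]),
    )
    return trace, pd.DataFrame(meta.get("events", []))
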
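"""Readers and writers for the pipeline's on-disk formats.

Sessions travel as CSV with one row per trial (timestamps to 6 decimal
places, missing first-lick as an empty field); raw photometry and
demodulated signals use an HDF5 container, with a (t, value) CSV fallback
for small demodulated fixtures. All readers validate schema and per-trial
timestamp ordering and name the offending trial on failure.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence, Union

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .photometry import DemodSignal, RawPhotometry
from .task import SESSION_COLUMNS, SessionTable


class SchemaError(ValueError):
    """Input file violates the expected schema."""


def write_sessions(sessions: Sequence[SessionTable],
                   path: Union[str, Path]) -> None:
    """Write sessions to one CSV (task-simulator dialect)."""
    frames = [s.trials for s in sessions]
    df = pd.concat(frames, ignore_index=True)[SESSION_COLUMNS]
    df.to_csv(path, index=False, float_format="%.6f")


def _validate_trial_order(df: pd.DataFrame) -> None:
    t_ce, t_cx = df["t_CE"].to_numpy(), df["t_CX"].to_numpy()
    t_se, t_sx = df["t_SE"].to_numpy(), df["t_SX"].to_numpy()
    bad = ~((t_ce < t_cx) & (t_cx <= t_se) & (t_se < t_sx))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        row = df.iloc[i]
        raise SchemaError(
            f"event timestamps out of order at mouse {row['mouse_id']} "
            f"session {row['session_id']} trial {row['trial']}")
    fl = df["t_FL"].to_numpy()
    has_fl = ~np.isnan(fl)
    bad_fl = has_fl & ~((t_se <= fl) & (fl < t_sx))
    if bad_fl.any():
        i = int(np.flatnonzero(bad_fl)[0])
        row = df.iloc[i]
        raise SchemaError(
            f"first lick outside side-port occupancy at trial {row['trial']}")


def read_sessions(path: Union[str, Path]) -> list[SessionTable]:
    """Read and validate a sessions CSV; one SessionTable per
    (mouse, session)."""
    df = pd.read_csv(path)
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    df["rewarded"] = df["rewarded"].astype(bool)
    _validate_trial_order(df)
    out = []
    for (mouse, sess), grp in df.groupby(["mouse_id", "session_id"],
                                         sort=True):
        grp = grp.sort_values("trial").reset_index(drop=True)
        out.append(SessionTable(grp[SESSION_COLUMNS], mouse_id=str(mouse),
                                session_id=str(sess)))
    return out


def write_photometry(raw: RawPhotometry, path: Union[str, Path]) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("raw")
        g.create_dataset("samples", data=raw.samples)
        g.create_dataset("fs", data=raw.fs)
        g.create_dataset("carriers", data=np.asarray(raw.carriers))
        if raw.events is not None:
            ev = f.create_group("events")
            ev.create_dataset(
                "name", data=np.array(raw.events["name"], dtype="S16"))
            ev.create_dataset("t", data=raw.events["t"].to_numpy(float))


def read_photometry(path: Union[str, Path]) -> RawPhotometry:
    with h5py.File(path, "r") as f:
        samples = f["raw/samples"][()]
        fs = float(f["raw/fs"][()])
        carriers = tuple(float(c) for c in f["raw/carriers"][()])
        events = None
        if "events" in f:
            events = pd.DataFrame({
                "name": [n.decode() for n in f["events/name"][()]],
                "t": f["events/t"][()],
            })
    return RawPhotometry(samples=samples, fs=fs, carriers=carriers,
                         events=events)


def write_demod(sig: DemodSignal, path: Union[str, Path]) -> None:
    """HDF5 for .h5 paths, (t, value) CSV fallback otherwise."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            g = f.create_group("demod")
            g.create_dataset("values", data=sig.values)
            g.create_dataset("t0", data=sig.t0)
            g.create_dataset("period", data=sig.period)
            if sig.power is not None:
                g.create_dataset("power", data=sig.power)
    else:
        pd.DataFrame({"t": sig.times, "value": sig.values}).to_csv(
            path, index=False)


def read_demod(path: Union[str, Path]) -> DemodSignal:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            power = f["demod/power"][()] if "demod/power" in f else None
            return DemodSignal(values=f["demod/values"][()],
                               t0=float(f["demod/t0"][()]),
                               period=float(f["demod/period"][()]),
                               power=power)
    df = pd.read_csv(path)
    t = df["t"].to_numpy(float)
    period = float(np.median(np.diff(t)))
    return DemodSignal(values=df["value"].to_numpy(float), t0=float(t[0]),
                       period=period)


class PipelineConfig(BaseModel):
    """Validated configuration; defaults are the task's standard settings."""

    p_high: float = 0.9
    p_low: float = 0.1
    rewards_per_block: int = 50
    n_trials: int = 500
    alpha: float = 1.0
    beta: float = 2.0
    tau: float = 1.4
    T: int = 20
    ridge_alpha: float = 1.0
    carriers: tuple[float, float] = (167.0, 223.0)
    spectrogram_window: int = 216
    spectrogram_hop: int = 108
    n_bins: int = 13
    outcome_window_s: float = 0.5
    zscore_window_s: float = 60.0
    hemisphere: str = Field(default="left", pattern="^(left|right)$")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as f:
            return cls(**(yaml.safe_load(f) or {}))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
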
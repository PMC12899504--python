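"""CSV / JSON interchange for trials and detected events.

Trial CSV layout: header ``t,pelvis_vz,foot_ax,foot_ay,foot_az`` with an
optional ``vgrf`` column; ``t`` in seconds, strictly increasing and uniform.
Because the force plate samples at 1000 Hz and the IMUs at 60 Hz, the force
channel normally lives in a separate two-column file (``t,vgrf``) on the
same trial clock.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .signals import (
    ContactEvent,
    Trial,
    TrialMeta,
    TriaxialSignal,
    UniformSignal,
)

_IMU_COLUMNS = ["pelvis_vz", "foot_ax", "foot_ay", "foot_az"]
_TIME_TOL_S = 1e-6


def _uniform_rate(t: np.ndarray, path: Path) -> tuple[float, float]:
    """Validate a strictly increasing uniform time column; return (rate, t0)."""
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 rows")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise FormatError(f"{path}: time not strictly increasing at row {row}")
    step = (t[-1] - t[0]) / (t.size - 1)
    dev = np.abs(dt - step)
    if dev.max() > _TIME_TOL_S:
        row = int(dev.argmax()) + 1
        raise FormatError(
            f"{path}: non-uniform time stamps at row {row} "
            f"(deviation {dev.max():.2e} s)"
        )
    return 1.0 / step, float(t[0])


def _read_csv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ["t", *required] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in df.columns:
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            row = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise FormatError(f"{path}: non-finite value at row {row}, column {col}")
    return df


def read_trial(
    path: str | Path, meta: TrialMeta, vgrf_path: str | Path | None = None
) -> Trial:
    """Load a trial from its IMU CSV, optionally with a separate force CSV.

    A ``vgrf`` column in the IMU file is honored (single-file layout); a
    separate ``vgrf_path`` takes precedence and allows the force channel
    its own (higher) rate.
    """
    path = Path(path)
    df = _read_csv(path, _IMU_COLUMNS)
    rate, t0 = _uniform_rate(df["t"].to_numpy(dtype=float), path)

    def chan(col: str) -> UniformSignal:
        return UniformSignal(df[col].to_numpy(dtype=float), rate=rate, t0=t0)

    pelvis = chan("pelvis_vz")
    foot = TriaxialSignal(chan("foot_ax"), chan("foot_ay"), chan("foot_az"))

    vgrf: Optional[UniformSignal] = None
    if vgrf_path is not None:
        gpath = Path(vgrf_path)
        gdf = _read_csv(gpath, ["vgrf"])
        grate, gt0 = _uniform_rate(gdf["t"].to_numpy(dtype=float), gpath)
        vgrf = UniformSignal(gdf["vgrf"].to_numpy(dtype=float), rate=grate, t0=gt0)
    elif "vgrf" in df.columns:
        vgrf = UniformSignal(df["vgrf"].to_numpy(dtype=float), rate=rate, t0=t0)

    return Trial(meta=meta, pelvis_vz=pelvis, foot_acc=foot, vgrf=vgrf)


def write_trial(
    trial: Trial, path: str | Path, vgrf_path: str | Path | None = None
) -> None:
    """Write a trial's IMU channels (and, if present, its force channel)."""
    path = Path(path)
    imu = pd.DataFrame(
        {
            "t": trial.pelvis_vz.times(),
            "pelvis_vz": trial.pelvis_vz.values,
            "foot_ax": trial.foot_acc.x.values,
            "foot_ay": trial.foot_acc.y.values,
            "foot_az": trial.foot_acc.z.values,
        }
    )
    imu.to_csv(path, index=False, float_format="%.12g")
    if trial.vgrf is not None and vgrf_path is not None:
        grf = pd.DataFrame({"t": trial.vgrf.times(), "vgrf": trial.vgrf.values})
        grf.to_csv(Path(vgrf_path), index=False, float_format="%.12g")


def write_events(
    events: Sequence[tuple[TrialMeta, str, Optional[ContactEvent]]],
    path: str | Path,
) -> None:
    """Write one JSON record per trial x algorithm.

    A missing event (detection failure) is recorded with ``failed: true``
    and null times, so failure counts stay auditable downstream.
    """
    records = []
    for meta, algorithm, event in events:
        rec = {
            "trial_id": meta.trial_id,
            "participant_id": meta.participant_id,
            "task": meta.task.value,
            "sex": meta.sex.value,
            "leg": meta.leg.value,
            "algorithm": str(algorithm),
            "failed": event is None,
            "ic_time_s": None if event is None else event.ic_time,
            "to_time_s": None if event is None else event.to_time,
            "duration_ms": None if event is None else 1000.0 * event.duration,
        }
        records.append(rec)
    Path(path).write_text(json.dumps(records, indent=1))


def read_events(path: str | Path) -> list[dict]:
    """Read back an events JSON file as a list of plain records."""
    records = json.loads(Path(path).read_text())
    if not isinstance(records, list):
        raise FormatError(f"{path}: expected a JSON array of event records")
    return records
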
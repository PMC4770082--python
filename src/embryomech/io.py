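"""File formats: cohort/trace CSV, TIFF stacks with JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from embryomech.tracking import ImageSequence
from embryomech.viscoelastic import AspirationTrace

TRACE_COLUMNS = ["time_s", "pressure_pa", "depth_m"]


def write_trace_csv(trace: AspirationTrace, path) -> None:
    pressure = (
        trace.pressure_pa
        if trace.pressure_pa is not None
        else np.full(trace.times_s.size, np.nan)
    )
    pd.DataFrame(
        {"time_s": trace.times_s, "pressure_pa": pressure, "depth_m": trace.depths_m}
    ).to_csv(path, index=False)


def read_trace_csv(path, rate_hz: float | None = None) -> AspirationTrace:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    times = df["time_s"].to_numpy(float)
    if rate_hz is None:
        rate_hz = 1.0 / float(np.median(np.diff(times)))
    pressure = df["pressure_pa"].to_numpy(float)
    if np.isnan(pressure).all():
        pressure = None
    return AspirationTrace(times, df["depth_m"].to_numpy(float), rate_hz, pressure)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["blastocyst"] = df["blastocyst"].astype(bool)
    return df


def write_stack(path, frames: np.ndarray, sidecar: dict | None = None) -> None:
    """Multi-page TIFF plus a JSON sidecar (same stem, .json suffix)."""
    tifffile.imwrite(path, frames)
    if sidecar is not None:
        Path(path).with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path) -> tuple[np.ndarray, dict]:
    frames = tifffile.imread(path)
    sidecar_path = Path(path).with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return frames, sidecar


def read_sequence(path) -> tuple[ImageSequence, dict]:
    frames, sidecar = read_stack(path)
    return (
        ImageSequence(
            frames=frames,
            pixel_size_m=float(sidecar.get("pixel_size_m", 0.5e-6)),
            frame_rate_hz=float(sidecar.get("frame_rate_hz", 75.0)),
        ),
        sidecar,
    )
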
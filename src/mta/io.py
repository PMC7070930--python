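"""File formats: measurement CSV, config YAML, frames + index, mode grids.

All text formats are comma-separated UTF-8 with ``.`` decimals and a
mandatory header.  Units are fixed by the header contract: time in seconds
(``time_s``), temperature in degC (``temp_C``), frequencies in Hz
(``<mode>_freq_Hz``), quality factors dimensionless (``<mode>_Q``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .deconvolution import DeconvolutionResult
from .mode_analysis import ModeGrid
from .signal_simulator import Measurement, TgScenario

_FREQ_RE = re.compile(r"^(?P<mode>.+)_freq_Hz$")


def write_measurement(measurement: Measurement, path: str | Path) -> None:
    """Write a measurement as CSV: time_s,temp_C,<mode>_freq_Hz,<mode>_Q.

    The embedded ground truth, when present, is echoed into a JSON sidecar
    next to the CSV (``<stem>.truth.json``).
    """
    path = Path(path)
    cols: dict[str, np.ndarray] = {
        "time_s": measurement.time,
        "temp_C": measurement.temperature,
    }
    for mid in measurement.mode_ids:
        cols[f"{mid}_freq_Hz"] = measurement.freq[mid]
        cols[f"{mid}_Q"] = measurement.quality[mid]
    pd.DataFrame(cols).to_csv(path, index=False)
    if measurement.truth is not None:
        sidecar = path.with_suffix(".truth.json")
        sidecar.write_text(json.dumps(dataclasses.asdict(measurement.truth), indent=2))


def load_trace(path: str | Path) -> Measurement:
    """Read a measurement CSV back into a validated Measurement."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "temp_C"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    mode_ids = [m.group("mode") for c in df.columns if (m := _FREQ_RE.match(c))]
    if not mode_ids:
        raise ValueError(f"no '<mode>_freq_Hz' columns found in {path}")
    for mid in mode_ids:
        if f"{mid}_Q" not in df.columns:
            raise ValueError(f"missing quality column {mid}_Q in {path}")
    time = df["time_s"].to_numpy(dtype=float)
    if time.size < 2 or np.any(np.diff(time) <= 0):
        raise ValueError(f"time column of {path} is not strictly increasing")
    dt = float(np.median(np.diff(time)))

    truth = None
    sidecar = path.with_suffix(".truth.json")
    if sidecar.exists():
        truth = TgScenario(**json.loads(sidecar.read_text()))

    return Measurement(
        time=time,
        temperature=df["temp_C"].to_numpy(dtype=float),
        freq={mid: df[f"{mid}_freq_Hz"].to_numpy(dtype=float) for mid in mode_ids},
        quality={mid: df[f"{mid}_Q"].to_numpy(dtype=float) for mid in mode_ids},
        mode_ids=mode_ids,
        dt=dt,
        truth=truth,
    )


def write_deconvolution(result: DeconvolutionResult, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": result.time,
            "temp_C": result.temperature,
            "raw": result.raw,
            "ufs": result.ufs,
            "periodic": result.periodic,
            "p_ue": result.p_ue,
            "ts_ue": result.ts_ue,
            "rs": result.rs,
        }
    ).to_csv(path, index=False)


def read_deconvolution(path: str | Path, P: float, dt: float,
                       edge_samples: Optional[int] = None) -> DeconvolutionResult:
    from .deconvolution import period_window

    df = pd.read_csv(path)
    need = {"time_s", "temp_C", "raw", "ufs", "periodic", "p_ue", "ts_ue", "rs"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"deconvolution CSV missing columns: {sorted(missing)}")
    return DeconvolutionResult(
        time=df["time_s"].to_numpy(float),
        temperature=df["temp_C"].to_numpy(float),
        raw=df["raw"].to_numpy(float),
        ufs=df["ufs"].to_numpy(float),
        periodic=df["periodic"].to_numpy(float),
        p_ue=df["p_ue"].to_numpy(float),
        ts_ue=df["ts_ue"].to_numpy(float),
        rs=df["rs"].to_numpy(float),
        P=P,
        dt=dt,
        edge_samples=period_window(P, dt) if edge_samples is None else edge_samples,
    )


# ---------------------------------------------------------------------------
# frames


def write_frames(frames: np.ndarray, temperature: np.ndarray, out_dir: str | Path) -> Path:
    """Write numbered 8-bit PNG frames plus a ``frame,temp_C`` index CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(out_dir / f"frame_{i:05d}.png", frame)
    index = out_dir / "index.csv"
    pd.DataFrame({"frame": np.arange(len(frames)), "temp_C": temperature}).to_csv(
        index, index=False
    )
    return index


def read_frames(frames_dir: str | Path, index_csv: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a numbered PNG/TIFF stack and its temperature index."""
    frames_dir = Path(frames_dir)
    index_csv = Path(index_csv)
    if not index_csv.exists():
        raise FileNotFoundError(f"missing frame index CSV: {index_csv}")
    idx = pd.read_csv(index_csv)
    if "frame" not in idx.columns or "temp_C" not in idx.columns:
        raise ValueError(f"index CSV {index_csv} must have columns frame,temp_C")
    paths = sorted(p for p in frames_dir.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"})
    if len(paths) != len(idx):
        raise ValueError(
            f"{len(paths)} frames in {frames_dir} but {len(idx)} index rows"
        )
    stack = np.stack([iio.imread(p) for p in paths])
    if stack.ndim == 4:  # grayscale saved with a channel axis
        stack = stack[..., 0]
    return stack.astype(np.uint8), idx["temp_C"].to_numpy(float)


# ---------------------------------------------------------------------------
# mode grids


def write_grid(grid: ModeGrid, path: str | Path) -> None:
    """Write a grid as CSV with a leading ``# frequency_Hz=`` header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# frequency_Hz={grid.frequency}\n")
        fh.write("x_frac,y_frac,re_amp,im_amp\n")
        for (x, y), a in zip(grid.points, grid.amplitudes):
            fh.write(f"{x},{y},{a.real},{a.imag}\n")


def read_grid(path: str | Path) -> ModeGrid:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# frequency_Hz="):
            raise ValueError(f"{path} missing '# frequency_Hz=' header line")
        freq = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    need = {"x_frac", "y_frac", "re_amp", "im_amp"}
    if not need <= set(df.columns):
        raise ValueError(f"grid CSV missing columns: {sorted(need - set(df.columns))}")
    return ModeGrid(
        points=df[["x_frac", "y_frac"]].to_numpy(float),
        amplitudes=df["re_amp"].to_numpy(float) + 1j * df["im_amp"].to_numpy(float),
        frequency=freq,
    )


# ---------------------------------------------------------------------------
# config


def write_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path: str | Path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, embedded in outputs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
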
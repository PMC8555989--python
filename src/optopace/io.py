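"""Readers and writers for the on-disk formats.

Conventions: CSV is comma-separated, UTF-8, ``.`` decimal, with
``#``-prefixed metadata header lines (``# key=value``); times are seconds as
floats.  Image stacks are multi-page TIFF with acquisition metadata in a
JSON sidecar (``<stem>.json``) rather than TIFF tags, for portability.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError, ValidationError
from .trace import TimeTrace
from .vessel import FrameStack


def _read_meta_header(path: Path) -> tuple[dict, int]:
    """Parse leading ``# key=value`` lines; returns (meta, n_header_lines)."""
    meta: dict[str, str] = {}
    n = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta, n


def write_time_trace(path: str | Path, trace: TimeTrace) -> None:
    """Write a trace as CSV with ``# fs_hz=`` and ``# t0_s=`` header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs_hz={trace.sampling_rate!r}\n")
        fh.write(f"# t0_s={trace.start_time!r}\n")
        fh.write("time_s,value\n")
        for t, v in zip(trace.times, trace.samples):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def read_time_trace(path: str | Path) -> TimeTrace:
    """Read a trace CSV; the ``# fs_hz=`` header is mandatory.

    Malformed data rows are skipped with a warning naming their 1-based line
    numbers; a non-monotone time column is a format error.
    """
    path = Path(path)
    meta, n_header = _read_meta_header(path)
    if "fs_hz" not in meta:
        raise FormatError(f"{path}: missing '# fs_hz=' header")
    try:
        fs = float(meta["fs_hz"])
    except ValueError as e:
        raise FormatError(f"{path}: unparsable fs_hz value {meta['fs_hz']!r}") from e
    t0 = float(meta.get("t0_s", 0.0))

    times: list[float] = []
    values: list[float] = []
    bad: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= n_header or lineno == n_header + 1:  # meta + column header
                continue
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                t, v = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                bad.append(lineno)
                continue
            times.append(t)
            values.append(v)
    if bad:
        warnings.warn(f"{path}: skipped malformed rows at lines {bad}")
    if not values:
        raise FormatError(f"{path}: no data rows")
    t_arr = np.asarray(times)
    if t_arr.size > 1 and np.any(np.diff(t_arr) <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    return TimeTrace(fs, np.asarray(values), t0)


def write_stack(
    path: str | Path,
    frames: np.ndarray,
    frame_rate: float,
    pixel_size: float,
    dtype: str | None = "uint16",
    extra_meta: dict | None = None,
) -> None:
    """Write frames as multi-page TIFF plus a JSON metadata sidecar.

    With ``dtype='uint16'`` (the default for synthetic output) values are
    clipped to [0, 65535] and rounded; pass ``dtype=None`` to keep float32.
    """
    path = Path(path)
    frames = np.asarray(frames)
    if dtype == "uint16":
        data = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    elif dtype is None:
        data = frames.astype(np.float32)
    else:
        data = frames.astype(dtype)
    tifffile.imwrite(path, data)
    meta = {"frame_rate_hz": frame_rate, "pixel_size_um": pixel_size}
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_stack(path: str | Path, exclusion: tuple[int, int, int, int] | None = None) -> FrameStack:
    """Read a multi-page TIFF and its JSON sidecar into a FrameStack."""
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as e:
        raise FormatError(f"{path}: expected a multi-page TIFF stack ({e})") from e
    if isinstance(data, (list, tuple)):
        raise FormatError(f"{path}: pages have inconsistent shapes")
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 2-D pages, got {data.ndim - 1}-D")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"{path}: missing metadata sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    for field in ("frame_rate_hz", "pixel_size_um"):
        if field not in meta:
            raise FormatError(f"{sidecar}: missing metadata field '{field}'")
    return FrameStack(
        data.astype(float), float(meta["frame_rate_hz"]), float(meta["pixel_size_um"]), exclusion
    )


BEAT_CSV_COLUMNS = [
    "r_peak_time_s",
    "p_peak_time_s",
    "label",
    "r_duration_ms",
    "pr_interval_ms",
    "matched_pulse_index",
]


def write_beat_table(path: str | Path, beats: pd.DataFrame) -> None:
    beats.to_csv(path, index=False, columns=BEAT_CSV_COLUMNS)


def read_beat_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in BEAT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing beat-table columns {missing}")
    return df[BEAT_CSV_COLUMNS]


def write_peak_times(path: str | Path, times: np.ndarray) -> None:
    """One peak time per row — the manual-curation exchange format: export,
    edit rows in any editor, re-import."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s\n")
        for t in np.asarray(times, dtype=float):
            fh.write(f"{float(t)!r}\n")


def read_peak_times(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing 'time_s' column")
    return df["time_s"].to_numpy(dtype=float)


def write_line_records(path: str | Path, lines, frame_rate: float | None = None) -> None:
    """LineRecordSet -> TIFF of line pixels + CSV sidecar with timestamps."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(lines.pixels, dtype=np.float32))
    df = pd.DataFrame({
        "line_index": np.arange(lines.times.size),
        "acquisition_time_s": lines.times,
        "row_index": lines.row_index,
    })
    header = f"# rows_per_frame={lines.rows_per_frame}\n"
    sidecar = path.with_suffix(".csv")
    with open(sidecar, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_line_records(path: str | Path):
    from .synth import LineRecordSet

    path = Path(path)
    pixels = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = path.with_suffix(".csv")
    if not sidecar.exists():
        raise FormatError(f"{path}: missing line-record sidecar {sidecar.name}")
    meta, _ = _read_meta_header(sidecar)
    if "rows_per_frame" not in meta:
        raise FormatError(f"{sidecar}: missing '# rows_per_frame=' header")
    df = pd.read_csv(sidecar, comment="#")
    if len(df) != pixels.shape[0]:
        raise FormatError(f"{sidecar}: row count differs from TIFF line count")
    return LineRecordSet(
        pixels,
        df["acquisition_time_s"].to_numpy(dtype=float),
        df["row_index"].to_numpy(dtype=int),
        int(meta["rows_per_frame"]),
    )


def write_diameter_trace(path: str | Path, trace: pd.DataFrame) -> None:
    trace.to_csv(path, index=False)


def read_diameter_trace(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("time_s", "width_um"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing diameter-trace column '{col}'")
    return df
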
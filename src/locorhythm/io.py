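"""File formats and analysis configuration.

Recordings travel as CSV: one column per channel, with the sampling rate
given either by a ``# sample_rate_hz=<value>`` comment line or by a
``time_s`` column of uniformly spaced timestamps.  Footprint runs are CSV
with columns run_id, step_index, paw, x_cm, y_cm.  Metrics tables are
written as TSV with a commented header recording the full parameter set.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .sigprep import TimeSeriesRecording
from .simgen import FootprintRun

__all__ = [
    "AnalysisConfig",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_footprints",
]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class AnalysisConfig:
    """Pipeline parameters; round-trips unchanged through JSON."""

    window_length_s: float = 60.0
    cutoff_hz: float = 5.0
    lag_step_s: float = 0.01
    ptcc_window_s: float = 3.75
    pairs: list[tuple[str, str]] = field(default_factory=list)
    ptcc_mode: str = "signed"       # signed | literal
    phase_mode: str = "peak_lag"    # peak_lag | literal
    burst_on_frac: float = 0.3
    burst_off_frac: float = 0.15
    min_burst_s: float = 0.2
    min_gap_s: float = 0.2
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["pairs"] = [list(p) for p in d["pairs"]]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        d = json.loads(text)
        d["pairs"] = [tuple(p) for p in d.get("pairs", [])]
        return cls(**d)


def write_recording(recording: TimeSeriesRecording, path: str | Path) -> None:
    """Write a recording as CSV with a sample-rate comment line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sample_rate_hz={recording.sample_rate_hz:g}\n")
        df = pd.DataFrame(
            {lab: recording.samples[i] for i, lab in enumerate(recording.channel_labels)}
        )
        df.to_csv(fh, index=False, float_format="%.6g")


def read_recording(path: str | Path) -> TimeSeriesRecording:
    """Read a recording CSV.

    The sampling rate comes from a ``# sample_rate_hz=`` comment or a
    ``time_s`` column, which must be uniformly spaced (relative tolerance
    1e-6) and monotone.
    """
    path = Path(path)
    rate: float | None = None
    lines = path.read_text().splitlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.startswith("sample_rate_hz"):
                try:
                    rate = float(stripped.split("=", 1)[1])
                except (IndexError, ValueError) as exc:
                    raise FormatError(f"{path}:{i + 1}: bad sample_rate_hz comment") from exc
            data_start = i + 1
        else:
            break
    try:
        df = pd.read_csv(_io.StringIO("\n".join(lines[data_start:])))
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + data_start + 2
        raise FormatError(f"{path}:{row}: ragged or missing values")

    if "time_s" in df.columns:
        t = df.pop("time_s").to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) == 0 or np.any(dt <= 0):
            raise FormatError(f"{path}: time_s column must be strictly increasing")
        if np.max(np.abs(dt - dt.mean())) > 1e-6 * dt.mean():
            row = int(np.argmax(np.abs(dt - dt.mean()))) + data_start + 3
            raise FormatError(f"{path}:{row}: non-uniform time_s spacing")
        inferred = 1.0 / dt.mean()
        if rate is None:
            rate = inferred
    if rate is None:
        raise FormatError(f"{path}: no sample_rate_hz comment and no time_s column")

    labels = [str(c) for c in df.columns]
    samples = df.to_numpy(dtype=float).T
    return TimeSeriesRecording(sample_rate_hz=rate, channel_labels=labels, samples=samples)


def read_footprints(path: str | Path) -> list[FootprintRun]:
    """Read footprint CSV (run_id, step_index, paw, x_cm, y_cm) into runs."""
    df = pd.read_csv(path)
    required = {"paw", "x_cm", "y_cm"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: footprint CSV needs columns {sorted(required)}")
    if "run_id" not in df.columns:
        df["run_id"] = "run1"
    bad = ~df["paw"].isin(FootprintRun.PAWS)
    if bad.any():
        raise FormatError(f"{path}: unknown paw label {df.loc[bad, 'paw'].iloc[0]!r}")
    runs = []
    for rid, sub in df.groupby("run_id", sort=True):
        runs.append(FootprintRun(run_id=str(rid), prints=sub.reset_index(drop=True)))
    return runs


def write_tsv(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    """Write a metrics table as TSV with a commented parameter header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# locorhythm v0.1.0\n")
        if params:
            fh.write(f"# params={json.dumps(params, sort_keys=True)}\n")
        df.to_csv(fh, sep="\t", index=False)
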
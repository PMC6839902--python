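"""Readers and writers for the on-disk formats.

Everything is plain delimited text plus a JSON sidecar, because the
canonical data source here is the synthetic generator rather than a
proprietary acquisition system:

* LFP channel: one sample per line (µV) + sidecar with ``sampling_rate``,
  ``animal_id``, ``genotype`` (``opsin+``/``opsin-``), ``location``
  (``HI``/``TT``) and ``units``.
* Event schedule: JSON list of ``{"onset": s, "frequency": Hz}``.
* Current-clamp sweep: three columns (time s, voltage mV, command pA).
* Behavioral bouts: CSV with phase, object, start, duration columns.

Units throughout the package: seconds, µV (LFP), mV (membrane potential),
pA (currents); indices 0-based; windows half-open [start, end).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENOTYPES = ("opsin+", "opsin-")
LOCATIONS = ("HI", "TT")

_SIDECAR_REQUIRED = ("sampling_rate", "animal_id", "genotype", "location")


@dataclass
class LFPRecording:
    """One channel's LFP sample series with its metadata."""

    samples: np.ndarray          # µV
    sampling_rate: float         # Hz
    animal_id: str
    genotype: str                # opsin+ | opsin-
    location: str                # HI | TT
    units: str = "uV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"location must be one of {LOCATIONS}, got {self.location!r}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass(frozen=True)
class StimEvent:
    """A single light-delivery epoch: onset time and pulse frequency."""

    onset: float      # s
    frequency: float  # Hz


# ---------------------------------------------------------------------------
# LFP recordings
# ---------------------------------------------------------------------------

def write_recording(rec: LFPRecording, data_path: str | Path) -> Path:
    """Write samples (one per line) and a JSON sidecar next to them."""
    data_path = Path(data_path)
    np.savetxt(data_path, rec.samples, fmt="%.10g")
    sidecar = data_path.with_suffix(data_path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "sampling_rate": rec.sampling_rate,
        "animal_id": rec.animal_id,
        "genotype": rec.genotype,
        "location": rec.location,
        "units": rec.units,
    }, indent=1))
    return data_path


def read_recording(data_path: str | Path) -> LFPRecording:
    """Read an LFP channel written by :func:`write_recording`."""
    data_path = Path(data_path)
    sidecar = data_path.with_suffix(data_path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing required field {key!r}")
    samples = _read_sample_column(data_path)
    if len(samples) == 0:
        raise ValueError(f"empty data file {data_path}")
    return LFPRecording(
        samples=samples,
        sampling_rate=float(meta["sampling_rate"]),
        animal_id=str(meta["animal_id"]),
        genotype=meta["genotype"],
        location=meta["location"],
        units=meta.get("units", "uV"),
    )


def _read_sample_column(path: Path) -> np.ndarray:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric sample {line!r}"
                ) from None
    return np.array(values)


# ---------------------------------------------------------------------------
# Event schedules
# ---------------------------------------------------------------------------

def write_events(events: list[StimEvent], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(
        [{"onset": e.onset, "frequency": e.frequency} for e in events], indent=1
    ))
    return path


def read_events(path: str | Path) -> list[StimEvent]:
    raw = json.loads(Path(path).read_text())
    return [StimEvent(onset=float(e["onset"]), frequency=float(e["frequency"]))
            for e in raw]


# ---------------------------------------------------------------------------
# Current-clamp sweeps
# ---------------------------------------------------------------------------

def write_sweep(t, v, i_cmd, path: str | Path, meta: dict | None = None) -> Path:
    """Write a sweep as three-column text (s, mV, pA) with optional sidecar."""
    path = Path(path)
    np.savetxt(path, np.column_stack([t, v, i_cmd]), fmt="%.10g",
               header="time_s voltage_mV current_pA")
    if meta is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_sweep(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    path = Path(path)
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValueError(f"{path}: expected three columns (s, mV, pA)")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return data[:, 0], data[:, 1], data[:, 2], meta


# ---------------------------------------------------------------------------
# Behavioral bout tables
# ---------------------------------------------------------------------------

def write_bouts(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    """Write a bout table (phase, object, start, duration) as CSV."""
    path = Path(path)
    df.to_csv(path, index=False)
    if meta is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_bouts(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"phase", "object", "start", "duration"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: bout table missing columns {sorted(missing)}")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return df, meta
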
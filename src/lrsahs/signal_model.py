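"""Domain types and plain-text I/O for overnight airflow / SpO2 screening.

The pipeline works on three kinds of input: a high-rate airflow channel
(typically 200 Hz, arbitrary device units), a pulse-oximetry SpO2 channel
(typically 10 Hz, stored internally as a saturation *fraction* in [0, 1]),
and a 30-s-epoch hypnogram with AASM stage labels W/N1/N2/N3/R.  Detected
respiratory events are half-open intervals ``[start_s, end_s)`` in seconds
from recording start.

File formats are deliberately plain text:

* signals -- 2-column CSV ``time_s,value`` (uniform sampling inferred from
  the time column) or 1-column values with a JSON sidecar ``{"rate_hz": r}``;
* events  -- CSV with header ``type,start_s,end_s``;
* hypnograms -- one stage label per line, one line per 30-s epoch.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventType",
    "SampledSignal",
    "RespEvent",
    "Hypnogram",
    "DetectorConfig",
    "DiagnosticReport",
    "Severity",
    "read_signal",
    "read_events",
    "write_events",
    "read_hypnogram",
    "write_hypnogram",
    "write_signal",
]

SLEEP_STAGES = ("W", "N1", "N2", "N3", "R")

_TIME_TOL_S = 1e-6  # allowed jitter in file timestamps before we call it non-uniform


class EventType(str, enum.Enum):
    APNEA = "apnea"
    HYPOPNEA = "hypopnea"
    SPO2_DROP = "spo2_drop"


class Severity(str, enum.Enum):
    NORMAL = "normal"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled time series.

    Parameters
    ----------
    samples:
        Amplitudes.  Airflow is in device units; SpO2 is a saturation
        fraction in [0, 1].
    rate:
        Samples per second (> 0).
    t0:
        Time of the first sample, seconds from recording start.
    kind:
        ``"airflow"`` or ``"spo2"``; SpO2 signals are range-checked.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0
    kind: str = "airflow"

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("signal must be a non-empty 1-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("signal contains non-finite samples")
        if not (self.rate > 0):
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if self.kind == "spo2" and (arr.min() < 0.0 or arr.max() > 1.0):
            raise ValueError("SpO2 samples must lie in [0, 1] (saturation fraction)")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate

    def times(self) -> np.ndarray:
        """Timestamps of the samples (strictly increasing)."""
        return self.t0 + np.arange(len(self)) / self.rate


@dataclass(frozen=True, order=True)
class RespEvent:
    """One respiratory event as a half-open interval [start_s, end_s)."""

    start_s: float
    end_s: float
    type: EventType

    def __init__(self, type: EventType | str, start_s: float, end_s: float):
        object.__setattr__(self, "type", EventType(type))
        object.__setattr__(self, "start_s", float(start_s))
        object.__setattr__(self, "end_s", float(end_s))
        if not self.start_s < self.end_s:
            raise ValueError(f"event must have start < end, got [{start_s}, {end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlap_s(self, other: "RespEvent") -> float:
        """Length of temporal overlap with another event (0 if disjoint)."""
        return max(0.0, min(self.end_s, other.end_s) - max(self.start_s, other.start_s))

    def retyped(self, new_type: EventType | str) -> "RespEvent":
        return RespEvent(new_type, self.start_s, self.end_s)


@dataclass(frozen=True)
class Hypnogram:
    """Ordered 30-s-epoch sleep-stage labels (AASM: W, N1, N2, N3, R)."""

    epochs: tuple[str, ...]
    epoch_s: float = 30.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(self.epochs))
        if len(self.epochs) == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        if not (self.epoch_s > 0):
            raise ValueError("epoch_s must be > 0")
        bad = [e for e in self.epochs if e not in SLEEP_STAGES]
        if bad:
            raise ValueError(f"unknown sleep stage label(s): {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def span_s(self) -> float:
        """Total recording span covered by the hypnogram, in seconds."""
        return len(self.epochs) * self.epoch_s

    def sleep_spans(self) -> list[tuple[float, float]]:
        """Contiguous non-wake intervals [start_s, end_s), merged across epochs."""
        spans: list[tuple[float, float]] = []
        for i, lab in enumerate(self.epochs):
            if lab == "W":
                continue
            s, e = i * self.epoch_s, (i + 1) * self.epoch_s
            if spans and math.isclose(spans[-1][1], s):
                spans[-1] = (spans[-1][0], e)
            else:
                spans.append((s, e))
        return spans


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the detector.

    ``window_s`` is the local-range window length Δt; ``ta``/``tc`` are the
    dual thresholds applied to 1/LR (``0 < ta < tc``); ``min_drop`` and ``k0``
    are the SpO2 sudden-drop amplitude (saturation fraction) and slope
    (fraction per second) criteria; ``lookback_s`` is the horizon used to
    attribute a desaturation to a preceding airflow apnea.
    """

    window_s: float = 10.0
    lr_step_s: float = 0.5
    ta: float = 10.0
    tc: float = 25.0
    min_drop: float = 0.03
    k0: float = 0.001
    lookback_s: float = 30.0
    valley_recovery: float = 0.01
    lr_floor: float = 1e-9
    onset_tol: float = 0.0025
    spo2_median_filter_s: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.ta < self.tc):
            raise ValueError(f"thresholds must satisfy 0 < ta < tc, got ta={self.ta}, tc={self.tc}")
        if not (self.window_s >= self.lr_step_s > 0):
            raise ValueError("must satisfy window_s >= lr_step_s > 0")
        if self.min_drop <= 0 or self.k0 <= 0:
            raise ValueError("min_drop and k0 must be > 0")
        if self.lookback_s < 0:
            raise ValueError("lookback_s must be >= 0")
        if self.lr_floor <= 0 or self.valley_recovery <= 0 or self.onset_tol < 0:
            raise ValueError("lr_floor, valley_recovery must be > 0; onset_tol >= 0")


@dataclass(frozen=True)
class DiagnosticReport:
    """Per-night summary: event counts, AHI, severity, duration percentages.

    Hypopnea-related fields are ``None`` when the pipeline ran in
    airflow-only mode (no SpO2 channel).  ``sleep_time_assumed`` is set when
    no hypnogram was supplied and the full recording span was used as total
    sleep time.
    """

    n_apnea: int
    n_hypopnea: int | None
    total_sleep_time_h: float
    ahi: float
    severity: Severity
    apnea_rate_per_h: float
    hypopnea_rate_per_h: float | None
    duration_pct_apnea: float
    duration_pct_hypopnea: float | None
    duration_pct_total: float
    sleep_time_assumed: bool = False

    @property
    def n_sah(self) -> int:
        return self.n_apnea + (self.n_hypopnea or 0)

    def to_dict(self) -> dict:
        d = {
            "n_apnea": self.n_apnea,
            "n_hypopnea": self.n_hypopnea,
            "n_sah": self.n_sah,
            "total_sleep_time_h": self.total_sleep_time_h,
            "ahi": self.ahi,
            "severity": self.severity.value,
            "apnea_rate_per_h": self.apnea_rate_per_h,
            "hypopnea_rate_per_h": self.hypopnea_rate_per_h,
            "duration_pct_apnea": self.duration_pct_apnea,
            "duration_pct_hypopnea": self.duration_pct_hypopnea,
            "duration_pct_total": self.duration_pct_total,
            "sleep_time_assumed": self.sleep_time_assumed,
        }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"schema": "lrsahs-report/1", **self.to_dict()}, indent=2))


# ---------------------------------------------------------------------------
# I/O


class SignalFormatError(ValueError):
    """Raised when a signal file violates the expected plain-text format."""


def _percent_to_fraction(values: np.ndarray) -> np.ndarray:
    # heuristic: SpO2 stored in percent (0-100) if values exceed 1.5
    if values.size and np.nanmax(values) > 1.5:
        return values / 100.0
    return values


def read_signal(path: str | Path, kind: str = "airflow") -> SampledSignal:
    """Read a signal from a 2-column ``time_s,value`` CSV (or 1 column + JSON sidecar).

    SpO2 files given in percent are converted to saturation fraction.
    Timestamps must be uniform to within 1e-6 s.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    ncol = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if lineno == 1 and any(not _is_number(p) for p in parts):
                continue  # header
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise SignalFormatError(f"{path}: non-numeric row at line {lineno}: {line!r}")
            if ncol is None:
                ncol = len(vals)
            elif len(vals) != ncol:
                raise SignalFormatError(f"{path}: inconsistent column count at line {lineno}")
            rows.append(vals)
    if not rows:
        raise SignalFormatError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    if ncol == 2:
        t, v = arr[:, 0], arr[:, 1]
        if len(t) < 2:
            raise SignalFormatError(f"{path}: need at least 2 samples to infer the rate")
        dt = np.diff(t)
        if np.any(np.abs(dt - dt[0]) > _TIME_TOL_S) or dt[0] <= 0:
            raise SignalFormatError(f"{path}: timestamps are not uniformly increasing")
        rate = 1.0 / dt[0]
        t0 = t[0]
    elif ncol == 1:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise SignalFormatError(f"{path}: single-column file requires sidecar {sidecar.name}")
        meta = json.loads(sidecar.read_text())
        rate = float(meta["rate_hz"])
        t0 = float(meta.get("t0_s", 0.0))
        v = arr[:, 0]
    else:
        raise SignalFormatError(f"{path}: expected 1 or 2 columns, found {ncol}")
    if kind == "spo2":
        v = _percent_to_fraction(v)
    return SampledSignal(samples=v, rate=rate, t0=t0, kind=kind)


def write_signal(sig: SampledSignal, path: str | Path) -> None:
    """Write a signal as a 2-column ``time_s,value`` CSV (SpO2 back in percent)."""
    v = sig.samples * 100.0 if sig.kind == "spo2" else sig.samples
    df = pd.DataFrame({"time_s": sig.times(), "value": v})
    df.to_csv(path, index=False)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_events(path: str | Path) -> list[RespEvent]:
    """Read events from a CSV with columns ``type,start_s,end_s``."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"type", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: events file must have columns {sorted(required)}")
    out: list[RespEvent] = []
    for i, row in df.iterrows():
        try:
            etype = EventType(str(row["type"]))
        except ValueError:
            raise ValueError(f"{path}: unknown event type {row['type']!r} in row {i}")
        if not float(row["start_s"]) < float(row["end_s"]):
            raise ValueError(f"{path}: start >= end in row {i}")
        out.append(RespEvent(etype, float(row["start_s"]), float(row["end_s"])))
    return out


def write_events(events: Iterable[RespEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"type": e.type.value, "start_s": e.start_s, "end_s": e.end_s} for e in events],
        columns=["type", "start_s", "end_s"],
    )
    df.to_csv(path, index=False)


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a hypnogram: one W/N1/N2/N3/R label per line (30-s epochs)."""
    labels: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            lab = line.strip()
            if not lab or lab.startswith("#"):
                continue
            if lab not in SLEEP_STAGES:
                raise ValueError(f"{path}: unknown sleep stage {lab!r} at line {lineno}")
            labels.append(lab)
    return Hypnogram(epochs=tuple(labels), epoch_s=30.0)


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    Path(path).write_text("\n".join(h.epochs) + "\n")


def check_sorted_disjoint(events: Sequence[RespEvent], what: str = "events") -> None:
    """Validate that a list of events is time-ordered with no overlaps."""
    for a, b in zip(events, events[1:]):
        if b.start_s < a.start_s:
            raise ValueError(f"{what} are not time-ordered")
        if b.start_s < a.end_s:
            raise ValueError(f"{what} overlap: [{a.start_s},{a.end_s}) and [{b.start_s},{b.end_s})")
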
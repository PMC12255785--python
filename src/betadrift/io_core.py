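"""Ingestion of minute-resolution beta-power logs and aDBS setting epochs.

The sensing-enabled pulse generator stores one beta-band power value per
minute.  Clinicians reprogram the device at follow-up visits, so a patient's
recording is partitioned into *setting epochs*: date intervals over which one
set of aDBS parameters (the two beta thresholds, the current limits, the
stimulation frequency and pulse width, and the driver hemisphere) applies.
This module reads both kinds of files, validates them, and slices recordings
by epoch and by time-of-day window.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Hemisphere",
    "MinuteSeries",
    "SettingEpoch",
    "PatientRecord",
    "ValidationError",
    "EmptySliceError",
    "read_minute_log",
    "write_minute_log",
    "read_settings",
    "write_settings",
    "slice_by_epoch",
    "select_awake_window",
    "split_into_days",
    "count_gaps",
]


class ValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


class EmptySliceError(ValueError):
    """Raised when a slice operation would silently return no samples."""


class Hemisphere(str, enum.Enum):
    CH1 = "CH1"  # left
    CH2 = "CH2"  # right


@dataclass(frozen=True)
class MinuteSeries:
    """Timestamped beta-power samples at nominal 1-minute resolution."""

    patient_id: str
    hemisphere: Hemisphere
    timestamps: np.ndarray  # datetime64[s], strictly increasing
    power: np.ndarray       # float, >= 0

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype="datetime64[s]")
        pw = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "power", pw)
        if ts.shape != pw.shape:
            raise ValidationError("timestamps and power must have equal length")
        if len(ts) > 1 and not (np.diff(ts.astype("int64")) > 0).all():
            raise ValidationError("timestamps must be strictly increasing")
        if len(pw) and (pw < 0).any():
            bad = np.nonzero(pw < 0)[0][:5]
            raise ValidationError(f"negative power at rows {bad.tolist()}")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def dates(self) -> np.ndarray:
        """Calendar date (datetime64[D]) of each sample; midnight-local days."""
        return self.timestamps.astype("datetime64[D]")


@dataclass(frozen=True)
class SettingEpoch:
    """One aDBS parameter set and the date interval (closed) it applied."""

    start_date: dt.date
    end_date: dt.date
    beta_min: float
    beta_max: float
    a_min: float = 0.0
    a_max: float = 0.0
    stim_frequency: float = 130.0
    pulse_width: float = 60.0
    driver_channel: Hemisphere = Hemisphere.CH1
    label: str = ""

    def __post_init__(self):
        if not self.beta_min < self.beta_max:
            raise ValidationError(
                f"beta_min ({self.beta_min}) must be < beta_max ({self.beta_max})")
        if self.a_min > self.a_max:
            raise ValidationError("a_min must be <= a_max")
        if self.start_date > self.end_date:
            raise ValidationError("epoch start_date must be <= end_date")

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


@dataclass(frozen=True)
class PatientRecord:
    series: MinuteSeries
    epochs: tuple[SettingEpoch, ...]
    power_window: tuple[float, float]
    beta_range_hz: tuple[float, float] = (13.0, 30.0)

    def __post_init__(self):
        object.__setattr__(self, "epochs", tuple(self.epochs))
        lo, hi = self.power_window
        if not lo < hi:
            raise ValidationError("power window must satisfy min < max")
        _check_epoch_overlap(self.epochs)
        for ep in self.epochs:
            if not (lo <= ep.beta_min and ep.beta_max <= hi):
                raise ValidationError(
                    f"epoch {ep.label or ep.start_date} thresholds outside power window")


def _check_epoch_overlap(epochs) -> None:
    ordered = sorted(epochs, key=lambda e: e.start_date)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_date <= a.end_date:
            raise ValidationError(
                f"epochs overlap: [{a.start_date}..{a.end_date}] and "
                f"[{b.start_date}..{b.end_date}]")


# ---------------------------------------------------------------------------
# minute logs
# ---------------------------------------------------------------------------

def read_minute_log(path, patient_id: str,
                    hemisphere: Hemisphere | str = Hemisphere.CH1,
                    ) -> tuple[MinuteSeries, int]:
    """Read a two-column (timestamp, power) delimited text file.

    The delimiter is sniffed (comma or tab), a header row is optional, and
    rows whose timestamp or power fail to parse are dropped and counted.

    Returns
    -------
    (series, n_bad_rows)
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     names=["timestamp", "power"], comment="#",
                     skip_blank_lines=True, dtype=str)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")

    def parse_float(v):  # correctly-rounded strtod, for exact round-trips
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    pw = df["power"].map(parse_float)
    ok = ts.notna() & pw.notna()
    n_bad = int((~ok).sum())
    # a header row parses as one bad row; do not count it
    if n_bad and not ok.iloc[0] and df["timestamp"].iloc[0].lower().lstrip(
            "﻿") in {"timestamp", "time", "date", "datetime"}:
        n_bad -= 1
    ts, pw = ts[ok], pw[ok]
    order = np.argsort(ts.values, kind="stable")
    ts = ts.values[order].astype("datetime64[s]")
    pw = pw.values[order]
    dup = np.nonzero(np.diff(ts.astype("int64")) == 0)[0]
    if len(dup):
        raise ValidationError(
            f"duplicate timestamps, first at {ts[dup[0]]}")
    if (pw < 0).any():
        bad = np.nonzero(pw < 0)[0][:5]
        raise ValidationError(f"negative power at sorted rows {bad.tolist()}")
    if isinstance(hemisphere, str):
        hemisphere = Hemisphere(hemisphere)
    return MinuteSeries(patient_id, hemisphere, ts, pw), n_bad


def write_minute_log(series: MinuteSeries, path) -> None:
    """Write ``timestamp,power`` CSV; round-trips bit-identically."""
    df = pd.DataFrame({
        "timestamp": np.datetime_as_string(series.timestamps, unit="s"),
        "power": [repr(float(p)) for p in series.power],
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# settings files
# ---------------------------------------------------------------------------

def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"malformed date: {value!r}") from exc


def read_settings(path) -> dict:
    """Read a YAML/JSON settings file.

    Expected structure::

        patient_id: NWK1
        driver_channel: CH1
        p_window: [0.0, 10.0]
        beta_range_hz: [13.0, 30.0]
        epochs:
          - {start: 2024-01-01, end: 2024-02-10, beta_min: 2.0, beta_max: 6.0,
             a_min: 1.0, a_max: 3.0, stim_frequency: 130, pulse_width: 60}

    Returns a dict with keys ``patient_id``, ``driver_channel``, ``p_window``,
    ``beta_range_hz`` and ``epochs`` (ordered list of :class:`SettingEpoch`).
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict) or "epochs" not in raw:
        raise ValidationError("settings file must be a mapping with an 'epochs' list")
    epochs = []
    for i, item in enumerate(raw["epochs"]):
        try:
            epochs.append(SettingEpoch(
                start_date=_parse_date(item["start"]),
                end_date=_parse_date(item["end"]),
                beta_min=float(item["beta_min"]),
                beta_max=float(item["beta_max"]),
                a_min=float(item.get("a_min", 0.0)),
                a_max=float(item.get("a_max", 0.0)),
                stim_frequency=float(item.get("stim_frequency", 130.0)),
                pulse_width=float(item.get("pulse_width", 60.0)),
                driver_channel=Hemisphere(item.get("driver_channel",
                                                   raw.get("driver_channel", "CH1"))),
                label=str(item.get("label", f"epoch{i}")),
            ))
        except KeyError as exc:
            raise ValidationError(f"epoch {i} missing field {exc}") from exc
    epochs.sort(key=lambda e: e.start_date)
    _check_epoch_overlap(epochs)
    out = {
        "patient_id": raw.get("patient_id", ""),
        "driver_channel": Hemisphere(raw.get("driver_channel", "CH1")),
        "epochs": epochs,
    }
    if "p_window" in raw:
        lo, hi = (float(v) for v in raw["p_window"])
        out["p_window"] = (lo, hi)
    if "beta_range_hz" in raw:
        out["beta_range_hz"] = tuple(float(v) for v in raw["beta_range_hz"])
    return out


def write_settings(settings: dict, path) -> None:
    epochs = [
        {
            "start": ep.start_date.isoformat(), "end": ep.end_date.isoformat(),
            "beta_min": ep.beta_min, "beta_max": ep.beta_max,
            "a_min": ep.a_min, "a_max": ep.a_max,
            "stim_frequency": ep.stim_frequency, "pulse_width": ep.pulse_width,
            "driver_channel": ep.driver_channel.value, "label": ep.label,
        }
        for ep in settings["epochs"]
    ]
    doc = {
        "patient_id": settings.get("patient_id", ""),
        "driver_channel": getattr(settings.get("driver_channel", "CH1"),
                                  "value", settings.get("driver_channel", "CH1")),
        "epochs": epochs,
    }
    if "p_window" in settings:
        doc["p_window"] = list(settings["p_window"])
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# slicing
# ---------------------------------------------------------------------------

def slice_by_epoch(series: MinuteSeries, epoch: SettingEpoch) -> MinuteSeries:
    """Samples whose calendar date lies in [start_date, end_date] (closed)."""
    dates = series.dates
    lo = np.datetime64(epoch.start_date, "D")
    hi = np.datetime64(epoch.end_date, "D")
    mask = (dates >= lo) & (dates <= hi)
    if not mask.any():
        raise EmptySliceError(
            f"epoch [{epoch.start_date}..{epoch.end_date}] contains no samples")
    return replace(series, timestamps=series.timestamps[mask],
                   power=series.power[mask])


def select_awake_window(series: MinuteSeries, start_hour: int = 9,
                        end_hour: int = 21) -> MinuteSeries:
    """Keep samples with time-of-day in [start_hour:00, end_hour:00)."""
    if not (0 <= start_hour < end_hour <= 24):
        raise ValueError(
            f"need 0 <= start_hour < end_hour <= 24, got ({start_hour}, {end_hour})")
    secs = (series.timestamps - series.dates).astype("timedelta64[s]").astype("int64")
    mask = (secs >= start_hour * 3600) & (secs < end_hour * 3600)
    if not mask.any():
        raise EmptySliceError(
            f"no samples inside the {start_hour}:00-{end_hour}:00 window")
    return replace(series, timestamps=series.timestamps[mask],
                   power=series.power[mask])


def split_into_days(series: MinuteSeries) -> dict[dt.date, MinuteSeries]:
    """Partition by calendar date, preserving order."""
    out: dict[dt.date, MinuteSeries] = {}
    dates = series.dates
    for day in np.unique(dates):
        mask = dates == day
        out[day.astype(dt.date)] = replace(
            series, timestamps=series.timestamps[mask], power=series.power[mask])
    return out


def count_gaps(series: MinuteSeries) -> int:
    """Number of missing nominal 1-minute slots between first and last sample."""
    if len(series) < 2:
        return 0
    steps = np.diff(series.timestamps.astype("int64")) // 60
    return int((steps - 1).sum())
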
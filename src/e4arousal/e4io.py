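"""Reading, writing and clock-aligning Empatica-E4-style raw sessions.

The raw export convention is one directory (or zip) per wearing session with
one CSV per channel.  For EDA/TEMP/ACC/BVP/HR the first row is the session
start as a Unix timestamp (UTC seconds), the second row the sampling rate in
Hz, and every following row one sample (three columns for ACC).  IBI.csv has
the start timestamp on the first row and ``offset_s,interval_s`` pairs after
that; it may be empty apart from the header because the device only reports
inter-beat intervals when two consecutive pulse peaks were detected reliably.

All timestamps are kept in UTC internally; clock-of-day semantics (reference
matching, dashboard axes) go through the session's IANA timezone.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable
from zoneinfo import ZoneInfo

import numpy as np

__all__ = [
    "SignalChannel",
    "IbiSeries",
    "E4Session",
    "SessionParseError",
    "read_session",
    "write_session",
    "clock_align",
    "CHANNEL_RATES",
    "ACC_COUNTS_PER_G",
]

#: native sampling rates of the raw export, Hz
CHANNEL_RATES = {
    "EDA": 4.0,
    "TEMP": 4.0,
    "ACC_X": 32.0,
    "ACC_Y": 32.0,
    "ACC_Z": 32.0,
    "BVP": 64.0,
    "HR": 1.0,
}

#: accelerometer raw counts per 1 g (device convention)
ACC_COUNTS_PER_G = 64.0

#: physiologically admissible inter-beat interval, seconds (exclusive bounds)
IBI_BOUNDS_S = (0.2, 3.0)

CHANNEL_NAMES = tuple(CHANNEL_RATES)

#: channels a session must carry to be analyzable (BVP is provenance only)
REQUIRED_CHANNELS = ("EDA", "TEMP", "ACC_X", "ACC_Y", "ACC_Z", "HR")


class SessionParseError(ValueError):
    """Raised when a session directory/zip is structurally invalid."""


@dataclass
class SignalChannel:
    """One regularly sampled channel of a session.

    ``values`` use NaN as the explicit missing marker — never 0, because a
    zero EDA reading is itself meaningful (the off-wrist signature).
    """

    name: str
    start_time: float  # UTC seconds, fractional allowed
    rate: float  # Hz
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("channel values must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Channel duration in seconds (samples / rate)."""
        return len(self.values) / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        """UTC timestamp of every sample."""
        return self.start_time + np.arange(len(self.values)) / self.rate

    def slice_window(self, start: float, end: float) -> np.ndarray:
        """Values with sample time in ``[start, end)``."""
        i0 = int(np.ceil((start - self.start_time) * self.rate - 1e-9))
        i1 = int(np.ceil((end - self.start_time) * self.rate - 1e-9))
        i0, i1 = max(i0, 0), min(max(i1, 0), len(self.values))
        return self.values[i0:i1]


@dataclass
class IbiSeries:
    """Irregular inter-beat-interval series.

    ``offsets`` are seconds since ``start_time`` of the *later* beat of each
    pair; ``intervals`` the beat-to-beat distance in seconds.  May be empty —
    valid IBI data is only available for a small fraction of wear time.
    """

    start_time: float
    offsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    intervals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.offsets.shape != self.intervals.shape:
            raise ValueError("offsets and intervals must have equal length")
        if len(self.offsets) > 1 and not np.all(np.diff(self.offsets) > 0):
            raise ValueError("IBI offsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.offsets)

    def beat_times(self) -> np.ndarray:
        return self.start_time + self.offsets


@dataclass
class E4Session:
    """A multi-channel wearing session on a common wall clock."""

    participant_id: str
    setting: str  # "clinic" | "daycare"
    day_index: int  # wearing day 1..5
    channels: dict[str, SignalChannel]
    ibi: IbiSeries
    timezone: str = "UTC"

    def __post_init__(self) -> None:
        for name, ch in self.channels.items():
            if ch.name != name:
                raise ValueError(f"channel key {name!r} != channel name {ch.name!r}")
            if name not in CHANNEL_NAMES:
                raise ValueError(f"unknown channel {name!r}")
        missing = [c for c in REQUIRED_CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"session missing required channels: {missing}")
        if self.setting not in ("clinic", "daycare"):
            raise ValueError(f"unknown setting {self.setting!r}")

    def __getitem__(self, name: str) -> SignalChannel:
        return self.channels[name]

    @property
    def tzinfo(self) -> ZoneInfo:
        return ZoneInfo(self.timezone)

    def local_date(self):
        """Local calendar date of the session start."""
        return datetime.fromtimestamp(self["EDA"].start_time, self.tzinfo).date()

    def overlap_window(self, channels: Iterable[str] | None = None) -> tuple[float, float]:
        """[start, end) over which all the given channels are recorded."""
        chans = [self.channels[c] for c in (channels or self.channels)]
        start = max(c.start_time for c in chans)
        end = min(c.end_time for c in chans)
        return start, end


# ---------------------------------------------------------------------------
# raw-export parsing


def _read_raw_csv(lines: list[str], fname: str, ncols: int) -> tuple[float, float, np.ndarray]:
    if len(lines) < 2:
        raise SessionParseError(f"{fname}: missing start-time/rate header rows")
    start = float(lines[0].split(",")[0])
    rate = float(lines[1].split(",")[0])
    if len(lines) > 2:
        data = np.loadtxt(lines[2:], delimiter=",", ndmin=2)
    else:
        data = np.empty((0, ncols))
    if data.shape[1] != ncols:
        raise SessionParseError(f"{fname}: expected {ncols} column(s), got {data.shape[1]}")
    return start, rate, data


def _read_ibi_csv(lines: list[str]) -> IbiSeries:
    if not lines:
        raise SessionParseError("IBI.csv: empty file, expected a start-time header")
    start = float(lines[0].split(",")[0])
    if len(lines) == 1:
        return IbiSeries(start)
    data = np.loadtxt(lines[1:], delimiter=",", ndmin=2)
    offsets, intervals = data[:, 0], data[:, 1]
    lo, hi = IBI_BOUNDS_S
    ok = (intervals > lo) & (intervals < hi)
    offsets, intervals = offsets[ok], intervals[ok]
    if len(offsets) > 1 and not np.all(np.diff(offsets) > 0):
        warnings.warn("IBI offsets not strictly increasing; rejecting IBI series")
        return IbiSeries(start)
    return IbiSeries(start, offsets, intervals)


def read_session(
    path: str | Path,
    timezone: str = "UTC",
    *,
    participant_id: str | None = None,
    setting: str | None = None,
    day_index: int | None = None,
) -> E4Session:
    """Read a raw session directory or zip into an :class:`E4Session`.

    ACC counts are converted to g (1/64 g per count).  A ``session_meta.json``
    sidecar, if present, supplies participant/setting/day/timezone; explicit
    keyword arguments override it.  An empty or invalid IBI file degrades to an
    empty series with a warning — it never fails the session.
    """
    path = Path(path)

    def get_lines(fname: str) -> list[str] | None:
        if path.suffix == ".zip":
            with zipfile.ZipFile(path) as zf:
                if fname not in zf.namelist():
                    return None
                raw = zf.read(fname).decode()
        else:
            f = path / fname
            if not f.exists():
                return None
            raw = f.read_text()
        return [ln for ln in raw.splitlines() if ln.strip()]

    meta: dict = {}
    meta_lines = get_lines("session_meta.json")
    if meta_lines:
        meta = json.loads("\n".join(meta_lines))

    channels: dict[str, SignalChannel] = {}
    for fname, names, ncols, scale in [
        ("EDA.csv", ("EDA",), 1, 1.0),
        ("TEMP.csv", ("TEMP",), 1, 1.0),
        ("ACC.csv", ("ACC_X", "ACC_Y", "ACC_Z"), 3, 1.0 / ACC_COUNTS_PER_G),
        ("BVP.csv", ("BVP",), 1, 1.0),
        ("HR.csv", ("HR",), 1, 1.0),
    ]:
        lines = get_lines(fname)
        if lines is None:
            raise SessionParseError(f"mandatory channel file missing: {fname}")
        start, rate, data = _read_raw_csv(lines, fname, ncols)
        for j, name in enumerate(names):
            channels[name] = SignalChannel(name, start, rate, data[:, j] * scale)

    ibi_lines = get_lines("IBI.csv")
    if ibi_lines is None:
        ibi = IbiSeries(channels["EDA"].start_time)
    else:
        try:
            ibi = _read_ibi_csv(ibi_lines)
        except ValueError as exc:
            warnings.warn(f"IBI.csv unusable ({exc}); keeping session with empty IBI")
            ibi = IbiSeries(channels["EDA"].start_time)

    return E4Session(
        participant_id=participant_id or meta.get("participant_id", path.stem),
        setting=setting or meta.get("setting", "clinic"),
        day_index=day_index if day_index is not None else int(meta.get("day_index", 1)),
        channels=channels,
        ibi=ibi,
        timezone=timezone if timezone != "UTC" else meta.get("timezone", timezone),
    )


def write_session(session: E4Session, path: str | Path) -> None:
    """Write a session in the exact raw-export dialect :func:`read_session` reads.

    ``read_session(write_session(s)) == s`` up to float formatting (1e-6).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    def header(ch: SignalChannel, ncols: int) -> list[str]:
        return [
            ",".join([f"{ch.start_time:.6f}"] * ncols),
            ",".join([f"{ch.rate:.6f}"] * ncols),
        ]

    for fname, names in [
        ("EDA.csv", ("EDA",)),
        ("TEMP.csv", ("TEMP",)),
        ("BVP.csv", ("BVP",)),
        ("HR.csv", ("HR",)),
    ]:
        ch = session[names[0]]
        lines = header(ch, 1) + [f"{v:.6f}" for v in ch.values]
        (path / fname).write_text("\n".join(lines) + "\n")

    axes = [session[n] for n in ("ACC_X", "ACC_Y", "ACC_Z")]
    counts = np.column_stack([np.round(a.values * ACC_COUNTS_PER_G) for a in axes])
    lines = header(axes[0], 3) + [f"{int(r[0])},{int(r[1])},{int(r[2])}" for r in counts]
    (path / "ACC.csv").write_text("\n".join(lines) + "\n")

    ibi_lines = [f"{session.ibi.start_time:.6f}, IBI"]
    ibi_lines += [
        f"{o:.6f},{i:.6f}" for o, i in zip(session.ibi.offsets, session.ibi.intervals)
    ]
    (path / "IBI.csv").write_text("\n".join(ibi_lines) + "\n")

    meta = {
        "participant_id": session.participant_id,
        "setting": session.setting,
        "day_index": session.day_index,
        "timezone": session.timezone,
    }
    (path / "session_meta.json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# clock alignment


def bin_mean(values: np.ndarray, factor: int) -> np.ndarray:
    """Mean over consecutive non-overlapping bins of ``factor`` samples.

    A trailing partial bin is averaged over the samples it has.  NaNs inside a
    bin are ignored; an all-NaN bin stays NaN.
    """
    n = len(values)
    nbins = int(np.ceil(n / factor))
    padded = np.full(nbins * factor, np.nan)
    padded[:n] = values
    padded = padded.reshape(nbins, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(padded, axis=1)


def clock_align(session: E4Session, grid_rate: float, channels: Iterable[str] | None = None):
    """Resample all channels of a session onto one shared clock grid.

    Downsampling is mean-within-bin; grid cells with no samples are NaN.
    The grid starts at the latest channel start and covers the overlap of all
    channels; zero overlap is an error.  Returns a pandas DataFrame indexed by
    UTC seconds with one column per channel.
    """
    import pandas as pd

    names = list(channels or session.channels)
    start, end = session.overlap_window(names)
    if end <= start:
        raise ValueError("channels have no overlapping wall-clock window")
    n_grid = int(np.floor((end - start) * grid_rate))
    grid = start + np.arange(n_grid) / grid_rate
    out = {}
    for name in names:
        ch = session[name]
        t = ch.times()
        inside = (t >= start) & (t < start + n_grid / grid_rate)
        idx = np.floor((t[inside] - start) * grid_rate).astype(int)
        sums = np.bincount(idx, weights=np.nan_to_num(ch.values[inside]), minlength=n_grid)
        cnts = np.bincount(idx, weights=np.isfinite(ch.values[inside]).astype(float), minlength=n_grid)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return pd.DataFrame(out, index=grid)
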
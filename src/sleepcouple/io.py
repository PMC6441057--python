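"""Data model and I/O for multichannel sleep electrophysiology recordings.

The in-memory containers mirror what a freely-moving rodent EEG/LFP session
produces: a :class:`Recording` (channels x samples, microvolts, one sampling
rate), a :class:`Hypnogram` (one sleep-state label per fixed-length bin), and
an :class:`EventTable` (detected or injected transient events such as
sharp-wave ripples).

Time convention: seconds from recording start; bin ``k`` covers the half-open
interval ``[k*bin_s, (k+1)*bin_s)``; sample ``i`` covers time ``i/fs``.

On disk, recordings use an HDF5 container that preserves sample dtype
bit-exactly (EDF's 16-bit physical scaling is lossy, so EDF is supported
read-only for interoperability). Event tables and hypnograms are plain CSV.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import BoundsError, ConfigurationError, FormatError, IntegrityError

REGIONS = ("sFC", "MC", "mFC", "Th-RT", "RS", "CA1", "DG", "EMG", "other")
KINDS = ("screw", "wire", "emg")
STATES = ("MOVE", "WI", "NREM", "REM")

EVENT_COLUMNS = ["start_s", "peak_s", "end_s", "channel", "kind"]


@dataclass(frozen=True)
class ChannelInfo:
    """Electrode metadata: name, anatomical target, and electrode type."""

    name: str
    region: str = "other"
    kind: str = "wire"

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ConfigurationError(f"unknown region {self.region!r}")
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown channel kind {self.kind!r}")
        if (self.region == "EMG") != (self.kind == "emg"):
            raise ConfigurationError("region must be EMG iff kind is emg")


@dataclass
class Hypnogram:
    """Per-bin sleep-state labels (MOVE / WI / NREM / REM).

    ``derived_from`` records which channels the labels were computed from
    (typically the cortical screw and EMG channels).
    """

    labels: np.ndarray
    bin_s: float = 2.0
    derived_from: tuple = ()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U4")
        if self.bin_s <= 0:
            raise ConfigurationError("bin_s must be positive")
        bad = set(np.unique(self.labels)) - set(STATES)
        if bad:
            raise IntegrityError(f"unknown state labels: {sorted(bad)}")

    @property
    def n_bins(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_s

    def label_at(self, t_s: float) -> str:
        i = int(t_s // self.bin_s)
        if not 0 <= i < self.n_bins:
            raise BoundsError(f"time {t_s} s outside hypnogram")
        return str(self.labels[i])

    def state_seconds(self, state: str) -> float:
        return float(np.sum(self.labels == state)) * self.bin_s

    def bouts(self, state: str) -> list[tuple[int, int]]:
        """Maximal runs of ``state`` as half-open bin index ranges."""
        mask = np.concatenate(([False], self.labels == state, [False]))
        edges = np.flatnonzero(np.diff(mask.astype(int)))
        return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]

    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(self.n_bins)
        return pd.DataFrame(
            {"bin_index": idx, "start_s": idx * self.bin_s, "label": self.labels}
        )


class EventTable:
    """Table of transient events with ``start_s <= peak_s <= end_s`` rows.

    Backed by a pandas DataFrame with at least the columns
    ``start_s, peak_s, end_s, channel, kind``; extra columns carry
    event attributes (e.g. ``peak_z``, ``intra_freq_hz``, ``state``).
    Rows must be sorted by ``start_s``.
    """

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            frame = pd.DataFrame(columns=EVENT_COLUMNS)
        missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
        if missing:
            raise IntegrityError(f"event table missing columns {missing}")
        frame = frame.reset_index(drop=True)
        if len(frame):
            s, p, e = frame["start_s"], frame["peak_s"], frame["end_s"]
            if not ((s <= p) & (p <= e)).all():
                raise IntegrityError("events must satisfy start_s <= peak_s <= end_s")
            if not s.is_monotonic_increasing:
                raise IntegrityError("events must be sorted by start_s")
        self.frame = frame

    @classmethod
    def from_records(cls, records: list[dict]) -> "EventTable":
        frame = pd.DataFrame.from_records(records)
        if len(frame):
            frame = frame.sort_values("start_s", kind="stable")
        else:
            frame = pd.DataFrame(columns=EVENT_COLUMNS)
        return cls(frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self.frame.equals(other.frame)

    def select(self, **column_values) -> "EventTable":
        """Rows where every given column equals the given value."""
        mask = np.ones(len(self.frame), dtype=bool)
        for col, val in column_values.items():
            mask &= (self.frame[col] == val).to_numpy()
        return EventTable(self.frame[mask])


@dataclass
class GroundTruth:
    """Exact generator-side truth, attached only to synthetic recordings."""

    hypnogram: Hypnogram
    events: EventTable
    params: dict = field(default_factory=dict)


@dataclass
class Recording:
    """Multichannel time series in microvolts at a single sampling rate."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channels: list[ChannelInfo]
    meta: dict = field(default_factory=dict)
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if self.data.shape[0] != len(self.channels):
            raise IntegrityError(
                f"{self.data.shape[0]} signal rows for {len(self.channels)} channels"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise IntegrityError("channel names must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(f"no channel named {name!r}") from None

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def find_channel(self, *, kind: str | None = None, region: str | None = None) -> str:
        """Name of the first channel matching the given kind/region."""
        for c in self.channels:
            if kind is not None and c.kind != kind:
                continue
            if region is not None and c.region != region:
                continue
            return c.name
        raise ConfigurationError(f"no channel with kind={kind!r} region={region!r}")

    def slice(self, start_s: float, end_s: float, channels: list[str] | None = None) -> "Recording":
        """Sub-recording for ``[start_s, end_s)``; ground truth is dropped
        (its event times refer to the original time axis)."""
        if not (0 <= start_s < end_s <= self.duration_s + 0.5 / self.fs):
            raise BoundsError(f"slice [{start_s}, {end_s}) outside [0, {self.duration_s}]")
        i0 = int(round(start_s * self.fs))
        i1 = int(round(end_s * self.fs))
        if channels is None:
            rows = slice(None)
            chans = list(self.channels)
        else:
            idx = [self.channel_index(n) for n in channels]
            rows = idx
            chans = [self.channels[i] for i in idx]
        return Recording(
            data=self.data[rows, i0:i1].copy(),
            fs=self.fs,
            channels=chans,
            meta=dict(self.meta),
        )


def concatenate_recordings(recordings: list[Recording]) -> Recording:
    """Concatenate recordings with identical channel layout along time."""
    first = recordings[0]
    for r in recordings[1:]:
        if r.channel_names != first.channel_names or r.fs != first.fs:
            raise IntegrityError("recordings differ in channels or sampling rate")
    data = np.concatenate([r.data for r in recordings], axis=1)
    return Recording(data=data, fs=first.fs, channels=list(first.channels), meta=dict(first.meta))


# ---------------------------------------------------------------------------
# HDF5 container


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording (and any ground truth) to the internal container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=rec.data)
        f.attrs["fs"] = rec.fs
        f.attrs["channels"] = json.dumps(
            [{"name": c.name, "region": c.region, "kind": c.kind} for c in rec.channels]
        )
        f.attrs["meta"] = json.dumps(rec.meta)
        if rec.ground_truth is not None:
            g = f.create_group("ground_truth")
            g.attrs["bin_s"] = rec.ground_truth.hypnogram.bin_s
            g.create_dataset(
                "labels",
                data=np.array(rec.ground_truth.hypnogram.labels, dtype="S4"),
            )
            g.attrs["events"] = rec.ground_truth.events.frame.to_json(orient="split")
            g.attrs["params"] = json.dumps(rec.ground_truth.params)


def _read_container(path: str | Path) -> Recording:
    import io as _stdio

    with h5py.File(path, "r") as f:
        data = f["signals"][...]
        fs = float(f.attrs["fs"])
        channels = [ChannelInfo(**c) for c in json.loads(f.attrs["channels"])]
        meta = json.loads(f.attrs["meta"])
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            labels = g["labels"][...].astype("U4")
            frame = pd.read_json(_stdio.StringIO(g.attrs["events"]), orient="split")
            if len(frame) == 0:
                frame = pd.DataFrame(columns=EVENT_COLUMNS)
            gt = GroundTruth(
                hypnogram=Hypnogram(labels, bin_s=float(g.attrs["bin_s"])),
                events=EventTable(frame),
                params=json.loads(g.attrs["params"]),
            )
    return Recording(data=data, fs=fs, channels=channels, meta=meta, ground_truth=gt)


def read_recording(path: str | Path, format: str = "container") -> Recording:
    """Read a recording from the internal container or from EDF."""
    if format == "container":
        return _read_container(path)
    if format == "edf":
        return _read_edf(path)
    raise FormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Minimal EDF support (read-only; no pre-installed EDF library)

_EDF_REGION_BY_TOKEN = {r.lower(): r for r in REGIONS}


def _guess_channel_info(label: str) -> ChannelInfo:
    token = label.strip()
    region = _EDF_REGION_BY_TOKEN.get(token.lower(), "other")
    if "emg" in token.lower():
        return ChannelInfo(name=token, region="EMG", kind="emg")
    kind = "screw" if region in ("sFC", "MC") else "wire"
    return ChannelInfo(name=token, region=region, kind=kind)


def _read_edf(path: str | Path) -> Recording:
    with open(path, "rb") as f:
        header = f.read(256)
        if len(header) < 256:
            raise FormatError("truncated EDF header")
        n_records = int(header[236:244].decode("ascii").strip())
        record_dur = float(header[244:252].decode("ascii").strip())
        ns = int(header[252:256].decode("ascii").strip())
        sig = f.read(ns * 256)
        labels = [sig[16 * i : 16 * (i + 1)].decode("ascii").strip() for i in range(ns)]
        off = 16 * ns + 80 * ns + 8 * ns
        phys_min = [float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns
        phys_max = [float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns
        dig_min = [int(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns
        dig_max = [int(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns + 80 * ns
        spr = [int(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
        if len(set(s / record_dur for s in spr)) != 1:
            raise IntegrityError("per-signal sampling rates differ; resampling is out of scope")
        fs = spr[0] / record_dur
        raw = f.read()
    expected = 2 * sum(spr) * n_records
    if len(raw) < expected:
        raise IntegrityError("EDF data shorter than header promises")
    values = np.frombuffer(raw[:expected], dtype="<i2")
    data = np.empty((ns, spr[0] * n_records), dtype=np.float64)
    pos = 0
    for rec_i in range(n_records):
        for ch in range(ns):
            chunk = values[pos : pos + spr[ch]]
            pos += spr[ch]
            scale = (phys_max[ch] - phys_min[ch]) / (dig_max[ch] - dig_min[ch])
            data[ch, rec_i * spr[ch] : (rec_i + 1) * spr[ch]] = (
                (chunk.astype(np.float64) - dig_min[ch]) * scale + phys_min[ch]
            )
    channels = [_guess_channel_info(lbl) for lbl in labels]
    return Recording(data=data, fs=fs, channels=channels, meta={"source": str(path)})


def _write_edf(path: str | Path, rec: Recording) -> None:
    """Minimal EDF writer used to build synthetic interop fixtures in tests.

    Quantizes to 16 bits (lossy); one 1-s data record per second, so the
    recording is truncated to a whole number of seconds.
    """
    ns = len(rec.channels)
    spr = int(round(rec.fs))
    n_records = rec.n_samples // spr
    pmins, pmaxs = [], []
    digitized = []
    for row in rec.data[:, : n_records * spr]:
        lo = float(min(row.min(), -1.0))
        hi = float(max(row.max(), 1.0))
        pmins.append(lo)
        pmaxs.append(hi)
        scaled = (row - lo) / (hi - lo) * 65535.0 - 32768.0
        digitized.append(np.clip(np.round(scaled), -32768, 32767).astype("<i2"))

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad("X", 80),
            pad("synthetic", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256 * ns), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )
    fields = [
        b"".join(pad(c.name, 16) for c in rec.channels),
        b"".join(pad("", 80) for _ in rec.channels),
        b"".join(pad("uV", 8) for _ in rec.channels),
        b"".join(pad(f"{v:.2f}"[:8], 8) for v in pmins),
        b"".join(pad(f"{v:.2f}"[:8], 8) for v in pmaxs),
        b"".join(pad("-32768", 8) for _ in rec.channels),
        b"".join(pad("32767", 8) for _ in rec.channels),
        b"".join(pad("", 80) for _ in rec.channels),
        b"".join(pad(str(spr), 8) for _ in rec.channels),
        b"".join(pad("", 32) for _ in rec.channels),
    ]
    with open(path, "wb") as f:
        f.write(header)
        for blk in fields:
            f.write(blk)
        for rec_i in range(n_records):
            for ch in range(ns):
                f.write(struct.pack(f"<{spr}h", *digitized[ch][rec_i * spr : (rec_i + 1) * spr]))


# ---------------------------------------------------------------------------
# CSV event tables and hypnograms


def write_events(table: EventTable, path: str | Path, decimals: int = 6) -> None:
    table.frame.to_csv(path, index=False, float_format=f"%.{decimals}f")


def read_events(path: str | Path) -> EventTable:
    frame = pd.read_csv(path)
    if len(frame) == 0:
        frame = pd.DataFrame(columns=list(frame.columns) or EVENT_COLUMNS)
    return EventTable(frame)


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    h.to_frame().to_csv(path, index=False, float_format="%.3f")


def read_hypnogram(path: str | Path) -> Hypnogram:
    frame = pd.read_csv(path)
    if len(frame) > 1:
        bin_s = float(frame["start_s"].iloc[1] - frame["start_s"].iloc[0])
    else:
        bin_s = 2.0
    return Hypnogram(frame["label"].to_numpy(dtype="U4"), bin_s=bin_s)
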
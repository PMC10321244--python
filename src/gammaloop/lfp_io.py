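"""Reading and writing multichannel LFP recordings and event tables.

Recordings live on disk as flat binary ``.dat`` files — little-endian,
channel-interleaved signed 16-bit counts, the de-facto dialect of
extracellular acquisition systems — next to a YAML sidecar that carries
everything the binary cannot: sampling rate, gain, and per-channel labels
and region roles.  Event tables are plain CSV.  All other modules consume
the in-memory :class:`Recording` and :class:`EventTable` containers and
never touch the file layer directly.

Conventions: times are seconds, 0-based from recording start; in-memory
sample values are physical amplitudes (count x gain).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RegionRole",
    "ChannelMeta",
    "Recording",
    "GammaEvent",
    "EventTable",
    "MalformedFileError",
    "SchemaError",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
]

_INT16_MIN = -32768
_INT16_MAX = 32767


class MalformedFileError(ValueError):
    """Binary payload inconsistent with its declared channel layout."""


class SchemaError(KeyError):
    """Sidecar metadata missing a required field."""


class RegionRole(str, Enum):
    """Anatomical role of a channel in the recording montage."""

    OB = "OB"
    PIRC_LEFT = "PIRC_LEFT"
    PIRC_RIGHT = "PIRC_RIGHT"
    REF_LEC_VHIP = "REF_LEC_VHIP"
    OTHER = "OTHER"


@dataclass(frozen=True)
class ChannelMeta:
    label: str
    region_role: RegionRole = RegionRole.OTHER

    def __post_init__(self) -> None:
        object.__setattr__(self, "region_role", RegionRole(self.region_role))


@dataclass
class Recording:
    """Multichannel LFP matrix with acquisition metadata.

    ``samples`` is ``(n_channels, n_samples)`` in physical units
    (volts, or whatever unit ``gain_volts_per_count`` maps counts into).
    """

    samples: np.ndarray
    sampling_rate_hz: float
    channels: list[ChannelMeta]
    gain_volts_per_count: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.gain_volts_per_count <= 0:
            raise ValueError("gain_volts_per_count must be > 0")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel descriptors for "
                f"{self.samples.shape[0]} sample rows"
            )
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def channel(self, label: str) -> np.ndarray:
        """Return the sample vector of the channel with the given label."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None
        return self.samples[idx]

    def by_role(self, role: RegionRole | str) -> list[str]:
        role = RegionRole(role)
        return [c.label for c in self.channels if c.region_role is role]


@dataclass(frozen=True)
class GammaEvent:
    """One detected gamma burst on a single channel."""

    onset_s: float
    offset_s: float
    peak_rms: float
    mean_rms: float
    channel: str = ""

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"offset_s ({self.offset_s}) must exceed onset_s ({self.onset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class EventTable:
    events: list[GammaEvent] = field(default_factory=list)
    source_channel: str = ""
    detector_config_digest: str = ""

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset_s)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def intervals(self) -> np.ndarray:
        """(n_events, 2) array of [onset_s, offset_s]."""
        if not self.events:
            return np.empty((0, 2))
        return np.array([[e.onset_s, e.offset_s] for e in self.events])


def config_digest(obj) -> str:
    """Short stable digest of a dataclass-like config, for provenance."""
    text = repr(sorted(vars(obj).items())) if hasattr(obj, "__dict__") else repr(obj)
    return hashlib.sha1(text.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Flat binary recordings


_REQUIRED_META = ("n_channels", "sampling_rate_hz", "gain_volts_per_count", "channels")


def write_recording(rec: Recording, data_path, meta_path) -> None:
    """Write interleaved little-endian int16 counts plus a YAML sidecar.

    Physical amplitudes are quantized to counts by dividing by the gain and
    rounding to nearest.  A count outside the signed 16-bit range raises
    ``OverflowError`` rather than clipping silently.
    """
    counts = np.round(rec.samples / rec.gain_volts_per_count)
    if counts.size and (counts.max() > _INT16_MAX or counts.min() < _INT16_MIN):
        raise OverflowError(
            "sample amplitude exceeds signed 16-bit range after gain quantization"
        )
    interleaved = counts.astype("<i2").T.reshape(-1)  # sample-major, channel-interleaved
    interleaved.tofile(data_path)

    meta = {
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "sampling_rate_hz": float(rec.sampling_rate_hz),
        "gain_volts_per_count": float(rec.gain_volts_per_count),
        "t0_s": float(rec.t0_s),
        "channels": [
            {"label": c.label, "region_role": c.region_role.value} for c in rec.channels
        ],
    }
    Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=False))

    expected = rec.n_channels * rec.n_samples * 2
    actual = Path(data_path).stat().st_size
    if actual != expected:  # pragma: no cover - file-system failure only
        raise IOError(f"wrote {actual} bytes, expected {expected}")


def read_recording(data_path, meta_path) -> Recording:
    """Read a flat binary recording written by :func:`write_recording`."""
    meta = yaml.safe_load(Path(meta_path).read_text())
    if not isinstance(meta, dict):
        raise SchemaError("sidecar metadata is not a mapping")
    for key in _REQUIRED_META:
        if key not in meta:
            raise SchemaError(f"sidecar metadata missing required field {key!r}")

    n_channels = int(meta["n_channels"])
    channels = [
        ChannelMeta(label=c["label"], region_role=RegionRole(c.get("region_role", "OTHER")))
        for c in meta["channels"]
    ]
    if len(channels) != n_channels:
        raise SchemaError(
            f"metadata declares n_channels={n_channels} but lists {len(channels)} channels"
        )

    n_bytes = Path(data_path).stat().st_size
    frame = n_channels * 2
    if n_bytes % frame != 0:
        raise MalformedFileError(
            f"file size {n_bytes} is not a multiple of n_channels x 2 = {frame} bytes"
        )
    counts = np.fromfile(data_path, dtype="<i2").reshape(-1, n_channels).T
    samples = counts.astype(float) * float(meta["gain_volts_per_count"])
    return Recording(
        samples=samples,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        channels=channels,
        gain_volts_per_count=float(meta["gain_volts_per_count"]),
        t0_s=float(meta.get("t0_s", 0.0)),
    )


# ---------------------------------------------------------------------------
# Event tables

_EVENT_COLUMNS = ["onset_s", "offset_s", "peak_rms", "mean_rms", "channel"]


def write_events(table: EventTable, path) -> None:
    df = pd.DataFrame(
        [
            {
                "onset_s": e.onset_s,
                "offset_s": e.offset_s,
                "peak_rms": e.peak_rms,
                "mean_rms": e.mean_rms,
                "channel": e.channel,
            }
            for e in table.events
        ],
        columns=_EVENT_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_events(path) -> EventTable:
    df = pd.read_csv(path)
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"event table missing columns: {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        if row.offset_s <= row.onset_s:
            raise ValueError(
                f"event with offset_s={row.offset_s} <= onset_s={row.onset_s}"
            )
        events.append(
            GammaEvent(
                onset_s=float(row.onset_s),
                offset_s=float(row.offset_s),
                peak_rms=float(row.peak_rms),
                mean_rms=float(row.mean_rms),
                channel="" if pd.isna(row.channel) else str(row.channel),
            )
        )
    return EventTable(events=events)
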
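"""FCS event data: containers, file I/O, transform, and compensation.

Mass cytometers write Flow Cytometry Standard (FCS) files holding an
event x channel matrix of ion counts.  This module provides a small,
self-contained reader for FCS 3.0/3.1 list-mode data and a writer for
FCS 3.1 (single dataset, 32-bit float, little-endian), plus the two
per-channel preprocessing steps used throughout the pipeline: the
variance-stabilizing arcsinh transform (``asinh(x / cofactor)``,
cofactor 5 by convention for mass cytometry) and single-channel
spillover compensation (e.g. removing a fixed fraction of a CD8
channel's signal from a gdTCR channel to correct oxide spillover).

The writer emits fully deterministic output: identical inputs produce
byte-identical files, which downstream provenance checks rely on.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EventMatrix",
    "PanelDefinition",
    "FcsFormatError",
    "read_fcs",
    "write_fcs",
    "arcsinh_transform",
    "compensate_channel",
    "DEFAULT_COFACTOR",
]

DEFAULT_COFACTOR = 5.0

#: Channel name used to persist per-event acquisition time inside FCS files.
TIME_CHANNEL = "Time"


class FcsFormatError(ValueError):
    """Raised when a file cannot be parsed as FCS list-mode data."""


@dataclass
class EventMatrix:
    """Events x channels intensity matrix with a scale tag.

    Parameters
    ----------
    values : ndarray, shape (n_events, n_channels)
        Ion counts when ``scale == "raw"``, dimensionless after the
        arcsinh transform.
    channel_names : list of str
        Unique channel short names (FCS $PnN).
    scale : {"raw", "arcsinh"}
    acquisition_time : ndarray or None
        Optional per-event acquisition time in seconds, non-decreasing
        in event order.
    """

    values: np.ndarray
    channel_names: list[str]
    scale: str = "raw"
    acquisition_time: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d events x channels matrix")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.scale not in ("raw", "arcsinh"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.acquisition_time is not None:
            t = np.asarray(self.acquisition_time, dtype=float)
            if t.shape != (self.values.shape[0],):
                raise ValueError("acquisition_time length must equal n_events")
            if t.size and (np.any(t < 0) or np.any(np.diff(t) < 0)):
                raise ValueError("acquisition_time must be non-negative and non-decreasing")
            self.acquisition_time = t

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def column(self, channel: str) -> np.ndarray:
        """Return the intensity vector of one channel."""
        return self.values[:, self._index(channel)]

    def _index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not present") from None

    def subset_channels(self, channels: Sequence[str]) -> np.ndarray:
        """Return a view-copy of the selected channel columns, in order."""
        idx = [self._index(c) for c in channels]
        return self.values[:, idx]

    def take(self, event_index: np.ndarray) -> "EventMatrix":
        """Row subset/reorder preserving metadata (times re-sliced)."""
        t = None if self.acquisition_time is None else self.acquisition_time[event_index]
        return EventMatrix(self.values[event_index], self.channel_names, self.scale, t)


@dataclass
class PanelDefinition:
    """Panel metadata: which channel carries which marker, and its role.

    Roles split the panel into barcoding channels (CD45-based inner
    tier, palladium outer tier), lineage markers used by the gating
    hierarchy, the screen readout (anti-PE), and housekeeping channels.
    """

    entries: list[tuple[str, str, str, str]] = field(default_factory=list)

    ROLES = frozenset(
        {"barcode_cd45", "barcode_pd", "lineage", "screen_readout", "viability", "dna", "other"}
    )

    def __post_init__(self) -> None:
        channels = [e[0] for e in self.entries]
        if len(set(channels)) != len(channels):
            raise ValueError("panel channels must be unique")
        for ch, metal, marker, role in self.entries:
            if role not in self.ROLES:
                raise ValueError(f"unknown role {role!r} for channel {ch!r}")
        cd45 = self.channels_by_role("barcode_cd45")
        pd = self.channels_by_role("barcode_pd")
        if set(cd45) & set(pd):
            raise ValueError("barcode_cd45 and barcode_pd channel sets must be disjoint")

    def channels_by_role(self, role: str) -> list[str]:
        return [ch for ch, _, _, r in self.entries if r == role]

    def marker_for(self, channel: str) -> str:
        for ch, _, marker, _ in self.entries:
            if ch == channel:
                return marker
        raise KeyError(f"channel {channel!r} not in panel")


# ---------------------------------------------------------------------------
# FCS file I/O


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Escaped delimiters (doubled) are rare in practice; split then re-join.
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        # Trailing empty chunk from delimiter at the end.
        if parts and parts[-1] == b"":
            parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise FcsFormatError("malformed TEXT segment: odd number of fields")
    out: dict[str, str] = {}
    for key, value in zip(parts[::2], parts[1::2]):
        out[key.decode("utf-8", "replace").strip().upper()] = value.decode("utf-8", "replace")
    return out


def read_fcs(path: str | Path) -> EventMatrix:
    """Read an FCS 3.0/3.1 list-mode file into a raw-scale EventMatrix.

    Channel short names ($PnN) become the channel names; a channel
    named ``Time`` is lifted out into ``acquisition_time``.  Event
    order is preserved.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 58:
        raise FcsFormatError(f"{path}: too short to be an FCS file")
    version = data[0:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsFormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        try:
            return int(data[lo:hi].decode("ascii").strip() or "0")
        except ValueError as exc:
            raise FcsFormatError(f"{path}: bad header offsets") from exc

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    if text_end <= text_start or text_end >= len(data):
        raise FcsFormatError(f"{path}: TEXT segment offsets out of range")
    text = _parse_text_segment(data[text_start : text_end + 1])

    if data_start == 0:
        data_start = int(text.get("$BEGINDATA", "0"))
    if data_end == 0:
        data_end = int(text.get("$ENDDATA", "0"))

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    dtype_code = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    if text.get("$MODE", "L").upper() != "L":
        raise FcsFormatError(f"{path}: only list mode ($MODE L) supported")

    names = []
    for i in range(1, n_par + 1):
        name = text.get(f"$P{i}N")
        if name is None:
            raise FcsFormatError(f"{path}: missing $P{i}N")
        names.append(name)
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate channel names in file")

    bits = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if dtype_code == "F":
        if any(b != 32 for b in bits):
            raise FcsFormatError(f"{path}: float data must be 32-bit")
        np_dtype = np.dtype("<f4" if little else ">f4")
    elif dtype_code == "D":
        np_dtype = np.dtype("<f8" if little else ">f8")
    elif dtype_code == "I":
        if any(b not in (16, 32) for b in bits) or len(set(bits)) != 1:
            raise FcsFormatError(f"{path}: unsupported integer widths")
        code = "u2" if bits[0] == 16 else "u4"
        np_dtype = np.dtype(("<" if little else ">") + code)
    else:
        raise FcsFormatError(f"{path}: unsupported $DATATYPE {dtype_code!r}")

    n_values = n_par * n_tot
    expected = n_values * np_dtype.itemsize
    segment = data[data_start : data_end + 1]
    if len(segment) < expected:
        raise FcsFormatError(
            f"{path}: truncated DATA segment ({len(segment)} bytes, need {expected})"
        )
    values = np.frombuffer(segment[:expected], dtype=np_dtype).astype(float)
    values = values.reshape(n_tot, n_par)

    acquisition_time = None
    if TIME_CHANNEL in names:
        ti = names.index(TIME_CHANNEL)
        acquisition_time = values[:, ti].copy()
        keep = [i for i in range(n_par) if i != ti]
        values = values[:, keep]
        names = [n for i, n in enumerate(names) if i != ti]
    return EventMatrix(values, names, scale="raw", acquisition_time=acquisition_time)


def write_fcs(events: EventMatrix, path: str | Path) -> Path:
    """Write a raw-scale EventMatrix as a deterministic FCS 3.1 file.

    Stores 32-bit little-endian floats, one dataset, fixed keyword
    order and no timestamps, so repeated writes are byte-identical.
    ``acquisition_time`` is stored as an extra ``Time`` channel.
    """
    path = Path(path)
    if events.scale != "raw":
        raise ValueError("only raw-scale event data may be written to FCS")
    if events.n_events and np.any(events.values < 0):
        raise ValueError("raw-scale intensities must be non-negative")

    values = events.values
    names = list(events.channel_names)
    if events.acquisition_time is not None:
        values = np.column_stack([values, events.acquisition_time]) if events.n_events else (
            np.empty((0, len(names) + 1))
        )
        names.append(TIME_CHANNEL)
    n_tot, n_par = values.shape

    payload = values.astype("<f4").tobytes()

    def build_text(begin_data: int, end_data: int) -> bytes:
        pairs: list[tuple[str, str]] = [
            ("$BEGINANALYSIS", "0"),
            ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"),
            ("$ENDSTEXT", "0"),
            ("$BEGINDATA", str(begin_data)),
            ("$ENDDATA", str(end_data)),
            ("$BYTEORD", "1,2,3,4"),
            ("$DATATYPE", "F"),
            ("$MODE", "L"),
            ("$NEXTDATA", "0"),
            ("$PAR", str(n_par)),
            ("$TOT", str(n_tot)),
        ]
        for i, name in enumerate(names, start=1):
            rng = max(1024.0, float(values[:, i - 1].max()) if n_tot else 1024.0)
            pairs += [
                (f"$P{i}B", "32"),
                (f"$P{i}E", "0,0"),
                (f"$P{i}N", name),
                (f"$P{i}R", str(int(np.ceil(rng)) + 1)),
            ]
        delim = "/"
        out = delim
        for key, value in pairs:
            out += f"{key}{delim}{value}{delim}"
        return out.encode("ascii")

    header_len = 58
    # Two passes: offsets depend on TEXT length, which depends on offsets.
    text = build_text(0, 0)
    for _ in range(3):
        text_start = header_len
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(payload) - 1 if payload else data_start
        new_text = build_text(data_start, data_end)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    else:  # pragma: no cover - offsets stabilize in <= 2 passes
        raise RuntimeError("TEXT segment offsets failed to stabilize")

    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(payload) - 1 if payload else data_start

    def field58(n: int) -> bytes:
        s = str(n)
        if len(s) > 8:
            return b"0" * 8  # deferred to TEXT $BEGINDATA/$ENDDATA
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + field58(text_start) + field58(text_end)
    header += field58(data_start) + field58(data_end)
    header += field58(0) + field58(0)
    assert len(header) == header_len
    path.write_bytes(header + text + payload)
    return path


# ---------------------------------------------------------------------------
# Preprocessing


def arcsinh_transform(events: EventMatrix, cofactor: float = DEFAULT_COFACTOR) -> EventMatrix:
    """Apply ``asinh(x / cofactor)`` to every channel.

    The transform is applied uniformly -- barcode and DNA channels
    included -- and the scale tag flips to ``"arcsinh"``.  Downstream
    operations select the channels they need explicitly.
    """
    if events.scale != "raw":
        raise ValueError("events are already transformed")
    if not cofactor > 0:
        raise ValueError("cofactor must be positive")
    return replace(events, values=np.arcsinh(events.values / cofactor), scale="arcsinh")


def inverse_arcsinh(events: EventMatrix, cofactor: float = DEFAULT_COFACTOR) -> EventMatrix:
    """Invert :func:`arcsinh_transform` (``sinh(x) * cofactor``)."""
    if events.scale != "arcsinh":
        raise ValueError("events are not arcsinh-scaled")
    return replace(events, values=np.sinh(events.values) * cofactor, scale="raw")


def compensate_channel(
    events: EventMatrix, target: str, source: str, fraction: float
) -> EventMatrix:
    """Subtract ``fraction`` of one channel's signal from another.

    Implements the single-channel spillover correction used for oxide
    spillover (e.g. removing 1.9% of the CD8 channel from the gdTCR
    channel).  Negative results are retained rather than clamped, so
    medians of compensated channels are not biased upward.
    """
    if events.scale != "raw":
        raise ValueError("compensation operates on raw-scale data")
    if target == source:
        raise ValueError("target and source channels must differ")
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    ti = events._index(target)
    si = events._index(source)
    values = events.values.copy()
    values[:, ti] = values[:, ti] - fraction * values[:, si]
    return replace(events, values=values)
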
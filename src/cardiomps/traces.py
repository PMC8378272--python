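"""Domain types and I/O for optical cardiac fluorescence recordings.

A recording is a single scalar fluorescence channel (voltage-sensitive dye
or genetically encoded calcium indicator) sampled uniformly, nominally at
100 frames per second for 6 s or 30 s.  Time is stored implicitly: the time
of sample ``i`` is ``t0 + i / sampling_rate``.  The on-disk format is a
plain-text CSV with ``#key=value`` header lines carrying the recording
metadata followed by ``time_s,fluorescence`` rows; the explicit time column
is redundant and is validated against the implicit model on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "Rhythm",
    "FluorescenceTrace",
    "RecordingMeta",
    "TraceSet",
    "TraceFormatError",
    "read_trace_csv",
    "write_trace_csv",
    "tiff_to_trace",
]

#: tolerance (s) when checking an explicit time column against uniform sampling
TIME_TOLERANCE_S = 1e-6


class TraceFormatError(ValueError):
    """Raised when a trace file violates the on-disk format contract."""


class Channel(str, Enum):
    VOLTAGE = "voltage"
    CALCIUM = "calcium"


class Rhythm(str, Enum):
    SPONTANEOUS = "spontaneous"
    PACED = "paced"


@dataclass(frozen=True, eq=False)
class FluorescenceTrace:
    """Uniformly sampled scalar fluorescence signal.

    Parameters
    ----------
    samples:
        Fluorescence intensity in arbitrary units, one value per frame.
    sampling_rate:
        Frame rate in Hz (default 100).
    channel:
        Which reporter produced the signal (voltage dye or calcium indicator).
    t0:
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sampling_rate: float = 100.0
    channel: Channel = Channel.CALCIUM
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if arr.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(arr)):
            raise ValueError("all samples must be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "channel", Channel(self.channel))

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Duration covered by the frames, ``n / sampling_rate``."""
        return self.n / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, ``t0 + i / sampling_rate``."""
        return self.t0 + np.arange(self.n) / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "FluorescenceTrace":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class RecordingMeta:
    """Provenance of one recording within a dose-escalation study.

    ``dose`` is always in µM; dose ladders expressed as multiples of Cmax are
    resolved to µM when the study design is loaded.  ``dose_index`` 0 denotes
    the drug-free baseline.
    """

    tissue_id: str
    chip_id: str
    chamber_index: int
    drug: str
    dose: float
    dose_index: int
    rhythm: Rhythm
    pacing_frequency: Optional[float] = None
    recording_length_s: float = 30.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rhythm", Rhythm(self.rhythm))
        if self.chamber_index not in (1, 2, 3, 4):
            raise ValueError("chamber_index must be in {1,2,3,4} (4-plex chip)")
        if self.dose < 0:
            raise ValueError("dose must be >= 0 µM")
        if self.dose_index < 0:
            raise ValueError("dose_index must be >= 0")
        if self.rhythm is Rhythm.PACED:
            if self.pacing_frequency is None or not self.pacing_frequency > 0:
                raise ValueError("paced recordings require pacing_frequency > 0")
        if self.recording_length_s <= 0:
            raise ValueError("recording_length_s must be positive")


def _trace_key(meta: RecordingMeta, trace: FluorescenceTrace) -> tuple:
    return (
        meta.tissue_id,
        meta.dose_index,
        trace.channel.value,
        meta.rhythm.value,
        meta.recording_length_s,
    )


class TraceSet:
    """A keyed collection of recordings.

    Entries are unique on ``(tissue_id, dose_index, channel, rhythm,
    recording_length_s)`` so that the study orchestrator can address the
    specific recording each metric is routed to.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple, Tuple[RecordingMeta, FluorescenceTrace]] = {}

    def add(self, meta: RecordingMeta, trace: FluorescenceTrace) -> None:
        key = _trace_key(meta, trace)
        if key in self._entries:
            raise ValueError(f"duplicate recording for key {key}")
        self._entries[key] = (meta, trace)

    def get(
        self,
        tissue_id: str,
        dose_index: int,
        channel: Channel | str,
        rhythm: Rhythm | str,
        recording_length_s: float,
    ) -> Optional[Tuple[RecordingMeta, FluorescenceTrace]]:
        key = (
            tissue_id,
            dose_index,
            Channel(channel).value,
            Rhythm(rhythm).value,
            recording_length_s,
        )
        return self._entries.get(key)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[Tuple[RecordingMeta, FluorescenceTrace]]:
        return iter(self._entries.values())

    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for meta, _ in self:
            seen.setdefault(meta.tissue_id, None)
        return list(seen)


# ---------------------------------------------------------------------------
# CSV dialect

_META_KEYS = (
    "tissue_id",
    "chip_id",
    "chamber_index",
    "drug",
    "dose",
    "dose_index",
    "rhythm",
    "pacing_frequency",
    "recording_length_s",
)


def write_trace_csv(meta: RecordingMeta, trace: FluorescenceTrace, path) -> None:
    """Write one recording to the plain-text trace dialect.

    The file holds ``#key=value`` header lines for every metadata field plus
    ``sampling_rate``, ``channel`` and ``t0``, then a ``time_s,fluorescence``
    table at full decimal precision so that a read-back is bit exact.
    """
    path = Path(path)
    lines = []
    for key in _META_KEYS:
        value = getattr(meta, key)
        if isinstance(value, Enum):
            value = value.value
        lines.append(f"#{key}={'' if value is None else value}")
    lines.append(f"#sampling_rate={float(trace.sampling_rate)!r}")
    lines.append(f"#channel={trace.channel.value}")
    lines.append(f"#t0={float(trace.t0)!r}")
    lines.append("time_s,fluorescence")
    times = trace.times
    for t, v in zip(times, trace.samples):
        lines.append(f"{float(t)!r},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_header(path: Path) -> dict[str, str]:
    header: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                header[key.strip()] = value.strip()
    return header


def read_trace_csv(path) -> Tuple[RecordingMeta, FluorescenceTrace]:
    """Read a recording written by :func:`write_trace_csv`.

    Raises :class:`TraceFormatError` on missing header keys, a non-uniform or
    decreasing time column, or non-finite samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = _parse_header(path)
    required = set(_META_KEYS) | {"sampling_rate", "channel", "t0"}
    missing = required - set(header)
    if missing:
        raise TraceFormatError(f"{path}: missing header keys {sorted(missing)}")

    try:
        sampling_rate = float(header["sampling_rate"])
        pacing = header["pacing_frequency"]
        meta = RecordingMeta(
            tissue_id=header["tissue_id"],
            chip_id=header["chip_id"],
            chamber_index=int(header["chamber_index"]),
            drug=header["drug"],
            dose=float(header["dose"]),
            dose_index=int(header["dose_index"]),
            rhythm=Rhythm(header["rhythm"]),
            pacing_frequency=float(pacing) if pacing else None,
            recording_length_s=float(header["recording_length_s"]),
        )
    except (ValueError, KeyError) as exc:
        raise TraceFormatError(f"{path}: bad header ({exc})") from exc

    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    if list(table.columns) != ["time_s", "fluorescence"]:
        raise TraceFormatError(f"{path}: expected columns time_s,fluorescence")
    values = table["fluorescence"].to_numpy(dtype=float)
    times = table["time_s"].to_numpy(dtype=float)
    if values.size < 2:
        raise TraceFormatError(f"{path}: trace must have at least 2 samples")
    if np.any(~np.isfinite(values)) or np.any(~np.isfinite(times)):
        raise TraceFormatError(f"{path}: non-finite sample or time value")

    t0 = float(header["t0"])
    expected = t0 + np.arange(values.size) / sampling_rate
    if np.max(np.abs(times - expected)) > TIME_TOLERANCE_S:
        raise TraceFormatError(
            f"{path}: time column deviates from uniform sampling at "
            f"{sampling_rate} Hz by more than {TIME_TOLERANCE_S} s"
        )

    trace = FluorescenceTrace(
        samples=values,
        sampling_rate=sampling_rate,
        channel=Channel(header["channel"]),
        t0=t0,
    )
    return meta, trace


# ---------------------------------------------------------------------------
# TIFF reduction

def tiff_to_trace(
    path,
    roi: Tuple[int, int, int, int],
    sampling_rate: float = 100.0,
    channel: Channel | str = Channel.CALCIUM,
) -> FluorescenceTrace:
    """Reduce a multi-frame grayscale TIFF stack to a mean-ROI trace.

    ``roi`` is ``(x0, x1, y0, y1)`` in 0-based half-open pixel coordinates;
    sample ``i`` of the returned trace is the mean pixel intensity of the ROI
    in frame ``i``.
    """
    import tifffile

    stack = np.asarray(tifffile.imread(str(path)))
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(
            f"expected a multi-frame single-channel stack, got shape {stack.shape}"
        )
    n_frames, height, width = stack.shape
    x0, x1, y0, y1 = roi
    if not (0 <= x0 < x1 <= width and 0 <= y0 < y1 <= height):
        raise ValueError(
            f"roi {roi} outside frame bounds {width}x{height} (half-open [x0,x1)x[y0,y1))"
        )
    values = stack[:, y0:y1, x0:x1].mean(axis=(1, 2)).astype(float)
    return FluorescenceTrace(values, sampling_rate=sampling_rate, channel=channel)
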
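"""Device specifications and file dialects for the two logger types.

Two head-mounted accelerometers are modelled. The burst-mode logger wakes
every 20 s and records 2.43 s of triaxial data at 33.8 Hz (82 samples per
axis per burst), encoded as unsigned counts in 0..4095. The continuous-mode
logger streams one sample per second ("heartbeat"), encoded as signed counts
in -32000..+32000, with transmission dropouts appearing as missing seconds.

The two devices mount differently on the head, so their raw x/y/z axes map
onto different body-frame (semantic) axes:

* sway  — lateral movement
* surge — anterior-posterior movement
* heave — dorso-ventral movement (carries gravity when the head is level)

All downstream code works on semantic axes; the mapping is applied at
ingest and inverted when writing files so exports look like real ones.

On-disk dialects (UTF-8 CSV, RFC 4180):

* burst CSV (long form): ``tag_id,individual,burst_start_iso8601,axis,
  sample_index,value`` with ``axis`` in raw labels x/y/z;
* continuous CSV: ``timestamp_iso8601,x,y,z[,pitch,roll]`` — any vendor
  pitch/roll columns are ignored on read (they are recomputed downstream);
* ethogram CSV: ``individual,start_iso8601,end_iso8601,behavior_code``.

Timestamps are ISO-8601 UTC on disk and UTC epoch seconds in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SEMANTIC_AXES = ("sway", "surge", "heave")

#: label given to bursts overlapping two or more observed behaviors
MIXED = "MIXED"
#: label given to bursts with no ethogram coverage
UNLABELED = "UNLABELED"


class DialectError(ValueError):
    """A device export file violates its documented dialect."""


@dataclass(frozen=True)
class DeviceSpec:
    """Sampling regime, raw encoding and axis orientation of one logger."""

    name: str
    mode: str  # "burst" or "continuous"
    sample_rate: float  # Hz
    raw_min: int
    raw_max: int
    axis_map: Mapping[str, str]  # raw label -> semantic axis
    burst_duration: Optional[float] = None  # s, burst mode only
    recording_interval: Optional[float] = None  # s between burst starts
    zero_g_count: float = 0.0  # raw count representing 0 g (orientation origin)

    def __post_init__(self) -> None:
        if self.mode not in ("burst", "continuous"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.raw_min >= self.raw_max:
            raise ValueError("raw_min must be < raw_max")
        if sorted(self.axis_map) != ["x", "y", "z"] or sorted(
            self.axis_map.values()
        ) != sorted(SEMANTIC_AXES):
            raise ValueError("axis_map must biject {x,y,z} onto semantic axes")
        if self.mode == "burst" and (
            self.burst_duration is None or self.recording_interval is None
        ):
            raise ValueError("burst mode needs burst_duration and recording_interval")

    @property
    def samples_per_burst(self) -> int:
        """Samples per axis per burst: floor(rate x duration)."""
        if self.mode != "burst":
            raise ValueError("samples_per_burst is burst-mode only")
        return int(np.floor(self.sample_rate * self.burst_duration))

    @property
    def inverse_axis_map(self) -> dict[str, str]:
        """Semantic axis -> raw label."""
        return {sem: raw for raw, sem in self.axis_map.items()}


#: burst-mode logger: x measures heave, y sway, z surge
EOBS = DeviceSpec(
    name="eobs",
    mode="burst",
    sample_rate=33.8,
    burst_duration=2.43,
    recording_interval=20.0,
    raw_min=0,
    raw_max=4095,
    axis_map={"x": "heave", "y": "sway", "z": "surge"},
    zero_g_count=2048.0,
)

#: continuous-mode logger: x measures surge, y sway, z heave
AWT = DeviceSpec(
    name="awt",
    mode="continuous",
    sample_rate=1.0,
    raw_min=-32000,
    raw_max=32000,
    axis_map={"x": "surge", "y": "sway", "z": "heave"},
)

DEVICES: dict[str, DeviceSpec] = {EOBS.name: EOBS, AWT.name: AWT}


@dataclass
class Burst:
    """One window of triaxial samples on semantic axes, optionally labeled."""

    individual: str
    device: str
    start_time: float  # epoch seconds
    samples_sway: np.ndarray
    samples_surge: np.ndarray
    samples_heave: np.ndarray
    label: str = UNLABELED

    def __post_init__(self) -> None:
        self.samples_sway = np.asarray(self.samples_sway, dtype=float)
        self.samples_surge = np.asarray(self.samples_surge, dtype=float)
        self.samples_heave = np.asarray(self.samples_heave, dtype=float)
        n = len(self.samples_sway)
        if not (len(self.samples_surge) == len(self.samples_heave) == n) or n < 1:
            raise ValueError("axis sample sequences must share a length >= 1")

    def __len__(self) -> int:
        return len(self.samples_sway)

    def axis(self, name: str) -> np.ndarray:
        return getattr(self, f"samples_{name}")


@dataclass
class SampleStream:
    """Time-ordered raw triaxial samples from one continuous deployment.

    Arrays are kept on raw axis labels (x/y/z) exactly as exported; use
    :func:`to_semantic_axes` or downstream segmentation to reach the body
    frame. Gaps are represented by absent timestamps, never interpolated.
    """

    individual: str
    device: str
    timestamps: np.ndarray  # epoch seconds, strictly increasing
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        for a in "xyz":
            setattr(self, a, np.asarray(getattr(self, a)))
        if np.any(np.diff(self.timestamps) <= 0):
            raise DialectError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    def semantic(self, spec: DeviceSpec) -> dict[str, np.ndarray]:
        """Per-semantic-axis views of the sample arrays."""
        return {spec.axis_map[raw]: getattr(self, raw) for raw in "xyz"}


def to_semantic_axes(
    raw_sample: tuple[float, float, float], axis_map: Mapping[str, str]
) -> tuple[float, float, float]:
    """Permute one raw (x, y, z) triple into (sway, surge, heave).

    Pure permutation — values are never transformed.
    """
    by_sem = {axis_map[raw]: v for raw, v in zip("xyz", raw_sample)}
    return tuple(by_sem[a] for a in SEMANTIC_AXES)


def parse_iso8601(value: str) -> float:
    """ISO-8601 (UTC assumed if naive) -> epoch seconds."""
    dt = datetime.fromisoformat(str(value).replace("Z", "+00:00"))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


def format_iso8601(seconds: float) -> str:
    dt = datetime.fromtimestamp(float(seconds), tz=timezone.utc)
    return dt.isoformat(timespec="microseconds").replace("+00:00", "Z")


def _check_bounds(values: np.ndarray, spec: DeviceSpec, context: str) -> None:
    bad = (values < spec.raw_min) | (values > spec.raw_max)
    if np.any(bad):
        v = values[bad][0]
        raise DialectError(
            f"{context}: value {v} outside [{spec.raw_min}, {spec.raw_max}]"
        )


def read_burst_device(path: str | Path, spec: DeviceSpec) -> list[Burst]:
    """Parse a burst-mode export (long-form CSV) into labeled-ready Bursts.

    Raw axes are remapped to semantic axes via the spec's axis_map. Every
    burst must contain exactly ``spec.samples_per_burst`` samples per axis,
    and every value must lie inside the raw encoding range.
    """
    if spec.mode != "burst":
        raise ValueError("read_burst_device requires a burst-mode spec")
    required = ["tag_id", "individual", "burst_start_iso8601", "axis",
                "sample_index", "value"]
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DialectError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise DialectError(f"{path}: missing columns {missing}")
    if table["axis"].isin(list("xyz")).all() is False or not set(
        table["axis"]
    ) <= set("xyz"):
        raise DialectError(f"{path}: axis labels must be x, y or z")
    for col in ("sample_index", "value"):
        numeric = pd.to_numeric(table[col], errors="coerce")
        if numeric.isna().any():
            line = int(numeric.index[numeric.isna()][0]) + 2  # header + 1-based
            raise DialectError(f"{path}: malformed {col} at line {line}")
        table[col] = numeric.astype(int)
    _check_bounds(table["value"].to_numpy(), spec, str(path))

    n_expect = spec.samples_per_burst
    bursts: list[Burst] = []
    for (tag, indiv, start_iso), group in table.groupby(
        ["tag_id", "individual", "burst_start_iso8601"], sort=True
    ):
        axes: dict[str, np.ndarray] = {}
        for raw in "xyz":
            sub = group[group["axis"] == raw].sort_values("sample_index")
            if len(sub) != n_expect:
                raise DialectError(
                    f"{path}: burst {tag}@{start_iso} axis {raw} has "
                    f"{len(sub)} samples, expected {n_expect}"
                )
            axes[spec.axis_map[raw]] = sub["value"].to_numpy(dtype=float)
        bursts.append(
            Burst(
                individual=str(indiv),
                device=spec.name,
                start_time=parse_iso8601(start_iso),
                samples_sway=axes["sway"],
                samples_surge=axes["surge"],
                samples_heave=axes["heave"],
            )
        )
    bursts.sort(key=lambda b: (b.individual, b.start_time))
    return bursts


def write_burst_device(
    bursts: Iterable[Burst], path: str | Path, spec: DeviceSpec, tag_id: str = "tag0"
) -> None:
    """Write Bursts back to the long-form burst CSV, on raw axis labels."""
    inv = spec.inverse_axis_map
    rows = []
    for b in bursts:
        start = format_iso8601(b.start_time)
        for sem in SEMANTIC_AXES:
            values = b.axis(sem)
            raw = inv[sem]
            for i, v in enumerate(values):
                rows.append((tag_id, b.individual, start, raw, i, int(v)))
    frame = pd.DataFrame(
        rows,
        columns=["tag_id", "individual", "burst_start_iso8601", "axis",
                 "sample_index", "value"],
    )
    frame.to_csv(path, index=False)


def read_continuous_device(
    path: str | Path, spec: DeviceSpec, individual: str = "unknown"
) -> SampleStream:
    """Parse a continuous-mode export into a SampleStream.

    Missing seconds (transmission dropouts) are preserved as absent
    timestamps. Vendor pitch/roll columns, if present, are dropped — the
    pipeline recomputes orientation identically for both devices.
    """
    if spec.mode != "continuous":
        raise ValueError("read_continuous_device requires a continuous-mode spec")
    table = pd.read_csv(path)
    for col in ("timestamp_iso8601", "x", "y", "z"):
        if col not in table.columns:
            raise DialectError(f"{path}: missing column {col}")
    times = np.array([parse_iso8601(t) for t in table["timestamp_iso8601"]])
    if np.any(np.diff(times) <= 0):
        raise DialectError(f"{path}: timestamps not strictly increasing")
    arrays = {}
    for col in "xyz":
        numeric = pd.to_numeric(table[col], errors="coerce")
        if numeric.isna().any():
            line = int(numeric.index[numeric.isna()][0]) + 2
            raise DialectError(f"{path}: malformed {col} at line {line}")
        arrays[col] = numeric.to_numpy(dtype=int)
        _check_bounds(arrays[col], spec, str(path))
    return SampleStream(
        individual=individual, device=spec.name, timestamps=times, **arrays
    )


def write_continuous_device(stream: SampleStream, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "timestamp_iso8601": [format_iso8601(t) for t in stream.timestamps],
            "x": stream.x.astype(int),
            "y": stream.y.astype(int),
            "z": stream.z.astype(int),
        }
    )
    frame.to_csv(path, index=False)
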
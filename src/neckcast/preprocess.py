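"""Ethogram labeling, continuous-stream segmentation, filtering, subsampling.

The observation protocol is a list of timed behavior intervals per
individual. Burst-mode windows are labeled by interval containment;
the continuous 1 Hz stream is cut into variable-length behavior sections
(one per maximal run of consecutive seconds inside a single interval, with
dropout gaps splitting sections). Only pure-behavior windows survive, and
the analysis set is a balanced random subsample per category, dropping
categories that do not reach the minimum count.

Containment convention: intervals are half-open [start, end) and a window
counts as inside an interval iff every one of its sample timestamps is.
Clock synchronization is assumed (observers synchronized to the second);
no tolerance slack is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .device_models import (
    Burst,
    DeviceSpec,
    MIXED,
    SampleStream,
    UNLABELED,
    format_iso8601,
    parse_iso8601,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EthogramInterval:
    """One observed behavior over a closed stretch of time."""

    individual: str
    start: float  # epoch seconds
    end: float
    behavior: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"interval start {self.start} must precede end {self.end}"
            )


@dataclass
class LabeledDataset:
    """Pure-behavior bursts ready for feature extraction."""

    bursts: list[Burst]
    provenance: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return len(self.bursts)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for b in self.bursts:
            out[b.label] = out.get(b.label, 0) + 1
        return dict(sorted(out.items()))

    @property
    def individuals(self) -> list[str]:
        return sorted({b.individual for b in self.bursts})


def read_ethogram(path: str | Path) -> list[EthogramInterval]:
    """Read the ethogram CSV dialect; checks per-individual non-overlap."""
    table = pd.read_csv(path)
    for col in ("individual", "start_iso8601", "end_iso8601", "behavior_code"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col}")
    intervals = [
        EthogramInterval(
            individual=str(r.individual),
            start=parse_iso8601(r.start_iso8601),
            end=parse_iso8601(r.end_iso8601),
            behavior=str(r.behavior_code),
        )
        for r in table.itertuples()
    ]
    _check_non_overlapping(intervals)
    return intervals


def write_ethogram(intervals: Iterable[EthogramInterval], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "individual": [iv.individual for iv in intervals],
            "start_iso8601": [format_iso8601(iv.start) for iv in intervals],
            "end_iso8601": [format_iso8601(iv.end) for iv in intervals],
            "behavior_code": [iv.behavior for iv in intervals],
        }
    )
    frame.to_csv(path, index=False)


def _check_non_overlapping(intervals: Sequence[EthogramInterval]) -> None:
    by_indiv: dict[str, list[EthogramInterval]] = {}
    for iv in intervals:
        by_indiv.setdefault(iv.individual, []).append(iv)
    for indiv, ivs in by_indiv.items():
        ivs = sorted(ivs, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping intervals for {indiv}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def _behaviors_touched(
    sample_times: np.ndarray, intervals: Sequence[EthogramInterval]
) -> tuple[set[str], bool]:
    """Behavior codes covering any sample, plus whether all samples covered."""
    starts = np.array([iv.start for iv in intervals])
    ends = np.array([iv.end for iv in intervals])
    behaviors: set[str] = set()
    covered = 0
    for t in sample_times:
        hit = np.flatnonzero((starts <= t) & (t < ends))
        if hit.size:
            behaviors.add(intervals[hit[0]].behavior)
            covered += 1
    return behaviors, covered == len(sample_times)


def label_bursts(
    bursts: Sequence[Burst],
    ethogram: Sequence[EthogramInterval],
    spec: DeviceSpec,
) -> list[Burst]:
    """Assign each burst the behavior observed throughout it.

    A burst wholly inside one interval gets that behavior code; one that
    touches two or more behaviors becomes MIXED; one with any unobserved
    (and no second observed) time becomes UNLABELED. Labeling is exhaustive
    and exclusive: every burst leaves with exactly one label.
    """
    by_indiv: dict[str, list[EthogramInterval]] = {}
    for iv in ethogram:
        by_indiv.setdefault(iv.individual, []).append(iv)
    for ivs in by_indiv.values():
        ivs.sort(key=lambda iv: iv.start)

    out = []
    for b in bursts:
        ivs = by_indiv.get(b.individual, [])
        times = b.start_time + np.arange(len(b)) / spec.sample_rate
        if not ivs:
            label = UNLABELED
        else:
            behaviors, fully_covered = _behaviors_touched(times, ivs)
            if len(behaviors) >= 2:
                label = MIXED
            elif len(behaviors) == 1 and fully_covered:
                label = next(iter(behaviors))
            else:
                label = UNLABELED
        out.append(
            Burst(
                individual=b.individual,
                device=b.device,
                start_time=b.start_time,
                samples_sway=b.samples_sway,
                samples_surge=b.samples_surge,
                samples_heave=b.samples_heave,
                label=label,
            )
        )
    return out


def segment_continuous(
    stream: SampleStream,
    ethogram: Sequence[EthogramInterval],
    spec: DeviceSpec,
) -> list[Burst]:
    """Cut a 1 Hz stream into labeled variable-length behavior sections.

    One Burst per maximal run of consecutive seconds falling inside a
    single behavior interval; dropout gaps (missing seconds) split
    sections. Unobserved samples are simply not emitted.
    """
    semantic = stream.semantic(spec)
    times = stream.timestamps
    ivs = sorted(
        (iv for iv in ethogram if iv.individual == stream.individual),
        key=lambda iv: iv.start,
    )
    sections: list[Burst] = []
    gap = 1.0 / spec.sample_rate
    for iv in ivs:
        inside = np.flatnonzero((times >= iv.start) & (times < iv.end))
        if inside.size == 0:
            continue
        # split where consecutive kept samples are more than one period apart
        breaks = np.flatnonzero(np.diff(times[inside]) > gap * 1.5)
        for run in np.split(inside, breaks + 1):
            sections.append(
                Burst(
                    individual=stream.individual,
                    device=stream.device,
                    start_time=float(times[run[0]]),
                    samples_sway=semantic["sway"][run].astype(float),
                    samples_surge=semantic["surge"][run].astype(float),
                    samples_heave=semantic["heave"][run].astype(float),
                    label=iv.behavior,
                )
            )
    sections.sort(key=lambda b: b.start_time)
    return sections


def filter_pure(
    bursts: Sequence[Burst], min_length: int = 1
) -> LabeledDataset:
    """Keep only pure-behavior bursts (and, optionally, long-enough ones).

    Mixed and unlabeled bursts are excluded from the analysis set. For
    variable-length continuous sections a minimum length (default 1, the
    pipeline uses 5) guards the moment and spectral features against
    degenerate inputs; discarded short sections are logged.
    """
    pure, short = [], 0
    for b in bursts:
        if b.label in (MIXED, UNLABELED):
            continue
        if len(b) < min_length:
            short += 1
            continue
        pure.append(b)
    if short:
        logger.info("filter_pure: discarded %d sections shorter than %d samples",
                    short, min_length)
    if not pure:
        logger.warning("filter_pure: no pure-behavior bursts retained")
    ds = LabeledDataset(bursts=pure)
    ds.provenance["filter"] = {
        "input": len(bursts),
        "retained": len(pure),
        "min_length": min_length,
        "counts": ds.counts,
    }
    return ds


def relabel(dataset: LabeledDataset, mapping: Mapping[str, str]) -> LabeledDataset:
    """Fold sub-codes into their parent category (e.g. STA_STILL -> STA)."""
    bursts = []
    for b in dataset.bursts:
        label = mapping.get(b.label, b.label)
        bursts.append(
            Burst(
                individual=b.individual,
                device=b.device,
                start_time=b.start_time,
                samples_sway=b.samples_sway,
                samples_surge=b.samples_surge,
                samples_heave=b.samples_heave,
                label=label,
            )
        )
    out = LabeledDataset(bursts=bursts, provenance=dict(dataset.provenance))
    out.provenance["relabel"] = dict(mapping)
    return out


def write_labeled_csv(
    dataset: LabeledDataset, path: str | Path, spec: DeviceSpec,
    tag_id: str = "tag0",
) -> None:
    """Labeled-dataset file: the long-form burst CSV plus a label column."""
    inv = spec.inverse_axis_map
    rows = []
    for b in dataset.bursts:
        start = format_iso8601(b.start_time)
        for sem in ("sway", "surge", "heave"):
            raw = inv[sem]
            for i, v in enumerate(b.axis(sem)):
                rows.append((tag_id, b.individual, start, raw, i, v, b.label))
    pd.DataFrame(
        rows,
        columns=["tag_id", "individual", "burst_start_iso8601", "axis",
                 "sample_index", "value", "label"],
    ).to_csv(path, index=False)


def read_labeled_csv(path: str | Path, spec: DeviceSpec) -> LabeledDataset:
    """Read a labeled-dataset file (variable burst lengths allowed)."""
    table = pd.read_csv(path)
    bursts = []
    for (_, indiv, start_iso, label), group in table.groupby(
        ["tag_id", "individual", "burst_start_iso8601", "label"], sort=True
    ):
        axes = {}
        for raw in "xyz":
            sub = group[group["axis"] == raw].sort_values("sample_index")
            axes[spec.axis_map[raw]] = sub["value"].to_numpy(dtype=float)
        bursts.append(
            Burst(
                individual=str(indiv),
                device=spec.name,
                start_time=parse_iso8601(start_iso),
                samples_sway=axes["sway"],
                samples_surge=axes["surge"],
                samples_heave=axes["heave"],
                label=str(label),
            )
        )
    bursts.sort(key=lambda b: (b.individual, b.start_time))
    return LabeledDataset(bursts=bursts)


def balanced_subsample(
    dataset: LabeledDataset,
    n_per_category: int,
    seed: int,
    min_n: Optional[int] = None,
) -> LabeledDataset:
    """Draw exactly n bursts per retained category, without replacement.

    Categories with fewer than ``min_n`` bursts (default: ``n_per_category``)
    are dropped entirely and reported in provenance — under-sampled
    behaviors would otherwise bias the class balance. Deterministic under
    the seed and invariant to input burst order.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    min_n = n_per_category if min_n is None else min_n
    if min_n < n_per_category:
        raise ValueError("min_n below n_per_category would make exact "
                         "sampling impossible")
    rng = np.random.default_rng(seed)
    by_cat: dict[str, list[Burst]] = {}
    for b in dataset.bursts:
        by_cat.setdefault(b.label, []).append(b)

    kept: list[Burst] = []
    dropped: dict[str, int] = {}
    for cat in sorted(by_cat):
        group = sorted(by_cat[cat], key=lambda b: (b.individual, b.start_time))
        if len(group) < min_n:
            dropped[cat] = len(group)
            continue
        chosen = rng.choice(len(group), size=n_per_category, replace=False)
        kept.extend(group[i] for i in sorted(chosen))
    if dropped:
        logger.info("balanced_subsample: dropped categories %s", dropped)
    out = LabeledDataset(bursts=kept, provenance=dict(dataset.provenance))
    out.provenance["subsample"] = {
        "n_per_category": n_per_category,
        "min_n": min_n,
        "seed": seed,
        "dropped": dropped,
    }
    return out
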
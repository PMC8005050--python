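"""Per-axis additive harmonization across individuals and attachments.

Re-attaching a head harness shifts the accelerometer's orientation
slightly, so the same posture reads different raw values on different
deployments. The correction is additive per semantic axis: the mean raw
value during the quiet-standing reference micro-behavior ("standing
without any movement", code STA_STILL in the ethogram) is computed per
individual, and every sample of an individual is shifted by the difference
between the reference individual's means and its own. Harmonized values
are kept as real numbers and never re-clipped into the integer encoding
range — clipping would distort the moment features.

This deliberately stops short of full orientation re-estimation (rotation
matrices); only the additive per-axis correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .device_models import Burst, SEMANTIC_AXES
from .preprocess import LabeledDataset


@dataclass(frozen=True)
class CalibrationOffsets:
    """Per-axis reference means (raw counts) during quiet standing."""

    individual: str
    device: str
    means: Mapping[str, float]  # semantic axis -> mean count
    n_reference_bursts: int = 1

    def __post_init__(self) -> None:
        if set(self.means) != set(SEMANTIC_AXES):
            raise ValueError("means must cover sway, surge, heave")
        if not all(np.isfinite(v) for v in self.means.values()):
            raise ValueError("offsets must be finite")


def reference_offsets(
    dataset: LabeledDataset, reference_code: str = "STA_STILL"
) -> dict[str, CalibrationOffsets]:
    """Per-individual, per-axis mean over all quiet-standing samples.

    The mean pools every sample of every reference burst (so unequal-length
    continuous sections are weighted by their length).
    """
    by_indiv: dict[str, list[Burst]] = {}
    for b in dataset.bursts:
        if b.label == reference_code:
            by_indiv.setdefault(b.individual, []).append(b)
    if not by_indiv:
        raise ValueError(
            f"no bursts labeled {reference_code!r}: supply reference intervals "
            f"for the quiet-standing micro-behavior in the ethogram"
        )
    out = {}
    for indiv, bursts in by_indiv.items():
        means = {
            a: float(np.concatenate([b.axis(a) for b in bursts]).mean())
            for a in SEMANTIC_AXES
        }
        out[indiv] = CalibrationOffsets(
            individual=indiv,
            device=bursts[0].device,
            means=means,
            n_reference_bursts=len(bursts),
        )
    return out


def harmonize(
    dataset: LabeledDataset,
    offsets: Mapping[str, CalibrationOffsets],
    reference: CalibrationOffsets,
) -> LabeledDataset:
    """Shift every individual's samples onto the reference's standing means.

    Each value v on axis a of individual i becomes
    ``v + (reference.means[a] - offsets[i].means[a])``. Labels are
    untouched; individuals without offsets are an error (silent
    pass-through would defeat the point). Idempotent: harmonizing an
    already-harmonized dataset against the same reference is the identity,
    because the reference-behavior means then equal the reference's.
    """
    shifted = []
    for b in dataset.bursts:
        if b.individual not in offsets:
            raise ValueError(f"no calibration offsets for {b.individual!r}")
        off = offsets[b.individual]
        if off.device != b.device or reference.device != b.device:
            raise ValueError(
                f"device mismatch: burst on {b.device!r}, offsets on "
                f"{off.device!r}/{reference.device!r}"
            )
        delta = {a: reference.means[a] - off.means[a] for a in SEMANTIC_AXES}
        shifted.append(
            Burst(
                individual=b.individual,
                device=b.device,
                start_time=b.start_time,
                samples_sway=b.samples_sway + delta["sway"],
                samples_surge=b.samples_surge + delta["surge"],
                samples_heave=b.samples_heave + delta["heave"],
                label=b.label,
            )
        )
    out = LabeledDataset(bursts=shifted, provenance=dict(dataset.provenance))
    out.provenance["harmonize"] = {
        "reference_individual": reference.individual,
        "reference_means": dict(reference.means),
    }
    return out
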
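"""Per-burst predictor variables for the behavior classifier.

For each window the following are computed per semantic axis: arithmetic
mean (mn), sample standard deviation (sd, n-1 denominator), inverse
coefficient of variation (icv = mean/sd), excess kurtosis and skewness
(moment estimators, no small-sample bias correction), and — for
fixed-length burst-mode windows only — the weighted mean frequency (wm) of
the discrete Fourier magnitude spectrum of the mean-removed signal (DC
excluded). Three combined predictors complete the vector: q, the
burst-mean per-sample Euclidean norm of the three axes, and the static
pitch and roll angles derived from the per-axis means under the usual
static-gravity convention:

    pitch = atan2(-mean_surge, sqrt(mean_sway^2 + mean_heave^2))
    roll  = atan2(mean_sway, mean_heave)

Orientation features (q, pitch, roll) are computed after subtracting the
device's zero-g count offset (burst device: 2048; continuous device: 0),
so both devices share one formula on a common physical origin. Angles are
radians internally.

Burst-mode vectors have exactly 21 entries; continuous-mode vectors 18
(variable section lengths make wm a proxy for length, so it is dropped).

Degenerate windows (zero spectral mass or zero sd) yield sentinel values
rather than NaN/inf so tree ensembles can still split on them: icv becomes
+/-1e9 signed by the mean, skewness/kurtosis 0, wm 0 Hz (outside the valid
(0, Nyquist] band).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .device_models import Burst, DeviceSpec
from .preprocess import LabeledDataset

#: sentinel magnitude for the inverse coefficient of variation at zero sd
ICV_SENTINEL = 1e9
#: sentinel for the weighted mean frequency of a flat spectrum
WM_SENTINEL = 0.0

MIN_SAMPLES = 5

_AXES = ("sway", "surge", "heave")

BURST_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{axis}"
    for stat in ("mn", "sd", "icv", "wm", "kurt", "skew")
    for axis in _AXES
) + ("q", "pitch", "roll")

CONTINUOUS_FEATURE_NAMES: tuple[str, ...] = tuple(
    n for n in BURST_FEATURE_NAMES if not n.startswith("wm_")
)

assert len(BURST_FEATURE_NAMES) == 21
assert len(CONTINUOUS_FEATURE_NAMES) == 18


def axis_moments(values: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mean, sd, icv, excess kurtosis, skewness) of one axis sequence."""
    values = np.asarray(values, dtype=float)
    if len(values) < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} samples, got {len(values)}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        icv = ICV_SENTINEL if mean >= 0 else -ICV_SENTINEL
        return mean, 0.0, icv, 0.0, 0.0
    icv = mean / sd
    kurt = float(stats.kurtosis(values, fisher=True, bias=True))
    skew = float(stats.skew(values, bias=True))
    return mean, sd, icv, kurt, skew


def weighted_mean_frequency(values: np.ndarray, sample_rate: float) -> float:
    """Amplitude-weighted mean frequency of the positive-frequency spectrum.

    The sequence is mean-removed, the DC bin excluded, and magnitudes (not
    powers) weight the bin frequencies. A flat (all-zero) spectrum returns
    the sentinel.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} samples, got {len(values)}")
    centered = values - values.mean()
    amplitude = np.abs(np.fft.rfft(centered))[1:]
    freqs = np.fft.rfftfreq(len(values), d=1.0 / sample_rate)[1:]
    total = amplitude.sum()
    if total <= 0.0:
        return WM_SENTINEL
    return float((freqs * amplitude).sum() / total)


def combined_features(
    sway: np.ndarray, surge: np.ndarray, heave: np.ndarray
) -> tuple[float, float, float]:
    """(q, pitch, roll) from the three zero-g-referenced axis sequences."""
    sway = np.asarray(sway, dtype=float)
    surge = np.asarray(surge, dtype=float)
    heave = np.asarray(heave, dtype=float)
    if not (len(sway) == len(surge) == len(heave)) or len(sway) < MIN_SAMPLES:
        raise ValueError("axes must share a length >= 5")
    q = float(np.sqrt(sway**2 + surge**2 + heave**2).mean())
    ms, mu, mh = sway.mean(), surge.mean(), heave.mean()
    pitch = float(np.arctan2(-mu, np.hypot(ms, mh)))
    roll = float(np.arctan2(ms, mh))
    return q, pitch, roll


def feature_vector(
    burst: Burst,
    mode: str,
    sample_rate: Optional[float] = None,
    zero_g_count: float = 0.0,
) -> dict[str, float]:
    """Assemble the named 21 (burst) or 18 (continuous) predictors.

    ``zero_g_count`` is subtracted before q/pitch/roll only; the moment
    features stay on the raw (or harmonized) count scale.
    """
    if mode not in ("burst", "continuous"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "burst" and sample_rate is None:
        raise ValueError("burst mode requires sample_rate for wm")
    out: dict[str, float] = {}
    for axis in _AXES:
        values = burst.axis(axis)
        mn, sd, icv, kurt, skew = axis_moments(values)
        out[f"mn_{axis}"] = mn
        out[f"sd_{axis}"] = sd
        out[f"icv_{axis}"] = icv
        if mode == "burst":
            out[f"wm_{axis}"] = weighted_mean_frequency(values, sample_rate)
        out[f"kurt_{axis}"] = kurt
        out[f"skew_{axis}"] = skew
    q, pitch, roll = combined_features(
        burst.samples_sway - zero_g_count,
        burst.samples_surge - zero_g_count,
        burst.samples_heave - zero_g_count,
    )
    out["q"], out["pitch"], out["roll"] = q, pitch, roll
    names = BURST_FEATURE_NAMES if mode == "burst" else CONTINUOUS_FEATURE_NAMES
    return {name: out[name] for name in names}


def feature_table(dataset: LabeledDataset, spec: DeviceSpec) -> pd.DataFrame:
    """One row per burst: individual, burst_id, label, then the predictors."""
    rows = []
    for i, b in enumerate(dataset.bursts):
        vec = feature_vector(
            b,
            mode=spec.mode,
            sample_rate=spec.sample_rate,
            zero_g_count=spec.zero_g_count,
        )
        row = {
            "individual": b.individual,
            "burst_id": f"{b.individual}:{b.start_time:.3f}",
            "label": b.label,
        }
        row.update(vec)
        rows.append(row)
    names = (
        BURST_FEATURE_NAMES if spec.mode == "burst" else CONTINUOUS_FEATURE_NAMES
    )
    return pd.DataFrame(rows, columns=["individual", "burst_id", "label", *names])
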
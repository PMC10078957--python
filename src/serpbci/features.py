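"""Feature extraction (F1, F2) and amplitude-threshold selection (FS1, FS2).

Two base feature methods on the downsampled sERPs of a single channel:

* **F1** — concatenation of the i-th consecutive pair of sERPs,
  [sERP(.SD) || sERP(.SV)], 120 features; class AD uses (ADSD, ADSV),
  class AV uses (AVSD, AVSV).  D-stimulation samples come first.
* **F2** — the i-th 60-sample difference wave, diffsERP(AD) or
  diffsERP(AV).

Selection rectifies the between-condition grand difference wave
diffsERP(ADAV) and sweeps an amplitude threshold from 0 upward in 0.1 uV
steps; each threshold keeps the sample indexes whose |ADAV| is >= the
threshold, giving nested, shrinking index sets.  FS1/FS2 are F1/F2
restricted to the selected indexes (FS1 applies the index set to both
halves of the concatenation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .erp import DiffWaveform, SERP_SAMPLES

F1_LENGTH = 2 * SERP_SAMPLES  # 120
F2_LENGTH = SERP_SAMPLES  # 60
THRESHOLD_INCREMENT_UV = 0.1

__all__ = [
    "F1_LENGTH",
    "F2_LENGTH",
    "THRESHOLD_INCREMENT_UV",
    "FeatureVector",
    "SelectionSweep",
    "EmptySelectionError",
    "extract_f1",
    "extract_f2",
    "select_indexes",
    "sweep_selection",
    "apply_selection",
]


class EmptySelectionError(ValueError):
    """A threshold selected no samples; caller must fall back to threshold 0."""


@dataclass
class FeatureVector:
    values: np.ndarray
    label: str  # "AD" | "AV"
    method: str  # "F1" | "F2" | "FS1" | "FS2"
    channel: str = ""
    selected_indexes: tuple[int, ...] | None = None
    threshold_uV: float | None = None


@dataclass
class SelectionSweep:
    """Threshold grid and the per-threshold selected index sets."""

    thresholds: np.ndarray  # 0, 0.1, 0.2, ...
    index_sets: list[tuple[int, ...]]  # one per threshold, nested non-increasing


def extract_f1(
    group_index: int, serps: dict[str, np.ndarray], label: str, channel: str = ""
) -> FeatureVector:
    """i-th [sERP(.SD) || sERP(.SV)] concatenation for one class."""
    sd, sv = (("ADSD", "ADSV") if label == "AD" else ("AVSD", "AVSV"))
    if not (0 <= group_index < len(serps[sd])) or not (0 <= group_index < len(serps[sv])):
        raise IndexError(f"group index {group_index} out of range")
    values = np.concatenate([serps[sd][group_index], serps[sv][group_index]])
    return FeatureVector(values, label, "F1", channel)


def extract_f2(
    group_index: int, diffs: np.ndarray, label: str, channel: str = ""
) -> FeatureVector:
    """i-th 60-sample difference wave for one class (rows of ``diffs``)."""
    if not (0 <= group_index < len(diffs)):
        raise IndexError(f"group index {group_index} out of range")
    return FeatureVector(diffs[group_index].copy(), label, "F2", channel)


def select_indexes(adav: DiffWaveform | np.ndarray, threshold_uV: float) -> tuple[int, ...]:
    """Ascending indexes where the rectified ADAV wave is >= threshold."""
    if threshold_uV < 0:
        raise ValueError("threshold must be >= 0")
    values = adav.values if isinstance(adav, DiffWaveform) else np.asarray(adav)
    return tuple(int(i) for i in np.nonzero(np.abs(values) >= threshold_uV)[0])


def sweep_selection(
    adav: DiffWaveform | np.ndarray, increment: float = THRESHOLD_INCREMENT_UV
) -> SelectionSweep:
    """Threshold sweep 0, increment, 2*increment, ... up to (exclusive) the
    first threshold selecting nothing.

    Threshold 0 always selects all indexes (rectified values are >= 0), so
    the sweep contains at least one usable threshold.
    """
    if increment <= 0:
        raise ValueError("increment must be > 0")
    thresholds: list[float] = []
    sets: list[tuple[int, ...]] = []
    k = 0
    while True:
        thr = k * increment
        idx = select_indexes(adav, thr)
        if not idx:
            break
        thresholds.append(thr)
        sets.append(idx)
        k += 1
    return SelectionSweep(np.array(thresholds), sets)


def apply_selection(
    method: str,
    group_index: int,
    serps: dict[str, np.ndarray] | None,
    diffs: np.ndarray | None,
    indexes: tuple[int, ...],
    label: str,
    channel: str = "",
    threshold_uV: float | None = None,
) -> FeatureVector:
    """FS1/FS2 vector at the selected indexes.

    FS1 = [sERP(.SD)[idx] || sERP(.SV)[idx]] (length 2 * |idx|);
    FS2 = diff[idx] (length |idx|).  With all 60 indexes selected these
    reduce exactly to F1/F2.
    """
    if not indexes:
        raise EmptySelectionError("empty index set; fall back to threshold 0")
    idx = np.asarray(indexes, dtype=np.intp)
    if method == "FS1":
        if serps is None:
            raise ValueError("FS1 needs the per-cluster sERP matrices")
        base = extract_f1(group_index, serps, label, channel)
        sd_half = base.values[:SERP_SAMPLES][idx]
        sv_half = base.values[SERP_SAMPLES:][idx]
        values = np.concatenate([sd_half, sv_half])
    elif method == "FS2":
        if diffs is None:
            raise ValueError("FS2 needs the per-class difference-wave matrix")
        values = extract_f2(group_index, diffs, label, channel).values[idx]
    else:
        raise ValueError(f"unknown selection method {method!r}")
    return FeatureVector(values, label, method, channel, tuple(indexes), threshold_uV)
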
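"""Front-end preprocessing of continuous EEG into clean single-trial epochs.

Pipeline order is fixed: bandpass filter the continuous data, segment into
500 ms stimulus-locked epochs (100 ms baseline + 400 ms post-stimulus),
subtract each channel's baseline mean, then reject epochs whose absolute
amplitude crosses 50 uV on any scalp channel or 80 uV on Fp1 (blink
artifacts).  Epoch order always preserves acquisition order because the
downstream averaging is over *consecutive* trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .protocol import StimulusEvent
from .synth import (
    EOG_CHANNEL,
    EPOCH_SAMPLES,
    POST_SAMPLES,
    PRE_SAMPLES,
    SCALP_CHANNELS,
    Recording,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Epoch",
    "EpochSet",
    "bandpass",
    "epoch",
    "baseline_correct",
    "reject_artifacts",
]


@dataclass
class Epoch:
    """One 500 ms stimulus-locked trial: 6 x 600 samples, stimulus at index 120."""

    data: np.ndarray  # channels x EPOCH_SAMPLES, uV
    event: StimulusEvent
    kept: bool = True
    rejection_reason: str | None = None  # "EEG" | "EOG" | None


@dataclass
class EpochSet:
    """Ordered epochs plus processing provenance."""

    epochs: list[Epoch]
    channel_labels: tuple[str, ...]
    rate_hz: float
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def kept(self) -> list[Epoch]:
        return [e for e in self.epochs if e.kept]

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


def bandpass(
    recording: Recording,
    low_hz: float = 0.1,
    high_hz: float = 25.0,
    order: int = 2,
    zero_phase: bool = True,
) -> Recording:
    """Butterworth bandpass of every channel (2nd order, 0.1-25 Hz defaults).

    Zero-phase (forward-backward) by default for offline analysis; set
    ``zero_phase=False`` for a causal filter when replaying pseudo-online.
    """
    nyq = recording.rate_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"need 0 < {low_hz} < {high_hz} < Nyquist {nyq}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=recording.rate_hz, output="sos")
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    else:
        filtered = signal.sosfilt(sos, recording.data, axis=1)
    return Recording(
        np.ascontiguousarray(filtered),
        recording.rate_hz,
        recording.channel_labels,
        recording.events,
    )


def epoch(recording: Recording) -> EpochSet:
    """Cut one epoch per event: half-open window [onset-120, onset+480).

    Events too close to a recording edge are skipped with a warning.
    """
    epochs: list[Epoch] = []
    skipped = 0
    for ev in recording.events.events:
        start = ev.onset_sample - PRE_SAMPLES
        stop = ev.onset_sample + POST_SAMPLES
        if start < 0 or stop > recording.n_samples:
            skipped += 1
            logger.warning(
                "event at sample %d too close to recording edge; skipped", ev.onset_sample
            )
            continue
        epochs.append(Epoch(recording.data[:, start:stop].copy(), ev))
    if skipped:
        logger.warning("skipped %d edge events of %d", skipped, len(recording.events.events))
    return EpochSet(
        epochs,
        recording.channel_labels,
        recording.rate_hz,
        provenance={"skipped_edge_events": skipped},
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each channel's mean over the 100 ms baseline from the whole epoch."""
    out = []
    for ep in epochs.epochs:
        baseline = ep.data[:, :PRE_SAMPLES].mean(axis=1, keepdims=True)
        out.append(replace(ep, data=ep.data - baseline))
    prov = dict(epochs.provenance, baseline_corrected=True)
    return EpochSet(out, epochs.channel_labels, epochs.rate_hz, prov)


def reject_artifacts(
    epochs: EpochSet, eeg_thr_uV: float = 50.0, eog_thr_uV: float = 80.0
) -> EpochSet:
    """Dual-threshold artifact rejection over the full 500 ms epoch.

    An epoch is rejected iff its absolute amplitude strictly exceeds
    ``eeg_thr_uV`` on any scalp channel (reason "EEG") or ``eog_thr_uV`` on
    Fp1 (reason "EOG"); boundary-equal values are kept.  Idempotent and
    order-independent.
    """
    scalp_idx = [epochs.channel_index(c) for c in SCALP_CHANNELS if c in epochs.channel_labels]
    eog_idx = (
        epochs.channel_index(EOG_CHANNEL) if EOG_CHANNEL in epochs.channel_labels else None
    )
    out = []
    n_eeg = n_eog = 0
    for ep in epochs.epochs:
        reason = None
        if scalp_idx and np.abs(ep.data[scalp_idx]).max() > eeg_thr_uV:
            reason = "EEG"
            n_eeg += 1
        elif eog_idx is not None and np.abs(ep.data[eog_idx]).max() > eog_thr_uV:
            reason = "EOG"
            n_eog += 1
        out.append(replace(ep, kept=reason is None, rejection_reason=reason))
    prov = dict(
        epochs.provenance,
        eeg_thr_uV=eeg_thr_uV,
        eog_thr_uV=eog_thr_uV,
        rejected_eeg=n_eeg,
        rejected_eog=n_eog,
    )
    logger.info("artifact rejection: %d EEG, %d EOG of %d epochs", n_eeg, n_eog, len(out))
    return EpochSet(out, epochs.channel_labels, epochs.rate_hz, prov)
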
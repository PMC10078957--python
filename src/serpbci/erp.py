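"""Four-cluster sERP formation: consecutive averaging, balancing, difference waves.

Kept single-trial epochs are partitioned by (attended site, stimulated
site) into the four clusters ADSD, ADSV, AVSD, AVSV.  Within each cluster,
consecutive non-overlapping groups of 3, 5 or 10 trials are averaged into
sERP waveforms (400 ms post-stimulus, 480 samples), decimated by 8 to 60
samples (150 Hz), and combined into difference waves:

    diffsERP(AD)   = sERP(ADSD) - sERP(ADSV)
    diffsERP(AV)   = sERP(AVSD) - sERP(AVSV)
    diffsERP(ADAV) = mean diffsERP(AD) - mean diffsERP(AV)

Clusters are balanced before grouping by dropping the *last* trials of
larger clusters so every cluster yields the same number of groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Epoch, EpochSet
from .protocol import Location
from .synth import POST_SAMPLES, PRE_SAMPLES

CLUSTER_KEYS = ("ADSD", "ADSV", "AVSD", "AVSV")

#: cluster key -> (attended_location, stimulated location)
CLUSTER_DEF = {
    "ADSD": (Location.D, Location.D),
    "ADSV": (Location.D, Location.V),
    "AVSD": (Location.V, Location.D),
    "AVSV": (Location.V, Location.V),
}

DOWNSAMPLE_FACTOR = 8
SERP_SAMPLES = POST_SAMPLES // DOWNSAMPLE_FACTOR  # 60 at 150 Hz

__all__ = [
    "CLUSTER_KEYS",
    "CLUSTER_DEF",
    "DOWNSAMPLE_FACTOR",
    "SERP_SAMPLES",
    "ClusterSet",
    "SerpWaveform",
    "DiffWaveform",
    "InsufficientDataError",
    "assign_clusters",
    "balance_and_group",
    "average_group",
    "downsample",
    "diff_serp",
    "grand_diff",
    "serp_matrix",
]


class InsufficientDataError(ValueError):
    """A cluster is too small for the requested averaging."""


@dataclass
class ClusterSet:
    """Kept epochs partitioned into the four attention x site clusters."""

    clusters: dict[str, list[Epoch]]
    channel_labels: tuple[str, ...]

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.clusters.items()}


@dataclass
class SerpWaveform:
    """One averaged sERP: a single channel's post-stimulus waveform."""

    channel: str
    values: np.ndarray  # 480 samples, or 60 after downsampling
    n_avg: int
    cluster: str
    index: int  # position in the consecutive-group sequence
    rate_hz: float = 1200.0


@dataclass
class DiffWaveform:
    """Difference wave on the decimated 60-sample grid."""

    channel: str
    values: np.ndarray
    condition: str  # "AD" | "AV" | "ADAV"
    n_avg: int
    index: int = -1


def assign_clusters(epochs: EpochSet) -> ClusterSet:
    """Partition kept epochs by (attended, stimulated), acquisition order preserved."""
    clusters: dict[str, list[Epoch]] = {k: [] for k in CLUSTER_KEYS}
    for ep in epochs.kept:
        for key, (att, stim) in CLUSTER_DEF.items():
            if ep.event.attended_location is att and ep.event.location is stim:
                clusters[key].append(ep)
                break
    return ClusterSet(clusters, epochs.channel_labels)


def balance_and_group(clusters: ClusterSet, n_avg: int) -> dict[str, list[list[Epoch]]]:
    """Equalize cluster sizes and cut consecutive non-overlapping groups.

    With m = min over clusters of floor(size / n_avg), each cluster is
    truncated from the end to m * n_avg trials and split into m consecutive
    groups of n_avg.  Raises :class:`InsufficientDataError` if any cluster
    holds fewer than n_avg trials.
    """
    if n_avg < 1:
        raise ValueError("n_avg must be >= 1")
    for key, eps in clusters.clusters.items():
        if len(eps) < n_avg:
            raise InsufficientDataError(
                f"cluster {key} has {len(eps)} trials, fewer than n_avg={n_avg}"
            )
    m = min(len(eps) // n_avg for eps in clusters.clusters.values())
    grouped: dict[str, list[list[Epoch]]] = {}
    for key, eps in clusters.clusters.items():
        kept = eps[: m * n_avg]
        grouped[key] = [kept[i * n_avg : (i + 1) * n_avg] for i in range(m)]
    return grouped


def average_group(
    group: list[Epoch], channel: str, channel_labels: tuple[str, ...],
    cluster: str = "", index: int = -1,
) -> SerpWaveform:
    """Pointwise mean of the 480-sample post-stimulus windows for one channel."""
    ci = channel_labels.index(channel)
    stack = np.stack([ep.data[ci, PRE_SAMPLES : PRE_SAMPLES + POST_SAMPLES] for ep in group])
    return SerpWaveform(channel, stack.mean(axis=0), len(group), cluster, index)


def downsample(w: SerpWaveform, factor: int = DOWNSAMPLE_FACTOR) -> SerpWaveform:
    """Decimate by plain sample selection (every ``factor``-th sample from 0).

    Safe at the default factor 8 because the 25 Hz low-pass leaves
    negligible energy above the decimated 75 Hz Nyquist.
    """
    n = len(w.values)
    if n % factor != 0:
        raise ValueError(f"waveform length {n} not divisible by factor {factor}")
    return SerpWaveform(
        w.channel, w.values[::factor].copy(), w.n_avg, w.cluster, w.index,
        rate_hz=w.rate_hz / factor,
    )


def diff_serp(w_D: SerpWaveform, w_V: SerpWaveform) -> DiffWaveform:
    """D-stim minus V-stim sERP within one attention condition (AD or AV)."""
    if w_D.channel != w_V.channel:
        raise ValueError(f"channel mismatch: {w_D.channel} vs {w_V.channel}")
    if len(w_D.values) != len(w_V.values):
        raise ValueError("waveform length mismatch")
    cond_D = w_D.cluster[:2] if w_D.cluster else ""
    cond_V = w_V.cluster[:2] if w_V.cluster else ""
    if cond_D and cond_V and cond_D != cond_V:
        raise ValueError(f"condition mismatch: {w_D.cluster} vs {w_V.cluster}")
    return DiffWaveform(
        w_D.channel, w_D.values - w_V.values, cond_D or "AD", w_D.n_avg, w_D.index
    )


def grand_diff(diffs_AD: list[DiffWaveform], diffs_AV: list[DiffWaveform]) -> DiffWaveform:
    """Between-condition difference of the class-mean difference waves (ADAV)."""
    if not diffs_AD or not diffs_AV:
        raise ValueError("need at least one difference wave per condition")
    mean_ad = np.mean([d.values for d in diffs_AD], axis=0)
    mean_av = np.mean([d.values for d in diffs_AV], axis=0)
    return DiffWaveform(
        diffs_AD[0].channel, mean_ad - mean_av, "ADAV", diffs_AD[0].n_avg
    )


def serp_matrix(
    grouped: dict[str, list[list[Epoch]]],
    channel: str,
    channel_labels: tuple[str, ...],
    factor: int = DOWNSAMPLE_FACTOR,
) -> dict[str, np.ndarray]:
    """Averaged + decimated sERPs for one channel: cluster -> (m, 60) array.

    Convenience used by the feature/classification stages: row i of each
    cluster array is the i-th consecutive group's downsampled sERP.
    """
    out = {}
    for key, groups in grouped.items():
        rows = [
            downsample(
                average_group(g, channel, channel_labels, cluster=key, index=i), factor
            ).values
            for i, g in enumerate(groups)
        ]
        out[key] = np.stack(rows) if rows else np.empty((0, POST_SAMPLES // factor))
    return out
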
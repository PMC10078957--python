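"""Recording I/O, run configuration, and the end-to-end pipeline.

Recordings travel as HDF5 (``/data`` channels x samples in uV, with rate
and channel-label attributes) or delimited text (TSV, one column per
channel); EDF files can additionally be *read* when mne is installed.
Event tables are TSV throughout.  ``run_pipeline`` executes the full
offline analysis — filter, epoch, baseline, reject, cluster, average,
feature extraction/selection, leave-one-out classification — for every
channel x method x n_avg x classifier combination in the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import erp, preprocess
from .classify import ChannelDataset, ClassifierSpec, CVResult, loo_crossval
from .preprocess import Epoch, EpochSet
from .protocol import Location, ProtocolConfig, StimulusEvent, StimulusSchedule, read_schedule_tsv
from .synth import CHANNELS, SCALP_CHANNELS, Recording

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_recording", "write_recording",
           "write_epochs", "read_epochs", "preprocess_recording",
           "run_pipeline", "build_channel_datasets",
           "datasets_from_epochs", "export_features", "results_frame"]


@dataclass
class RunConfig:
    """End-to-end pipeline settings; defaults are the published constants."""

    channels: tuple[str, ...] = SCALP_CHANNELS
    low_hz: float = 0.1
    high_hz: float = 25.0
    filter_order: int = 2
    zero_phase: bool = True
    eeg_thr_uV: float = 50.0
    eog_thr_uV: float = 80.0
    n_avg_set: tuple[int, ...] = (3, 5, 10)
    methods: tuple[str, ...] = ("F1", "F2", "FS1", "FS2")
    classifiers: tuple[str, ...] = ("SVM", "LDA")
    selection: str | float = "inner"
    downsample_factor: int = 8
    seed: int = 0


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as HDF5 (.h5/.hdf5) or TSV (anything else)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("data", data=recording.data)
            dset.attrs["rate_hz"] = recording.rate_hz
            dset.attrs["channel_labels"] = list(recording.channel_labels)
            dset.attrs["unit"] = "uV"
    else:
        pd.DataFrame(recording.data.T, columns=list(recording.channel_labels)).to_csv(
            path, sep="\t", index=False
        )


class RecordingFormatError(ValueError):
    pass


def read_recording(
    path: str | Path,
    events_path: str | Path | None = None,
    rate_hz: float = 1200.0,
    schedule: StimulusSchedule | None = None,
) -> Recording:
    """Read a recording from HDF5, TSV or EDF and join its event table.

    The 1,200 Hz rate is verified when the container stores one.  Events
    (from ``events_path`` TSV or a given schedule) are bounds-checked
    against the recording length.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            dset = f["data"]
            data = np.asarray(dset)
            rate = float(dset.attrs.get("rate_hz", rate_hz))
            labels = tuple(
                lab.decode() if isinstance(lab, bytes) else str(lab)
                for lab in dset.attrs.get("channel_labels", CHANNELS)
            )
    elif path.suffix.lower() == ".edf":
        import mne  # optional dependency

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        rate = float(raw.info["sfreq"])
        labels = tuple(raw.ch_names)
    else:
        df = pd.read_csv(path, sep="\t")
        data = df.to_numpy().T
        rate, labels = rate_hz, tuple(df.columns)

    if abs(rate - rate_hz) > 1e-6:
        raise RecordingFormatError(f"expected {rate_hz} Hz, file reports {rate} Hz")
    missing = [c for c in CHANNELS if c not in labels]
    if missing:
        raise RecordingFormatError(f"missing channels: {missing}")

    if schedule is None:
        if events_path is None:
            raise ValueError("need either events_path or a schedule")
        schedule = read_schedule_tsv(events_path)
    n = data.shape[1]
    for i, ev in enumerate(schedule.events):
        if ev.onset_sample + 480 > n:
            raise RecordingFormatError(
                f"event {i} (onset {ev.onset_sample}) extends past the recording end"
            )
    return Recording(np.asarray(data, float), rate_hz, labels, schedule)


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Persist an epoch set as HDF5: data cube, event table, kept flags."""
    ev = [e.event for e in epochs.epochs]
    with h5py.File(path, "w") as f:
        cube = f.create_dataset(
            "epochs", data=np.stack([e.data for e in epochs.epochs])
        )
        cube.attrs["channel_labels"] = list(epochs.channel_labels)
        cube.attrs["rate_hz"] = epochs.rate_hz
        cube.attrs["provenance"] = json.dumps(epochs.provenance)
        f.create_dataset("kept", data=np.array([e.kept for e in epochs.epochs]))
        f.create_dataset(
            "rejection_reason",
            data=np.array([e.rejection_reason or "" for e in epochs.epochs], dtype="S8"),
        )
        f.create_dataset("onset_sample", data=np.array([e.onset_sample for e in ev]))
        f.create_dataset("location", data=np.array([e.location.value for e in ev], dtype="S1"))
        f.create_dataset("block", data=np.array([e.block for e in ev]))
        f.create_dataset("sub_block", data=np.array([e.sub_block for e in ev]))
        f.create_dataset(
            "attended_location",
            data=np.array([e.attended_location.value for e in ev], dtype="S1"),
        )


def read_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        cube = f["epochs"]
        labels = tuple(
            lab.decode() if isinstance(lab, bytes) else str(lab)
            for lab in cube.attrs["channel_labels"]
        )
        rate = float(cube.attrs["rate_hz"])
        prov = json.loads(cube.attrs.get("provenance", "{}"))
        data = np.asarray(cube)
        kept = np.asarray(f["kept"])
        reasons = [r.decode() or None for r in np.asarray(f["rejection_reason"])]
        events = [
            StimulusEvent(
                int(o), Location(loc.decode()), int(b), int(sb), Location(att.decode())
            )
            for o, loc, b, sb, att in zip(
                np.asarray(f["onset_sample"]), np.asarray(f["location"]),
                np.asarray(f["block"]), np.asarray(f["sub_block"]),
                np.asarray(f["attended_location"]),
            )
        ]
    eps = [
        Epoch(data[i], events[i], bool(kept[i]), reasons[i]) for i in range(len(events))
    ]
    return EpochSet(eps, labels, rate, prov)


def is_epochs_file(path: str | Path) -> bool:
    path = Path(path)
    if path.suffix not in (".h5", ".hdf5"):
        return False
    with h5py.File(path, "r") as f:
        return "epochs" in f


def preprocess_recording(recording: Recording, config: RunConfig | None = None) -> EpochSet:
    """Filter -> epoch -> baseline -> reject with the configured constants."""
    config = config or RunConfig()
    filtered = preprocess.bandpass(
        recording, config.low_hz, config.high_hz, config.filter_order, config.zero_phase
    )
    epochs = preprocess.epoch(filtered)
    epochs = preprocess.baseline_correct(epochs)
    return preprocess.reject_artifacts(epochs, config.eeg_thr_uV, config.eog_thr_uV)


def build_channel_datasets(
    recording: Recording, config: RunConfig | None = None
) -> dict[int, dict[str, ChannelDataset]]:
    """Preprocess a recording into per-(n_avg, channel) grouped-sERP datasets."""
    config = config or RunConfig()
    return datasets_from_epochs(preprocess_recording(recording, config), config)


def datasets_from_epochs(
    epochs: EpochSet, config: RunConfig | None = None
) -> dict[int, dict[str, ChannelDataset]]:
    config = config or RunConfig()
    clusters = erp.assign_clusters(epochs)
    logger.info("cluster sizes after rejection: %s", clusters.counts())
    out: dict[int, dict[str, ChannelDataset]] = {}
    for n_avg in config.n_avg_set:
        grouped = erp.balance_and_group(clusters, n_avg)
        out[n_avg] = {}
        for ch in config.channels:
            serps = erp.serp_matrix(grouped, ch, epochs.channel_labels,
                                    config.downsample_factor)
            out[n_avg][ch] = ChannelDataset(ch, serps, n_avg)
    return out


def export_features(dataset: ChannelDataset, method: str, path: str | Path) -> None:
    """Write a base F1/F2 feature matrix as TSV: metadata columns then values."""
    X = dataset.base_features(method)
    y = dataset.labels()
    meta = pd.DataFrame(
        {"channel": dataset.channel, "method": method, "n_avg": dataset.n_avg,
         "label": y}
    )
    values = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
    pd.concat([meta, values], axis=1).to_csv(path, sep="\t", index=False)


def run_pipeline(recording: Recording, config: RunConfig | None = None) -> list[CVResult]:
    """Full offline analysis: one CVResult per channel x method x n_avg x classifier."""
    config = config or RunConfig()
    datasets = build_channel_datasets(recording, config)
    results: list[CVResult] = []
    for n_avg, per_channel in datasets.items():
        for ch, ds in per_channel.items():
            for method in config.methods:
                for kind in config.classifiers:
                    spec = ClassifierSpec(kind=kind, heuristic_seed=config.seed)
                    res = loo_crossval(ds, method, spec, selection=config.selection)
                    results.append(res)
                    logger.info(
                        "%s %s n_avg=%d %s: %.1f%%",
                        ch, method, n_avg, kind, res.accuracy_pct,
                    )
    return results


def results_frame(results: list[CVResult]) -> pd.DataFrame:
    """Tidy summary table (one row per CVResult) with confusion percentages."""
    return pd.DataFrame([r.to_record() for r in results])


def best_channel_summary(results: list[CVResult]) -> pd.DataFrame:
    """Best channel per method x n_avg x classifier, by accuracy."""
    df = results_frame(results)
    idx = df.groupby(["method", "n_avg", "classifier"], observed=True)[
        "accuracy_pct"
    ].idxmax()
    return df.loc[idx].reset_index(drop=True)


def write_results_json(results: list[CVResult], path: str | Path) -> None:
    records = [r.to_record() for r in results]
    Path(path).write_text(json.dumps({"schema": 1, "results": records}, indent=2))
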
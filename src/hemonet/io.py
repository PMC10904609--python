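"""File I/O: SNIRF recordings, event tables, feature matrices.

SNIRF is the HDF5-based standard container for fNIRS data; this module
reads and writes the subset the pipeline needs — continuous-wave intensity
(dataType 1) with a measurement list, probe wavelengths/positions, and stim
groups.  Events also round-trip through a plain 3-column TSV
(onset, duration, condition).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import (
    HemodynamicRecording,
    OpticalRecording,
    StimEvent,
    StimulusTimeline,
)
from .features import FeatureMatrix

__all__ = [
    "write_snirf", "read_snirf",
    "write_events_tsv", "read_events_tsv",
    "write_features_csv", "read_features_csv",
    "write_hemodynamics_csv",
]


def _str_ds(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(value))


def write_snirf(
    path, rec: OpticalRecording, timeline: StimulusTimeline | None = None
) -> None:
    """Write an intensity recording (and optional stimulus groups) to SNIRF."""
    with h5py.File(path, "w") as f:
        _str_ds(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        for k, v in (
            ("SubjectID", "synthetic"),
            ("MeasurementDate", "unknown"),
            ("MeasurementTime", "unknown"),
            ("LengthUnit", "cm"),
            ("TimeUnit", "s"),
            ("FrequencyUnit", "Hz"),
        ):
            _str_ds(meta, k, v)

        data = nirs.create_group("data1")
        C, W, T = rec.intensity.shape
        series = rec.intensity.reshape(C * W, T).T  # (T, nMeas)
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=rec.times)
        m = 1
        for c in range(C):
            for w in range(W):
                ml = data.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=c + 1)
                ml.create_dataset("detectorIndex", data=c + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
                m += 1

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths))
        # schematic linear montage at the configured separation
        src = np.array([[i * rec.source_detector_distance, 0.0, 0.0] for i in range(C)])
        det = src + np.array([rec.source_detector_distance, 0.0, 0.0])
        probe.create_dataset("sourcePos3D", data=src)
        probe.create_dataset("detectorPos3D", data=det)

        if timeline is not None:
            for i, cond in enumerate(timeline.conditions, start=1):
                evs = [e for e in timeline.events if e.condition == cond]
                stim = nirs.create_group(f"stim{i}")
                _str_ds(stim, "name", cond)
                stim.create_dataset(
                    "data",
                    data=np.array([[e.onset, e.duration, 1.0] for e in evs]),
                )


def read_snirf(path) -> tuple[OpticalRecording, StimulusTimeline | None]:
    """Read a SNIRF intensity recording written by :func:`write_snirf`
    (or any file using the same continuous-wave subset)."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"])  # (T, nMeas)
        time = np.asarray(data["time"])
        if time.size < 2:
            raise ValueError("SNIRF time vector too short")
        fs = 1.0 / float(np.median(np.diff(time)))

        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda s: int(s[len("measurementList"):]),
        )
        pairs, wl_idx = [], []
        for name in ml_names:
            ml = data[name]
            pairs.append((int(ml["sourceIndex"][()]), int(ml["detectorIndex"][()])))
            wl_idx.append(int(ml["wavelengthIndex"][()]) - 1)
        wavelengths = tuple(np.asarray(nirs["probe"]["wavelengths"]).tolist())

        chans = list(dict.fromkeys(pairs))
        C, W, T = len(chans), len(wavelengths), series.shape[0]
        intensity = np.empty((C, W, T))
        for m, (pair, w) in enumerate(zip(pairs, wl_idx)):
            intensity[chans.index(pair), w] = series[:, m]

        rec = OpticalRecording(
            intensity=intensity,
            sampling_rate=fs,
            wavelengths=wavelengths,
            channel_ids=tuple(f"S{s}-D{d}" for s, d in chans),
            time_offset=float(time[0]),
        )

        events = []
        total = float(time[-1])
        for k in sorted(k for k in nirs.keys() if k.startswith("stim")):
            stim = nirs[k]
            cond = stim["name"][()].decode() if isinstance(stim["name"][()], bytes) \
                else str(stim["name"][()])
            for onset, dur, _ in np.atleast_2d(np.asarray(stim["data"])):
                events.append(StimEvent(float(onset), float(dur), cond))
                total = max(total, float(onset + dur))
        timeline = None
        if events:
            events.sort(key=lambda e: e.onset)
            timeline = StimulusTimeline(tuple(events), total_duration=total,
                                        sampling_rate=fs)
        return rec, timeline


# ---------------------------------------------------------------------------
# events TSV
# ---------------------------------------------------------------------------

def write_events_tsv(path, timeline: StimulusTimeline) -> None:
    df = pd.DataFrame(
        [{"onset": e.onset, "duration": e.duration, "condition": e.condition}
         for e in timeline.events]
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(
    path, total_duration: float | None = None, sampling_rate: float = 3.9063
) -> StimulusTimeline:
    df = pd.read_csv(path, sep="\t")
    events = tuple(
        StimEvent(float(r.onset), float(r.duration), str(r.condition))
        for r in df.itertuples()
    )
    if total_duration is None:
        total_duration = max(e.onset + e.duration for e in events)
    return StimulusTimeline(events, total_duration=total_duration,
                            sampling_rate=sampling_rate)


# ---------------------------------------------------------------------------
# features / hemodynamics CSV
# ---------------------------------------------------------------------------

def write_features_csv(path, fm: FeatureMatrix) -> None:
    fm.to_frame().to_csv(path, index=False)


def read_features_csv(path) -> FeatureMatrix:
    return FeatureMatrix.from_frame(pd.read_csv(path))


def write_hemodynamics_csv(path, hb: HemodynamicRecording) -> None:
    """Long format: channel, chromophore, time_s, value (uM or z-units)."""
    t = hb.time_offset + np.arange(hb.n_samples) / hb.sampling_rate
    frames = []
    for chrom in ("hbo", "hbr", "hbt"):
        arr = hb.chromophore(chrom)
        for c, cid in enumerate(hb.channel_ids):
            frames.append(pd.DataFrame(
                {"channel": cid, "chromophore": chrom, "time_s": t, "value": arr[c]}
            ))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
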
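"""Event-locked epoching and feature-matrix assembly.

Each task block yields one epoch per (channel, chromophore) spanning 5 s
before onset to 15 s after (10 s task + 5 s post-task).  At the 3.9063 Hz
acquisition rate an epoch is represented by 77 samples.  Within-condition
epochs are averaged per channel and chromophore; each average is one
training example (a 1 x 77 vector) labelled with the finger condition, so a
balanced paradigm gives channels x chromophores x conditions rows per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from .containers import (
    CHROMOPHORES,
    VALID_CONDITIONS,
    HemodynamicRecording,
    StimulusTimeline,
)

__all__ = [
    "EpochSet",
    "EventAverageSet",
    "FeatureMatrix",
    "EPOCH_N_SAMPLES",
    "extract_epochs",
    "event_average",
    "build_feature_matrix",
    "standard_scale",
]

#: Epoch length in samples for the default (-5 s, +15 s) window at 3.9063 Hz.
EPOCH_N_SAMPLES: int = 77


def _epoch_length(t_pre: float, t_post: float, fs: float) -> int:
    # floor(span * fs) - 1 keeps the window strictly inside (-t_pre, t_post);
    # 77 samples at the defaults (20 s * 3.9063 Hz = 78.125)
    return int(np.floor((t_pre + t_post) * fs)) - 1


@dataclass
class EpochSet:
    """Stimulus-locked epochs: (trial, channel, chromophore, sample)."""

    epochs: np.ndarray
    conditions: tuple[str, ...]          # per trial, ordered by onset
    t_grid: np.ndarray                   # seconds relative to onset
    channel_ids: tuple[str, ...]
    chromophores: tuple[str, ...] = CHROMOPHORES

    def __post_init__(self) -> None:
        n_trials, n_ch, n_chrom, n_s = self.epochs.shape
        if len(self.conditions) != n_trials:
            raise ValueError("one condition label per trial required")
        if len(self.channel_ids) != n_ch or len(self.chromophores) != n_chrom:
            raise ValueError("axis labels do not match epoch array shape")
        if self.t_grid.shape != (n_s,):
            raise ValueError("t_grid must match the epoch sample axis")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]


@dataclass
class EventAverageSet:
    """Within-condition trial means: (channel, chromophore, condition, sample)."""

    averages: np.ndarray
    conditions: tuple[str, ...]
    t_grid: np.ndarray
    channel_ids: tuple[str, ...]
    chromophores: tuple[str, ...] = CHROMOPHORES
    run_id: str = "run0"


@dataclass
class FeatureMatrix:
    """N x T event-average design matrix with finger labels.

    ``X[i]`` is one channel's event average (77 samples by default) and
    ``y[i]`` its condition; ``meta`` records run, channel, chromophore and
    condition per row.
    """

    X: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (rows x time samples)")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        bad = set(np.unique(self.y)) - VALID_CONDITIONS
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if len(self.meta) not in (0, self.X.shape[0]):
            raise ValueError("meta must have one row per sample")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(np.unique(self.y)))

    def to_frame(self) -> pd.DataFrame:
        cols = {f"f{i:03d}": self.X[:, i] for i in range(self.X.shape[1])}
        df = pd.DataFrame(cols)
        df["label"] = self.y
        if len(self.meta):
            df = pd.concat([self.meta.reset_index(drop=True), df], axis=1)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
        meta_cols = [c for c in df.columns if c not in fcols and c != "label"]
        return cls(
            X=df[fcols].to_numpy(float),
            y=df["label"].to_numpy(),
            meta=df[meta_cols].copy() if meta_cols else pd.DataFrame(),
        )


def extract_epochs(
    hb: HemodynamicRecording,
    timeline: StimulusTimeline,
    t_pre: float = 5.0,
    t_post: float = 15.0,
    n_samples: int | None = None,
) -> EpochSet:
    """Cut one epoch per task event per (channel, chromophore).

    The epoch starts at sample ceil(-t_pre * fs) relative to the onset
    sample and spans ``n_samples`` samples (77 at the defaults, matching the
    feature dimensionality used throughout).  Events whose epoch would
    exceed the recording raise, naming the event.
    """
    if t_pre < 0 or t_post <= 0:
        raise ValueError("need t_pre >= 0 and t_post > 0")
    fs = hb.sampling_rate
    if n_samples is None:
        n_samples = _epoch_length(t_pre, t_post, fs)
    if n_samples < 1:
        raise ValueError("epoch window too short for the sampling rate")
    k_start_rel = int(np.ceil(-t_pre * fs))
    events = timeline.task_events
    if not events:
        raise ValueError("timeline has no task events")

    data = np.stack([hb.dHbO, hb.dHbR, hb.dHbT], axis=1)  # (C, 3, T)
    epochs = np.empty((len(events), hb.n_channels, len(CHROMOPHORES), n_samples))
    for i, ev in enumerate(events):
        onset_idx = int(np.round((ev.onset - hb.time_offset) * fs))
        k0 = onset_idx + k_start_rel
        k1 = k0 + n_samples
        if k0 < 0 or k1 > hb.n_samples:
            raise ValueError(
                f"epoch for event {i} ({ev.condition!r} at {ev.onset} s) "
                f"exceeds the recording (samples [{k0}, {k1}) of {hb.n_samples})"
            )
        epochs[i] = data[:, :, k0:k1]

    t_grid = (k_start_rel + np.arange(n_samples)) / fs
    return EpochSet(
        epochs=epochs,
        conditions=tuple(e.condition for e in events),
        t_grid=t_grid,
        channel_ids=hb.channel_ids,
        chromophores=CHROMOPHORES,
    )


def event_average(epochs: EpochSet, run_id: str = "run0") -> EventAverageSet:
    """Elementwise mean across trials within each condition."""
    conds = []
    for c in epochs.conditions:
        if c not in conds:
            conds.append(c)
    out = np.empty(
        (len(epochs.channel_ids), len(epochs.chromophores), len(conds),
         epochs.epochs.shape[-1])
    )
    for j, cond in enumerate(conds):
        mask = np.array([c == cond for c in epochs.conditions])
        if not mask.any():
            raise ValueError(f"no epochs for condition {cond!r}")
        out[:, :, j, :] = epochs.epochs[mask].mean(axis=0)
    return EventAverageSet(
        averages=out,
        conditions=tuple(conds),
        t_grid=epochs.t_grid,
        channel_ids=epochs.channel_ids,
        chromophores=epochs.chromophores,
        run_id=run_id,
    )


def build_feature_matrix(
    averages: "EventAverageSet | list[EventAverageSet]",
    include_hbt: bool = True,
) -> FeatureMatrix:
    """Stack event averages into a labelled design matrix.

    One row per (run, channel, chromophore, condition); the label is the
    condition.  dHbT rows are included by default and can be dropped.
    """
    sets = [averages] if isinstance(averages, EventAverageSet) else list(averages)
    if not sets:
        raise ValueError("no average sets given")
    n_t = sets[0].averages.shape[-1]
    rows, labels, meta = [], [], []
    for s in sets:
        if s.averages.shape[-1] != n_t:
            raise ValueError("average sets have mixed vector lengths")
        for ci, ch in enumerate(s.channel_ids):
            for mi, chrom in enumerate(s.chromophores):
                if chrom == "hbt" and not include_hbt:
                    continue
                for ki, cond in enumerate(s.conditions):
                    rows.append(s.averages[ci, mi, ki])
                    labels.append(cond)
                    meta.append(
                        {"run": s.run_id, "channel": ch,
                         "chromophore": chrom, "condition": cond}
                    )
    return FeatureMatrix(
        X=np.array(rows), y=np.array(labels), meta=pd.DataFrame(meta)
    )


def standard_scale(
    X_train: np.ndarray, X_apply: np.ndarray | None = None
) -> tuple[np.ndarray, StandardScaler]:
    """Column-wise standardisation with statistics learned on the training
    split only.  Returns (scaled apply-set, fitted scaler)."""
    X_train = np.asarray(X_train, dtype=float)
    if np.any(X_train.std(axis=0) == 0):
        raise ValueError("training matrix has zero-variance columns")
    scaler = StandardScaler().fit(X_train)
    target = X_train if X_apply is None else np.asarray(X_apply, dtype=float)
    return scaler.transform(target), scaler
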
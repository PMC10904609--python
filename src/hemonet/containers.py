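"""Core data containers shared across the pipeline.

A *channel* is a source-detector pair; each channel is measured at two
near-infrared wavelengths (760 and 850 nm by default).  Raw data are
detected light intensities in arbitrary device units; after conversion
through the modified Beer-Lambert law they become chromophore
concentration changes (dHbO, dHbR, dHbT) in micromolar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: The five task conditions, in canonical presentation order.
FINGERS: tuple[str, ...] = ("thumb", "index", "middle", "ring", "little")

#: Label used for rest periods when they are modelled as explicit events.
REST: str = "rest"

#: Conditions a timeline may carry.
VALID_CONDITIONS: frozenset[str] = frozenset(FINGERS) | {REST}

#: Default acquisition rate of the continuous-wave instrument, Hz.
DEFAULT_SAMPLING_RATE: float = 3.9063

#: Default source-detector separation, cm.
DEFAULT_DISTANCE_CM: float = 3.0

#: Default wavelengths, nm.
DEFAULT_WAVELENGTHS: tuple[float, float] = (760.0, 850.0)

#: Chromophore order used throughout.
CHROMOPHORES: tuple[str, ...] = ("hbo", "hbr", "hbt")


@dataclass(frozen=True)
class StimEvent:
    """One block of the paradigm: ``condition`` shown at ``onset`` for ``duration`` seconds."""

    onset: float
    duration: float
    condition: str

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"event duration must be > 0, got {self.duration}")
        if self.onset < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset}")
        if self.condition not in VALID_CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class StimulusTimeline:
    """Ordered block-design stimulus timeline.

    ``events`` holds the task (and optionally rest) blocks sorted by onset;
    rest between blocks is implicit unless rest events are included.
    """

    events: tuple[StimEvent, ...]
    total_duration: float
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        onsets = [e.onset for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")
        for a, b in zip(self.events, self.events[1:]):
            if a.onset + a.duration > b.onset + 1e-9:
                raise ValueError(
                    f"events overlap: ({a.onset}, {a.duration}) and ({b.onset}, {b.duration})"
                )
        if self.events:
            last = self.events[-1]
            if self.total_duration + 1e-9 < last.onset + last.duration:
                raise ValueError("total_duration shorter than the last event")

    @property
    def task_events(self) -> tuple[StimEvent, ...]:
        return tuple(e for e in self.events if e.condition != REST)

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.events:
            if e.condition not in seen:
                seen.append(e.condition)
        return tuple(seen)

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.total_duration * self.sampling_rate)) + 1


def seconds_to_samples(t: float, sampling_rate: float) -> int:
    """Convert seconds to a sample index (0-based, round-half-even)."""
    return int(np.round(t * sampling_rate))


@dataclass
class OpticalRecording:
    """Raw dual-wavelength intensity recording.

    ``intensity`` has shape (n_channels, n_wavelengths, n_samples) and must be
    strictly positive (detected light).  ``time_offset`` is the acquisition
    time of sample 0 in seconds; truncation advances it so that stimulus
    onsets (absolute seconds) remain meaningful after cropping.
    """

    intensity: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS
    channel_ids: tuple[str, ...] = ()
    source_detector_distance: float = DEFAULT_DISTANCE_CM
    time_offset: float = 0.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (channels, wavelengths, samples)")
        if self.intensity.shape[1] != len(self.wavelengths):
            raise ValueError("wavelength axis does not match wavelengths tuple")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")
        if np.any(self.intensity <= 0):
            raise ValueError("intensity must be strictly positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.channel_ids:
            self.channel_ids = tuple(f"S{i + 1}-D{i + 1}" for i in range(self.n_channels))
        if len(self.channel_ids) != self.n_channels:
            raise ValueError("channel_ids length mismatch")

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.time_offset + np.arange(self.n_samples) / self.sampling_rate

    def copy_with(self, **kwargs) -> "OpticalRecording":
        return replace(self, **kwargs)


@dataclass
class HemodynamicRecording:
    """Per-channel chromophore concentration changes after MBLL, in uM.

    dHbT equals dHbO + dHbR at construction; z-normalisation applied late in
    the pipeline intentionally breaks that identity (each chromophore is
    scaled independently), recorded by the ``normalized`` flag.
    """

    dHbO: np.ndarray
    dHbR: np.ndarray
    dHbT: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    channel_ids: tuple[str, ...] = ()
    rejected_channels: tuple[str, ...] = ()
    time_offset: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.dHbO = np.asarray(self.dHbO, dtype=float)
        self.dHbR = np.asarray(self.dHbR, dtype=float)
        self.dHbT = np.asarray(self.dHbT, dtype=float)
        if not (self.dHbO.shape == self.dHbR.shape == self.dHbT.shape):
            raise ValueError("chromophore arrays must share one shape")
        if self.dHbO.ndim != 2:
            raise ValueError("chromophore arrays must be (channels, samples)")
        if not self.channel_ids:
            self.channel_ids = tuple(f"S{i + 1}-D{i + 1}" for i in range(self.n_channels))
        if len(self.channel_ids) != self.n_channels:
            raise ValueError("channel_ids length mismatch")
        if not self.normalized:
            if not np.allclose(self.dHbT, self.dHbO + self.dHbR, atol=1e-12, rtol=0):
                raise ValueError("dHbT must equal dHbO + dHbR")

    @property
    def n_channels(self) -> int:
        return self.dHbO.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dHbO.shape[1]

    def chromophore(self, name: str) -> np.ndarray:
        try:
            return {"hbo": self.dHbO, "hbr": self.dHbR, "hbt": self.dHbT}[name]
        except KeyError:
            raise ValueError(f"unknown chromophore {name!r}") from None

    def copy_with(self, **kwargs) -> "HemodynamicRecording":
        return replace(self, **kwargs)


@dataclass
class ArtifactLog:
    """Positions of injected motion artifacts (ground truth for correction tests)."""

    spikes: list[tuple[int, int, int, float]] = field(default_factory=list)
    """(channel, wavelength, sample, amplitude) per injected spike."""

    shifts: list[tuple[int, int, int, float]] = field(default_factory=list)
    """(channel, wavelength, start sample, amplitude) per baseline shift."""


@dataclass
class GroundTruth:
    """Noise-free generator state accompanying a synthetic recording."""

    clean_dHbO: np.ndarray
    clean_dHbR: np.ndarray
    event_labels: tuple[str, ...]
    artifacts: ArtifactLog = field(default_factory=ArtifactLog)

    def __post_init__(self) -> None:
        if self.clean_dHbO.shape != self.clean_dHbR.shape:
            raise ValueError("clean chromophore arrays must share one shape")
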
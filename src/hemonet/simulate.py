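"""Synthetic block-design fNIRS generator.

Produces dual-wavelength intensity recordings with known ground truth so the
whole decoding pipeline can be exercised and tested without access to real
recordings.  The generator emulates the study conditions of a finger-tapping
experiment: a 3.9063 Hz acquisition over a motor-cortex montage, a block
design of 10 s rest / 10 s tapping for five finger conditions across three
sessions after a 30 s baseline, canonical double-gamma hemodynamic responses
with class-dependent amplitudes, physiological oscillations (cardiac,
respiratory, Mayer waves), white measurement noise, and optional spike /
baseline-shift motion artifacts.

The hemodynamic signal is converted to light intensity through the *forward*
Beer-Lambert relation, so inverting it with :func:`hemonet.preprocess.mbll`
recovers the injected concentration changes exactly on noiseless data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .containers import (
    DEFAULT_DISTANCE_CM,
    DEFAULT_SAMPLING_RATE,
    DEFAULT_WAVELENGTHS,
    FINGERS,
    REST,
    ArtifactLog,
    GroundTruth,
    OpticalRecording,
    StimEvent,
    StimulusTimeline,
)
from .optics import DEFAULT_DPF, forward_optical_density

__all__ = [
    "HRFParams",
    "NoiseConfig",
    "ArtifactConfig",
    "SyntheticConfig",
    "CLASS_PEAK_UM",
    "build_paradigm",
    "canonical_hrf",
    "simulate_recording",
    "inject_artifacts",
    "class_amplitude_map",
    "somatotopic_amplitude_map",
    "preset_config",
]


# ---------------------------------------------------------------------------
# paradigm
# ---------------------------------------------------------------------------

def build_paradigm(
    n_sessions: int = 3,
    conditions: tuple[str, ...] = FINGERS,
    trial_rest: float = 10.0,
    trial_task: float = 10.0,
    baseline: float = 30.0,
    terminal_rest: float = 20.0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    shuffle_seed: int | None = None,
    include_rest_events: bool = False,
) -> StimulusTimeline:
    """Build the block-design timeline.

    The default reproduces the study paradigm: a 30 s baseline, then three
    sessions each presenting the five finger conditions as (10 s rest, 10 s
    task) trials, and a terminal rest, totalling 350 s.

    total_duration = baseline + n_sessions * len(conditions)
                     * (trial_rest + trial_task) + terminal_rest

    Parameters
    ----------
    shuffle_seed : if given, the condition order is shuffled independently
        within each session; by default conditions run in the given order.
    include_rest_events : also emit the per-trial rest blocks as explicit
        ``rest`` events (for rest-vs-task decoding).
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if not conditions:
        raise ValueError("conditions must be non-empty")
    if min(trial_rest, trial_task, baseline, terminal_rest) < 0:
        raise ValueError("durations must be non-negative")
    if trial_task <= 0:
        raise ValueError("trial_task must be > 0 (empty trials are not allowed)")

    rng = np.random.default_rng(shuffle_seed) if shuffle_seed is not None else None
    events: list[StimEvent] = []
    t = float(baseline)
    for _ in range(n_sessions):
        order = list(conditions)
        if rng is not None:
            rng.shuffle(order)
        for cond in order:
            if include_rest_events and trial_rest > 0:
                events.append(StimEvent(t, trial_rest, REST))
            t += trial_rest
            events.append(StimEvent(t, trial_task, cond))
            t += trial_task
    total = t + terminal_rest
    return StimulusTimeline(tuple(events), total_duration=total, sampling_rate=sampling_rate)


# ---------------------------------------------------------------------------
# hemodynamic response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFParams:
    """Double-gamma hemodynamic response parameters (conventional defaults)."""

    peak_delay: float = 6.0       # s, time-to-peak of the positive lobe
    undershoot_delay: float = 16.0  # s, time-to-trough of the undershoot
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0  # undershoot amplitude relative to peak


def canonical_hrf(time_grid: np.ndarray, params: HRFParams = HRFParams()) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF on ``time_grid`` (seconds).

    h(t) = g(t; peak_delay/disp, disp) - ratio * g(t; u_delay/u_disp, u_disp),
    normalised so the global maximum is 1.  The response is 0 at t = 0, peaks
    once near ``peak_delay`` and shows a late undershoot returning to 0.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time_grid must be a 1-D array of at least 2 points")
    if np.any(t < 0):
        raise ValueError("time_grid must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    if params.peak_dispersion <= 0 or params.undershoot_dispersion <= 0:
        raise ValueError("dispersions must be > 0")
    if params.peak_delay <= 0 or params.undershoot_delay <= 0:
        raise ValueError("delays must be > 0")

    peak = _gamma_dist.pdf(
        t, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    under = _gamma_dist.pdf(
        t,
        params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    h = peak - params.undershoot_ratio * under
    m = h.max()
    if m <= 0:
        raise ValueError("degenerate HRF: non-positive maximum")
    return h / m


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Per-class HbO peak amplitude, uM.  Every channel carries the class signal
#: at the same strength by default, which makes the class identifiable from a
#: single channel's event average; levels are evenly spaced (0.325 uM gaps)
#: so no pair of conditions is disproportionately confusable, and HbR rows
#: (scaled by the default hbr_ratio of -1/3) keep proportional spacing.
CLASS_PEAK_UM: dict[str, float] = {
    "thumb": 0.3,
    "index": 0.625,
    "middle": 0.95,
    "ring": 1.275,
    "little": 1.6,
}


def class_amplitude_map(
    n_channels: int,
    peaks: dict[str, float] | None = None,
    scale: float = 1.0,
) -> dict[str, np.ndarray]:
    """Uniform amplitude map: every channel responds with the class peak."""
    peaks = CLASS_PEAK_UM if peaks is None else peaks
    return {c: np.full(n_channels, scale * a, dtype=float) for c, a in peaks.items()}


def somatotopic_amplitude_map(
    n_channels: int,
    peaks: dict[str, float] | None = None,
    width: float = 4.0,
    floor: float = 0.05,
) -> dict[str, np.ndarray]:
    """Spatially focal alternative: each condition peaks on its own channel
    cluster (Gaussian profile across the montage), mimicking somatotopy."""
    peaks = CLASS_PEAK_UM if peaks is None else peaks
    conds = list(peaks)
    centers = np.linspace(0, n_channels - 1, len(conds) + 2)[1:-1]
    ch = np.arange(n_channels)
    out = {}
    for cond, center in zip(conds, centers):
        profile = np.exp(-0.5 * ((ch - center) / width) ** 2)
        out[cond] = peaks[cond] * np.maximum(profile, floor)
    return out


@dataclass(frozen=True)
class NoiseConfig:
    """Additive noise at the intensity level (device units; baseline 1.0).

    Sinusoid phases are drawn independently per channel and wavelength.  The
    cardiac component (~1 Hz) sits above the 0.5 Hz analysis band and, at the
    3.9063 Hz acquisition rate, below Nyquist (1.95 Hz); no anti-alias
    constraint is imposed, so faster components would alias as they do on a
    real instrument.
    """

    cardiac_hz: float = 1.0
    cardiac_amp: float = 0.01
    resp_hz: float = 0.3
    resp_amp: float = 0.005
    mayer_hz: float = 0.1
    mayer_amp: float = 0.005
    white_sd: float = 0.005


@dataclass(frozen=True)
class ArtifactConfig:
    """Motion-artifact rates (events per minute) and amplitudes (intensity units)."""

    spike_rate_per_min: float = 0.0
    spike_amplitude: float = 0.1
    shift_rate_per_min: float = 0.0
    shift_amplitude: float = 0.05


@dataclass
class SyntheticConfig:
    """Everything the generator needs; ``seed`` fixes all randomness."""

    montage_channels: int = 48
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    hrf_params: HRFParams = HRFParams()
    amplitude_map: dict[str, np.ndarray] = field(default_factory=dict)
    hbr_ratio: float = -1.0 / 3.0
    noise: NoiseConfig = NoiseConfig()
    artifact: ArtifactConfig = ArtifactConfig()
    seed: int = 0
    baseline_intensity: float = 1.0
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS
    dpf: tuple[float, float] = DEFAULT_DPF
    source_detector_distance: float = DEFAULT_DISTANCE_CM

    def __post_init__(self) -> None:
        if self.montage_channels < 1:
            raise ValueError("montage_channels must be >= 1")
        if not self.amplitude_map:
            self.amplitude_map = class_amplitude_map(self.montage_channels)
        for cond, amp in self.amplitude_map.items():
            amp = np.asarray(amp, dtype=float)
            if amp.shape != (self.montage_channels,):
                raise ValueError(
                    f"amplitude map for {cond!r} has shape {amp.shape}, "
                    f"expected ({self.montage_channels},)"
                )
            if not np.all(np.isfinite(amp)):
                raise ValueError(f"non-finite amplitude for {cond!r}")
            self.amplitude_map[cond] = amp


def preset_config(kind: str, montage_channels: int = 48, seed: int = 0) -> SyntheticConfig:
    """Named study conditions.

    - ``default``: the generator's reference conditions.
    - ``high_snr``: low noise; classes cleanly decodable from one channel.
    - ``mid_snr``: moderate noise; classes partially confusable.
    - ``null``: all class amplitudes equal (0.8 uM); nothing to decode.
    """
    amp = class_amplitude_map(montage_channels)
    if kind == "default":
        noise = NoiseConfig()
    elif kind == "high_snr":
        noise = NoiseConfig(
            cardiac_amp=0.005, resp_amp=0.0005, mayer_amp=0.0002, white_sd=0.0003
        )
    elif kind == "mid_snr":
        noise = NoiseConfig(
            cardiac_amp=0.01, resp_amp=0.005, mayer_amp=0.002, white_sd=0.006
        )
    elif kind == "null":
        noise = NoiseConfig()
        amp = {c: np.full(montage_channels, 0.8) for c in FINGERS}
    else:
        raise ValueError(f"unknown preset {kind!r}")
    return SyntheticConfig(
        montage_channels=montage_channels, amplitude_map=amp, noise=noise, seed=seed
    )


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def _block_response(duration: float, hrf: np.ndarray, fs: float) -> np.ndarray:
    """HRF response to one task block, peak-normalised to 1."""
    n_on = max(int(np.round(duration * fs)), 1)
    boxcar = np.ones(n_on)
    r = np.convolve(boxcar, hrf)
    return r / r.max()


def clean_hemodynamics(
    timeline: StimulusTimeline, cfg: SyntheticConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (dHbO, dHbR) of shape (channels, samples), in uM."""
    fs = cfg.sampling_rate
    n = timeline.n_samples
    hrf_t = np.arange(0.0, 40.0, 1.0 / fs)
    hrf = canonical_hrf(hrf_t, cfg.hrf_params)

    dHbO = np.zeros((cfg.montage_channels, n))
    responses: dict[float, np.ndarray] = {}
    for ev in timeline.task_events:
        if ev.condition not in cfg.amplitude_map:
            raise ValueError(f"no amplitude entry for condition {ev.condition!r}")
        if ev.duration not in responses:
            responses[ev.duration] = _block_response(ev.duration, hrf, fs)
        r = responses[ev.duration]
        k0 = int(np.round(ev.onset * fs))
        k1 = min(k0 + r.size, n)
        if k0 >= n:
            continue
        dHbO[:, k0:k1] += cfg.amplitude_map[ev.condition][:, None] * r[: k1 - k0]
    dHbR = cfg.hbr_ratio * dHbO
    return dHbO, dHbR


def simulate_recording(
    timeline: StimulusTimeline, cfg: SyntheticConfig
) -> tuple[OpticalRecording, GroundTruth]:
    """Generate a raw dual-wavelength recording plus its ground truth.

    Intensity is the forward Beer-Lambert image of the clean hemodynamics
    (I = I0 * 10**(-dOD)) plus physiological sinusoids and white noise.
    The same (timeline, cfg) pair, including ``cfg.seed``, yields
    bit-identical output.
    """
    if abs(timeline.sampling_rate - cfg.sampling_rate) > 1e-9:
        raise ValueError("timeline and config sampling rates differ")
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    n = timeline.n_samples
    t = np.arange(n) / fs

    dHbO, dHbR = clean_hemodynamics(timeline, cfg)
    od = forward_optical_density(
        dHbO,
        dHbR,
        wavelengths=cfg.wavelengths,
        dpf=cfg.dpf,
        distance=cfg.source_detector_distance,
    )
    intensity = cfg.baseline_intensity * 10.0 ** (-od)

    nz = cfg.noise
    shape = (cfg.montage_channels, len(cfg.wavelengths))
    for hz, amp in (
        (nz.cardiac_hz, nz.cardiac_amp),
        (nz.resp_hz, nz.resp_amp),
        (nz.mayer_hz, nz.mayer_amp),
    ):
        if amp > 0:
            phase = rng.uniform(0, 2 * np.pi, size=shape)
            intensity += amp * np.sin(2 * np.pi * hz * t[None, None, :] + phase[:, :, None])
    if nz.white_sd > 0:
        intensity += rng.normal(0.0, nz.white_sd, size=intensity.shape)

    # detected light cannot be <= 0; clip far below physiological range
    np.clip(intensity, 1e-6, None, out=intensity)

    rec = OpticalRecording(
        intensity=intensity,
        sampling_rate=fs,
        wavelengths=cfg.wavelengths,
        source_detector_distance=cfg.source_detector_distance,
    )
    gt = GroundTruth(
        clean_dHbO=dHbO,
        clean_dHbR=dHbR,
        event_labels=tuple(e.condition for e in timeline.task_events),
    )
    rec, gt.artifacts = inject_artifacts(rec, cfg, rng=rng)
    return rec, gt


def inject_artifacts(
    rec: OpticalRecording,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[OpticalRecording, ArtifactLog]:
    """Add seeded spike and baseline-shift artifacts; returns the new
    recording and a log of positions (for correction-quality tests).

    Spikes are isolated single-sample deflections of +/- spike_amplitude;
    shifts are sustained steps from a random sample to the end of the
    recording.  Counts are Poisson with the configured per-minute rates.
    With both rates zero the input is returned unchanged.
    """
    art = cfg.artifact
    if art.spike_rate_per_min < 0 or art.shift_rate_per_min < 0:
        raise ValueError("artifact rates must be >= 0")
    log = ArtifactLog()
    if art.spike_rate_per_min == 0 and art.shift_rate_per_min == 0:
        return rec, log
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    minutes = rec.n_samples / rec.sampling_rate / 60.0
    intensity = rec.intensity.copy()
    for c in range(rec.n_channels):
        for w in range(len(rec.wavelengths)):
            n_spikes = rng.poisson(art.spike_rate_per_min * minutes)
            for k in rng.integers(1, rec.n_samples - 1, size=n_spikes):
                a = art.spike_amplitude * rng.choice([-1.0, 1.0])
                intensity[c, w, k] += a
                log.spikes.append((c, w, int(k), a))
            n_shifts = rng.poisson(art.shift_rate_per_min * minutes)
            for k in rng.integers(1, rec.n_samples - 1, size=n_shifts):
                a = art.shift_amplitude * rng.choice([-1.0, 1.0])
                intensity[c, w, k:] += a
                log.shifts.append((c, w, int(k), a))
    np.clip(intensity, 1e-6, None, out=intensity)
    return rec.copy_with(intensity=intensity), log
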
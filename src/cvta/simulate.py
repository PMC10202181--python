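"""Synthetic signals, road scenes, and ground truth.

Every generator here returns its artifact together with the ground truth
needed to score downstream modules (the attended item, the clench intervals,
the road mask), and is deterministic under a fixed seed. The generators are
deliberately simple surrogates:

* ERP trials: Gaussian background noise on six channels (FC5, Cz, PO4, PO7,
  PO8, Oz at 250 Hz); flashes containing the attended item add a one-sided
  raised-cosine (Hann) bump on the four posterior feature channels, peaking
  ``erp_latency_ms`` after flash onset — a parameter-light stand-in for the
  late positive ERP component.
* EMG traces: a low-amplitude uniform-noise resting baseline with
  high-amplitude sinusoid-carrier bursts during teeth-clench intervals, so
  peak-to-peak amplitude separates the two regimes exactly.
* Road scenes: a two-tone perspective road (full-width trapezoid narrowing
  toward the top) on a background color, with rectangular obstacle holes and
  optional Gaussian color noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import erp
from .signals import SignalRecording

__all__ = [
    "ErpSimConfig",
    "EmgSimConfig",
    "RoadSceneConfig",
    "generate_erp_recording",
    "generate_emg_trace",
    "generate_road_scene",
]

DEFAULT_CHANNELS = ("FC5", "Cz", "PO4", "PO7", "PO8", "Oz")
ERP_CHANNELS = ("PO4", "PO7", "PO8", "Oz")


@dataclass
class ErpSimConfig:
    """Settings for synthetic oddball-trial EEG.

    Amplitudes are in arbitrary signal units (think microvolts); the default
    amplitude/noise ratio emulates a reliably decodable subject.
    """

    sampling_rate: float = 250.0
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    erp_amplitude: float = 5.0
    erp_latency_ms: float = 300.0
    erp_width_ms: float = 200.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not self.erp_width_ms > 0:
            raise ValueError("erp_width_ms must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class EmgSimConfig:
    """Settings for a synthetic single-channel teeth-clench EMG trace."""

    sampling_rate: float = 250.0
    rest_amplitude: float = 1.0
    burst_amplitude: float = 40.0
    burst_intervals: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.rest_amplitude < 0:
            raise ValueError("rest_amplitude must be non-negative")
        if not self.burst_amplitude > self.rest_amplitude:
            raise ValueError("burst_amplitude must exceed rest_amplitude")
        ivals = sorted((float(a), float(b)) for a, b in self.burst_intervals)
        for a, b in ivals:
            if not b > a or a < 0:
                raise ValueError(f"invalid burst interval ({a}, {b})")
        for (_, b0), (a1, _) in zip(ivals, ivals[1:]):
            if a1 < b0:
                raise ValueError("burst intervals must not overlap")
        self.burst_intervals = ivals


@dataclass
class RoadSceneConfig:
    """Settings for a synthetic two-tone road scene.

    The road is a trapezoid spanning the full image width at the bottom and
    ``top_width_frac`` of it at the top row (a crude perspective); obstacles
    are background-colored rectangles ``(x, y, w, h)`` in pixels cut out of
    the road.
    """

    width: int = 160
    height: int = 120
    road_color: tuple[int, int, int] = (110, 110, 110)
    background_color: tuple[int, int, int] = (40, 150, 60)
    obstacle_rects: list[tuple[int, int, int, int]] = field(default_factory=list)
    color_noise_sd: float = 0.0
    top_width_frac: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ValueError("image must be at least 2x2")
        if tuple(self.road_color) == tuple(self.background_color):
            raise ValueError("road_color must differ from background_color")
        if not 0 < self.top_width_frac <= 1:
            raise ValueError("top_width_frac must be in (0, 1]")
        for x, y, w, h in self.obstacle_rects:
            if w <= 0 or h <= 0 or x < 0 or y < 0:
                raise ValueError(f"invalid obstacle rect {(x, y, w, h)}")
            if x + w > self.width or y + h > self.height:
                raise ValueError(f"obstacle rect {(x, y, w, h)} exceeds image bounds")


# --------------------------------------------------------------------- ERP


def erp_template(config: ErpSimConfig) -> tuple[int, np.ndarray]:
    """Sampled ERP bump and its onset offset in samples.

    Returns ``(offset, waveform)`` where ``offset`` is the number of samples
    between flash onset and the first template sample. The waveform is a Hann
    bump of total width ``erp_width_ms`` centered ``erp_latency_ms`` after
    flash onset — positive only ("one-sided"), zero at both ends.
    """
    fs = config.sampling_rate
    half = config.erp_width_ms / 2000.0
    start = config.erp_latency_ms / 1000.0 - half
    n = int(round(2 * half * fs)) + 1
    wave = config.erp_amplitude * np.hanning(max(n, 1))
    return int(round(start * fs)), wave


def generate_erp_recording(
    config: ErpSimConfig,
    schedule: erp.FlashSchedule,
    target_item: int,
    duration: float | None = None,
) -> SignalRecording:
    """Synthesize one oddball trial with a known attended item.

    Flashes whose row or column contains ``target_item`` get the ERP template
    added on the posterior channels (PO4, PO7, PO8, Oz), time-locked at
    sample resolution; background is seeded Gaussian noise on all channels.
    Markers on the returned recording are the schedule events.
    """
    if not 1 <= target_item <= erp.N_ITEMS:
        raise ValueError(f"target_item must be in 1..{erp.N_ITEMS}")
    fs = config.sampling_rate
    tail = 1.0  # room for the last epoch window
    needed = (schedule.events[-1][0] if schedule.events else 0.0) + tail
    if duration is None:
        duration = needed
    elif duration < needed:
        raise ValueError(
            f"schedule needs {needed:.2f} s but only {duration:.2f} s requested"
        )
    n = int(round(duration * fs))
    labels = list(config.channel_labels)
    rng = np.random.default_rng(config.seed)
    data = rng.normal(0.0, config.noise_sd, size=(n, len(labels)))
    if config.noise_sd == 0:
        data = np.zeros((n, len(labels)))

    offset, wave = erp_template(config)
    erp_cols = [labels.index(c) for c in ERP_CHANNELS if c in labels]
    flags = schedule.target_flags(target_item)
    for (onset, _), is_target in zip(schedule.events, flags):
        if not is_target:
            continue
        i0 = int(round(onset * fs)) + offset
        i1 = min(i0 + len(wave), n)
        lo = max(i0, 0)
        if lo >= i1:
            continue
        data[lo:i1, erp_cols] += wave[lo - i0 : i1 - i0, None]
    return SignalRecording(data, labels, fs, markers=list(schedule.events))


# --------------------------------------------------------------------- EMG

_BURST_CARRIER_HZ = 35.0


def generate_emg_trace(
    config: EmgSimConfig, duration: float
) -> tuple[SignalRecording, list[tuple[float, float]]]:
    """Synthesize an FC5 clench trace plus its ground-truth burst intervals.

    Rest segments are uniform noise in ``±rest_amplitude``; bursts replace
    them with a ``burst_amplitude`` sinusoid carrier, so peak-to-peak inside
    a burst is 2x the burst amplitude and outside at most 2x the rest
    amplitude.
    """
    if config.burst_intervals and config.burst_intervals[-1][1] > duration:
        raise ValueError("duration does not cover all burst intervals")
    fs = config.sampling_rate
    n = int(round(duration * fs))
    rng = np.random.default_rng(config.seed)
    x = config.rest_amplitude * rng.uniform(-1.0, 1.0, size=n)
    t = np.arange(n) / fs
    for a, b in config.burst_intervals:
        sel = (t >= a) & (t < b)
        x[sel] = config.burst_amplitude * np.sin(
            2 * np.pi * _BURST_CARRIER_HZ * (t[sel] - a) + np.pi / 4
        )
    rec = SignalRecording(x[:, None], ["FC5"], fs)
    return rec, list(config.burst_intervals)


# -------------------------------------------------------------------- scene


def _road_polygon_mask(config: RoadSceneConfig) -> np.ndarray:
    """Trapezoidal road mask (no obstacles), full-width at the bottom row."""
    H, W = config.height, config.width
    mask = np.zeros((H, W), dtype=bool)
    cx = (W - 1) / 2.0
    for y in range(H):
        frac = y / (H - 1)  # 0 at top, 1 at bottom
        width = W * (config.top_width_frac + (1 - config.top_width_frac) * frac)
        lo = int(np.ceil(cx - width / 2))
        hi = int(np.floor(cx + width / 2))
        mask[y, max(lo, 0) : min(hi, W - 1) + 1] = True
    return mask


def generate_road_scene(
    config: RoadSceneConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a road scene and its ground-truth road mask.

    Returns ``(image, mask)``: a ``(H, W, 3)`` uint8 image and a boolean road
    mask. Pixels inside obstacle rectangles or outside the road trapezoid
    take the background color. The bottom-center pixel must be road (the
    anchor "under the robot's feet"); a scene violating that is rejected.
    """
    H, W = config.height, config.width
    mask = _road_polygon_mask(config)
    for x, y, w, h in config.obstacle_rects:
        mask[y : y + h, x : x + w] = False
    if not mask[H - 1, W // 2]:
        raise ValueError("invalid scene: bottom-center pixel is not road")
    img = np.empty((H, W, 3), dtype=float)
    img[:] = config.background_color
    img[mask] = config.road_color
    if config.color_noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        img += rng.normal(0.0, config.color_noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), mask
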
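"""EMG teeth-clench detection: the idle -> control "brain state switch".

A clench is detected when the peak-to-peak amplitude of the EMG channel
within a 1 s sliding window (250 samples, no overlap) reaches a
subject-specific threshold T0:

    F = 1  if  max{e_i} - min{e_i} >= T0   (closed inequality at T0)
    F = 0  otherwise

Scanning stops at the first triggering window — once the control state is
entered, EMG monitoring is suspended.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import SignalRecording

__all__ = [
    "EmgWindowConfig",
    "ClenchThreshold",
    "CalibrationOverlapError",
    "peak_to_peak",
    "detect_clench",
    "calibrate_threshold",
    "monitor_stream",
]


class CalibrationOverlapError(ValueError):
    """Resting and clenching calibration amplitudes are not separable."""


@dataclass
class EmgWindowConfig:
    """Sliding-window layout: ``window_samples`` per window (1 s at 250 Hz),
    stepping by ``window_samples - overlap`` (default: no overlap)."""

    window_samples: int = 250
    sampling_rate: float = 250.0
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.window_samples <= 0:
            raise ValueError("window_samples must be positive")
        if not 0 <= self.overlap < self.window_samples:
            raise ValueError("overlap must be in [0, window_samples)")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class ClenchThreshold:
    """Subject-specific trigger threshold, optionally with its calibration
    record (resting / clenching peak-to-peak values)."""

    t0: float
    resting_p2p: list[float] = field(default_factory=list)
    clenching_p2p: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.t0 > 0:
            raise ValueError("T0 must be positive")
        if self.resting_p2p and self.clenching_p2p:
            if not max(self.resting_p2p) < self.t0 <= min(self.clenching_p2p):
                raise ValueError(
                    "calibrated T0 must separate resting and clenching amplitudes"
                )


def peak_to_peak(window: np.ndarray) -> float:
    """max - min of a sample window; always >= 0."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    return float(window.max() - window.min())


def detect_clench(window: np.ndarray, threshold: ClenchThreshold,
                  config: EmgWindowConfig | None = None) -> int:
    """Trigger flag for one window: 1 iff peak-to-peak >= T0."""
    config = config or EmgWindowConfig()
    window = np.asarray(window, dtype=float)
    if window.shape != (config.window_samples,):
        raise ValueError(
            f"window must have exactly {config.window_samples} samples, "
            f"got {window.shape}"
        )
    return int(peak_to_peak(window) >= threshold.t0)


def calibrate_threshold(
    resting: list[np.ndarray], clenching: list[np.ndarray]
) -> ClenchThreshold:
    """Set T0 from calibration windows.

    T0 is the midpoint between the largest resting and the smallest
    clenching peak-to-peak value — a reproducible surrogate for the by-eye
    on-screen calibration an operator would do. Overlapping classes are an error rather
    than a silent bad threshold.
    """
    if not resting or not clenching:
        raise ValueError("both calibration lists must be non-empty")
    rest = [peak_to_peak(w) for w in resting]
    clench = [peak_to_peak(w) for w in clenching]
    if min(clench) <= max(rest):
        raise CalibrationOverlapError(
            f"classes overlap: max resting p2p {max(rest):.3g} >= "
            f"min clenching p2p {min(clench):.3g}"
        )
    t0 = 0.5 * (max(rest) + min(clench))
    return ClenchThreshold(t0, resting_p2p=rest, clenching_p2p=clench)


def monitor_stream(
    recording: SignalRecording,
    threshold: ClenchThreshold,
    channel: str = "FC5",
    config: EmgWindowConfig | None = None,
) -> float | None:
    """Scan a recorded stream window by window; return the first trigger time.

    Windows start at sample 0 and step by ``window - overlap`` samples
    (non-overlapping by default). The return value is the end time of the
    first window whose flag is 1, in seconds — the moment the switch fires —
    or ``None`` if no window triggers. Scanning stops at the first trigger.
    """
    config = config or EmgWindowConfig()
    x = recording.channel(channel)  # KeyError on unknown channel
    P = config.window_samples
    step = P - config.overlap
    for start in range(0, len(x) - P + 1, step):
        if peak_to_peak(x[start : start + P]) >= threshold.t0:
            return (start + P) / recording.fs
    return None
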
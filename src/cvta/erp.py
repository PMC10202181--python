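"""Row-column oddball paradigm and ERP decoding.

The visual interface is a 3x4 matrix of 12 items flashed by rows and
columns (7 flash groups). An attended item's row and column evoke a late
positive ERP; selecting the item amounts to picking the row group and the
column group whose flash epochs score highest under a Fisher linear
discriminant.

The decoding chain mirrors the standard pipeline: common average reference,
third-order Butterworth band-pass (0.01-30 Hz, zero-phase), epoching 50-750 ms
post-stimulus, decimation by 7 (250 Hz -> ~35 Hz, 25 samples per channel),
and concatenation over the four posterior feature channels (PO4, PO7, PO8,
Oz) into a 100-dimensional feature vector.

Coordinate conventions: items are indexed 1..12 row-major; flash groups are
integers 0..6 where 0..2 are rows 1..3 and 3..6 are columns 1..4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import SignalRecording

__all__ = [
    "N_ROWS",
    "N_COLS",
    "N_ITEMS",
    "N_GROUPS",
    "ROW_GROUPS",
    "COL_GROUPS",
    "item_groups",
    "group_items",
    "FlashSchedule",
    "build_schedule",
    "EpochConfig",
    "FldaModel",
    "car_filter",
    "bandpass",
    "extract_epoch",
    "featurize",
    "flda_train",
    "flda_score",
    "classify_target",
    "item_to_command",
    "SS_COMMANDS",
    "SS_LABELS",
    "train_decoder",
]

N_ROWS = 3
N_COLS = 4
N_ITEMS = N_ROWS * N_COLS
N_GROUPS = N_ROWS + N_COLS
ROW_GROUPS = tuple(range(N_ROWS))  # groups 0..2
COL_GROUPS = tuple(range(N_ROWS, N_GROUPS))  # groups 3..6


def item_groups(item: int) -> tuple[int, int]:
    """Return the ``(row_group, col_group)`` containing 1-based ``item``."""
    if not 1 <= item <= N_ITEMS:
        raise ValueError(f"item must be in 1..{N_ITEMS}, got {item}")
    row = (item - 1) // N_COLS
    col = (item - 1) % N_COLS
    return row, N_ROWS + col


def group_items(group: int) -> tuple[int, ...]:
    """Items (1-based) flashed by ``group``."""
    if not 0 <= group < N_GROUPS:
        raise ValueError(f"group must be in 0..{N_GROUPS - 1}, got {group}")
    if group < N_ROWS:
        return tuple(group * N_COLS + c + 1 for c in range(N_COLS))
    col = group - N_ROWS
    return tuple(r * N_COLS + col + 1 for r in range(N_ROWS))


@dataclass
class FlashSchedule:
    """Timed sequence of row/column flashes making up one selection trial.

    ``events`` holds ``(onset_s, group)`` pairs sorted by onset; within each
    repetition every one of the 7 groups appears exactly once, so every item
    flashes twice per repetition (its row and its column).
    """

    events: list[tuple[float, int]]
    soa: float = 0.140
    flash_on: float = 0.100
    flash_off: float = 0.040
    n_repetitions: int = 1

    def __post_init__(self) -> None:
        self.events = [(float(t), int(g)) for t, g in self.events]
        if sorted(self.events) != self.events:
            raise ValueError("events must be sorted by onset")
        for _, g in self.events:
            if not 0 <= g < N_GROUPS:
                raise ValueError(f"invalid flash group {g}")

    @property
    def duration(self) -> float:
        """Nominal duration: ``n_repetitions * 7 * soa`` seconds."""
        return self.n_repetitions * N_GROUPS * self.soa

    def target_flags(self, item: int) -> np.ndarray:
        """Boolean per event: does the flashed group contain ``item``?"""
        rg, cg = item_groups(item)
        return np.array([g in (rg, cg) for _, g in self.events])


def build_schedule(
    n_repetitions: int, soa: float = 0.140, seed: int = 0
) -> FlashSchedule:
    """Random row/column flash order: a fresh permutation of the 7 groups per
    repetition, one onset every ``soa`` seconds.

    With the default 140 ms SOA one repetition lasts 0.98 s.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    rng = np.random.default_rng(seed)
    events: list[tuple[float, int]] = []
    for rep in range(n_repetitions):
        order = rng.permutation(N_GROUPS)
        t0 = rep * N_GROUPS * soa
        events.extend((t0 + k * soa, int(g)) for k, g in enumerate(order))
    return FlashSchedule(events, soa=soa, n_repetitions=n_repetitions)


@dataclass
class EpochConfig:
    """Feature-extraction settings for single-flash epochs.

    ``window`` is seconds post-stimulus, half-open ``[50, 750)`` ms so a
    250 Hz epoch is exactly 175 samples; decimation by 7 keeps 25 samples per
    channel and the four feature channels give 4 x 25 = 100 features.
    """

    window: tuple[float, float] = (0.050, 0.750)
    band: tuple[float, float] = (0.01, 30.0)
    order: int = 3
    decimation: int = 7
    feature_channels: tuple[str, ...] = ("PO4", "PO7", "PO8", "Oz")

    def n_epoch_samples(self, fs: float) -> int:
        return int(round((self.window[1] - self.window[0]) * fs))

    def n_features(self, fs: float) -> int:
        per_channel = -(-self.n_epoch_samples(fs) // self.decimation)
        return len(self.feature_channels) * per_channel


@dataclass
class FldaModel:
    """Fisher linear discriminant: ``f(x) = w @ x + w0``; positive => target."""

    w: np.ndarray
    w0: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        self.w0 = float(self.w0)

    def to_dict(self) -> dict:
        return {"w": self.w.tolist(), "w0": self.w0}

    @classmethod
    def from_dict(cls, d: dict) -> "FldaModel":
        return cls(np.asarray(d["w"], dtype=float), float(d["w0"]))


# ------------------------------------------------------------------ filtering


def car_filter(
    recording: SignalRecording, channels: list[str] | None = None
) -> SignalRecording:
    """Common average reference over a channel set.

    Each referenced channel gets the instantaneous mean of the set subtracted;
    channels outside the set (by default only the EMG channel FC5) pass
    through untouched. At every sample the referenced set then has zero mean.
    """
    if channels is None:
        channels = [c for c in recording.channels if c != "FC5"]
    if len(channels) < 2:
        raise ValueError("CAR needs at least 2 channels")
    idx = [recording.channel_index(c) for c in channels]
    out = recording.data.copy()
    out[:, idx] -= out[:, idx].mean(axis=1, keepdims=True)
    return recording.with_data(out)


def bandpass(
    recording: SignalRecording,
    band: tuple[float, float] = (0.01, 30.0),
    order: int = 3,
) -> SignalRecording:
    """Zero-phase Butterworth band-pass (forward-backward, SOS form).

    Zero-phase filtering preserves ERP latency, which matters because the
    epoch window is defined relative to flash onset. The 0.01 Hz high-pass
    edge puts a pole extremely close to DC, so even (mirror) padding is used
    for the forward-backward pass: it keeps the boundary extension
    continuous and minimizes the slow transient that odd padding excites.
    """
    lo, hi = band
    nyq = recording.fs / 2
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} must satisfy 0 < low < high < Nyquist ({nyq})")
    sos = sps.butter(order, band, btype="bandpass", fs=recording.fs, output="sos")
    return recording.with_data(
        sps.sosfiltfilt(sos, recording.data, axis=0, padtype="even")
    )


# ------------------------------------------------------------------- features


def extract_epoch(
    recording: SignalRecording, onset: float, config: EpochConfig | None = None
) -> np.ndarray:
    """Post-stimulus epoch as ``(n_channels, n_samples)``.

    Samples cover ``[onset + window[0], onset + window[1])`` (half-open); at
    250 Hz with the default window that is indices ``round(onset*fs)+13`` for
    175 samples.
    """
    config = config or EpochConfig()
    fs = recording.fs
    # half-up rounding: 0.05 s at 250 Hz is sample 13, not banker's 12
    start = int(np.floor(onset * fs + 0.5)) + int(
        np.floor(config.window[0] * fs + 0.5)
    )
    n = config.n_epoch_samples(fs)
    if start < 0 or start + n > recording.n_samples:
        raise ValueError(
            f"epoch [{start}, {start + n}) exceeds recording of "
            f"{recording.n_samples} samples"
        )
    return recording.data[start : start + n].T


def featurize(
    epoch: np.ndarray,
    channel_labels: list[str],
    config: EpochConfig | None = None,
) -> np.ndarray:
    """Decimate and concatenate the feature channels of one epoch.

    Keeps every ``decimation``-th sample starting at index 0 of each feature
    channel (anti-aliasing is provided by the 30 Hz low-pass upstream) and
    concatenates channel blocks in ``config.feature_channels`` order.
    """
    config = config or EpochConfig()
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] != len(channel_labels):
        raise ValueError("epoch must be (n_channels, n_samples) matching labels")
    blocks = []
    for label in config.feature_channels:
        try:
            row = epoch[channel_labels.index(label)]
        except ValueError:
            raise ValueError(f"feature channel {label!r} missing from epoch") from None
        blocks.append(row[:: config.decimation])
    return np.concatenate(blocks)


# ----------------------------------------------------------------------- FLDA


def flda_train(
    features: np.ndarray, labels: np.ndarray, shrinkage: float = 0.1
) -> FldaModel:
    """Fit a Fisher linear discriminant with shrinkage regularization.

    The pooled within-class covariance is shrunk toward a scaled identity,
    ``(1-g)*S + g*(tr S / d)*I``, which keeps the solve well-posed when the
    feature dimension (100) rivals the epoch count. The threshold ``w0``
    places the decision boundary at the midpoint of the projected class
    means, so ``f(x) > 0`` marks the target (label 1) class.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_obs, n_dim) matching labels")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    d = X.shape[1]
    S = np.zeros((d, d))
    for Xi, mui in ((X0, mu0), (X1, mu1)):
        Z = Xi - mui
        S += Z.T @ Z
    dof = max(n0 + n1 - 2, 1)
    S /= dof
    S = (1.0 - shrinkage) * S + shrinkage * (np.trace(S) / d) * np.eye(d)
    w = np.linalg.solve(S, mu1 - mu0)
    w0 = -0.5 * float(w @ (mu0 + mu1))
    return FldaModel(w, w0)


def flda_score(model: FldaModel, x: np.ndarray) -> float:
    """Discriminant value ``f(x) = w @ x + w0``; positive means target."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape != model.w.shape:
        raise ValueError(f"dimension mismatch: w is {model.w.shape}, x is {x.shape}")
    return float(model.w @ x + model.w0)


# ----------------------------------------------------------------- selection


def classify_target(
    recording: SignalRecording,
    schedule: FlashSchedule,
    model: FldaModel,
    config: EpochConfig | None = None,
    car_channels: list[str] | None = None,
) -> int:
    """Decode the attended item (1..12) from one trial.

    Preprocess once (CAR then band-pass), score every flash epoch with the
    discriminant, sum scores per flash group over all repetitions, and
    intersect the best row group with the best column group. Ties break
    toward the lowest group index, so an all-zero recording yields item 1.
    """
    config = config or EpochConfig()
    if not schedule.events:
        raise ValueError("schedule has no events")
    prepped = bandpass(car_filter(recording, car_channels), config.band, config.order)
    scores = np.zeros(N_GROUPS)
    for onset, group in schedule.events:
        epoch = extract_epoch(prepped, onset, config)
        x = featurize(epoch, prepped.channels, config)
        scores[group] += flda_score(model, x)
    row = int(np.argmax(scores[: N_ROWS]))
    col = int(np.argmax(scores[N_ROWS:]))
    return row * N_COLS + col + 1


def train_decoder(
    trials: list[tuple[SignalRecording, FlashSchedule, int]],
    config: EpochConfig | None = None,
    car_channels: list[str] | None = None,
    shrinkage: float = 0.1,
) -> FldaModel:
    """Fit the FLDA from labeled trials.

    Every flash epoch of every trial becomes one observation, labeled target
    when the flashed group contains that trial's attended item.
    """
    config = config or EpochConfig()
    feats, labels = [], []
    for recording, schedule, target in trials:
        prepped = bandpass(
            car_filter(recording, car_channels), config.band, config.order
        )
        flags = schedule.target_flags(target)
        for (onset, _), is_target in zip(schedule.events, flags):
            epoch = extract_epoch(prepped, onset, config)
            feats.append(featurize(epoch, prepped.channels, config))
            labels.append(int(is_target))
    return flda_train(np.asarray(feats), np.asarray(labels), shrinkage=shrinkage)


# ------------------------------------------------------------------ commands

#: Single-step (arrow marker) command per item, row-major per the interface
#: layout; item 12 is Exit in both modes.
SS_COMMANDS: dict[int, str] = {
    1: "turn_left_30",
    2: "left_front_20",
    3: "right_front_20",
    4: "turn_right_30",
    5: "forward_40",
    6: "left_20",
    7: "right_20",
    8: "backward_20",
    9: "forward_20",
    10: "left_rear_20",
    11: "right_rear_20",
    12: "exit",
}

SS_LABELS: dict[str, str] = {
    "turn_left_30": "Turn left 30°",
    "left_front_20": "Move to the left front 20 cm",
    "right_front_20": "Move to the right front 20 cm",
    "turn_right_30": "Turn right 30°",
    "forward_40": "Move forward 40 cm",
    "left_20": "Move to the left 20 cm",
    "right_20": "Move to the right 20 cm",
    "backward_20": "Move backward 20 cm",
    "forward_20": "Move forward 20 cm",
    "left_rear_20": "Move to the left rear 20 cm",
    "right_rear_20": "Move to the right rear 20 cm",
    "exit": "Exit",
}


def item_to_command(item: int, mode: str) -> str | int:
    """Map a selected item to its command.

    ``mode="SS"`` returns the arrow-marker step command name (see
    :data:`SS_COMMANDS`); ``mode="CVT"`` returns the numeric sub-goal 1..11.
    Item 12 returns ``"exit"`` in both modes.
    """
    if not 1 <= item <= N_ITEMS:
        raise ValueError(f"item must be in 1..{N_ITEMS}, got {item}")
    mode = mode.upper()
    if mode == "SS":
        return SS_COMMANDS[item]
    if mode == "CVT":
        return "exit" if item == N_ITEMS else item
    raise ValueError(f"mode must be 'SS' or 'CVT', got {mode!r}")
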
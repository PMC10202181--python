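"""Multichannel sampled time series.

:class:`SignalRecording` is the carrier for raw EEG/EMG throughout the
package: a ``(n_samples, n_channels)`` float array with channel labels and a
sampling rate, plus optional stimulus markers ``(onset_s, group)``.

On disk a recording is a plain CSV (one column per channel, header row =
channel labels) with an optional JSON sidecar holding the sampling rate and
the markers, so recordings round-trip through ordinary spreadsheet tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SignalRecording"]


@dataclass
class SignalRecording:
    """A multichannel recording sampled at a fixed rate.

    Parameters
    ----------
    data
        Array of shape ``(n_samples, n_channels)``.
    channels
        Channel labels, one per column of ``data`` (e.g. ``"FC5"``, ``"Oz"``).
    fs
        Sampling rate in Hz.
    markers
        Optional stimulus events as ``(onset_seconds, group_id)`` pairs.
    """

    data: np.ndarray
    channels: list[str]
    fs: float
    markers: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_samples, n_channels)")
        self.channels = [str(c) for c in self.channels]
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel labels for "
                f"{self.data.shape[1]} data columns"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        self.markers = [(float(t), int(g)) for t, g in self.markers]

    # ------------------------------------------------------------------ views

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None

    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D view."""
        return self.data[:, self.channel_index(label)]

    def with_data(self, data: np.ndarray) -> "SignalRecording":
        """Copy of this recording with ``data`` replaced (metadata kept)."""
        return replace(self, data=np.asarray(data, dtype=float))

    # --------------------------------------------------------------------- io

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write the samples as CSV; rate and markers go to a JSON sidecar.

        If ``sidecar`` is omitted it defaults to ``<path>.json``.
        """
        path = Path(path)
        pd.DataFrame(self.data, columns=self.channels).to_csv(path, index=False)
        sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(
            path.suffix + ".json"
        )
        meta = {"fs": self.fs, "markers": [[t, g] for t, g in self.markers]}
        sidecar.write_text(json.dumps(meta))

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        fs: float | None = None,
        sidecar: str | Path | None = None,
    ) -> "SignalRecording":
        """Load a recording written by :meth:`to_csv`.

        ``fs`` overrides the sidecar value; at least one of the two must
        provide the sampling rate.
        """
        path = Path(path)
        frame = pd.read_csv(path)
        markers: list[tuple[float, int]] = []
        candidate = Path(sidecar) if sidecar is not None else path.with_suffix(
            path.suffix + ".json"
        )
        if candidate.exists():
            meta = json.loads(candidate.read_text())
            markers = [(float(t), int(g)) for t, g in meta.get("markers", [])]
            if fs is None:
                fs = meta.get("fs")
        if fs is None:
            raise ValueError("sampling rate not given and no sidecar found")
        return cls(frame.to_numpy(dtype=float), list(frame.columns), float(fs), markers)
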
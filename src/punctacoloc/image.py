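"""Core in-memory container for one cell's multi-channel time-lapse image."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CellImage:
    """One cell's pixel data as a ``frames x channels x H x W`` float array.

    Attributes
    ----------
    data:
        Array of shape ``(T, C, H, W)``; integer input is widened to float64
        without changing values.
    channels:
        Channel labels, one per channel axis entry (unique).
    roi:
        Boolean whole-cell region-of-interest mask of shape ``(H, W)``.
        All normalizations and statistics are restricted to this mask.
    frame_interval:
        Minutes between consecutive frames (metadata only; the math is in
        frame indices).
    """

    data: np.ndarray
    channels: tuple[str, ...]
    roi: np.ndarray | None = None
    frame_interval: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"data must be (frames, channels, H, W); got shape {self.data.shape}"
            )
        if np.issubdtype(self.data.dtype, np.integer):
            self.data = self.data.astype(np.float64)
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {self.data.shape[1]} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.roi is not None:
            self.roi = np.asarray(self.roi, dtype=bool)
            if self.roi.shape != self.data.shape[2:]:
                raise ValueError("roi shape must match the image frame shape")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in {self.channels}"
            ) from None

    def frame(self, t: int, channel: str | int) -> np.ndarray:
        """Return one 2-D frame by frame index and channel label or index."""
        c = channel if isinstance(channel, int) else self.channel_index(channel)
        return self.data[t, c]

    def times(self) -> np.ndarray:
        """Frame times in minutes (frame_index * frame_interval)."""
        return np.arange(self.n_frames, dtype=float) * self.frame_interval
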
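"""In-memory container for a two-channel time-lapse movie."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np


@dataclass
class MovieStack:
    """Multi-frame two-channel intensity stack plus acquisition metadata.

    ``pixels`` has shape (frames, channels, H, W) and non-negative values.
    ``stimulation_frame`` is the 0-based index of the first post-stimulation
    frame; frame ``k`` is at time ``(k - stimulation_frame) *
    frame_interval_s`` seconds.  ``channel_roles`` maps the roles
    ``nuclear_dye`` and ``reporter`` to channel indices.
    """

    pixels: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    stimulation_frame: int
    channel_roles: Dict[str, int] = field(
        default_factory=lambda: {"nuclear_dye": 0, "reporter": 1}
    )

    def __post_init__(self) -> None:
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be (frames, channels, H, W)")
        if self.pixels.shape[0] < 2:
            raise ValueError("movie needs at least 2 frames")
        if self.stimulation_frame < 1:
            raise ValueError("at least one pre-stimulation frame is required")
        roles = set(self.channel_roles)
        if roles != {"nuclear_dye", "reporter"}:
            raise ValueError("channel_roles must map nuclear_dye and reporter")
        if self.channel_roles["nuclear_dye"] == self.channel_roles["reporter"]:
            raise ValueError("nuclear_dye and reporter must be distinct channels")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self):
        return self.pixels.shape[2:]

    def times_s(self) -> np.ndarray:
        """Frame times in seconds relative to stimulation."""
        return (
            np.arange(self.n_frames, dtype=float) - self.stimulation_frame
        ) * self.frame_interval_s

    def channel(self, role: str) -> np.ndarray:
        """(frames, H, W) view of the channel with the given role."""
        return self.pixels[:, self.channel_roles[role]]
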
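"""Shared data containers for blot scans and lane traces, plus TIFF I/O.

Coordinates are 0-based pixel indices; all windows are half-open
``[start, end)``. The migration axis runs along image rows, lanes along
columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import tifffile

__all__ = ["LaneProfile", "BlotImage"]


@dataclass
class LaneProfile:
    """1-D intensity trace along the migration axis for one lane.

    Parameters
    ----------
    positions
        Strictly increasing pixel indices along the migration axis.
    intensities
        Non-negative summed intensity at each position (same length).
    lane_id
        Identifier tying the trace back to a lane / sample.
    calibration
        Optional mapping from pixel position to apparent molecular
        weight (kDa); purely annotational.
    """

    positions: np.ndarray
    intensities: np.ndarray
    lane_id: str = ""
    calibration: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.positions.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("positions and intensities must be 1-D")
        if len(self.positions) != len(self.intensities):
            raise ValueError("positions and intensities differ in length")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class BlotImage:
    """Grayscale scan of a (simulated or real) film with lane geometry.

    ``pixels`` has shape ``(migration_axis_length, n_columns)`` in
    arbitrary linear intensity units. ``lanes`` maps lane_id to the
    half-open column span occupied by that lane.
    """

    pixels: np.ndarray
    lanes: dict[str, tuple[int, int]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        ncol = self.pixels.shape[1]
        for lane_id, (a, b) in self.lanes.items():
            if not (0 <= a < b <= ncol):
                raise ValueError(f"lane {lane_id!r} span ({a}, {b}) outside image")

    @property
    def lane_ids(self) -> list[str]:
        return list(self.lanes)

    def save_tiff(self, path, gain: float = 1.0) -> None:
        """Write as 16-bit grayscale TIFF; lane metadata goes into the
        image description as JSON. Intensities are scaled by ``gain``,
        rounded and clipped to the uint16 range."""
        scaled = np.clip(np.rint(self.pixels * gain), 0, 65535).astype(np.uint16)
        desc = json.dumps(
            {"lanes": {k: list(v) for k, v in self.lanes.items()}, "gain": gain}
        )
        tifffile.imwrite(path, scaled, description=desc, photometric="minisblack")

    @classmethod
    def load_tiff(cls, path) -> "BlotImage":
        """Read a TIFF written by :meth:`save_tiff` (or any grayscale
        TIFF; lane metadata then defaults to one full-width lane)."""
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            pixels = page.asarray().astype(np.float64)
            desc = page.description or ""
        lanes: dict[str, tuple[int, int]] = {}
        gain = 1.0
        if desc:
            try:
                parsed = json.loads(desc)
                lanes = {k: (int(a), int(b)) for k, (a, b) in parsed["lanes"].items()}
                gain = float(parsed.get("gain", 1.0))
            except (ValueError, KeyError, TypeError):
                pass
        if not lanes:
            lanes = {"lane0": (0, pixels.shape[1])}
        if gain != 1.0:
            pixels = pixels / gain
        return cls(pixels=pixels, lanes=lanes, meta={"source": str(path)})
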
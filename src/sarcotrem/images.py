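"""Calibrated single-channel images and their TIFF + JSON-sidecar I/O.

A :class:`StriatedImage` is the unit of image scoring: a 2-D nonnegative
intensity field with a pixel size in micrometres and a channel label
(``alpha_actinin`` marks Z-disks, ``smybpc`` marks C-zones).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import CalibrationError

CHANNELS = ("alpha_actinin", "smybpc")


@dataclass
class StriatedImage:
    """A calibrated fluorescence image of striated muscle.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Nonnegative intensities. Stored as float64; the nominal dynamic
        range after generation/loading is [0, 1] plus noise.
    pixel_size_um : float
        Physical size of one pixel edge, micrometres.
    channel : str
        ``"alpha_actinin"`` or ``"smybpc"``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = "alpha_actinin"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if not (self.pixel_size_um > 0):
            raise CalibrationError("pixel_size_um must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height_um(self) -> float:
        return self.shape[0] * self.pixel_size_um

    @property
    def width_um(self) -> float:
        return self.shape[1] * self.pixel_size_um

    @property
    def area_um2(self) -> float:
        """Field area in square micrometres."""
        return self.height_um * self.width_um

    # ------------------------------------------------------------------ I/O
    def to_tiff(self, path: str | Path) -> Path:
        """Write a 16-bit TIFF plus a JSON sidecar with the calibration.

        Intensities are clipped to [0, 1] and scaled to the full 16-bit
        range. The sidecar ``<stem>.json`` carries ``pixel_size_um``,
        ``channel`` and any ``meta`` entries (e.g. ground truth).
        """
        path = Path(path)
        scaled = np.clip(self.pixels, 0.0, 1.0)
        tifffile.imwrite(path, (scaled * 65535).round().astype(np.uint16))
        sidecar = {
            "pixel_size_um": self.pixel_size_um,
            "channel": self.channel,
            **self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        pixel_size_um: float | None = None,
        channel: str | None = None,
    ) -> "StriatedImage":
        """Read a single-channel TIFF; calibration from argument or sidecar."""
        path = Path(path)
        pixels = tifffile.imread(path).astype(float)
        if pixels.dtype.kind != "f":
            pixels = pixels.astype(float)
        if pixels.max() > 0:
            pixels = pixels / pixels.max()
        meta: dict = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        if pixel_size_um is None:
            pixel_size_um = meta.get("pixel_size_um")
        if pixel_size_um is None:
            raise CalibrationError(
                f"no pixel size given and no sidecar found for {path}"
            )
        if channel is None:
            channel = meta.get("channel", "alpha_actinin")
        return cls(pixels, float(pixel_size_um), channel, meta=meta)
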
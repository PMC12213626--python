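"""Core image container for a single OCT B-scan."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BScan"]


@dataclass
class BScan:
    """A 2-D OCT cross-section (rows = depth, columns = A-scans).

    Parameters
    ----------
    data
        Intensity grid, shape ``(n_rows, n_ascans)``.  Row 0 is the
        vitreous side (closest to the instrument).
    axial_pitch_um
        Micrometers of depth per pixel row.
    lateral_pitch_um
        Micrometers per A-scan column.
    scale
        ``"linear"`` if pixel values are proportional to signal power,
        ``"log"`` for display-compressed images.
    meta
        Free-form metadata (display-compression parameters, provenance).
    """

    data: np.ndarray
    axial_pitch_um: float = 1.7
    lateral_pitch_um: float = 1.4
    scale: str = "linear"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BScan data must be 2-D (rows x A-scans)")
        if self.axial_pitch_um <= 0 or self.lateral_pitch_um <= 0:
            raise ValueError("pixel pitches must be positive")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.data.shape[1]

    @property
    def width_mm(self) -> float:
        return self.n_ascans * self.lateral_pitch_um / 1000.0
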
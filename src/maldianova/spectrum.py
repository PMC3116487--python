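"""The Spectrum container and its processing-stage state machine."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class Stage(enum.IntEnum):
    """Pre-processing stages, in the only order they may be applied."""

    RAW = 0
    LOGGED = 1
    SMOOTHED = 2
    BASELINED = 3
    ALIGNED = 4


@dataclass
class Spectrum:
    """One acquisition's intensity trace on a shared m/z axis.

    ``axis`` is strictly increasing m/z; ``intensities`` has the same
    length.  ``stage`` only moves forward through :class:`Stage`.
    """

    spectrum_id: str
    axis: np.ndarray
    intensities: np.ndarray
    stage: Stage = Stage.RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.axis.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("axis and intensities must be 1-D")
        if len(self.axis) != len(self.intensities):
            raise ValueError("axis/intensity length mismatch")
        if len(self.axis) > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("m/z axis must be strictly increasing")

    def __len__(self) -> int:
        return len(self.axis)

    def advanced(self, intensities: np.ndarray, stage: Stage) -> "Spectrum":
        """Return a copy at the next stage; transitions must move forward."""
        if stage <= self.stage:
            raise ValueError(
                f"stage may only advance ({self.stage.name} -> {stage.name})"
            )
        return Spectrum(self.spectrum_id, self.axis, intensities,
                        stage, dict(self.meta))
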
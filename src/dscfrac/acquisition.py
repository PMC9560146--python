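"""Acquisition metadata for dynamic susceptibility contrast (DSC) series.

Defaults follow a 3T gradient-echo EPI perfusion protocol: TE 20 ms,
TR 1.71 s, 45 dynamic frames (~90 s), 4 mm slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class AcquisitionParams:
    """Scanner settings of a DSC acquisition.

    Parameters
    ----------
    te : float
        Echo time in seconds. Converts signal drop to ΔR2*.
    tr : float
        Repetition time in seconds; the dynamic frame spacing.
    n_timepoints : int
        Number of dynamic frames.
    voxel_size : tuple of float
        (dx, dy, dz) voxel edge lengths in mm.
    baseline_points : int
        Number of pre-bolus frames expected before contrast arrival.
    """

    te: float = 0.020
    tr: float = 1.71
    n_timepoints: int = 45
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 4.0)
    baseline_points: int = 8

    def __post_init__(self) -> None:
        if self.te <= 0:
            raise ValueError(f"te must be positive, got {self.te}")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.baseline_points < 1:
            raise ValueError("baseline_points must be >= 1")
        if self.n_timepoints < self.baseline_points + 10:
            raise ValueError(
                "n_timepoints must leave at least 10 post-baseline frames "
                f"(got {self.n_timepoints} with {self.baseline_points} baseline)"
            )

    @property
    def time_grid(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_timepoints) * self.tr

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world (RAS, mm) transform implied by the voxel size."""
        aff = np.diag((*self.voxel_size, 1.0))
        return aff
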
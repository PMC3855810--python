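"""Dbh-based allometry: tree height and crown geometry.

Height follows a power law of dbh capped at the canopy height,
``h = min(h0 * dbh_cm**h1, cap)``; crown radius is a power law of dbh and
crown depth a fixed fraction of height.  Coefficients are configurable —
the defaults are generic tropical-forest values chosen for the synthetic
stand, not fitted to any particular site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AllometryConfig:
    """Height and crown models as functions of dbh.

    height (m) = min(h0 * dbh_cm**h1, canopy_height_cap)
    crown radius (m) = r0 * dbh_cm**r1
    crown depth (m) = crown_depth_frac * height
    """

    h0: float = 3.0
    h1: float = 0.6
    canopy_height_cap: float = 33.0
    r0: float = 0.5
    r1: float = 0.6
    crown_depth_frac: float = 0.3

    def __post_init__(self) -> None:
        if self.h0 <= 0 or self.r0 <= 0 or self.canopy_height_cap <= 0:
            raise ValueError("allometry coefficients must be positive")
        if not 0 < self.crown_depth_frac <= 1:
            raise ValueError("crown depth fraction must be in (0, 1]")

    def height(self, dbh_mm) -> np.ndarray:
        """Tree height in m from dbh in mm."""
        dbh_cm = np.asarray(dbh_mm, dtype=float) / 10.0
        return np.minimum(self.h0 * dbh_cm**self.h1, self.canopy_height_cap)

    def crown_radius(self, dbh_mm) -> np.ndarray:
        dbh_cm = np.asarray(dbh_mm, dtype=float) / 10.0
        return self.r0 * dbh_cm**self.r1

    def crown_extent(self, dbh_mm) -> tuple[np.ndarray, np.ndarray]:
        """(crown bottom, crown top) heights in m."""
        top = self.height(dbh_mm)
        return top * (1.0 - self.crown_depth_frac), top
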
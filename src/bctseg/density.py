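"""Stage 3: HU-derived volumetric breast density.

The reference ("HU-derived") breast density is the linear interpolation
of the mean HU of the cleaned breast soft tissue between the pure
adipose and pure glandular reference values:

    d = (mean_HU(mask) - HU_fat) / (HU_gland - HU_fat)

clipped to [0, 1].  The breast mask excludes skin, muscle, skinfold,
hard components and air.  The error rate between a segmentation-based
density and this reference is the signed percentage-point difference
100 * (seg - ref).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationTable
from .core_io import Volume

__all__ = ["DensityReport", "hu_derived_density", "density_error_rate"]


@dataclass
class DensityReport:
    hu_derived_density: float
    seg_based_density: float
    error_rate: float  # percentage points, seg - reference
    component_volumes_ml: dict[str, float] = field(default_factory=dict)
    bias_audit: dict[str, float] | None = None
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "hu_derived_density": self.hu_derived_density,
            "seg_based_density": self.seg_based_density,
            "error_rate": self.error_rate,
            "component_volumes_ml": self.component_volumes_ml,
            "bias_audit": self.bias_audit,
            "flags": self.flags,
        }


def hu_derived_density(v: Volume, breast_mask: np.ndarray, cal: CalibrationTable) -> float:
    """Linear-interpolation density of the breast soft tissue, in [0, 1]."""
    if not breast_mask.any():
        raise ValueError("empty breast mask")
    hu_fat, hu_gland = cal.mean("fat"), cal.mean("gland")
    if hu_gland == hu_fat:
        raise ValueError("degenerate calibration: HU_gland equals HU_fat")
    mean_hu = float(v.data[breast_mask].mean())
    d = (mean_hu - hu_fat) / (hu_gland - hu_fat)
    return float(np.clip(d, 0.0, 1.0))


def density_error_rate(seg_density: float, ref_density: float) -> float:
    """Signed percentage-point difference of the two density estimates."""
    return 100.0 * (seg_density - ref_density)
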
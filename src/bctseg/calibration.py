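"""Per-component Hounsfield-unit calibration.

The segmentation framework never hard-codes HU thresholds: every stage
derives its thresholds from a :class:`CalibrationTable` holding the mean
and standard deviation of each breast component's HU distribution.  The
table can be fitted from a labeled scan (median filtering to suppress
partial-volume voxels, threshold-based exclusion band for the fat/gland
split, then per-component mean/SD/CV), or loaded from a YAML config.

The default table ships with literature-typical breast-CT values; the
coefficient of variation is reported as cv = sd / (mean - offset) with
the offset anchored at air (-1000 HU) so the denominator is a positive
attenuation-like scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage as ndi

from .core_io import Volume, LabelMap

__all__ = [
    "ComponentStats",
    "CalibrationTable",
    "DEFAULT_CALIBRATION",
    "default_calibration",
    "suppress_partial_volume",
    "pure_tissue_histogram",
    "fit_calibration",
]

#: voxels below this count give a low-confidence (but not fatal) fit
MIN_FIT_VOXELS = 100


@dataclass
class ComponentStats:
    mean_hu: float
    sd_hu: float
    n_voxels: int | None = None
    low_confidence: bool = False


@dataclass
class CalibrationTable:
    """HU mean/SD per component plus the CV offset.

    ``components`` maps component names (lower-case, as in
    :data:`bctseg.core_io.COMPONENT_CODES`) to :class:`ComponentStats`.
    ``air`` is always present so that soft-tissue/air thresholds can be
    derived by the same mean-of-neighbors rule as tissue/tissue ones.
    """

    components: dict[str, ComponentStats] = field(default_factory=dict)
    offset_hu: float = -1000.0

    def __post_init__(self) -> None:
        for stats in self.components.values():
            if stats.sd_hu <= 0:
                raise ValueError("sd_hu must be positive")
        if "fat" in self.components and "gland" in self.components:
            if not self.mean("fat") < self.mean("gland"):
                raise ValueError("fat must be radiolucent relative to gland")

    def has(self, component: str) -> bool:
        return component in self.components

    def mean(self, component: str) -> float:
        if component not in self.components:
            raise KeyError(f"component {component!r} unavailable in calibration table")
        return self.components[component].mean_hu

    def sd(self, component: str) -> float:
        if component not in self.components:
            raise KeyError(f"component {component!r} unavailable in calibration table")
        return self.components[component].sd_hu

    def cv(self, component: str) -> float:
        """Coefficient of variation, cv = sd / (mean - offset)."""
        return self.sd(component) / (self.mean(component) - self.offset_hu)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "offset_hu": self.offset_hu,
            "components": {
                name: {
                    "mean_hu": float(s.mean_hu),
                    "sd_hu": float(s.sd_hu),
                    "n_voxels": s.n_voxels,
                    "low_confidence": bool(s.low_confidence),
                }
                for name, s in self.components.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CalibrationTable":
        doc = yaml.safe_load(Path(path).read_text())
        comps = {
            name: ComponentStats(
                mean_hu=float(c["mean_hu"]),
                sd_hu=float(c["sd_hu"]),
                n_voxels=c.get("n_voxels"),
                low_confidence=bool(c.get("low_confidence", False)),
            )
            for name, c in doc["components"].items()
        }
        return cls(components=comps, offset_hu=float(doc.get("offset_hu", -1000.0)))


def default_calibration() -> CalibrationTable:
    """Literature-typical breast-CT HU table (the shipped default)."""
    return CalibrationTable(
        components={
            "air": ComponentStats(-1000.0, 5.0),
            "fat": ComponentStats(-150.0, 15.0),
            "gland": ComponentStats(30.0, 20.0),
            "skin": ComponentStats(20.0, 25.0),
            "muscle": ComponentStats(45.0, 25.0),
            "skinfold": ComponentStats(-150.0, 15.0),
            "rib": ComponentStats(450.0, 80.0),
            "implant": ComponentStats(120.0, 15.0),
        },
        offset_hu=-1000.0,
    )


DEFAULT_CALIBRATION = default_calibration()


def suppress_partial_volume(v: Volume) -> Volume:
    """3x3x3 volumetric median filter suppressing mixed-tissue HU signals.

    Edge voxels use reflected padding.  The median never widens the data
    range, so min/max of the output are within those of the input.
    """
    filtered = ndi.median_filter(v.data, size=3, mode="reflect")
    return Volume(data=filtered, spacing_mm=v.spacing_mm)


def pure_tissue_histogram(
    v: Volume,
    threshold: float,
    cal: CalibrationTable | None = None,
    mask: np.ndarray | None = None,
    band_hu: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split (already median-filtered) breast tissue into pure fat / gland HU samples.

    Voxels within ``band_hu`` of ``threshold`` are partial-volume mixtures
    and are dropped; the remainder splits at the threshold into the fat
    (below) and gland (above) samples.  ``band_hu`` defaults to
    0.5 * min(sd_fat, sd_gland) of the calibration table.

    Returns the two 1D arrays of retained HU values.
    """
    cal = cal if cal is not None else DEFAULT_CALIBRATION
    if not (cal.mean("fat") < threshold < cal.mean("gland")):
        raise ValueError(
            f"threshold {threshold} must lie strictly between the fat "
            f"({cal.mean('fat')}) and gland ({cal.mean('gland')}) means"
        )
    if band_hu is None:
        band_hu = 0.5 * min(cal.sd("fat"), cal.sd("gland"))
    values = v.data[mask] if mask is not None else v.data.ravel()
    keep = np.abs(values - threshold) > band_hu
    values = values[keep]
    return values[values < threshold], values[values >= threshold]


def fit_calibration(
    v: Volume,
    l: LabelMap,
    offset_hu: float = -1000.0,
    band_hu: float | None = None,
) -> CalibrationTable:
    """Derive a calibration table from a labeled volume.

    Skin, muscle, rib, implant and skinfold statistics come directly from
    their labeled regions.  Fat and gland statistics come from the
    median-filtered breast soft tissue via :func:`pure_tissue_histogram`,
    which drops the partial-volume band around the fat/gland midpoint.
    Components absent from the label map are left out of the table
    (marked unavailable); components with fewer than 100 voxels are
    flagged low-confidence.
    """
    if v.shape != l.shape:
        raise ValueError("volume and label map shapes differ")
    comps: dict[str, ComponentStats] = {}

    def _stats(values: np.ndarray) -> ComponentStats | None:
        n = values.size
        if n == 0:
            return None
        return ComponentStats(
            mean_hu=float(values.mean()),
            sd_hu=float(max(values.std(), 1e-6)),
            n_voxels=int(n),
            low_confidence=n < MIN_FIT_VOXELS,
        )

    for name in ("air", "skin", "muscle", "rib", "implant", "skinfold"):
        s = _stats(v.data[l.mask(name)])
        if s is not None:
            comps[name] = s

    breast = l.mask("fat", "gland")
    if breast.any():
        filtered = suppress_partial_volume(v)
        fat0 = filtered.data[l.mask("fat")]
        gland0 = filtered.data[l.mask("gland")]
        if fat0.size and gland0.size:
            midpoint = 0.5 * (float(fat0.mean()) + float(gland0.mean()))
            if band_hu is None:
                band_hu = 0.5 * min(
                    max(float(fat0.std()), 1e-6), max(float(gland0.std()), 1e-6)
                )
            # volume-effect exclusion: besides the band around the split
            # threshold, drop voxels whose filtered neighborhood spans a
            # large HU range - their median mixes the two tissues and is
            # biased toward the neighboring mode
            local_range = ndi.maximum_filter(
                filtered.data, size=3, mode="reflect"
            ) - ndi.minimum_filter(filtered.data, size=3, mode="reflect")
            span = float(gland0.mean()) - float(fat0.mean())
            pure = local_range < 0.5 * span
            vals = filtered.data[breast & pure]
            keep = np.abs(vals - midpoint) > band_hu
            vals = vals[keep]
            fat_s = _stats(vals[vals < midpoint])
            gland_s = _stats(vals[vals >= midpoint])
        else:
            fat_s = _stats(filtered.data[l.mask("fat")])
            gland_s = _stats(filtered.data[l.mask("gland")])
        if fat_s is not None:
            comps["fat"] = fat_s
        if gland_s is not None:
            comps["gland"] = gland_s

    return CalibrationTable(components=comps, offset_hu=offset_hu)
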
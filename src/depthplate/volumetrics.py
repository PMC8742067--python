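"""Volume integration and intake accounting.

Food volume is the Riemann sum of per-pixel differential volumes over the
food mask, V = sum_{i in F} (delta_x)^2 * h_i, with delta_x the plate-derived
lateral scale in mm/px and h_i the food height in mm; mm^3 convert to mL by
dividing by 1000.  Intake is the difference between the full-portion plate
volume and the current plate volume, and percent intake is that difference
relative to the full portion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .calibration import HeightMap
from .errors import ShapeMismatch, ZeroReference


@dataclass(frozen=True)
class IntakeReport:
    """Per-plate intake summary, the pipeline's end product."""

    plate_id: str
    portion: str
    plate_volume_ml: float
    full_portion_volume_ml: float | None = None
    mask_source: str = "color"
    refined: bool = True

    @property
    def intake_ml(self) -> float | None:
        if self.full_portion_volume_ml is None:
            return None
        return intake_volume(self.full_portion_volume_ml, self.plate_volume_ml)

    @property
    def intake_percent(self) -> float | None:
        if self.full_portion_volume_ml is None:
            return None
        return percent_intake(self.full_portion_volume_ml, self.plate_volume_ml)

    def to_dict(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "portion": self.portion,
            "plate_volume_ml": self.plate_volume_ml,
            "full_portion_volume_ml": self.full_portion_volume_ml,
            "intake_ml": self.intake_ml,
            "intake_percent": self.intake_percent,
            "mask_source": self.mask_source,
            "refined": self.refined,
        }


def food_volume(
    h: HeightMap | np.ndarray,
    mask: np.ndarray,
    scale_mm_per_px: float,
    clamp_negative: bool = False,
) -> float:
    """Integrate masked heights into a volume in mL.

    Negative heights (depth noise below the plate) are included by default
    so zero-mean noise cancels; ``clamp_negative`` floors them at 0 for
    heavily reflective surfaces.  Invalid (NaN) pixels contribute nothing.
    """
    values = h.values if isinstance(h, HeightMap) else np.asarray(h, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ShapeMismatch(f"heights {values.shape} vs mask {mask.shape}")
    if scale_mm_per_px <= 0:
        raise ValueError("scale_mm_per_px must be positive")
    sel = values[mask]
    sel = sel[np.isfinite(sel)]
    if clamp_negative:
        sel = np.maximum(sel, 0.0)
    return float(scale_mm_per_px**2 * sel.sum() / 1000.0)


def intake_volume(full_ml: float, current_ml: float) -> float:
    """full - current; negative values are kept but flagged as noise inversion."""
    diff = full_ml - current_ml
    if diff < 0:
        warnings.warn(
            f"negative intake ({diff:.2f} mL): current portion estimated larger "
            "than the full portion (estimation noise inversion)",
            stacklevel=2,
        )
    return diff


def percent_intake(full_ml: float, current_ml: float) -> float:
    """100 * (full - current) / full."""
    if full_ml <= 0:
        raise ZeroReference("full-portion volume must be positive")
    return 100.0 * (full_ml - current_ml) / full_ml
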
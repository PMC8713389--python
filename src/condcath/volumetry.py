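"""Radius-to-volume conversion and equivalent circular radius.

Two ventricular volume models are provided: the Wyatt model
``LVV = (5/6)*pi*R^2*LV_h`` (an ellipsoid-like correction applied when the
radius is measured at the ventricle's centre) and the plain cylindrical model
``pi*R^2*L`` used with the classical Wei method.  Volumes are returned in mL
from mm inputs.

For non-circular reference cross-sections (CT-derived phantom slices) the
reference radius is the equivalent circular radius ``sqrt(A/pi)`` of the
measured area.
"""

from __future__ import annotations

import math

__all__ = ["wyatt_volume", "cylinder_volume", "equivalent_radius_from_area"]

_MM3_PER_ML = 1000.0


def wyatt_volume(R: float, LV_h: float) -> float:
    """Wyatt ventricular volume (mL): ``(5/6)*pi*R^2*LV_h`` with mm inputs."""
    if R < 0:
        raise ValueError(f"radius must be non-negative, got {R}")
    if LV_h <= 0:
        raise ValueError(f"ventricle height must be positive, got {LV_h}")
    return (5.0 / 6.0) * math.pi * R * R * LV_h / _MM3_PER_ML


def cylinder_volume(R: float, L: float) -> float:
    """Cylindrical segment volume (mL): ``pi*R^2*L`` with mm inputs."""
    if R < 0:
        raise ValueError(f"radius must be non-negative, got {R}")
    if L <= 0:
        raise ValueError(f"segment length must be positive, got {L}")
    return math.pi * R * R * L / _MM3_PER_ML


def equivalent_radius_from_area(A: float) -> float:
    """Equivalent circular radius (mm) of a cross-sectional area (mm^2)."""
    if A < 0:
        raise ValueError(f"area must be non-negative, got {A}")
    return math.sqrt(A / math.pi)
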
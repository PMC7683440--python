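"""Derived tree-hollow habitat variables.

Veteran-tree surveys record raw measurements (cavity depth, entrance
dimensions, ring widths, core ages).  The functions here turn those into the
analysis variables: wood-mould volume, entrance area, the 12-category
entrance-direction score, projected diameters and geometric-mean volumes.

Units are explicit in every name: lengths in cm, areas in cm**2, volumes in
dm**3, angles in degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field


class InvalidMeasurementError(ValueError):
    """A raw field measurement is outside its physical domain."""


def wood_mould_volume(depth_cm: float, surface_cm2: float) -> float:
    """Approximate wood-mould volume in a hollow, in dm**3.

    The cavity is treated as a cone standing on the mould surface:
    ``V = depth * S / 3`` (cm**3), converted to dm**3.

    Parameters
    ----------
    depth_cm : depth of the cavity measured from the mould surface.
    surface_cm2 : area of the mould surface.
    """
    if depth_cm < 0 or surface_cm2 < 0:
        raise InvalidMeasurementError(
            f"depth and surface must be non-negative, got depth={depth_cm}, "
            f"surface={surface_cm2}"
        )
    return depth_cm * surface_cm2 / 3.0 / 1000.0


#: shape label -> (number of dimensions, area function on full widths)
_AREA_FORMULAS = {
    "circle": (1, lambda d: math.pi * d * d / 4.0),
    "ellipse": (2, lambda a, b: math.pi * a * b / 4.0),
    "rectangle": (2, lambda w, h: w * h),
    "triangle": (2, lambda b, h: b * h / 2.0),
}


def entrance_area(shape: str, *dims: float) -> float:
    """Area (cm**2) of an entrance hole measured as the shape it resembles.

    ``dims`` are full widths: diameter for a circle, the two axes for an
    ellipse, width x height for a rectangle, base x height for a triangle.
    """
    try:
        arity, formula = _AREA_FORMULAS[shape]
    except KeyError:
        raise InvalidMeasurementError(
            f"unknown shape {shape!r}; expected one of {sorted(_AREA_FORMULAS)}"
        ) from None
    if len(dims) != arity:
        raise InvalidMeasurementError(
            f"shape {shape!r} takes {arity} dimension(s), got {len(dims)}"
        )
    if any(d <= 0 for d in dims):
        raise InvalidMeasurementError(f"dimensions must be positive, got {dims}")
    return formula(*dims)


def direction_category(angle_deg: float) -> int:
    """Score an entrance direction by its angular distance from due south.

    The circle is divided into 24 sectors of 15 deg; sectors equidistant from
    south (180 deg) on the east and west side share a score, giving 12
    categories: 1 = most southerly pair, 12 = most northerly.  Equivalent to
    ``floor(|angle - 180| / 15) + 1`` clamped to 12, which is symmetric about
    the north-south axis by construction.

    Angles outside [0, 360) are normalised modulo 360 with a warning.
    """
    if not math.isfinite(angle_deg):
        raise InvalidMeasurementError(f"angle must be finite, got {angle_deg}")
    if not 0.0 <= angle_deg < 360.0:
        warnings.warn(
            f"angle {angle_deg} outside [0, 360); normalising modulo 360",
            stacklevel=2,
        )
        angle_deg = angle_deg % 360.0
    dist_from_south = abs(angle_deg - 180.0)
    return min(12, int(dist_from_south // 15.0) + 1)


def canopy_class(cover_pct: float) -> int:
    """Canopy-cover class: <25% -> 0, 25-75% -> 1, >75% -> 2 (bounds in 1)."""
    if not 0.0 <= cover_pct <= 100.0:
        raise InvalidMeasurementError(f"cover percentage out of range: {cover_pct}")
    if cover_pct < 25.0:
        return 0
    if cover_pct <= 75.0:
        return 1
    return 2


def project_diameter(d_start_cm: float, ring_width_cm: float, years: int = 18) -> float:
    """Project a stem diameter forward by radial growth.

    Adds ``2 * years * ring_width`` (two radii per year of growth); the
    default interval is the 18 years between the two measurement campaigns.
    ``ring_width_cm`` must be in cm — convert mm ring measurements first.
    """
    if d_start_cm < 0 or ring_width_cm < 0:
        raise InvalidMeasurementError("diameter and ring width must be >= 0")
    return d_start_cm + 2.0 * years * ring_width_cm


def age_from_core(core_age: float, years_since_coring: int = 14) -> float:
    """Tree age at the final survey from a core collected earlier.

    Default offset is 14 years (cores collected in 2005, final survey 2019).
    """
    if core_age < 0:
        raise InvalidMeasurementError("core age must be >= 0")
    return core_age + years_since_coring


def geometric_mean_volume(v_first: float | None, v_second: float | None) -> float:
    """Geometric mean of two wood-mould volume measurements.

    One missing value (None or NaN) passes the other through; both missing is
    an error.
    """

    def _missing(v):
        return v is None or (isinstance(v, float) and math.isnan(v))

    m1, m2 = _missing(v_first), _missing(v_second)
    if m1 and m2:
        raise InvalidMeasurementError("both volume measurements are missing")
    if m1:
        v = v_second
    elif m2:
        v = v_first
    else:
        if v_first < 0 or v_second < 0:
            raise InvalidMeasurementError("volumes must be >= 0")
        return math.sqrt(v_first * v_second)
    if v < 0:
        raise InvalidMeasurementError("volumes must be >= 0")
    return float(v)


@dataclass
class TreeAttributes:
    """Per-tree habitat variables entering the turnover models."""

    canopy_class: int
    entrance_direction_deg: float
    direction_category: int
    entrance_height_cm: float
    entrance_size_cm2: float
    alive: bool
    age_years: float
    diameter_cm: float
    wood_mould_dm3: float
    connectivity_m: float = field(default=float("nan"))
    n_possible_occasions: int = field(default=0)

    def __post_init__(self) -> None:
        if not 1 <= self.direction_category <= 12:
            raise InvalidMeasurementError(
                f"direction category out of range: {self.direction_category}"
            )
        if self.canopy_class not in (0, 1, 2):
            raise InvalidMeasurementError(f"canopy class invalid: {self.canopy_class}")
        for name in ("entrance_height_cm", "entrance_size_cm2", "diameter_cm",
                     "wood_mould_dm3"):
            if getattr(self, name) < 0:
                raise InvalidMeasurementError(f"{name} must be >= 0")
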
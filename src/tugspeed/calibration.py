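"""Planar pixel-to-metre calibration from four scene markers.

Two markers on the floor span the 3 m walkway (horizontal scale), two
markers beside the chair span a known 0.5 m vertical distance (vertical
scale).  The calibration is a linear two-point model per axis: no lens
distortion, no perspective.
"""

from __future__ import annotations

from dataclasses import dataclass

from tugspeed.errors import CalibrationDegenerateError, InvalidParameterError

__all__ = ["MarkerSet", "CalibrationModel", "build_calibration", "pixel_to_world"]


@dataclass(frozen=True)
class MarkerSet:
    """Pixel coordinates of the four calibration markers.

    Parameters
    ----------
    m1_px, m2_px
        Walkway markers ``(u, v)`` in pixels.  ``m2_px`` is the chair-side
        (start-of-walkway) marker and becomes the world-x origin; ``m1_px``
        is the far marker at the turn mark.
    m3_px, m4_px
        Vertical-scale markers ``(u, v)``: ``m3_px`` on the floor (world
        y = 0), ``m4_px`` a known height above it.
    dist_x_m, dist_y_m
        True metric separations of the marker pairs (default 3.0 m and
        0.5 m).
    """

    m1_px: tuple[float, float]
    m2_px: tuple[float, float]
    m3_px: tuple[float, float]
    m4_px: tuple[float, float]
    dist_x_m: float = 3.0
    dist_y_m: float = 0.5


@dataclass(frozen=True)
class CalibrationModel:
    """Per-axis metre-per-pixel scale plus the world origin in pixels.

    ``x_sign`` is +1 when pixel columns grow from the chair toward the turn
    mark and -1 for a mirrored camera, so world x always increases along the
    outbound walk.
    """

    one_pixel_x_m: float
    one_pixel_y_m: float
    origin_u_px: float
    floor_v_px: float
    x_sign: float = 1.0


def build_calibration(markers: MarkerSet) -> CalibrationModel:
    """Derive the two-axis linear calibration from the marker pixels.

    The horizontal scale is ``dist_x_m`` divided by the absolute pixel-column
    separation of the walkway markers; the vertical scale is ``dist_y_m``
    divided by the absolute pixel-row separation of the chair markers.
    Absolute separations make the model independent of camera left/right
    orientation.

    Raises
    ------
    InvalidParameterError
        If a world distance is not strictly positive.
    CalibrationDegenerateError
        If a marker pair coincides along its scaling axis.
    """
    if markers.dist_x_m <= 0 or markers.dist_y_m <= 0:
        raise InvalidParameterError(
            f"marker world distances must be positive, got "
            f"dist_x_m={markers.dist_x_m}, dist_y_m={markers.dist_y_m}"
        )
    du = abs(markers.m2_px[0] - markers.m1_px[0])
    dv = abs(markers.m4_px[1] - markers.m3_px[1])
    if du == 0:
        raise CalibrationDegenerateError("walkway markers share a pixel column (zero x baseline)")
    if dv == 0:
        raise CalibrationDegenerateError("vertical markers share a pixel row (zero y baseline)")
    return CalibrationModel(
        one_pixel_x_m=markers.dist_x_m / du,
        one_pixel_y_m=markers.dist_y_m / dv,
        origin_u_px=markers.m2_px[0],
        floor_v_px=markers.m3_px[1],
        x_sign=1.0 if markers.m1_px[0] >= markers.m2_px[0] else -1.0,
    )


def pixel_to_world(u_px, v_px, model: CalibrationModel):
    """Map image coordinates to walkway coordinates in metres.

    World x grows from the chair (0 m) toward the turn mark; world y grows
    upward from the floor (image rows grow downward).  Accepts scalars or
    arrays and extrapolates freely beyond the markers.
    """
    x_m = (u_px - model.origin_u_px) * model.one_pixel_x_m * model.x_sign
    y_m = (model.floor_v_px - v_px) * model.one_pixel_y_m
    return x_m, y_m
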
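"""Geometric core: the carpal tunnel as a truncated cone (frustum).

The carpal tunnel is modelled as a frustum of height ``L`` (the tunnel
length, mm) whose inlet radius ``r2`` (scaphoid–pisiform level) is fixed
and whose outlet radius ``r1`` (trapezium–hamate-hook level) depends on
the curvature angle ``alpha`` of the hook of the hamate.  The law of
cosines applied to the hook geometry collapses into the single relation

    r1(alpha) = sqrt(B * (1 - cos alpha)) / 2

where ``B`` (mm^2) is a constant calibrated once from a reference
measurement (r1_0, alpha_0).  Tunnel volume then follows the frustum
closed form

    V = (1/3) * pi * L * (r1^2 + r1*r2 + r2^2).

Two deliberate numeric conventions, both configurable, mirror the source
measurement protocol this package emulates:

* pi enters the *volume* formula as the rounded literal 3.14
  (``pi_volume``), while radian conversion and area<->radius conversion
  use full-precision ``math.pi``;
* the cosine of the reference angle is rounded to 3 decimals before
  calibration, and the calibrated B is truncated (not rounded) to
  2 decimals — the convention under which the published reference sweep
  is exactly reproducible.

Units are mm / mm^2 / mm^3 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Union

import pandas as pd

__all__ = [
    "FrustumModel",
    "Calibration",
    "CrossSection",
    "VolumeTableRow",
    "degrees_to_radians",
    "area_to_radius",
    "calibrate_b",
    "outlet_radius",
    "frustum_volume",
    "generate_volume_table",
    "table_to_dataframe",
    "write_volume_table_csv",
    "default_calibration",
    "default_volume_table",
    "DEFAULTS",
]

#: Reference model inputs: outlet area A1 and inlet area A2 (mm^2),
#: tunnel length L (mm), reference hook angle (deg), reference outlet
#: radius r1_0 (mm, as printed from A1), inlet radius r2 (mm, as printed
#: from A2), the pi convention of the volume formula, and the sweep grid.
DEFAULTS = {
    "A1": 216.0,
    "A2": 304.0,
    "L": 19.4,
    "alpha0_deg": 98.0,
    "r1_0": 8.29,
    "r2": 9.8369,
    "pi_volume": 3.14,
    "cos_decimals": 3,
    "b_decimals": 2,
    "alpha_start": 98.0,
    "alpha_end": 140.0,
    "step": 2.0,
}

#: Sentinel accepted wherever a decimals argument may disable rounding.
FULL = "full"

_DecimalSpec = Union[int, str]


def _check_angle_domain(alpha_deg: float, name: str = "alpha_deg") -> None:
    # Curvature angles live on (0, 180]: the straight-line limit (180 deg,
    # cos = -1) is geometrically meaningful, a zero or reflex angle is not.
    if not math.isfinite(alpha_deg):
        raise ValueError(f"{name} must be finite, got {alpha_deg!r}")
    if not 0.0 < alpha_deg <= 180.0:
        raise ValueError(
            f"{name} must lie in (0, 180] degrees, got {alpha_deg!r}"
        )


def _truncate(value: float, decimals: _DecimalSpec) -> float:
    """Truncate toward zero to `decimals` places; pass through on FULL."""
    if decimals == FULL:
        return value
    factor = 10.0 ** int(decimals)
    return math.trunc(value * factor) / factor


@dataclass(frozen=True)
class FrustumModel:
    """Frustum state: outlet radius r1, inlet radius r2, height L (mm)."""

    r1: float
    r2: float
    L: float
    pi_volume: float = 3.14

    def __post_init__(self) -> None:
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("radii must be non-negative")
        if self.L <= 0:
            raise ValueError("tunnel length L must be positive")
        if not 3.0 < self.pi_volume < 3.2:
            raise ValueError("pi_volume must be a value of pi (3, 3.2)")


@dataclass(frozen=True)
class Calibration:
    """Calibrated outlet-radius law r1(alpha) = sqrt(B*(1-cos alpha))/2.

    ``cos_decimals`` / ``b_decimals`` record the rounding conventions under
    which ``B`` was produced, so that B is recomputable from the other
    fields (see :func:`calibrate_b`).
    """

    alpha0_deg: float
    r1_0: float
    cos_decimals: _DecimalSpec
    B: float
    b_decimals: _DecimalSpec = 2

    def __post_init__(self) -> None:
        _check_angle_domain(self.alpha0_deg, "alpha0_deg")
        if self.r1_0 <= 0:
            raise ValueError("reference outlet radius r1_0 must be positive")
        if self.B <= 0:
            raise ValueError("calibration constant B must be positive")


@dataclass(frozen=True)
class CrossSection:
    """A circular tunnel cross-section: area (mm^2) and radius (mm)."""

    area: float
    radius: float

    @classmethod
    def from_area(cls, area: float) -> "CrossSection":
        return cls(area=area, radius=area_to_radius(area))


@dataclass(frozen=True)
class VolumeTableRow:
    """One row of the angle sweep: alpha, cos alpha, r1, r2, L, volume."""

    alpha_deg: float
    alpha_rad: float
    cos_alpha: float
    r1: float
    r2: float
    L: float
    volume: float


def degrees_to_radians(angle_deg: float) -> float:
    """Convert degrees to radians with full-precision pi."""
    if not math.isfinite(angle_deg):
        raise ValueError(f"angle_deg must be finite, got {angle_deg!r}")
    return angle_deg * math.pi / 180.0


def area_to_radius(area: float) -> float:
    """Radius of the circle of a given area: sqrt(area/pi), full-precision pi."""
    if not math.isfinite(area) or area < 0:
        raise ValueError(f"area must be finite and non-negative, got {area!r}")
    return math.sqrt(area / math.pi)


def calibrate_b(
    r1_0: float,
    alpha0_deg: float,
    cos_decimals: _DecimalSpec = 3,
    b_decimals: _DecimalSpec = 2,
) -> Calibration:
    """Calibrate the constant B from a reference outlet radius and angle.

    B = (2*r1_0)^2 / (1 - cos alpha_0).  ``cos_decimals`` rounds the
    reference cosine before use (pass :data:`FULL` to disable);
    ``b_decimals`` truncates the resulting B (pass :data:`FULL` to keep
    full precision).  The defaults (3, 2) reproduce the published
    constant B = 241.34 from r1_0 = 8.29 at alpha_0 = 98 deg.

    Raises
    ------
    ValueError
        If alpha_0 is outside (0, 180] degrees, r1_0 is not positive, or
        the (rounded) cosine equals 1 (degenerate geometry, division by
        zero).
    """
    _check_angle_domain(alpha0_deg, "alpha0_deg")
    if r1_0 <= 0:
        raise ValueError("reference outlet radius r1_0 must be positive")
    c = math.cos(degrees_to_radians(alpha0_deg))
    if cos_decimals != FULL:
        c = round(c, int(cos_decimals))
    if c >= 1.0:
        raise ValueError(
            "degenerate geometry: cos(alpha0) rounds to 1, B undefined"
        )
    b = (2.0 * r1_0) ** 2 / (1.0 - c)
    b = _truncate(b, b_decimals)
    return Calibration(
        alpha0_deg=alpha0_deg,
        r1_0=r1_0,
        cos_decimals=cos_decimals,
        B=b,
        b_decimals=b_decimals,
    )


def outlet_radius(alpha_deg: float, calibration: Calibration) -> float:
    """Outlet radius r1 at hook angle alpha: sqrt(B*(1 - cos alpha))/2.

    The cosine is evaluated at full precision; the rounding conventions
    apply only inside :func:`calibrate_b`.  Strictly increasing in alpha
    on (0, 180].
    """
    _check_angle_domain(alpha_deg)
    c = math.cos(degrees_to_radians(alpha_deg))
    return math.sqrt(calibration.B * (1.0 - c)) / 2.0


def frustum_volume(model: FrustumModel) -> float:
    """Frustum volume (1/3)*pi*L*(r1^2 + r1*r2 + r2^2) in mm^3."""
    r1, r2 = model.r1, model.r2
    return model.pi_volume * model.L * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0


def generate_volume_table(
    alpha_start: float = DEFAULTS["alpha_start"],
    alpha_end: float = DEFAULTS["alpha_end"],
    step: float = DEFAULTS["step"],
    calibration: Calibration | None = None,
    r2: float = DEFAULTS["r2"],
    L: float = DEFAULTS["L"],
    pi_volume: float = DEFAULTS["pi_volume"],
) -> List[VolumeTableRow]:
    """Sweep the hook angle on an inclusive grid and tabulate r1 and volume.

    One row per angle in ``alpha_start, alpha_start+step, ..., alpha_end``
    (inclusive of the endpoint when it lies on the grid), ascending.
    All row fields are kept at full floating precision; rounding for
    display is a presentation concern.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step!r}")
    if alpha_start > alpha_end:
        raise ValueError("alpha_start must not exceed alpha_end")
    _check_angle_domain(alpha_start, "alpha_start")
    _check_angle_domain(alpha_end, "alpha_end")
    if calibration is None:
        calibration = default_calibration()
    n_steps = int(math.floor((alpha_end - alpha_start) / step + 1e-9))
    rows: List[VolumeTableRow] = []
    for i in range(n_steps + 1):
        alpha = alpha_start + i * step
        rad = degrees_to_radians(alpha)
        r1 = outlet_radius(alpha, calibration)
        vol = frustum_volume(FrustumModel(r1=r1, r2=r2, L=L, pi_volume=pi_volume))
        rows.append(
            VolumeTableRow(
                alpha_deg=alpha,
                alpha_rad=rad,
                cos_alpha=math.cos(rad),
                r1=r1,
                r2=r2,
                L=L,
                volume=vol,
            )
        )
    return rows


#: CSV header of the volume table, in column order.
TABLE_COLUMNS = [
    "alpha_deg",
    "alpha_rad",
    "cos_alpha",
    "r1_mm",
    "r2_mm",
    "L_mm",
    "volume_mm3",
]


def table_to_dataframe(rows: Iterable[VolumeTableRow]) -> pd.DataFrame:
    """Volume-sweep rows as a DataFrame with the canonical CSV columns."""
    return pd.DataFrame(
        [
            (r.alpha_deg, r.alpha_rad, r.cos_alpha, r.r1, r.r2, r.L, r.volume)
            for r in rows
        ],
        columns=TABLE_COLUMNS,
    )


def write_volume_table_csv(rows: Iterable[VolumeTableRow], path) -> None:
    """Write the sweep as UTF-8 CSV ('.' decimal separator, full precision)."""
    table_to_dataframe(rows).to_csv(path, index=False)


def default_calibration() -> Calibration:
    """The reference calibration: r1_0=8.29 mm at alpha_0=98 deg -> B=241.34."""
    return calibrate_b(
        r1_0=DEFAULTS["r1_0"],
        alpha0_deg=DEFAULTS["alpha0_deg"],
        cos_decimals=DEFAULTS["cos_decimals"],
        b_decimals=DEFAULTS["b_decimals"],
    )


def default_volume_table() -> List[VolumeTableRow]:
    """The reference 98-140 deg, 2-deg-step sweep (22 rows)."""
    return generate_volume_table(calibration=default_calibration())
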
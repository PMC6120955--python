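"""Closed-form calculators for the post-objective mirror-pair device.

A pair of small mirrors mounted under the objective displaces a square
field of view (FOV) away from the optical axis; rotating the mirror
holder about the axis by an angle ``theta`` moves the FOV center along a
circle of radius equal to the mirror-to-mirror distance.  Rapidly
alternating between two angles images two distant FOVs quasi-
simultaneously.  The functions here compute FOV placement, the annulus
of reachable positions, the achievable dual-field frame rate, pixel
throughput, and the coverglass-clearance penalty of a tilted cranial
window.

All interface angles are in degrees, lengths in millimetres and times in
milliseconds unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple


class GeometryError(ValueError):
    """Invalid argument or configuration for a geometry calculation."""


class AnnulusBounds(NamedTuple):
    """Inner and outer radius (mm) of the observable donut."""

    inner_radius: float
    outer_radius: float


@dataclass(frozen=True)
class DeviceConfig:
    """Geometry and timing constants of the mirror-pair device.

    Parameters
    ----------
    d_mirror_mirror:
        Distance between the two mirrors (mm).  Sets the radius of the
        circle on which the FOV center travels.
    mirror_width, mirror_height:
        Footprint of the mirror perpendicular to / along the folded
        beam path (mm); their ratio is the beam-ellipticity compensation
        factor.
    working_distance:
        Objective working distance (mm).
    fov_side:
        Side of the square FOV (mm).
    scan_time:
        Time to scan one full frame (ms).
    rotation_time:
        Mapping from rotation angle (deg) to the time the holder needs
        to rotate by that angle (ms).  Interpolated linearly between
        tabulated angles; extrapolation is refused.
    d_mirror_coverglass:
        Mirror-holder-to-coverglass clearance (mm).
    imaging_depth:
        Depth of the focal plane below the coverglass (mm).
    """

    d_mirror_mirror: float = 2.5
    mirror_width: float = 4.0
    mirror_height: float = 2.5
    working_distance: float = 8.0
    fov_side: float = 1.0
    scan_time: float = 33.3
    rotation_time: dict[float, float] = field(
        default_factory=lambda: {60.0: 43.0, 180.0: 80.0}
    )
    d_mirror_coverglass: float = 1.15
    imaging_depth: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "d_mirror_mirror",
            "mirror_width",
            "mirror_height",
            "working_distance",
            "fov_side",
            "scan_time",
            "d_mirror_coverglass",
            "imaging_depth",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be strictly positive")
        if self.fov_side >= self.d_mirror_mirror:
            raise GeometryError("fov_side must be smaller than d_mirror_mirror")
        angles = sorted(self.rotation_time)
        times = [self.rotation_time[a] for a in angles]
        if any(t <= 0 for t in times):
            raise GeometryError("rotation times must be strictly positive")
        if any(b < a for a, b in zip(times, times[1:])):
            raise GeometryError("rotation_time must be nondecreasing in angle")


def center_distance(cfg: DeviceConfig, theta: float) -> float:
    """Distance (mm) between the two FOV centers at rotation angle ``theta``.

    The FOV center sits at radius ``d_mirror_mirror`` from the axis, so
    two positions separated by ``theta`` are ``2 d sin(theta/2)`` apart.
    """
    if not 0.0 <= theta <= 360.0:
        raise GeometryError(f"theta must be in [0, 360] deg, got {theta}")
    return cfg.d_mirror_mirror * 2.0 * math.sin(math.radians(theta) / 2.0)


def angle_for_distance(cfg: DeviceConfig, dist: float) -> float:
    """Rotation angle (deg, in [0, 180]) placing the FOV centers ``dist`` apart."""
    d_max = 2.0 * cfg.d_mirror_mirror
    if dist < 0:
        raise GeometryError("distance must be nonnegative")
    if dist > d_max:
        raise GeometryError(
            f"distance {dist} mm infeasible; maximum is {d_max} mm "
            f"(2 x d_mirror_mirror)"
        )
    return math.degrees(2.0 * math.asin(dist / d_max))


def observable_annulus(cfg: DeviceConfig) -> AnnulusBounds:
    """Radial bounds of the donut reachable by mirror rotation.

    The square FOV rotates with the device, so a corner can point
    radially: the annulus extends half a FOV diagonal on either side of
    the center-travel circle.
    """
    half_diag = cfg.fov_side * math.sqrt(2.0) / 2.0
    return AnnulusBounds(
        inner_radius=cfg.d_mirror_mirror - half_diag,
        outer_radius=cfg.d_mirror_mirror + half_diag,
    )


def _rotation_time_at(cfg: DeviceConfig, theta: float) -> float:
    angles = sorted(cfg.rotation_time)
    if theta in cfg.rotation_time:
        return cfg.rotation_time[theta]
    if not angles or theta < angles[0] or theta > angles[-1]:
        raise GeometryError(
            f"no rotation timing tabulated for theta={theta} deg and "
            f"extrapolation outside [{angles[0] if angles else '-'}, "
            f"{angles[-1] if angles else '-'}] is not supported"
        )
    for lo, hi in zip(angles, angles[1:]):
        if lo <= theta <= hi:
            frac = (theta - lo) / (hi - lo)
            return cfg.rotation_time[lo] + frac * (
                cfg.rotation_time[hi] - cfg.rotation_time[lo]
            )
    raise GeometryError(f"cannot interpolate rotation time at theta={theta}")


def ideal_dual_field_rate(cfg: DeviceConfig, theta: float) -> float:
    """Ideal per-field frame rate (Hz) when alternating between two FOVs.

    One dual-field cycle is two frame scans plus two rotations, so each
    field is revisited every ``2 (scan_time + rotation_time(theta))``.
    """
    rot = _rotation_time_at(cfg, theta)
    period_ms = 2.0 * (cfg.scan_time + rot)
    return 1000.0 / period_ms


def pixel_throughput(
    width_px: int, height_px: int, n_fields: int, per_field_rate: float
) -> float:
    """Imaged pixels per second: ``width * height * n_fields * rate``."""
    if min(width_px, height_px, n_fields) <= 0 or per_field_rate <= 0:
        raise GeometryError("all throughput factors must be positive")
    return float(width_px) * float(height_px) * float(n_fields) * per_field_rate


def tilt_dmc_delta(window_length: float, tilt: float) -> float:
    """Extra mirror-to-coverglass clearance (mm) consumed by a tilted window.

    Tilting a cranial window of length ``window_length`` by ``tilt``
    degrees lowers its far edge by ``window_length * sin(tilt)``.
    """
    if not 0.0 <= tilt < 90.0:
        raise GeometryError(f"tilt must be in [0, 90) deg, got {tilt}")
    return window_length * math.sin(math.radians(tilt))


def beam_ellipticity(cfg: DeviceConfig) -> float:
    """Mirror aspect ratio width/height compensating the 45-degree fold."""
    return cfg.mirror_width / cfg.mirror_height


def geometry_report(cfg: DeviceConfig, theta: float | None = None) -> dict:
    """All calculator outputs for one configuration, as a plain dict."""
    annulus = observable_annulus(cfg)
    report = {
        "d_mirror_mirror_mm": cfg.d_mirror_mirror,
        "fov_side_mm": cfg.fov_side,
        "annulus_inner_mm": annulus.inner_radius,
        "annulus_outer_mm": annulus.outer_radius,
        "max_observable_distance_mm": 2.0 * annulus.outer_radius,
        "beam_ellipticity": beam_ellipticity(cfg),
    }
    if theta is not None:
        report["theta_deg"] = theta
        report["center_distance_mm"] = center_distance(cfg, theta)
        try:
            report["ideal_dual_field_rate_hz"] = ideal_dual_field_rate(cfg, theta)
        except GeometryError:
            pass
    return report
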
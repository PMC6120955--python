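"""Selection of somatic components from extracted spatial footprints.

Source-extraction algorithms return soft spatial footprints (pixel
weights) that include somata but also apical dendrites and other
processes.  Somatic components are kept by size (> 50 µm²) and by the
eccentricity of the ellipse whose second central moments match the
footprint's weight distribution (> 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traces import EventMatrix, TraceMatrix


class RoiError(ValueError):
    """Invalid footprint or ROI set."""


@dataclass(frozen=True)
class RoiFootprint:
    """One spatial component: a weight patch plus placement metadata.

    ``pixel_weights`` is a nonnegative patch; ``offset`` (row, col) is
    the patch origin in field pixels; ``centroid`` is (x, y) in µm in
    field coordinates; ``area_label`` tags the cortical area.
    """

    pixel_weights: np.ndarray
    offset: tuple[int, int] = (0, 0)
    centroid: tuple[float, float] = (0.0, 0.0)
    field_id: str = "field0"
    area_label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.pixel_weights)
        if w.ndim != 2 or not np.any(w > 0):
            raise RoiError("footprint needs a 2-D patch with a positive weight")
        if np.any(w < 0):
            raise RoiError("footprint weights must be nonnegative")


@dataclass
class RoiSet:
    """Footprints linked row-for-row with their traces and events."""

    rois: list[RoiFootprint]
    scale_um_per_px: float
    traces: TraceMatrix | None = None
    events: EventMatrix | None = None

    def __post_init__(self) -> None:
        if self.scale_um_per_px <= 0:
            raise RoiError("scale must be positive")
        for mat in (self.traces, self.events):
            if mat is not None and mat.n_units != len(self.rois):
                raise RoiError("one trace/event row per footprint required")

    def __len__(self) -> int:
        return len(self.rois)


def footprint_shape_metrics(
    roi: RoiFootprint,
    scale_um_per_px: float,
    support_fraction: float = 0.1,
    binary: bool = False,
):
    """Area (µm²) and moment-ellipse eccentricity of one footprint.

    Area counts pixels whose weight exceeds ``support_fraction`` of the
    footprint's maximum weight (footprints are soft).  Eccentricity is
    that of the ellipse with matching second central moments of the
    weight distribution — or of the binary support mask when
    ``binary=True`` — and lies in [0, 1).
    """
    w = np.asarray(roi.pixel_weights, dtype=float)
    support = w > support_fraction * w.max()
    if not support.any():
        raise RoiError("footprint support is empty")
    area = float(support.sum()) * scale_um_per_px**2

    weights = support.astype(float) if binary else np.where(support, w, 0.0)
    total = weights.sum()
    yy, xx = np.indices(w.shape)
    cy = (weights * yy).sum() / total
    cx = (weights * xx).sum() / total
    myy = (weights * (yy - cy) ** 2).sum() / total
    mxx = (weights * (xx - cx) ** 2).sum() / total
    mxy = (weights * (yy - cy) * (xx - cx)).sum() / total
    cov = np.array([[myy, mxy], [mxy, mxx]])
    lam2, lam1 = np.sort(np.linalg.eigvalsh(cov))
    if lam1 <= 0:
        ecc = 0.0
    else:
        ecc = float(np.sqrt(max(0.0, 1.0 - lam2 / lam1)))
    return area, ecc


def select_somatic_components(
    roi_set: RoiSet,
    min_area_um2: float = 50.0,
    min_eccentricity: float = 0.5,
    support_fraction: float = 0.1,
):
    """Keep footprints with area > min_area AND eccentricity > min_ecc.

    Both comparisons are strict, matching the published rule; the
    rejection log records, per rejected ROI, which criteria failed.
    Returns ``(selected RoiSet, rejection_log)``.
    """
    keep = np.zeros(len(roi_set), dtype=bool)
    rejection_log: list[dict] = []
    for i, roi in enumerate(roi_set.rois):
        area, ecc = footprint_shape_metrics(
            roi, roi_set.scale_um_per_px, support_fraction=support_fraction
        )
        reasons = []
        if not area > min_area_um2:
            reasons.append(f"area {area:.1f} um^2 <= {min_area_um2}")
        if not ecc > min_eccentricity:
            reasons.append(f"eccentricity {ecc:.3f} <= {min_eccentricity}")
        if reasons:
            rejection_log.append({"index": i, "reasons": reasons})
        else:
            keep[i] = True

    idx = np.flatnonzero(keep)

    def _subset(mat):
        if mat is None:
            return None
        cls = type(mat)
        return cls(
            values=mat.values[idx],
            frame_rate=mat.frame_rate,
            timestamps=mat.timestamps,
            unit_ids=np.asarray(mat.unit_ids)[idx],
        )

    selected = RoiSet(
        rois=[roi_set.rois[i] for i in idx],
        scale_um_per_px=roi_set.scale_um_per_px,
        traces=_subset(roi_set.traces),
        events=_subset(roi_set.events),
    )
    return selected, rejection_log
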
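"""Per-trace transformations for fluorescence and deconvolved event data.

The pipeline's activity signals are either raw fluorescence traces or
"inferred spike events" — nonnegative deconvolved calcium-transient
amplitudes.  This module implements the shared preprocessing: percentile
ΔF/F baseline, zero-phase Gaussian smoothing of event trains, peak-event
detection, decimation by frame skipping, linear resampling onto an
acquisition clock (for interleaved dual-field data), and masking of
lever-movement periods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal


class TraceError(ValueError):
    """Invalid trace/event data or parameters."""


@dataclass(frozen=True)
class TraceMatrix:
    """Units x frames real-valued traces on a common clock.

    ``timestamps`` (s) are optional; when absent, frames are assumed
    uniformly spaced at ``frame_rate``.
    """

    values: np.ndarray
    frame_rate: float
    timestamps: np.ndarray | None = None
    unit_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise TraceError("values must be a 2-D (units x frames) matrix")
        if self.frame_rate <= 0:
            raise TraceError("frame_rate must be positive")
        if self.timestamps is not None:
            ts = np.asarray(self.timestamps, dtype=float)
            if ts.shape != (self.values.shape[1],):
                raise TraceError("timestamps length must equal frame count")
            if np.any(np.diff(ts) <= 0):
                raise TraceError("timestamps must be strictly increasing")
        if self.unit_ids is None:
            object.__setattr__(
                self, "unit_ids", np.arange(self.values.shape[0])
            )

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def clock(self) -> np.ndarray:
        """Frame times in seconds (explicit timestamps or uniform grid)."""
        if self.timestamps is not None:
            return np.asarray(self.timestamps, dtype=float)
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class EventMatrix(TraceMatrix):
    """Deconvolved event amplitudes: same layout, values constrained >= 0."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < 0):
            raise TraceError("event amplitudes must be nonnegative")


def compute_dff(raw: TraceMatrix, baseline_percentile: float = 8.0):
    """ΔF/F with a per-unit whole-series percentile baseline.

    Returns ``(dff, flagged_unit_ids)``: units whose baseline F0 is not
    strictly positive are excluded from the output and reported.
    Percentiles use linear interpolation between order statistics.
    """
    f0 = np.percentile(raw.values, baseline_percentile, axis=1)
    good = f0 > 0
    flagged = np.asarray(raw.unit_ids)[~good]
    if flagged.size:
        warnings.warn(
            f"{flagged.size} unit(s) with nonpositive baseline excluded: "
            f"{flagged.tolist()}",
            stacklevel=2,
        )
    dff_values = (raw.values[good] - f0[good, None]) / f0[good, None]
    dff = TraceMatrix(
        values=dff_values,
        frame_rate=raw.frame_rate,
        timestamps=raw.timestamps,
        unit_ids=np.asarray(raw.unit_ids)[good],
    )
    return dff, flagged


def gaussian_filter_zero_phase(ev: TraceMatrix, sigma_s: float) -> TraceMatrix:
    """Zero-phase Gaussian smoothing with a unit-sum kernel.

    ``sigma_s`` is the kernel standard deviation in seconds.  A
    symmetric FIR Gaussian applied in a single pass is zero-phase by
    construction; the kernel is truncated at ±4σ and edges are handled
    by reflection, so total mass is conserved away from the edges.
    """
    if sigma_s <= 0:
        raise TraceError("sigma_s must be positive")
    sigma_samples = sigma_s * ev.frame_rate
    if sigma_samples < 0.5:
        warnings.warn(
            f"filter sigma {sigma_s} s is below half a frame at "
            f"{ev.frame_rate} Hz; the filter is close to identity",
            stacklevel=2,
        )
    filtered = ndimage.gaussian_filter1d(
        ev.values.astype(float), sigma=sigma_samples, axis=1,
        mode="reflect", truncate=4.0,
    )
    if isinstance(ev, EventMatrix):
        # positive kernel on nonnegative input; clip guards float round-off
        filtered = np.clip(filtered, 0, None)
    cls = type(ev)
    return cls(
        values=filtered,
        frame_rate=ev.frame_rate,
        timestamps=ev.timestamps,
        unit_ids=ev.unit_ids,
    )


def detect_peak_events(ev_filtered: TraceMatrix, threshold_sd: float = 2.0):
    """Per-unit peak events in smoothed event traces.

    A peak is a local maximum (strictly greater than both neighbours)
    whose height exceeds ``threshold_sd`` times the unit's standard
    deviation over the analysed trace.  Returns ``(counts, indices)``
    with one entry per unit.
    """
    if ev_filtered.n_frames < 3:
        raise TraceError("at least 3 frames needed for peak detection")
    counts = np.zeros(ev_filtered.n_units, dtype=int)
    indices: list[np.ndarray] = []
    sds = ev_filtered.values.std(axis=1)
    for i, (trace, sd) in enumerate(zip(ev_filtered.values, sds)):
        if sd == 0:
            indices.append(np.array([], dtype=int))
            continue
        peaks, _ = signal.find_peaks(trace, height=threshold_sd * sd)
        counts[i] = peaks.size
        indices.append(peaks)
    return counts, indices


def downsample_by_skip(x: TraceMatrix, factor: int) -> TraceMatrix:
    """Decimate by keeping frames 0, factor, 2*factor, ... (no anti-alias)."""
    if int(factor) != factor or factor < 1:
        raise TraceError("factor must be a positive integer")
    factor = int(factor)
    if factor > x.n_frames:
        raise TraceError(f"factor {factor} exceeds frame count {x.n_frames}")
    kept = slice(None, None, factor)
    cls = type(x)
    return cls(
        values=x.values[:, kept].copy(),
        frame_rate=x.frame_rate / factor,
        timestamps=None if x.timestamps is None else np.asarray(x.timestamps)[kept],
        unit_ids=x.unit_ids,
    )


def union_clock(*clocks: np.ndarray) -> np.ndarray:
    """Merged, sorted acquisition clock of several interleaved fields."""
    merged = np.unique(np.concatenate([np.asarray(c, dtype=float) for c in clocks]))
    return merged


def resample_to_clock(x: TraceMatrix, target_timestamps: np.ndarray) -> TraceMatrix:
    """Linear interpolation of every unit onto a new clock.

    Used to put two interleaved fields (each at r Hz, offset by half a
    period) onto their common 2r Hz clock.  Extrapolation outside the
    source time span is refused.
    """
    src = x.clock()
    target = np.asarray(target_timestamps, dtype=float)
    if target[0] < src[0] - 1e-12 or target[-1] > src[-1] + 1e-12:
        raise TraceError(
            "target clock extends outside the source recording span; "
            "extrapolation is not supported"
        )
    out = np.empty((x.n_units, target.size))
    for i, trace in enumerate(x.values):
        out[i] = np.interp(target, src, trace)
    rate = 1.0 / float(np.median(np.diff(target)))
    cls = type(x)
    return cls(
        values=out, frame_rate=rate, timestamps=target, unit_ids=x.unit_ids
    )


def mask_lever_periods(
    x: TraceMatrix,
    lever_move_intervals: list[tuple[float, float]] | np.ndarray,
    pad_s: float = 1.0,
):
    """Drop frames around lever movements and concatenate the remainder.

    Frames within ``pad_s`` seconds of any (start, stop) movement
    interval are removed; the surviving frames are concatenated in order
    so correlations can be computed on quiet periods only.  Returns
    ``(masked, kept_indices)``.
    """
    times = x.clock()
    keep = np.ones(times.size, dtype=bool)
    intervals = np.asarray(lever_move_intervals, dtype=float)
    if intervals.size:
        for start, stop in np.atleast_2d(intervals):
            keep &= ~((times >= start - pad_s) & (times <= stop + pad_s))
    if not keep.any():
        raise TraceError("masking removed every frame")
    kept_idx = np.flatnonzero(keep)
    cls = type(x)
    masked = cls(
        values=x.values[:, kept_idx].copy(),
        frame_rate=x.frame_rate,
        timestamps=None,
        unit_ids=x.unit_ids,
    )
    return masked, kept_idx
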
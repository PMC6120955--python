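"""Bead-based point-spread-function characterization.

Sub-diffraction fluorescent beads are imaged as a z-stack; the apparent
bead extent is the PSF.  The estimator follows the profile-and-fit
recipe standard in two-photon microscopy: average the repeat frames per
focal plane, take X and Y line profiles through the bead center in the
brightest plane, take axial profiles along the bead's elongation
direction in reconstructed XZ and YZ sections, fit a Gaussian to each
profile and report full widths at half maximum (FWHM = 2*sqrt(2 ln 2)
sigma).  The axial FWHM is the mean of the XZ- and YZ-derived values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class PsfError(ValueError):
    """Invalid bead volume or profile for FWHM estimation."""


class FitError(RuntimeError):
    """Gaussian fit failed to converge; carries the residual report."""


@dataclass(frozen=True)
class BeadVolume:
    """A bead image stack: ``data[z, y, x]`` with voxel size in µm (x, y, z)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (0.249, 0.249, 0.5)
    frames_per_plane: int = 5

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise PsfError("voxel sizes must be positive")
        if self.data.ndim != 3:
            raise PsfError("bead volume must be 3-D (z, y, x)")


@dataclass(frozen=True)
class Profile:
    """1-D intensity profile with uniform physical sample spacing (µm)."""

    values: np.ndarray
    spacing: float


@dataclass(frozen=True)
class FwhmEstimate:
    """Per-bead FWHM estimates (µm) and the goodness of each fit."""

    lateral_x: float
    lateral_y: float
    axial: float
    fit_r2: dict[str, float]


def average_plane_repeats(
    raw_frames: np.ndarray,
    frames_per_plane: int = 5,
    voxel_size: tuple[float, float, float] = (0.249, 0.249, 0.5),
) -> BeadVolume:
    """Average the repeat frames acquired at each focal plane.

    ``raw_frames`` is a (n_frames, y, x) stack ordered z-major with the
    repeats innermost; n_frames must be divisible by ``frames_per_plane``.
    """
    if raw_frames.ndim != 3:
        raise PsfError("raw frames must be a 3-D stack (frame, y, x)")
    n = raw_frames.shape[0]
    if frames_per_plane < 1 or n % frames_per_plane:
        raise PsfError(
            f"{n} frames not divisible by frames_per_plane={frames_per_plane}"
        )
    planes = raw_frames.reshape(
        n // frames_per_plane, frames_per_plane, *raw_frames.shape[1:]
    ).mean(axis=1)
    return BeadVolume(
        data=planes, voxel_size=voxel_size, frames_per_plane=frames_per_plane
    )


def _background(vol: np.ndarray) -> float:
    """Median intensity of the volume's border voxels."""
    border = np.ones(vol.shape, dtype=bool)
    border[1:-1, 1:-1, 1:-1] = False
    return float(np.median(vol[border]))


def _check_single_bead(vol: np.ndarray, background: float) -> None:
    peak = vol.max()
    if peak <= background:
        raise PsfError("no voxel above background; empty volume")
    labels, n = ndimage.label(vol > background + 0.5 * (peak - background))
    if n > 1:
        # isolated hot voxels from noise are not beads
        sizes = ndimage.sum_labels(np.ones_like(vol), labels, np.arange(1, n + 1))
        peaks = ndimage.maximum(vol, labels, index=np.arange(1, n + 1))
        peaks = np.sort(peaks[sizes >= 5])[::-1]
        if peaks.size > 1 and peaks[1] > 0.5 * peaks[0]:
            raise PsfError(
                "multiple comparably bright beads in volume; a single "
                "dominant bead is required"
            )


def _signal_weights(img: np.ndarray, threshold_fraction: float = 0.2) -> np.ndarray:
    """Background-subtracted weights, zeroed below a fraction of the peak.

    Suppresses clipped noise that would otherwise bias centroids and
    second moments toward the patch center.
    """
    w = np.clip(np.asarray(img, dtype=float), 0, None)
    peak = w.max()
    if peak <= 0:
        raise PsfError("no signal above background")
    w = np.where(w >= threshold_fraction * peak, w, 0.0)
    return w


def _weighted_centroid(img: np.ndarray) -> np.ndarray:
    w = _signal_weights(img)
    total = w.sum()
    grids = np.indices(img.shape)
    return np.array([float((g * w).sum() / total) for g in grids])


def _principal_axis(section: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    """Unit vector (physical units) of the section's elongation direction.

    Intensity-weighted second central moments of the above-background
    signal, computed on physically scaled coordinates.
    """
    w = _signal_weights(section)
    cy, cx = _weighted_centroid(w)
    yy, xx = np.indices(section.shape)
    dy = (yy - cy) * spacing[0]
    dx = (xx - cx) * spacing[1]
    total = w.sum()
    cov = np.array(
        [
            [(w * dy * dy).sum(), (w * dy * dx).sum()],
            [(w * dy * dx).sum(), (w * dx * dx).sum()],
        ]
    ) / total
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, np.argmax(vals)]
    if axis[0] < 0:
        axis = -axis
    return axis


def _line_profile(
    section: np.ndarray,
    spacing: tuple[float, float],
    direction: np.ndarray,
    step: float,
    center: np.ndarray,
) -> Profile:
    """Sample the section along ``direction`` through the bead center."""
    extent = float(np.hypot(section.shape[0] * spacing[0], section.shape[1] * spacing[1]))
    ts = np.arange(-extent / 2.0, extent / 2.0 + step, step)
    rows = center[0] + ts * direction[0] / spacing[0]
    cols = center[1] + ts * direction[1] / spacing[1]
    inside = (
        (rows >= 0)
        & (rows <= section.shape[0] - 1)
        & (cols >= 0)
        & (cols <= section.shape[1] - 1)
    )
    coords = np.vstack([rows[inside], cols[inside]])
    values = ndimage.map_coordinates(section, coords, order=1, mode="nearest")
    return Profile(values=values, spacing=step)


def extract_profiles(vol: BeadVolume) -> dict[str, Profile]:
    """Line profiles through the bead: lateral X/Y and axial from XZ/YZ.

    Lateral profiles are the single row/column through the intensity-
    weighted bead centroid in the plane of maximum average intensity.
    Axial profiles are sampled from the XZ and YZ sections through the
    bead center, along each section's principal (elongation) axis,
    interpolated to uniform physical spacing.
    """
    data = vol.data.astype(float)
    bg = _background(data)
    _check_single_bead(data, bg)
    vx, vy, vz = vol.voxel_size

    z_best = int(np.argmax(data.mean(axis=(1, 2))))
    plane = data[z_best]
    # centroids from a lightly smoothed copy: the 20%-of-peak support
    # threshold inside the centroid is reliable only once isolated noise
    # voxels are suppressed
    plane_sm = ndimage.gaussian_filter(plane, 1.0)
    cy, cx = _weighted_centroid(np.clip(plane_sm - bg, 0, None))
    row, col = int(round(cy)), int(round(cx))
    profiles = {
        "x": Profile(values=plane[row, :].copy(), spacing=vx),
        "y": Profile(values=plane[:, col].copy(), spacing=vy),
    }

    data_sm = ndimage.gaussian_filter(data, 1.0)
    zc, yc, xc = _weighted_centroid(np.clip(data_sm - bg, 0, None))
    xz = data[:, int(round(yc)), :]  # axes (z, x)
    yz = data[:, :, int(round(xc))]  # axes (z, y)
    for name, section, sp in (
        ("xz", xz, (vz, vx)),
        ("yz", yz, (vz, vy)),
    ):
        step = min(sp)
        # direction and centroid from a lightly smoothed section: the
        # second moments are otherwise dominated by noise voxels; the
        # profile itself is sampled from the raw section
        smooth = ndimage.gaussian_filter(section, sigma=1.0)
        signal = np.clip(smooth - np.median(smooth), 0, None)
        axis = _principal_axis(signal, sp)
        center = _weighted_centroid(signal)
        profiles[name] = _line_profile(section, sp, axis, step, center)
    return profiles


def _gaussian(x: np.ndarray, offset: float, amp: float, center: float, sigma: float):
    return offset + amp * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def fit_gaussian_fwhm(profile: Profile | np.ndarray, sample_spacing: float | None = None):
    """Fit offset + Gaussian to a 1-D profile; return (FWHM µm, r²).

    Initialization is deterministic: center at the argmax, sigma from the
    background-subtracted second moment, offset at the profile minimum.
    """
    if isinstance(profile, Profile):
        values = np.asarray(profile.values, dtype=float)
        spacing = profile.spacing
    else:
        values = np.asarray(profile, dtype=float)
        if sample_spacing is None:
            raise PsfError("sample_spacing required for a bare array profile")
        spacing = sample_spacing
    n = values.size
    if n < 7:
        raise PsfError(f"profile has {n} samples; at least 7 required")
    peak = int(np.argmax(values))
    if peak in (0, n - 1):
        raise PsfError("profile peak at edge; bead not centered in the volume")

    x = np.arange(n) * spacing
    offset0 = float(values.min())
    amp0 = float(values[peak] - offset0)

    # half-max walk from the peak: a local width estimate that noise far
    # from the bead cannot inflate
    half = offset0 + amp0 / 2.0
    left = peak
    while left > 0 and values[left - 1] > half:
        left -= 1
    right = peak
    while right < n - 1 and values[right + 1] > half:
        right += 1
    hw = max(right - left, 1) / 2.0  # samples
    sigma0 = max(hw * spacing / 1.177, spacing / 2.0)

    # fit only a local window around the peak so distant noise cannot pull
    # the optimum toward a broad spurious bump
    pad = max(int(np.ceil(6.0 * sigma0 / spacing)), 6)
    lo = max(peak - pad, 0)
    hi = min(peak + pad + 1, n)
    xw, vw = x[lo:hi], values[lo:hi]
    span = xw[-1] - xw[0]
    try:
        popt, _ = curve_fit(
            _gaussian,
            xw,
            vw,
            p0=[offset0, amp0, x[peak], min(sigma0, span / 2)],
            # keep the peak inside the window and the width physical
            bounds=(
                [-np.inf, 0.0, xw[0], spacing / 4.0],
                [np.inf, np.inf, xw[-1], span],
            ),
            maxfev=10000,
        )
    except RuntimeError as exc:
        resid = vw - _gaussian(xw, offset0, amp0, x[peak], sigma0)
        raise FitError(
            f"Gaussian fit did not converge (initial RMS residual "
            f"{np.sqrt(np.mean(resid ** 2)):.4g})"
        ) from exc
    fitted = _gaussian(xw, *popt)
    ss_res = float(((vw - fitted) ** 2).sum())
    ss_tot = float(((vw - vw.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    fwhm = FWHM_PER_SIGMA * abs(popt[3])
    return fwhm, r2


def characterize_bead(vol: BeadVolume) -> FwhmEstimate:
    """Full per-bead estimate: lateral X/Y FWHM and mean XZ/YZ axial FWHM."""
    profiles = extract_profiles(vol)
    fwhm_x, r2_x = fit_gaussian_fwhm(profiles["x"])
    fwhm_y, r2_y = fit_gaussian_fwhm(profiles["y"])
    fwhm_xz, r2_xz = fit_gaussian_fwhm(profiles["xz"])
    fwhm_yz, r2_yz = fit_gaussian_fwhm(profiles["yz"])
    return FwhmEstimate(
        lateral_x=fwhm_x,
        lateral_y=fwhm_y,
        axial=0.5 * (fwhm_xz + fwhm_yz),
        fit_r2={"x": r2_x, "y": r2_y, "xz": r2_xz, "yz": r2_yz},
    )
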
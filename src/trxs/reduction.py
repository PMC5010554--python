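"""Reduction of raw scattering acquisitions to clean difference curves.

Stages, in the order a time-resolved solution-scattering experiment applies
them: azimuthal (ring) integration of the 2-D detector readout, normalization
to the water-dominated 14–16 nm⁻¹ window, merging of small- and wide-angle
detectors via their q overlap, laser-off reference subtraction (removes slow
radiation-damage drift), and heat-signal subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .models import (
    DifferenceCurve,
    ScatteringCurve,
    require_same_grid,
)

__all__ = [
    "NORMALIZATION_WINDOW",
    "HEAT_FIT_WINDOW",
    "DetectorImage",
    "AcquisitionTriplet",
    "integrate_rings",
    "normalize_window",
    "subtract_laser_off",
    "merge_detectors",
    "subtract_heat",
    "pixel_q_map",
]

#: Default normalization window (nm⁻¹): water scattering dominates here and is
#: insensitive to protein conformation.
NORMALIZATION_WINDOW = (14.0, 16.0)

#: Default q window (nm⁻¹) for fitting the solvent heating pattern.
HEAT_FIT_WINDOW = (1.0, 2.0)


@dataclass
class DetectorImage:
    """2-D detector readout plus the geometry needed for the q(pixel) map."""

    data: np.ndarray  # (ny, nx) intensities
    center_px: tuple[float, float]  # (row, col) beam center
    pixel_mm: float
    distance_mm: float
    wavelength_nm: float
    mask: Optional[np.ndarray] = None  # True = invalid pixel

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("detector data must be 2-D")
        for name, v in (("pixel_mm", self.pixel_mm),
                        ("distance_mm", self.distance_mm),
                        ("wavelength_nm", self.wavelength_nm)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mask is None:
            self.mask = np.zeros(self.data.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data shape")
        if np.any(self.data[~self.mask] < 0):
            raise ValueError("negative intensities outside the mask")


def pixel_q_map(image: DetectorImage) -> np.ndarray:
    """Per-pixel q (nm⁻¹): q = (4π/λ)·sin(θ/2), θ from radius and distance."""
    ny, nx = image.data.shape
    rows, cols = np.indices((ny, nx))
    r_mm = image.pixel_mm * np.hypot(rows - image.center_px[0],
                                     cols - image.center_px[1])
    theta = np.arctan2(r_mm, image.distance_mm)  # full scattering angle 2θ_B
    return (4.0 * np.pi / image.wavelength_nm) * np.sin(theta / 2.0)


def integrate_rings(image: DetectorImage, n_bins: int = 200) -> ScatteringCurve:
    """Azimuthal integration: mean intensity per q ring; empty bins dropped.

    Per-bin mean (not sum) so that masked-pixel fractions cancel.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    ny, nx = image.data.shape
    cy, cx = image.center_px
    if not (0 <= cy < ny and 0 <= cx < nx):
        raise ValueError("beam center lies outside the image")
    valid = ~image.mask
    if not np.any(valid):
        raise ValueError("no valid pixels (image fully masked)")
    q_px = pixel_q_map(image)[valid]
    i_px = image.data[valid]
    edges = np.linspace(q_px.min(), q_px.max(), n_bins + 1)
    which = np.clip(np.digitize(q_px, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=i_px, minlength=n_bins)
    q_sums = np.bincount(which, weights=q_px, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    occupied = counts > 0
    # report the mean q of the contributing pixels, not the bin center: the
    # two differ visibly in sparse inner rings
    return ScatteringCurve(
        q=q_sums[occupied] / counts[occupied],
        intensity=sums[occupied] / counts[occupied],
        provenance="ring-integration",
    )


def normalize_window(
    curve: ScatteringCurve,
    window: tuple[float, float] = NORMALIZATION_WINDOW,
) -> ScatteringCurve:
    """Divide by the mean intensity over a q window (mean becomes 1)."""
    lo, hi = window
    sel = (curve.q >= lo) & (curve.q <= hi)
    if not np.any(sel):
        raise ValueError(f"normalization window {window} contains no grid points")
    mean = curve.intensity[sel].mean()
    if mean == 0.0:
        raise ValueError("mean intensity over the normalization window is zero")
    return ScatteringCurve(
        q=curve.q.copy(),
        intensity=curve.intensity / mean,
        sigma=None if curve.sigma is None else curve.sigma / abs(mean),
        provenance=curve.provenance,
    )


@dataclass
class AcquisitionTriplet:
    """Laser-on acquisition flanked by two laser-off references, one grid."""

    off_before: ScatteringCurve
    on: ScatteringCurve
    off_after: ScatteringCurve

    def __post_init__(self) -> None:
        require_same_grid(self.off_before.q, self.on.q, "triplet curves")
        require_same_grid(self.on.q, self.off_after.q, "triplet curves")


def subtract_laser_off(triplet: AcquisitionTriplet) -> DifferenceCurve:
    """ΔS = on − (off_before + off_after)/2; cancels linear drift."""
    ref = 0.5 * (triplet.off_before.intensity + triplet.off_after.intensity)
    return DifferenceCurve(
        q=triplet.on.q.copy(),
        delta=triplet.on.intensity - ref,
        provenance="laser-off-subtracted",
    )


def merge_detectors(
    small_angle: ScatteringCurve, wide_angle: ScatteringCurve
) -> tuple[ScatteringCurve, float]:
    """Scale the wide-angle curve onto the small-angle one over their overlap
    and splice at the overlap midpoint. Returns (merged curve, scale).

    The scale is the least-squares scalar c minimizing Σ (small − c·wide)²
    over the overlap, evaluated on the finer of the two grids there.
    """
    lo = max(small_angle.q.min(), wide_angle.q.min())
    hi = min(small_angle.q.max(), wide_angle.q.max())
    if hi <= lo:
        raise ValueError("detector q ranges do not overlap")
    in_s = (small_angle.q >= lo) & (small_angle.q <= hi)
    in_w = (wide_angle.q >= lo) & (wide_angle.q <= hi)
    # evaluate on whichever grid samples the overlap more finely
    ref_q = small_angle.q[in_s] if in_s.sum() >= in_w.sum() else wide_angle.q[in_w]
    if ref_q.size < 2:
        raise ValueError("overlap contains fewer than 2 points")
    s_ov = np.interp(ref_q, small_angle.q, small_angle.intensity)
    w_ov = np.interp(ref_q, wide_angle.q, wide_angle.intensity)
    den = float(np.dot(w_ov, w_ov))
    if den == 0.0:
        raise ValueError("wide-angle intensity vanishes over the overlap")
    scale = float(np.dot(s_ov, w_ov)) / den

    mid = 0.5 * (lo + hi)
    keep_s = small_angle.q <= mid
    keep_w = wide_angle.q > mid
    q = np.concatenate([small_angle.q[keep_s], wide_angle.q[keep_w]])
    i = np.concatenate(
        [small_angle.intensity[keep_s], scale * wide_angle.intensity[keep_w]]
    )
    order = np.argsort(q)
    merged = ScatteringCurve(q=q[order], intensity=i[order],
                             provenance="merged")
    return merged, scale


def subtract_heat(
    curve: DifferenceCurve,
    heat_pattern: DifferenceCurve,
    fit_window: tuple[float, float] = HEAT_FIT_WINDOW,
) -> tuple[DifferenceCurve, float]:
    """Remove the solvent-heating contribution: ΔS − c·heat, with c fit by
    least squares over ``fit_window``. Returns (corrected curve, c)."""
    require_same_grid(curve.q, heat_pattern.q, "curve and heat pattern")
    lo, hi = fit_window
    sel = (curve.q >= lo) & (curve.q <= hi)
    if not np.any(sel):
        raise ValueError(f"heat fit window {fit_window} contains no grid points")
    h = heat_pattern.delta[sel]
    den = float(np.dot(h, h))
    if den == 0.0:
        raise ValueError("heat pattern vanishes over the fit window")
    c = float(np.dot(curve.delta[sel], h)) / den
    return (
        DifferenceCurve(
            q=curve.q.copy(),
            delta=curve.delta - c * heat_pattern.delta,
            sigma=curve.sigma,
            time_s=curve.time_s,
            provenance="heat-subtracted",
        ),
        c,
    )
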
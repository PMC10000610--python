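"""Roundness-deviation spectral analysis of a contour slice.

The chain implemented here is the classic roundness-metrology recipe
applied to each contour: fit the least-squares circle, unwrap the
contour into a radial deviation profile

    e(theta) = R - r(theta)

on a uniform angular grid (mean-centred), take its FFT, express the
harmonics as spatial wavelengths lambda_k = P/k along the perimeter
P = 2 pi R, and summarise the in-band roughness energy as

    Q = integral of |FFT(e)| over lambda.

Conventions: the forward FFT is unnormalised and the one-sided
magnitudes carry no doubling correction at DC or Nyquist; the DC bin is
dropped (it is ~0 after mean-centring).  Q values are therefore
comparable between layers and samples under this one fixed convention,
which is all the grading needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .slicing import ContourSlice

__all__ = [
    "CircleFit",
    "DeviationProfile",
    "RoughnessSpectrum",
    "fit_circle",
    "unwrap",
    "spectrum",
    "compute_Q",
    "layer_std",
    "default_band",
    "peak_wavelength",
]


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle: centre, radius and RMS radial residual."""

    center: tuple[float, float]
    R: float
    rms_residual: float


@dataclass
class DeviationProfile:
    """Radial deviation of one contour resampled on a uniform angular grid.

    theta : M uniform angles in [0, 2 pi), M a power of two
    r : resampled contour radii about the fitted centre
    e : mean-centred deviations R - r(theta)
    perimeter : 2 pi R of the fitted circle
    s : arc positions theta * R along the nominal perimeter
    """

    layer_index: int
    theta: np.ndarray
    r: np.ndarray
    e: np.ndarray
    R: float

    @property
    def M(self) -> int:
        return len(self.theta)

    @property
    def perimeter(self) -> float:
        return 2.0 * np.pi * self.R

    @property
    def s(self) -> np.ndarray:
        return self.theta * self.R


@dataclass
class RoughnessSpectrum:
    """One-sided deviation spectrum over spatial wavelength.

    k : harmonic indices 1..M/2 (cycles per revolution)
    lam : wavelengths P/k (distance units), strictly decreasing
    beta : spatial frequencies k/P = 1/lam (cycles per distance unit)
    mag : FFT magnitudes |FFT(e)|_k (unnormalised, one-sided)
    """

    layer_index: int
    k: np.ndarray
    lam: np.ndarray
    mag: np.ndarray
    perimeter: float

    @property
    def beta(self) -> np.ndarray:
        return 1.0 / self.lam


def fit_circle(points: np.ndarray) -> CircleFit:
    """Algebraic (Kasa) least-squares circle through 2-D points.

    Solves the linear system for the circle equation
    ``x^2 + y^2 + D x + E y + F = 0`` in the least-squares sense; the
    fit is exact on noiseless circular data.  Requires at least three
    non-collinear points.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 3:
        raise ValueError("need at least 3 (x, y) points")
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = -(x**2 + y**2)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("points are collinear; circle fit is singular")
    D, E, F = sol
    cx, cy = -D / 2.0, -E / 2.0
    R2 = cx * cx + cy * cy - F
    if R2 <= 0.0:
        raise ValueError("points are collinear; circle fit is singular")
    R = float(np.sqrt(R2))
    radial = np.hypot(x - cx, y - cy)
    rms = float(np.sqrt(np.mean((radial - R) ** 2)))
    return CircleFit(center=(float(cx), float(cy)), R=R, rms_residual=rms)


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


def unwrap(contour: ContourSlice, fit: CircleFit, M: int = 512) -> DeviationProfile:
    """Unwrap a contour about its fitted circle onto M uniform angles.

    Each contour point maps to ``(theta_i, r_i)`` about the fitted
    centre; points are sorted by angle (duplicate angles averaged, the
    least-surprising reduction when a lump makes r(theta) multi-valued)
    and linearly interpolated, with periodic wraparound, onto M uniform
    angles.  The deviation ``e = (R - r)`` is then mean-centred.
    """
    if not (_is_power_of_two(M) and M >= 16):
        raise ValueError(f"M must be a power of two >= 16, got {M}")
    pts = np.asarray(contour.points, dtype=np.float64)
    if len(pts) < 3:
        raise ValueError("contour must have at least 3 points")
    cx, cy = fit.center
    theta = np.mod(np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx), 2.0 * np.pi)
    r = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    order = np.argsort(theta, kind="stable")
    theta, r = theta[order], r[order]
    # average radii sharing an angle (within fp resolution)
    dup = np.diff(theta) < 1e-12
    if np.any(dup):
        keys = np.concatenate([[0], np.cumsum(~dup)])
        counts = np.bincount(keys)
        theta = np.bincount(keys, weights=theta) / counts
        r = np.bincount(keys, weights=r) / counts
    grid = 2.0 * np.pi * np.arange(M) / M
    r_g = np.interp(grid, theta, r, period=2.0 * np.pi)
    e = fit.R - r_g
    e = e - e.mean()
    return DeviationProfile(layer_index=contour.layer_index, theta=grid, r=r_g, e=e, R=fit.R)


def spectrum(profile: DeviationProfile) -> RoughnessSpectrum:
    """One-sided magnitude spectrum of the deviation profile.

    Harmonics k = 1..M/2; the DC bin is excluded (zero after centring)
    and no one-sided doubling is applied anywhere, including Nyquist.
    """
    M = profile.M
    F = np.fft.rfft(profile.e)
    k = np.arange(1, M // 2 + 1)
    mag = np.abs(F[1:])
    lam = profile.perimeter / k
    return RoughnessSpectrum(
        layer_index=profile.layer_index, k=k, lam=lam, mag=mag, perimeter=profile.perimeter
    )


def default_band(spec: RoughnessSpectrum) -> tuple[float, float]:
    """Default integration band [2P/M, P/2].

    Keeps every harmonic except the k = 1 fundamental (ellipse-like
    drift of the fitted centre) -- the near-Nyquist bins are excluded
    only when the caller abridges the band further.
    """
    M = 2 * len(spec.k)
    return 2.0 * spec.perimeter / M, spec.perimeter / 2.0


def compute_Q(
    spec: RoughnessSpectrum, lam_min: float | None = None, lam_max: float | None = None
) -> float:
    """Roughness energy: trapezoidal integral of |FFT(e)| over wavelength.

    Integration runs over the (non-uniform) wavelength grid restricted
    to ``[lam_min, lam_max]``; the default band is ``[2P/M, P/2]``.
    Raises if no harmonic falls inside the band.
    """
    if lam_min is None and lam_max is None:
        lam_min, lam_max = default_band(spec)
    elif lam_min is None or lam_max is None:
        raise ValueError("give both lam_min and lam_max, or neither")
    if not lam_min < lam_max:
        raise ValueError("lam_min must be < lam_max")
    mask = (spec.lam >= lam_min) & (spec.lam <= lam_max)
    if not np.any(mask):
        raise ValueError(f"no harmonics inside the band [{lam_min}, {lam_max}]")
    lam = spec.lam[mask][::-1]  # ascending for integration
    mag = spec.mag[mask][::-1]
    if len(lam) == 1:
        return 0.0
    return float(np.trapezoid(mag, lam))


def peak_wavelength(
    spec: RoughnessSpectrum, lam_min: float | None = None, lam_max: float | None = None
) -> float:
    """Wavelength of the largest in-band FFT magnitude.

    A smooth isolated lump is a low-pass feature, so this locator is
    informative only once the wavelength axis has been abridged to the
    expected lump-size region (the usual practice when the lump scale
    is known a priori).
    """
    if lam_min is None and lam_max is None:
        lam_min, lam_max = default_band(spec)
    mask = (spec.lam >= lam_min) & (spec.lam <= lam_max)
    if not np.any(mask):
        raise ValueError(f"no harmonics inside the band [{lam_min}, {lam_max}]")
    lam = spec.lam[mask]
    mag = spec.mag[mask]
    return float(lam[np.argmax(mag)])


def layer_std(profile: DeviationProfile) -> float:
    """Population standard deviation of the deviation profile e(theta)."""
    return float(np.std(profile.e))
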
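"""(002) Debye-ring analysis: azimuthal integration, Voigt peak fitting,
and c-lattice residual-strain relaxation.

Dehydration tenses the collagen and compresses the co-aligned carbonated
apatite nanocrystals along their c-axis; radiation damage fragments the
collagen and releases that compression, so the (002) d-spacing grows with
exposure.  The chain here is: mask detector gaps, integrate each area
frame azimuthally (full 360 degrees) into I(2theta), subtract an
empty-beam profile, fit a Voigt + linear background to the (002) window,
convert the fitted center to the c-lattice parameter through Bragg's law
(c = 2 d_002), and express the series as percentage strain relative to
the first exposure, with a saturating-exponential relaxation fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

from . import constants
from .fitting import FitError, fit_saturating_exponential

#: Default (002) fit window at 18 keV, bracketing c = 6.8-6.9 A.
DEFAULT_WINDOW_DEG = (10.5, 12.5)


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat area-detector geometry with the beam normal to the detector."""

    sample_detector_mm: float
    pixel_size_um: float
    beam_center_px: tuple  # (cx, cy) in pixel units
    energy_kev: float

    def __post_init__(self):
        if self.sample_detector_mm <= 0:
            raise ValueError("sample-detector distance must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.energy_kev <= 0:
            raise ValueError("photon energy must be positive")

    @property
    def wavelength_a(self) -> float:
        return constants.HC_KEV_A / self.energy_kev

    def two_theta_deg(self, radius_px) -> np.ndarray:
        """Scattering angle 2theta (deg) at a radial pixel distance."""
        r_mm = np.asarray(radius_px, dtype=float) * self.pixel_size_um * 1e-3
        return np.degrees(np.arctan2(r_mm, self.sample_detector_mm))


@dataclass
class RadialProfile:
    """Azimuthally integrated profile I(2theta).

    ``intensity`` is the mean counts per contributing pixel; ``npix``
    keeps the per-bin pixel count so total counts are recoverable
    (conservation: sum(intensity * npix) = sum of unmasked pixels).
    """

    two_theta_deg: np.ndarray
    intensity: np.ndarray
    npix: np.ndarray
    azimuth_range_deg: tuple = (0.0, 360.0)

    def __post_init__(self):
        self.two_theta_deg = np.asarray(self.two_theta_deg, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.npix = np.asarray(self.npix)
        if np.any(np.diff(self.two_theta_deg) <= 0):
            raise ValueError("two_theta grid must be strictly increasing")


@dataclass
class PeakFitResult:
    """Voigt + linear-background fit of one diffraction peak."""

    center_2theta_deg: float
    center_se_deg: float | None
    gaussian_sigma_deg: float
    lorentzian_gamma_deg: float
    amplitude: float
    linear_slope: float
    linear_intercept: float
    redchi: float


@dataclass
class StrainSeries:
    """Time-resolved (002) strain: c(t) and Delta c / c in percent.

    Strain is referenced to the first exposure point (percentage strain
    change); the relaxation fit is strain(t) = plateau (1 - e^{-rate t}).
    """

    exposure_s: np.ndarray
    c_lattice_a: np.ndarray
    strain_pct: np.ndarray
    strain_se_pct: np.ndarray
    flux: float | None = None
    relaxation_rate: float | None = None
    relaxation_plateau_pct: float | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure_s": self.exposure_s,
                "c_A": self.c_lattice_a,
                "strain_pct": self.strain_pct,
                "strain_se_pct": self.strain_se_pct,
            }
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.exposure_s, self.strain_pct, yerr=self.strain_se_pct,
                    fmt="o", capsize=3)
        if self.relaxation_rate is not None:
            tt = np.linspace(0, self.exposure_s.max(), 200)
            ax.plot(tt, self.relaxation_plateau_pct * (1 - np.exp(-self.relaxation_rate * tt)),
                    "-", color="magenta")
        ax.set_xlabel("exposure (s)")
        ax.set_ylabel("strain change (%)")
        return ax


def build_detector_mask(frame_shape: tuple, gap_stripes=()) -> np.ndarray:
    """Boolean mask, True on valid pixels, False on detector-gap stripes.

    ``gap_stripes`` is a list of ("h"|"v", start_px, width_px): horizontal
    stripes span rows, vertical stripes span columns.
    """
    mask = np.ones(frame_shape, dtype=bool)
    ny, nx = frame_shape
    for orient, start, width in gap_stripes:
        if width <= 0:
            raise ValueError("stripe width must be positive")
        limit = ny if orient == "h" else nx
        if orient not in ("h", "v"):
            raise ValueError(f"stripe orientation must be 'h' or 'v', got {orient!r}")
        if start < 0 or start + width > limit:
            raise ValueError(
                f"stripe {orient, start, width} lies outside frame of shape {frame_shape}"
            )
        if orient == "h":
            mask[start : start + width, :] = False
        else:
            mask[:, start : start + width] = False
    return mask


def azimuthal_integration(
    frame: np.ndarray,
    geometry: DetectorGeometry,
    mask: np.ndarray | None = None,
    n_bins: int = 800,
    two_theta_range: tuple | None = None,
) -> RadialProfile:
    """Full-azimuth (0-360 degree) integration of an area frame.

    Each unmasked pixel is assigned a 2theta from its radial distance to
    the beam center; bins hold the mean intensity of their pixels.  Bins
    without pixels get zero intensity and npix = 0.
    """
    frame = np.asarray(frame, dtype=float)
    ny, nx = frame.shape
    cx, cy = geometry.beam_center_px
    yy, xx = np.ogrid[:ny, :nx]
    radius = np.hypot(xx - cx, yy - cy)
    tth = geometry.two_theta_deg(radius)
    if mask is None:
        mask = np.ones(frame.shape, dtype=bool)
    if two_theta_range is None:
        two_theta_range = (0.0, float(tth[mask].max()))
    lo, hi = two_theta_range
    edges = np.linspace(lo, hi, n_bins + 1)
    sel = mask & (tth >= lo) & (tth <= hi)  # inclusive: conserve every pixel
    idx = np.clip(((tth[sel] - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    sums = np.bincount(idx, weights=frame[sel], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(centers, mean, counts)


def subtract_empty_beam(profile: RadialProfile, empty: RadialProfile) -> RadialProfile:
    """Pointwise background subtraction, clipped at zero; grids must match."""
    if profile.two_theta_deg.shape != empty.two_theta_deg.shape or not np.allclose(
        profile.two_theta_deg, empty.two_theta_deg, rtol=0, atol=1e-12
    ):
        raise ValueError("profiles are on different 2theta grids")
    return RadialProfile(
        profile.two_theta_deg.copy(),
        np.clip(profile.intensity - empty.intensity, 0.0, None),
        profile.npix.copy(),
        profile.azimuth_range_deg,
    )


def fit_voigt_linear(
    profile: RadialProfile, window_deg: tuple = DEFAULT_WINDOW_DEG
) -> PeakFitResult:
    """Least-squares Voigt + linear fit of the peak inside ``window_deg``."""
    lo, hi = window_deg
    sel = (profile.two_theta_deg >= lo) & (profile.two_theta_deg <= hi)
    empty = sel & (profile.npix == 0)
    if empty.any():
        bad = profile.two_theta_deg[empty]
        raise ValueError(
            f"empty integration bins inside the fit window near 2theta = "
            f"{bad[:5].round(4).tolist()}"
        )
    x = profile.two_theta_deg[sel]
    y = profile.intensity[sel]
    if x.size < 10:
        raise ValueError("fit window contains fewer than 10 bins")

    base = 0.5 * (y[:3].mean() + y[-3:].mean())
    net = np.clip(y - base, 0.0, None)
    if net.sum() <= 0:
        raise ValueError("no peak above the linear background in the window")
    centroid = float((x * net).sum() / net.sum())
    spread = float(np.sqrt(((x - centroid) ** 2 * net).sum() / net.sum()))
    spread = max(spread, np.diff(x).mean())

    model = lmfit.models.VoigtModel(prefix="v_") + lmfit.models.LinearModel(prefix="l_")
    attempts = []
    best = None
    for scale in (1.0, 0.5, 2.0):
        params = model.make_params(
            v_amplitude=dict(value=float(net.sum() * np.diff(x).mean()), min=0.0),
            v_center=dict(value=centroid, min=lo, max=hi),
            v_sigma=dict(value=spread * scale / 2.0, min=1e-5),
            v_gamma=dict(value=spread * scale / 4.0, min=1e-6, vary=True),
            l_slope=dict(value=0.0),
            l_intercept=dict(value=float(base)),
        )
        try:
            res = model.fit(y, params, x=x)
        except Exception as exc:
            attempts.append((scale, repr(exc)))
            continue
        attempts.append((scale, f"success={res.success} redchi={res.redchi:.4g}"))
        if res.success and (best is None or res.redchi < best.redchi):
            best = res
    if best is None:
        raise FitError("Voigt+linear fit did not converge", attempts)
    p = best.params
    return PeakFitResult(
        center_2theta_deg=float(p["v_center"].value),
        center_se_deg=None if p["v_center"].stderr is None else float(p["v_center"].stderr),
        gaussian_sigma_deg=float(p["v_sigma"].value),
        lorentzian_gamma_deg=float(p["v_gamma"].value),
        amplitude=float(p["v_amplitude"].value),
        linear_slope=float(p["l_slope"].value),
        linear_intercept=float(p["l_intercept"].value),
        redchi=float(best.redchi),
    )


def two_theta_to_c(center_2theta_deg: float, geometry: DetectorGeometry) -> float:
    """c-lattice parameter (A) from the (002) center: d = lambda/(2 sin theta), c = 2 d."""
    if not 0.0 < center_2theta_deg < 180.0:
        raise ValueError("2theta must lie in (0, 180) degrees")
    theta = math.radians(center_2theta_deg) / 2.0
    d = geometry.wavelength_a / (2.0 * math.sin(theta))
    return 2.0 * d


def c_to_two_theta(c_a: float, geometry: DetectorGeometry) -> float:
    """Inverse of :func:`two_theta_to_c` (degrees)."""
    if c_a <= 0:
        raise ValueError("lattice parameter must be positive")
    s = geometry.wavelength_a / c_a  # = lambda / (2 d)
    if not 0.0 < s < 1.0:
        raise ValueError("no Bragg solution for this wavelength and lattice parameter")
    return math.degrees(2.0 * math.asin(s))


def _dc_dtth(center_deg: float, geometry: DetectorGeometry) -> float:
    """Derivative dc/d(2theta) in A/deg, for error propagation."""
    theta = math.radians(center_deg) / 2.0
    dc_dtheta = -geometry.wavelength_a * math.cos(theta) / math.sin(theta) ** 2
    return dc_dtheta * math.pi / 180.0 / 2.0


def strain_series(
    fits,
    exposures_s,
    geometry: DetectorGeometry,
    flux: float | None = None,
    fit_relaxation: bool = True,
) -> StrainSeries:
    """c(t) and percentage strain change from per-exposure peak fits.

    Strain(t) = 100 (c(t) - c(0)) / c(0) with first-order propagation of
    the fitted center standard errors.
    """
    exposures = np.asarray(exposures_s, dtype=float)
    if len(fits) != exposures.size:
        raise ValueError("number of fits and exposures differ")
    if exposures.size < 2:
        raise ValueError("need at least 2 time points")
    c = np.array([two_theta_to_c(f.center_2theta_deg, geometry) for f in fits])
    c_se = np.array(
        [
            abs(_dc_dtth(f.center_2theta_deg, geometry)) * (f.center_se_deg or 0.0)
            for f in fits
        ]
    )
    strain = 100.0 * (c - c[0]) / c[0]
    se = 100.0 * np.sqrt(c_se**2 + c_se[0] ** 2) / c[0]
    se[0] = 0.0
    rate = plateau = None
    if fit_relaxation:
        res = fit_saturating_exponential(exposures, strain, y0=0.0)
        rate = float(res.params["k"].value)
        plateau = float(res.params["plateau"].value)
    return StrainSeries(
        exposure_s=exposures,
        c_lattice_a=c,
        strain_pct=strain,
        strain_se_pct=se,
        flux=flux,
        relaxation_rate=rate,
        relaxation_plateau_pct=plateau,
    )
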
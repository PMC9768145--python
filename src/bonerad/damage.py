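"""Convolution damage-spread model and damage-accumulation kinetics.

The 1-D model chain is:

* ``B(w, x) = rect(x / w)`` -- the photoelectron source created inside the
  beam footprint of width ``w`` (um);
* ``eta(w, x) = (B * P) / integral(P)`` -- the energy-deposition profile,
  the convolution of the source with the photoelectron penetration
  distribution ``P(d_e)``; the normalization makes the profile conserve
  energy, ``integral(eta) = w`` for any ``P``;
* ``H(w, x, dt) = dt * eta(w, x)`` -- cumulative deposition after exposure
  ``dt`` (the time integral collapses to a product because ``eta`` does
  not depend on time);
* ``x_w`` -- the outermost ``|x|`` where ``H`` crosses the damage
  threshold (0.05 by default);
* ``zeta = 2 |x_w| / w`` -- damage diameter over beam diameter;
* ``Z = zeta_H * zeta_V`` -- relative damaged volume (area ratio of the
  damaged ellipse to the beam disc); for strongly anisotropic tissue
  ``zeta_V ~ 1`` and ``Z ~ zeta_H``.

The model object follows the Model -> Results convention:
``DamageSpreadModel(P).evaluate(w, dt)`` returns a
:class:`DamageModelResult`; ``sweep`` evaluates a (w, dt) grid into a
DataFrame.  ``ExponentialDamageModel`` fits first-order accumulation
kinetics to measured damage-vs-time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .fitting import FitError, fit_saturating_exponential
from .transport import PenetrationDistribution

#: Dimensionless cumulative-deposition threshold beyond which damage is
#: observed.
DEFAULT_THRESHOLD = 0.05


@dataclass(frozen=True)
class DamageModelConfig:
    """Numerical configuration of the damage-spread evaluation.

    ``grid_step``/``grid_extent`` default to automatic choices satisfying
    step <= min(beam width, P bin width) / 4 and full coverage of the
    kernel support.  ``zeta_v_mode`` selects whether the vertical spread
    ratio is fixed at unity (anisotropic tissue) or computed from a
    vertical penetration distribution.
    """

    threshold: float = DEFAULT_THRESHOLD
    grid_step: float | None = None
    grid_extent: float | None = None
    zeta_v_mode: str = "unity"
    tail_extrapolation: bool = True
    tail_fraction: float = 0.3

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.zeta_v_mode not in ("unity", "computed"):
            raise ValueError(f"unknown zeta_v_mode {self.zeta_v_mode!r}")


@dataclass
class DamageModelResult:
    """Damage-spread evaluation at one (beam width, exposure) point."""

    w_um: float
    dt_s: float
    x_um: np.ndarray
    eta: np.ndarray
    cumulative: np.ndarray
    x_w_um: float | None
    zeta_h: float
    zeta_v: float

    @property
    def relative_damage_volume(self) -> float:
        return relative_damage_volume(self.zeta_h, self.zeta_v)

    @property
    def z_percent(self) -> float:
        return 100.0 * self.relative_damage_volume

    def to_dict(self) -> dict:
        return {
            "w_um": self.w_um,
            "dt_s": self.dt_s,
            "x_w_um": np.nan if self.x_w_um is None else self.x_w_um,
            "zeta_h": self.zeta_h,
            "zeta_v": self.zeta_v,
            "Z_percent": self.z_percent,
        }

    def plot(self, ax=None):
        """Deposition profile with the beam edge and damage extent marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.x_um, self.cumulative, label="H(x)")
        ax.axvline(self.w_um / 2, color="gray", ls=":", label="beam edge")
        if self.x_w_um is not None:
            ax.axvline(self.x_w_um, color="crimson", ls="--", label="x_w")
        ax.set_xlabel("x (um)")
        ax.set_ylabel("cumulative deposition H")
        ax.set_yscale("log")
        ax.legend()
        return ax


def beam_source(w: float, x) -> np.ndarray:
    """rect(x/w): 1 inside the beam, 0 outside, 1/2 on the edge exactly."""
    if w <= 0:
        raise ValueError("beam width must be positive")
    x = np.asarray(x, dtype=float)
    inside = (np.abs(x) < w / 2).astype(float)
    edge = np.abs(np.abs(x) - w / 2) == 0.0
    return np.where(edge, 0.5, inside)


def _rect_cell_average(w: float, x: np.ndarray, step: float) -> np.ndarray:
    """Cell-averaged rect: overlap of each grid cell with [-w/2, w/2].

    Using cell averages (rather than point samples) makes the discrete
    convolution conserve integral(eta) = w exactly for any grid alignment.
    """
    lo = np.maximum(x - step / 2.0, -w / 2.0)
    hi = np.minimum(x + step / 2.0, w / 2.0)
    return np.clip(hi - lo, 0.0, None) / step


def _auto_grid(w: float, p: PenetrationDistribution, config: DamageModelConfig):
    step = config.grid_step
    if step is None:
        step = min(w / 8.0, p.bin_width / 4.0)
        step = max(step, 1e-5)
    if step > min(w, p.bin_width) / 4.0 + 1e-12:
        raise ValueError(
            "grid_step must be at most min(beam width, P bin width)/4"
        )
    extent = config.grid_extent
    if extent is None:
        extent = w / 2.0 + p.support_um + 2.0
    if extent < w / 2.0 + p.support_um:
        raise ValueError("grid_extent too small: truncates the P support")
    n_half = int(np.ceil(extent / step))
    x = np.arange(-n_half, n_half + 1) * step
    return x, step


def _rebin_mass(p: PenetrationDistribution, x: np.ndarray, step: float) -> np.ndarray:
    cell_edges = np.concatenate([x - step / 2.0, [x[-1] + step / 2.0]])
    cum = p.cdf(cell_edges)
    return np.diff(cum)


def energy_deposition(
    w: float, p: PenetrationDistribution, config: DamageModelConfig | None = None
):
    """Energy-deposition profile eta(w, x); returns (x, eta).

    Discrete convolution of the cell-averaged beam source with the
    penetration histogram, normalized by the total P mass so that
    integral(eta) dx = w (energy conservation).
    """
    if w <= 0:
        raise ValueError("beam width must be positive")
    config = config or DamageModelConfig()
    x, step = _auto_grid(w, p, config)
    mass = _rebin_mass(p, x, step)
    b = _rect_cell_average(w, x, step)
    eta = fftconvolve(b, mass / mass.sum(), mode="same")
    return x, np.clip(eta, 0.0, None)


def cumulative_deposition(eta: np.ndarray, dt_s: float) -> np.ndarray:
    """H = dt * eta (eta is time-independent, so the time integral is a product)."""
    if dt_s < 0:
        raise ValueError("exposure time must be non-negative")
    return dt_s * np.asarray(eta, dtype=float)


def damage_extent(
    x: np.ndarray, cumulative: np.ndarray, config: DamageModelConfig | None = None
) -> float | None:
    """Outermost |x| where H crosses the threshold; None if never damaged.

    The crossing is located by linear interpolation between the bracketing
    grid points on the decaying flank.
    """
    config = config or DamageModelConfig()
    thr = config.threshold
    h = np.asarray(cumulative, dtype=float)
    above = np.flatnonzero(h >= thr)
    if above.size == 0:
        return None
    i = above[-1]
    if i == h.size - 1:
        raise ValueError("H still above threshold at the grid edge; enlarge grid_extent")
    x1, x2, h1, h2 = x[i], x[i + 1], h[i], h[i + 1]
    if h1 == h2:
        return float(abs(x1))
    return float(abs(x1 + (h1 - thr) / (h1 - h2) * (x2 - x1)))


def relative_damage(x_w: float | None, w: float) -> float:
    """zeta = 2 |x_w| / w (0 when no point exceeds the threshold)."""
    if w <= 0:
        raise ValueError("beam width must be positive")
    if x_w is None:
        return 0.0
    return 2.0 * abs(x_w) / w


def relative_damage_volume(zeta_h: float, zeta_v: float) -> float:
    """Z = zeta_H * zeta_V, the damaged-to-illuminated area (= volume) ratio."""
    if zeta_h < 0 or zeta_v < 0:
        raise ValueError("zeta ratios must be non-negative")
    return zeta_h * zeta_v


class DamageSpreadModel:
    """Damage-spread predictions from a penetration distribution.

    Parameters
    ----------
    penetration : PenetrationDistribution
        Horizontal P(d_e).  Unless ``config.tail_extrapolation`` is off,
        its outer tail is replaced once by the fitted exponential
        extrapolation (the threshold probes survival levels below the raw
        histogram resolution).
    config : DamageModelConfig, optional
    penetration_vertical : PenetrationDistribution, optional
        Used only in ``zeta_v_mode="computed"``.
    """

    def __init__(
        self,
        penetration: PenetrationDistribution,
        config: DamageModelConfig | None = None,
        penetration_vertical: PenetrationDistribution | None = None,
    ):
        self.config = config or DamageModelConfig()
        self.penetration = self._prepare(penetration)
        self.penetration_vertical = (
            self._prepare(penetration_vertical)
            if penetration_vertical is not None
            else None
        )
        if self.config.zeta_v_mode == "computed" and self.penetration_vertical is None:
            raise ValueError("zeta_v_mode='computed' needs a vertical P(d_e)")

    def _prepare(self, p: PenetrationDistribution) -> PenetrationDistribution:
        if self.config.tail_extrapolation and "tail" not in p.meta and p.n_electrons:
            return p.with_exponential_tail(self.config.tail_fraction)
        return p

    def _zeta(self, p: PenetrationDistribution, w: float, dt: float):
        x, eta = energy_deposition(w, p, self.config)
        h = cumulative_deposition(eta, dt)
        x_w = damage_extent(x, h, self.config)
        return x, eta, h, x_w, relative_damage(x_w, w)

    def evaluate(self, w_um: float, dt_s: float) -> DamageModelResult:
        x, eta, h, x_w, zeta_h = self._zeta(self.penetration, w_um, dt_s)
        if self.config.zeta_v_mode == "unity":
            zeta_v = 1.0
        else:
            *_, x_wv, zeta_v = self._zeta(self.penetration_vertical, w_um, dt_s)
        return DamageModelResult(w_um, dt_s, x, eta, h, x_w, zeta_h, zeta_v)

    def sweep(self, widths_um, exposures_s) -> pd.DataFrame:
        rows = [
            self.evaluate(w, dt).to_dict()
            for w in widths_um
            for dt in exposures_s
        ]
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# first-order damage-accumulation kinetics
# ----------------------------------------------------------------------

@dataclass
class ExponentialDamageResults:
    """First-order accumulation fit D(t) = D_inf - (D_inf - 100) e^{-kt}."""

    k: float  # % / s rate constant
    plateau: float  # D_inf, %
    k_stderr: float | None
    plateau_stderr: float | None
    nobs: int
    redchi: float
    _lmfit_result: object = field(repr=False, default=None)

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.plateau - (self.plateau - 100.0) * np.exp(-self.k * t)

    def summary(self) -> str:
        se_k = "n/a" if self.k_stderr is None else f"{self.k_stderr:.4g}"
        se_p = "n/a" if self.plateau_stderr is None else f"{self.plateau_stderr:.4g}"
        lines = [
            "First-order damage accumulation  D(t) = D_inf - (D_inf - 100) exp(-k t)",
            f"  n obs           : {self.nobs}",
            f"  k   (% / s)     : {self.k:.5g}  (se {se_k})",
            f"  D_inf (%)       : {self.plateau:.5g}  (se {se_p})",
            f"  red. chi-square : {self.redchi:.4g}",
        ]
        return "\n".join(lines)


class ExponentialDamageModel:
    """Fit first-order accumulation kinetics to a damage-vs-time series.

    The curve is anchored at 100 % at t = 0 (damage is reported relative
    to the beam footprint, which is damaged immediately).
    """

    def __init__(self, times_s, damage_percent):
        self.times = np.asarray(times_s, dtype=float)
        self.damage = np.asarray(damage_percent, dtype=float)
        if self.times.size < 3:
            raise ValueError("need at least 3 time points")
        if self.times.size != self.damage.size:
            raise ValueError("times and damage series differ in length")

    def fit(self) -> ExponentialDamageResults:
        res = fit_saturating_exponential(self.times, self.damage, y0=100.0)
        k = res.params["k"]
        plateau = res.params["plateau"]
        return ExponentialDamageResults(
            k=float(k.value),
            plateau=float(plateau.value),
            k_stderr=None if k.stderr is None else float(k.stderr),
            plateau_stderr=None if plateau.stderr is None else float(plateau.stderr),
            nobs=self.times.size,
            redchi=float(res.redchi),
            _lmfit_result=res,
        )


__all__ = [
    "DEFAULT_THRESHOLD",
    "DamageModelConfig",
    "DamageModelResult",
    "DamageSpreadModel",
    "ExponentialDamageModel",
    "ExponentialDamageResults",
    "FitError",
    "beam_source",
    "cumulative_deposition",
    "damage_extent",
    "energy_deposition",
    "relative_damage",
    "relative_damage_volume",
]
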
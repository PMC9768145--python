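"""Monte-Carlo photoelectron transport in bone-like materials.

Single-scattering simulation in the continuous-slowing-down approximation:
free flights are sampled from the screened-Rutherford elastic mean free
path, polar deflections from the screened-Rutherford angular distribution,
and energy is degraded along each step with the Joy-Luo modified Bethe
stopping power.  This is the published physics of low-beam-energy electron
microscopy simulators, adequate for the <= 18 keV photoelectrons of
interest here.

The product consumed downstream is the penetration-depth distribution
P(d_e): for each electron d_e is the maximum displacement from its origin
projected on a fixed axis (the damage-relevant reach along a line through
the beam), histogrammed over mirrored signed values so that
P(+|d_e|) = P(-|d_e|) holds exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import constants
from .materials import Material, atomic_to_mass_fractions

#: Default electron kinetic-energy cutoff, keV.  The residual range below
#: this is far smaller than a histogram bin and is folded into the final
#: step.
DEFAULT_CUTOFF_KEV = 0.2

_MAX_ENERGY_KEV = 100.0
# fraction of the current energy an electron may lose in one step; caps the
# step length so the CSDA energy loss stays locally linear
_MAX_STEP_LOSS = 0.2


def _material_arrays(material: Material):
    mf = atomic_to_mass_fractions(material)
    syms = list(mf)
    ci = np.array([mf[s] for s in syms])
    zi = np.array([float(constants.atomic_number(s)) for s in syms])
    ai = np.array([constants.atomic_weight(s) for s in syms])
    ji = np.array([constants.MEAN_IONIZATION_KEV[s] for s in syms])
    return ci, zi, ai, ji, material.density


def stopping_power(energy_kev, material: Material, cutoff_kev: float = DEFAULT_CUTOFF_KEV):
    """Collision stopping power, keV per um (Joy-Luo modified Bethe).

    The Joy-Luo low-energy correction keeps the logarithm positive down to
    a few hundred eV, where the plain Bethe formula breaks down.
    Vectorized over ``energy_kev``.
    """
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < cutoff_kev):
        raise ValueError(f"energy below cutoff ({cutoff_kev} keV)")
    if np.any(e > _MAX_ENERGY_KEV):
        raise ValueError(f"energy above supported maximum ({_MAX_ENERGY_KEV} keV)")
    ci, zi, ai, ji, rho = _material_arrays(material)
    ki = 0.731 + 0.0688 * np.log10(zi)
    term = (ci * zi / ai) * np.log(1.166 * (e[..., None] + ki * ji) / ji)
    s_kev_cm = 78500.0 * rho / e * term.sum(axis=-1)
    return s_kev_cm * 1e-4  # keV/um


def csda_range(
    energy_kev: float,
    material: Material,
    cutoff_kev: float = DEFAULT_CUTOFF_KEV,
    n_grid: int = 4096,
) -> float:
    """Continuous-slowing-down path length from ``energy_kev`` to cutoff, um."""
    if energy_kev <= cutoff_kev:
        return 0.0
    grid = np.linspace(cutoff_kev, energy_kev, n_grid)
    return float(np.trapezoid(1.0 / stopping_power(grid, material), grid))


@dataclass
class Trajectory:
    """One simulated electron path.

    ``positions`` (k, 3) are scattering vertices in um starting at the
    origin; ``energies`` (k,) the residual kinetic energy in keV at each
    vertex, strictly decreasing.
    """

    positions: np.ndarray
    energies: np.ndarray
    start_energy_kev: float
    terminated: bool

    @property
    def path_length_um(self) -> float:
        steps = np.diff(self.positions, axis=0)
        return float(np.sqrt((steps**2).sum(axis=1)).sum())

    def max_projected_reach(self, axis: int = 0) -> float:
        return float(np.abs(self.positions[:, axis]).max())


def _transport(
    energy_kev: float,
    material: Material,
    n: int,
    rng: np.random.Generator,
    cutoff_kev: float,
    record: bool,
    direction: str = "isotropic",
):
    """Lockstep transport of ``n`` electrons; returns (reach, history)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if energy_kev < cutoff_kev or energy_kev > _MAX_ENERGY_KEV:
        raise ValueError(
            f"start energy must lie in [{cutoff_kev}, {_MAX_ENERGY_KEV}] keV"
        )
    ci, zi, ai, ji, rho = _material_arrays(material)
    ki = 0.731 + 0.0688 * np.log10(zi)
    n_i = constants.N_AVOGADRO * rho * ci / ai  # atoms / cm^3 per element

    pos = np.zeros((n, 3))
    energy = np.full(n, float(energy_kev))
    if direction == "isotropic":
        u = rng.random(n) * 2.0 - 1.0
        phi = rng.random(n) * 2.0 * np.pi
        st = np.sqrt(1.0 - u**2)
        direc = np.stack([u, st * np.cos(phi), st * np.sin(phi)], axis=1)
    elif direction == "pencil":
        direc = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))
    else:
        raise ValueError(f"unknown source direction {direction!r}")

    reach = np.zeros(n)
    active = energy > cutoff_kev
    history = [(np.arange(n), pos.copy(), energy.copy())] if record else None
    # residual CSDA range below the cutoff, folded into the terminal step
    residual_um = cutoff_kev / float(stopping_power(cutoff_kev, material, cutoff_kev / 10))

    while active.any():
        ia = np.flatnonzero(active)
        e = energy[ia]

        # screened-Rutherford elastic cross-sections per element
        alpha = 3.4e-3 * zi ** 0.67 / e[:, None]
        sigma = (
            5.21e-21
            * zi**2
            / e[:, None] ** 2
            * (4.0 * np.pi / (alpha * (1.0 + alpha)))
            * ((e[:, None] + 511.0) / (e[:, None] + 1022.0)) ** 2
        )
        per_el = n_i * sigma  # 1/cm per element
        inv_mfp = per_el.sum(axis=1)
        mfp_um = 1e4 / inv_mfp
        p_el = per_el / inv_mfp[:, None]

        step = -mfp_um * np.log(rng.random(ia.size))
        s_pow = np.asarray(stopping_power(e, material, cutoff_kev))
        step = np.minimum(step, _MAX_STEP_LOSS * e / s_pow)

        # clamp terminal steps so energy lands exactly on the cutoff and
        # append the sub-cutoff residual range
        e_new = e - s_pow * step
        dying = e_new <= cutoff_kev
        step = np.where(dying, (e - cutoff_kev) / s_pow + residual_um, step)
        e_new = np.where(dying, cutoff_kev, e_new)

        pos[ia] += direc[ia] * step[:, None]
        reach[ia] = np.maximum(reach[ia], np.abs(pos[ia, 0]))
        energy[ia] = e_new
        if record:
            history.append((ia, pos[ia].copy(), e_new.copy()))

        # elastic deflection of survivors (draws made for all for
        # reproducibility regardless of termination pattern)
        choice = (rng.random(ia.size)[:, None] > np.cumsum(p_el, axis=1)).sum(axis=1)
        a = alpha[np.arange(ia.size), choice]
        r = rng.random(ia.size)
        cos_t = 1.0 - 2.0 * a * r / (1.0 + a - r)
        sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
        phi = rng.random(ia.size) * 2.0 * np.pi
        ez = direc[ia]
        ref = np.where(
            np.abs(ez[:, 2:3]) < 0.99,
            np.array([[0.0, 0.0, 1.0]]),
            np.array([[1.0, 0.0, 0.0]]),
        )
        e1 = np.cross(ez, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(ez, e1)
        direc[ia] = (
            cos_t[:, None] * ez
            + sin_t[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        )
        active[ia] = ~dying

    return reach, history


def simulate_electrons(
    energy_kev: float,
    material: Material,
    n: int,
    seed: int,
    cutoff_kev: float = DEFAULT_CUTOFF_KEV,
    direction: str = "isotropic",
) -> list:
    """Simulate ``n`` photoelectron trajectories; reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    _, history = _transport(energy_kev, material, n, rng, cutoff_kev, True, direction)
    verts = [[] for _ in range(n)]
    eners = [[] for _ in range(n)]
    for ia, p, e in history:
        for j, idx in enumerate(ia):
            verts[idx].append(p[j])
            eners[idx].append(e[j])
    return [
        Trajectory(
            positions=np.asarray(v),
            energies=np.asarray(en),
            start_energy_kev=float(energy_kev),
            terminated=True,
        )
        for v, en in zip(verts, eners)
    ]


def penetration_depths(
    energy_kev: float,
    material: Material,
    n: int,
    seed: int,
    cutoff_kev: float = DEFAULT_CUTOFF_KEV,
    direction: str = "isotropic",
) -> np.ndarray:
    """Max axis-projected reach per electron (um), without storing paths.

    Uses the same sampling scheme as :func:`simulate_electrons`; identical
    seeds give identical depths.
    """
    rng = np.random.default_rng(seed)
    reach, _ = _transport(energy_kev, material, n, rng, cutoff_kev, False, direction)
    return reach


@dataclass
class PenetrationDistribution:
    """Symmetric histogram P(d_e) of photoelectron reach.

    ``bin_edges`` (2m+1,) span [-d_max, +d_max]; ``mass`` (2m,) sums to 1
    and mirrors exactly about zero.  ``meta`` records provenance (seed,
    cutoff, tail extrapolation parameters).
    """

    bin_edges: np.ndarray
    mass: np.ndarray
    n_electrons: int
    material: str
    energy_kev: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.bin_edges.size != self.mass.size + 1:
            raise ValueError("bin_edges must have len(mass)+1 entries")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("probability mass must sum to 1")
        if not np.allclose(self.mass, self.mass[::-1], rtol=0, atol=0):
            raise ValueError("mass must be exactly symmetric about zero")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(np.diff(self.bin_edges).min())

    @property
    def support_um(self) -> float:
        return float(self.bin_edges[-1])

    def half_survival(self):
        """(positive edges, survival of |d_e| at each edge)."""
        m = self.mass.size // 2
        half = self.mass[m:]
        edges = self.bin_edges[m:]
        surv = 1.0 - 2.0 * np.concatenate([[0.0], np.cumsum(half)])
        return edges, np.clip(surv, 0.0, 1.0)

    def cdf(self, x):
        """Piecewise-linear CDF at ``x`` (mass uniform within each bin)."""
        cum = np.concatenate([[0.0], np.cumsum(self.mass)])
        return np.interp(x, self.bin_edges, cum, left=0.0, right=1.0)

    def attenuation_length(self, tail_fraction: float = 0.3) -> float:
        return attenuation_length(self, tail_fraction)

    def with_exponential_tail(self, tail_fraction: float = 0.3, floor: float = 1e-9):
        """Replace the outer tail by its fitted exponential extrapolation.

        The sparse outer histogram is extrapolated smoothly beyond the
        last simulated electron, extending the support until the survival
        falls below ``floor``.  This reproduces the smooth-tail treatment
        the damage-spread analysis requires: the damage threshold probes
        survival levels well below the resolution of a finite electron
        sample.
        """
        lam, amp, knot = _fit_tail(self, tail_fraction)
        width = float(np.diff(self.bin_edges).mean())
        m = self.mass.size // 2
        half_mass = self.mass[m:].copy()
        edges = self.bin_edges[m:]

        def surv(d):
            return amp * np.exp(-d / lam)

        d_end = max(knot + lam * np.log(max(surv(knot), floor) / floor), edges[-1])
        n_ext = int(np.ceil((d_end - edges[-1]) / width))
        new_edges = np.concatenate([edges, edges[-1] + width * np.arange(1, n_ext + 1)])
        new_half = np.zeros(new_edges.size - 1)
        keep = new_edges[1:] <= knot
        new_half[: keep.sum()] = half_mass[: keep.sum()]
        lo = new_edges[:-1][~keep]
        hi = new_edges[1:][~keep]
        # survival at the knot from the empirical histogram, redistributed
        # along the fitted exponential so total mass is conserved
        tail_mass = 0.5 - new_half[: keep.sum()].sum()
        raw = np.exp(-lo / lam) - np.exp(-hi / lam)
        raw[-1] += np.exp(-hi[-1] / lam)  # beyond-grid remainder
        new_half[~np.concatenate([keep, np.zeros(0, bool)])] = tail_mass * raw / raw.sum()
        full_edges = np.concatenate([-new_edges[::-1], new_edges[1:]])
        full_mass = np.concatenate([new_half[::-1], new_half])
        meta = dict(self.meta)
        meta["tail"] = {
            "lambda_um": lam,
            "knot_um": float(knot),
            "tail_fraction": tail_fraction,
        }
        return PenetrationDistribution(
            full_edges, full_mass, self.n_electrons, self.material, self.energy_kev,
            self.seed, meta,
        )

    # ------------------------------------------------------------------
    # constructors and serialization
    # ------------------------------------------------------------------
    @classmethod
    def from_depths(
        cls, depths, n_bins: int = 120, material: str = "", energy_kev: float = 0.0,
        seed: int | None = None, meta: dict | None = None,
    ):
        depths = np.abs(np.asarray(depths, dtype=float))
        if depths.size == 0:
            raise ValueError("no penetration depths given")
        d_max = float(depths.max())
        if d_max == 0.0:
            d_max = 1e-6
        half, edges = np.histogram(depths, bins=n_bins, range=(0.0, d_max))
        half = half / (2.0 * depths.size)
        full_edges = np.concatenate([-edges[::-1], edges[1:]])
        full_mass = np.concatenate([half[::-1], half])
        return cls(full_edges, full_mass, depths.size, material, energy_kev, seed,
                   meta or {})

    @classmethod
    def from_laplace(cls, scale_um: float, extent_um: float | None = None,
                     n_bins: int = 400):
        """Analytic double-exponential kernel (oracle / generator default)."""
        if scale_um <= 0:
            raise ValueError("scale must be positive")
        extent = extent_um if extent_um is not None else 20.0 * scale_um
        edges = np.linspace(0.0, extent, n_bins + 1)
        half = 0.5 * (np.exp(-edges[:-1] / scale_um) - np.exp(-edges[1:] / scale_um))
        half[-1] += 0.5 * np.exp(-edges[-1] / scale_um)
        full_edges = np.concatenate([-edges[::-1], edges[1:]])
        full_mass = np.concatenate([half[::-1], half])
        return cls(full_edges, full_mass, 0, f"laplace({scale_um})", 0.0)

    @classmethod
    def from_point_mass(cls, half_width_um: float = 1e-3):
        edges = np.array([-half_width_um, 0.0, half_width_um])
        return cls(edges, np.array([0.5, 0.5]), 0, "point-mass", 0.0)

    def to_csv(self, path, sidecar: bool = True):
        import pandas as pd

        pd.DataFrame({"bin_center_um": self.centers, "mass": self.mass}).to_csv(
            path, index=False
        )
        if sidecar:
            side = {
                "material": self.material,
                "energy_kev": self.energy_kev,
                "n_electrons": self.n_electrons,
                "seed": self.seed,
                "bin_width_um": float(np.diff(self.bin_edges).mean()),
                "meta": self.meta,
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(side, fh, indent=1)

    @classmethod
    def from_csv(cls, path):
        import pandas as pd

        df = pd.read_csv(path)
        centers = df["bin_center_um"].to_numpy()
        mass = df["mass"].to_numpy()
        width = np.diff(centers).mean()
        edges = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
        meta = {}
        material, energy, n_el, seed = "", 0.0, 0, None
        try:
            with open(str(path) + ".json") as fh:
                side = json.load(fh)
            material = side.get("material", "")
            energy = side.get("energy_kev", 0.0)
            n_el = side.get("n_electrons", 0)
            seed = side.get("seed")
            meta = side.get("meta", {})
        except FileNotFoundError:
            pass
        mass = mass / mass.sum()
        mass = 0.5 * (mass + mass[::-1])  # restore exact symmetry after IO rounding
        return cls(edges, mass, n_el, material, energy, seed, meta)


def penetration_distribution(source, n_bins: int = 120, **kwargs) -> PenetrationDistribution:
    """Build P(d_e) from trajectories or precomputed depths.

    ``source`` is a list of :class:`Trajectory` (d_e = max axis-projected
    reach of each) or an array of depths in um.
    """
    if isinstance(source, (list, tuple)):
        if len(source) == 0:
            raise ValueError("empty trajectory list")
        if isinstance(source[0], Trajectory):
            depths = np.array([t.max_projected_reach() for t in source])
            kwargs.setdefault("energy_kev", source[0].start_energy_kev)
        else:
            depths = np.asarray(source, dtype=float)
    else:
        depths = np.asarray(source, dtype=float)
    return PenetrationDistribution.from_depths(depths, n_bins=n_bins, **kwargs)


def _fit_tail(p: PenetrationDistribution, tail_fraction: float):
    if not (0.0 < tail_fraction <= 0.5):
        raise ValueError("tail_fraction must lie in (0, 0.5]")
    edges, surv = p.half_survival()
    m = p.mass.size // 2
    half = p.mass[m:]
    sel = (surv <= tail_fraction) & (surv > 0.0)
    sel[-1] = False  # final edge has no bin (and zero survival) to weight it
    if sel.sum() < 4:
        raise ValueError(
            f"fewer than 4 bins in the outer {tail_fraction:.0%} tail; "
            "increase n_bins or tail_fraction"
        )
    # weight each edge by the probability mass of the bin to its right, so
    # the fit reflects electrons rather than sparse far-tail bins
    wts = np.sqrt(np.maximum(half[sel[:-1]], 1e-30))
    slope, intercept = np.polyfit(edges[sel], np.log(surv[sel]), 1, w=wts)
    if slope >= 0:
        raise ValueError("tail survival does not decay; cannot fit attenuation length")
    lam = -1.0 / slope
    return lam, float(np.exp(intercept)), float(edges[sel][0])


def attenuation_length(p: PenetrationDistribution, tail_fraction: float = 0.3) -> float:
    """1/e length (um) of the outer tail of the survival of |d_e|.

    Least-squares slope of log-survival over the bins holding the outer
    ``tail_fraction`` of probability mass.
    """
    lam, _, _ = _fit_tail(p, tail_fraction)
    return lam
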
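"""Materials, emission energetics, beam attenuation and absorbed dose.

The bone composite is described by three presets matching the compositions
used throughout the analysis:

* ``bone``     -- whole mineralized tissue, Ca0.09863 P0.05918 O0.31413
  N0.04946 C0.17861 H0.3 at 1.41 g/cm^3;
* ``mineral``  -- the carbonated-apatite phase, H2 O26 P6 Ca10 at
  1.01 g/cm^3 (the effective mineral density within the tissue);
* ``collagen`` -- the organic matrix, H0.49514 C0.31554 N0.08738 O0.10194
  at 0.41 g/cm^3.

Compositions are stored as atomic fractions; mass-based quantities
(attenuation, stopping power) convert through the standard atomic weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import constants
from .constants import UnknownElementError


@dataclass(frozen=True)
class Material:
    """A homogeneous material: atomic composition plus mass density.

    Atomic fractions are normalized to sum to one on construction, so
    formula-unit counts (e.g. ``{"H": 2, "O": 26, "P": 6, "Ca": 10}``)
    are accepted as-is.
    """

    name: str
    atomic_fractions: dict
    density: float  # g/cm^3

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if not self.atomic_fractions:
            raise ValueError("atomic_fractions must not be empty")
        total = 0.0
        for sym, frac in self.atomic_fractions.items():
            if sym not in constants.ELEMENTS:
                raise UnknownElementError(sym)
            if frac <= 0:
                raise ValueError(f"atomic fraction for {sym} must be positive")
            total += frac
        normalized = {s: f / total for s, f in self.atomic_fractions.items()}
        object.__setattr__(self, "atomic_fractions", normalized)

    @property
    def elements(self) -> tuple:
        return tuple(self.atomic_fractions)

    def mass_fractions(self) -> dict:
        return atomic_to_mass_fractions(self)


@dataclass(frozen=True)
class BeamSpec:
    """Incident X-ray microbeam.

    ``width_h_um``/``width_v_um`` are the lateral beam dimensions (the
    pinhole diameter for a circular beam); they are the ``w`` entering the
    damage-spread model.
    """

    energy_kev: float
    flux: float  # photons / s
    width_h_um: float
    width_v_um: float
    profile: str = "rect"
    smear_um: float = 0.0

    def __post_init__(self):
        if self.energy_kev <= 0:
            raise ValueError("beam energy must be positive")
        if self.width_h_um <= 0 or self.width_v_um <= 0:
            raise ValueError("beam widths must be positive")
        if self.flux < 0:
            raise ValueError("flux must be non-negative")
        if self.profile not in ("rect", "rect-gaussian-smeared"):
            raise ValueError(f"unknown beam profile {self.profile!r}")

    @property
    def area_um2(self) -> float:
        """Elliptical beam cross-section (circular if widths equal)."""
        return math.pi / 4.0 * self.width_h_um * self.width_v_um


@dataclass(frozen=True)
class EmissionEvent:
    """Photoionization of an inner shell: ejected electron + fluorescence."""

    element: str
    shell: str
    photoelectron_energy_kev: float
    fluorescence_energy_kev: float


BONE = Material(
    "bone",
    {"Ca": 0.09863, "P": 0.05918, "O": 0.31413, "N": 0.04946, "C": 0.17861, "H": 0.3},
    1.41,
)
MINERAL = Material("mineral", {"H": 2, "O": 26, "P": 6, "Ca": 10}, 1.01)
COLLAGEN = Material(
    "collagen", {"H": 0.49514, "C": 0.31554, "N": 0.08738, "O": 0.10194}, 0.41
)

PRESETS = {m.name: m for m in (BONE, MINERAL, COLLAGEN)}


def get_material(name: str) -> Material:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown material preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def load_material(path) -> Material:
    """Read a material from a key-value text config.

    Expected keys: ``name``, ``elements`` (comma list of symbols),
    ``fractions`` (comma list of numbers), ``density`` (g/cm^3).
    Lines starting with ``#`` are ignored; ``=`` or ``:`` separate keys
    from values.
    """
    entries = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            for sep in ("=", ":"):
                if sep in line:
                    key, val = line.split(sep, 1)
                    entries[key.strip().lower()] = val.strip()
                    break
    missing = {"name", "elements", "fractions", "density"} - set(entries)
    if missing:
        raise ValueError(f"material config missing keys: {sorted(missing)}")
    symbols = [s.strip() for s in entries["elements"].split(",")]
    fractions = [float(x) for x in entries["fractions"].split(",")]
    if len(symbols) != len(fractions):
        raise ValueError("elements and fractions have different lengths")
    return Material(entries["name"], dict(zip(symbols, fractions)), float(entries["density"]))


def atomic_to_mass_fractions(material: Material) -> dict:
    """Convert atomic fractions to mass fractions (sum exactly 1)."""
    masses = {
        sym: frac * constants.atomic_weight(sym)
        for sym, frac in material.atomic_fractions.items()
    }
    total = sum(masses.values())
    return {sym: m / total for sym, m in masses.items()}


def photoelectron_energy(incident_kev: float, element: str, shell: str = "K") -> float:
    """Kinetic energy of the ejected photoelectron, keV.

    E_pe = E_photon - E_binding(shell).  Raises if the incident photon is
    below the absorption edge.
    """
    if shell != "K":
        raise ValueError(f"only the K shell is tabulated, got {shell!r}")
    if element not in constants.K_EDGE_KEV:
        raise UnknownElementError(element)
    binding = constants.K_EDGE_KEV[element]
    if incident_kev < binding:
        raise ValueError(
            f"{incident_kev} keV is below the {element} {shell} absorption edge "
            f"({binding} keV)"
        )
    return incident_kev - binding


def fluorescence_energy(element: str, shell: str = "K") -> float:
    """K-alpha fluorescence line energy, keV."""
    if shell != "K":
        raise ValueError(f"only the K shell is tabulated, got {shell!r}")
    try:
        return constants.KALPHA_KEV[element]
    except KeyError:
        raise UnknownElementError(element) from None


def emission_event(incident_kev: float, element: str, shell: str = "K") -> EmissionEvent:
    return EmissionEvent(
        element,
        shell,
        photoelectron_energy(incident_kev, element, shell),
        fluorescence_energy(element, shell),
    )


def mass_attenuation(material: Material, energy_kev: float) -> float:
    """Mass-fraction-weighted photoelectric mu/rho of the mixture, cm^2/g."""
    mf = atomic_to_mass_fractions(material)
    return sum(w * constants.mu_rho_photoelectric(sym, energy_kev) for sym, w in mf.items())


def transmission(material: Material, thickness_um: float, energy_kev: float) -> float:
    """Beer-Lambert transmitted fraction through ``thickness_um`` of material."""
    if thickness_um < 0:
        raise ValueError("thickness must be non-negative")
    mu = mass_attenuation(material, energy_kev) * material.density  # 1/cm
    return math.exp(-mu * thickness_um * 1e-4)


def absorbed_dose(
    beam: BeamSpec, material: Material, thickness_um: float, exposure_s: float
) -> float:
    """Absorbed dose in Gy for the illuminated volume.

    dose = N_photons * E_photon * (1 - T) / m_illuminated, with the
    illuminated mass rho * A_beam * t.  The absorbed (not incident) energy
    enters, per the definition of the gray.
    """
    if exposure_s < 0:
        raise ValueError("exposure must be non-negative")
    if beam.area_um2 <= 0:
        raise ValueError("beam cross-section must be positive")
    energy_j = beam.energy_kev * 1.602176634e-16
    absorbed_fraction = 1.0 - transmission(material, thickness_um, beam.energy_kev)
    mass_kg = material.density * beam.area_um2 * 1e-8 * thickness_um * 1e-4 * 1e-3
    if mass_kg == 0:
        raise ValueError("illuminated mass is zero (zero thickness)")
    return beam.flux * exposure_s * energy_j * absorbed_fraction / mass_kg
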
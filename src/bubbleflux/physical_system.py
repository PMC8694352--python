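"""Gas, liquid and column definitions shared by every model in the package.

All quantities are SI internally (m, s, Pa, mol, K).  Interface layers (the
CLI, file readers) convert bench units such as μm, ml min⁻¹ or h⁻¹ exactly
once, at the boundary.

The bulk liquid state is expressed through per-gas *saturation ratios*
``S = C / C*``: the dissolved concentration divided by the equilibrium
solubility of that gas.  ``S = 1`` for an air gas means equilibrium with
ambient air (the gas's atmospheric partial pressure); ``S = 1`` for CO₂
means equilibrium with pure CO₂ at the reference pressure, matching
sparging with pure CO₂.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "R_GAS",
    "GRAVITY",
    "AIR_MOLE_FRACTION",
    "GasSpecies",
    "DissolvedGasState",
    "LiquidMedium",
    "Column",
    "ColumnSystem",
    "InvalidSolubilityError",
    "saturation_ratio",
    "gas_solubility",
    "register_gas",
    "get_gas",
    "load_system",
    "save_system",
    "default_system",
]

R_GAS = 8.314462618  # J mol⁻¹ K⁻¹
GRAVITY = 9.81  # m s⁻²

#: Mole fractions of dry air used as the saturation reference for air gases.
AIR_MOLE_FRACTION = {"O2": 0.2095, "N2": 0.7905}


class InvalidSolubilityError(ValueError):
    """Raised when a solubility (C*) is zero or negative."""


@dataclass(frozen=True)
class GasSpecies:
    """A gas with the physical constants the mass-transfer model needs.

    Parameters
    ----------
    name
        Identifier, e.g. ``"CO2"``.
    henry_constant
        Solubility per unit partial pressure, mol m⁻³ Pa⁻¹.
    diffusivity
        Liquid-phase diffusion coefficient, m² s⁻¹.
    molar_mass
        kg mol⁻¹.
    """

    name: str
    henry_constant: float
    diffusivity: float
    molar_mass: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gas species needs a non-empty name")
        for attr in ("henry_constant", "diffusivity", "molar_mass"):
            if not getattr(self, attr) > 0.0:
                raise ValueError(f"{self.name}: {attr} must be positive")


@dataclass(frozen=True)
class DissolvedGasState:
    """Bulk dissolved state of one gas, expressed as a saturation ratio.

    ``reference_fraction`` defines what "saturated" means for this gas: the
    mole fraction of the gas in the phase the liquid equilibrates with.  Air
    gases default to their atmospheric mole fractions (O₂ 0.2095, N₂
    0.7905); any other gas defaults to 1.0 (saturation against the pure
    gas), which matches sparging with pure CO₂.
    """

    species: GasSpecies
    saturation_ratio: float
    concentration: float | None = None
    solubility: float | None = None
    reference_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.saturation_ratio < 0.0:
            raise ValueError("saturation ratio must be >= 0")
        if self.reference_fraction is None:
            object.__setattr__(
                self,
                "reference_fraction",
                AIR_MOLE_FRACTION.get(self.species.name, 1.0),
            )
        if (self.concentration is None) != (self.solubility is None):
            raise ValueError("concentration and solubility must be given together")
        if self.concentration is not None and self.solubility is not None:
            implied = saturation_ratio(self.concentration, self.solubility)
            if not math.isclose(implied, self.saturation_ratio, rel_tol=1e-12, abs_tol=1e-15):
                raise ValueError(
                    f"{self.species.name}: saturation ratio {self.saturation_ratio} "
                    f"inconsistent with C/C* = {implied}"
                )


@dataclass(frozen=True)
class LiquidMedium:
    """Liquid-phase properties plus the bulk dissolved-gas state.

    Attributes
    ----------
    density : kg m⁻³
    dynamic_viscosity : Pa s
    surface_tension : N m⁻¹
    temperature : K
    dissolved : tuple of DissolvedGasState, one entry per gas
    """

    density: float
    dynamic_viscosity: float
    surface_tension: float
    temperature: float
    dissolved: tuple[DissolvedGasState, ...] = ()

    def __post_init__(self) -> None:
        for attr in ("density", "dynamic_viscosity", "temperature"):
            if not getattr(self, attr) > 0.0:
                raise ValueError(f"{attr} must be positive")
        if self.surface_tension < 0.0:
            raise ValueError("surface tension must be >= 0")
        names = [s.species.name for s in self.dissolved]
        if len(names) != len(set(names)):
            raise ValueError("exactly one dissolved state per gas species")
        object.__setattr__(self, "dissolved", tuple(self.dissolved))

    @property
    def species(self) -> tuple[GasSpecies, ...]:
        return tuple(s.species for s in self.dissolved)

    def state_of(self, name: str) -> DissolvedGasState:
        for s in self.dissolved:
            if s.species.name == name:
                return s
        raise KeyError(f"no dissolved state for gas {name!r}")

    def saturation_of(self, name: str) -> float:
        return self.state_of(name).saturation_ratio

    def with_saturations(self, **ratios: float) -> "LiquidMedium":
        """Return a copy with selected saturation ratios replaced.

        Example: ``medium.with_saturations(CO2=1.0, O2=0.0, N2=0.0)`` builds
        the CO₂-saturated, air-stripped bulk that prolonged CO₂ sparging
        produces.
        """
        unknown = set(ratios) - {s.species.name for s in self.dissolved}
        if unknown:
            raise KeyError(f"unknown gas species: {sorted(unknown)}")
        new = tuple(
            replace(s, saturation_ratio=ratios.get(s.species.name, s.saturation_ratio),
                    concentration=None, solubility=None)
            for s in self.dissolved
        )
        return replace(self, dissolved=new)


@dataclass(frozen=True)
class Column:
    """Bubble-column geometry and headspace pressure.

    ``fill_height`` is the liquid height above the sparger (m);
    ``ambient_pressure`` the pressure at the liquid surface (Pa).
    """

    fill_height: float
    ambient_pressure: float

    def __post_init__(self) -> None:
        if not self.fill_height > 0.0:
            raise ValueError("fill height must be positive")
        if not self.ambient_pressure > 0.0:
            raise ValueError("ambient pressure must be positive")


@dataclass(frozen=True)
class ColumnSystem:
    """A named (medium, column) pair — everything one simulation needs."""

    name: str
    medium: LiquidMedium
    column: Column

    def __iter__(self) -> Iterator:
        # allows ``medium, column = system`` unpacking (name accessible as attr)
        return iter((self.medium, self.column))


def saturation_ratio(concentration: float, solubility: float) -> float:
    """Saturation ratio S = C / C* of a dissolved gas.

    Parameters
    ----------
    concentration
        Dissolved gas concentration C, mol m⁻³ (>= 0).
    solubility
        Equilibrium solubility C*, mol m⁻³ (> 0).
    """
    if not solubility > 0.0:
        raise InvalidSolubilityError(f"solubility must be positive, got {solubility}")
    if concentration < 0.0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    return concentration / solubility


def gas_solubility(species: GasSpecies, partial_pressure: float) -> float:
    """Henry's-law solubility C* = H · p at a given partial pressure (Pa)."""
    if partial_pressure < 0.0:
        raise ValueError(f"partial pressure must be >= 0, got {partial_pressure}")
    return species.henry_constant * partial_pressure


# ---------------------------------------------------------------------------
# Default gas set (pure-water constants at 30 °C) and registry
# ---------------------------------------------------------------------------

CO2 = GasSpecies("CO2", henry_constant=3.46e-4, diffusivity=1.14e-9, molar_mass=44.01e-3)
O2 = GasSpecies("O2", henry_constant=1.2e-5, diffusivity=2.2e-9, molar_mass=31.998e-3)
N2 = GasSpecies("N2", henry_constant=6.4e-6, diffusivity=2.0e-9, molar_mass=28.014e-3)

_GAS_REGISTRY: dict[str, GasSpecies] = {g.name: g for g in (CO2, O2, N2)}


def register_gas(species: GasSpecies) -> None:
    """Make a gas available by name to config loading and the CLI."""
    _GAS_REGISTRY[species.name] = species


def get_gas(name: str) -> GasSpecies:
    try:
        return _GAS_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown gas {name!r}; registered: {sorted(_GAS_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

_CONFIG_DIR = Path(__file__).parent / "configs"


def _config_path(name_or_path: str | Path) -> Path:
    p = Path(name_or_path)
    if p.suffix in {".yaml", ".yml"} or p.exists():
        return p
    shipped = _CONFIG_DIR / f"{name_or_path}.yaml"
    if shipped.exists():
        return shipped
    raise FileNotFoundError(
        f"no config {name_or_path!r}; shipped configs: "
        f"{sorted(q.stem for q in _CONFIG_DIR.glob('*.yaml'))}"
    )


def load_system(name_or_path: str | Path) -> ColumnSystem:
    """Load a column system from a shipped config name or a YAML path.

    The shipped ``"tea_1M_30C"`` config holds the 1 M aqueous
    triethanolamine system at 30 °C and 101.3 kPa with pure-water gas
    constants, initialized air-saturated (S_O2 = S_N2 = 1) and CO₂-free.
    """
    path = _config_path(name_or_path)
    raw = yaml.safe_load(path.read_text())
    gases = {}
    for name, props in raw.get("gases", {}).items():
        gases[name] = GasSpecies(
            name,
            henry_constant=float(props["henry_constant"]),
            diffusivity=float(props["diffusivity"]),
            molar_mass=float(props["molar_mass"]),
        )
    dissolved = tuple(
        DissolvedGasState(gases[name], saturation_ratio=float(s))
        for name, s in raw.get("dissolved", {}).items()
    )
    med = raw["medium"]
    medium = LiquidMedium(
        density=float(med["density"]),
        dynamic_viscosity=float(med["dynamic_viscosity"]),
        surface_tension=float(med["surface_tension"]),
        temperature=float(med["temperature"]),
        dissolved=dissolved,
    )
    col = raw["column"]
    column = Column(
        fill_height=float(col["fill_height"]),
        ambient_pressure=float(col["ambient_pressure"]),
    )
    return ColumnSystem(name=str(raw.get("name", path.stem)), medium=medium, column=column)


def save_system(system: ColumnSystem, path: str | Path) -> None:
    """Serialize a system to YAML; ``load_system`` round-trips bit-exactly."""
    doc = {
        "name": system.name,
        "medium": {
            "density": system.medium.density,
            "dynamic_viscosity": system.medium.dynamic_viscosity,
            "surface_tension": system.medium.surface_tension,
            "temperature": system.medium.temperature,
        },
        "column": {
            "fill_height": system.column.fill_height,
            "ambient_pressure": system.column.ambient_pressure,
        },
        "gases": {
            s.species.name: {
                "henry_constant": s.species.henry_constant,
                "diffusivity": s.species.diffusivity,
                "molar_mass": s.species.molar_mass,
            }
            for s in system.medium.dissolved
        },
        "dissolved": {
            s.species.name: s.saturation_ratio for s in system.medium.dissolved
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_system() -> ColumnSystem:
    """The shipped 1 M aqueous TEA system at 30 °C ("tea_1M_30C")."""
    return load_system("tea_1M_30C")
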
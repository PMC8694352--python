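"""Single-bubble shrinkage, composition exchange and rise.

The model integrates the mole inventory n_i of each gas in one spherical
bubble together with its height z above the sparger:

    dn_i/dt = −k_L,i · π d² · ( H_i x_i P_b − S_i H_i x_ref,i P_ref(z) )
    dz/dt   = v(d)

with

* P_b = P_atm + ρ_l g (h − z) + 4σ/d — internal pressure including the
  hydrostatic head and the Laplace excess, which grows as the bubble
  shrinks and accelerates the final stage of dissolution;
* k_L,i from the Ranz–Marshall correlation Sh = 2 + 0.6 Re^½ Sc^⅓;
* v(d) from the Stokes or Hadamard–Rybczynski creeping-flow law;
* the dissolved-side driving force S_i H_i x_ref,i P_ref(z), where
  x_ref,i is the gas's saturation reference composition (atmospheric
  fractions for O₂/N₂, 1.0 for CO₂) and P_ref(z) is by default the local
  hydrostatic pressure P_atm + ρ_l g (h − z): the bulk is taken to be
  equilibrated in situ by bubbles dissolving at depth.  The alternative
  convention P_ref = P_atm is selectable.

The bubble is isothermal at the medium temperature, ideal-gas, and rises
through an infinite bath (bulk saturation ratios constant during a run).
Coalescence, swarm interactions and liquid flow are outside the model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .physical_system import (
    GRAVITY,
    R_GAS,
    Column,
    GasSpecies,
    LiquidMedium,
)

__all__ = [
    "RiseLaw",
    "BubbleState",
    "BubbleTrajectory",
    "InvalidDiameterError",
    "IntegrationError",
    "NoThresholdError",
    "bubble_pressure",
    "rise_velocity",
    "film_coefficient",
    "diameter_from_moles",
    "simulate_bubble",
    "surfacing_threshold",
    "DISSOLUTION_CUTOFF",
]

#: Diameter below which a bubble counts as fully dissolved (m).  Well below
#: the 9 μm optical detection limit; avoids the 1/d singularity of the
#: Laplace term.
DISSOLUTION_CUTOFF = 1e-6


class InvalidDiameterError(ValueError):
    """Raised for a non-positive bubble diameter."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries solver diagnostics."""


class NoThresholdError(RuntimeError):
    """Raised when no dissolved/surfaced transition exists in the scan range."""


class RiseLaw(str, enum.Enum):
    """Creeping-flow terminal rise velocity law.

    ``STOKES``: rigid sphere, v = g d² (ρ_l − ρ_g) / (18 η).
    ``HADAMARD_RYBCZYNSKI``: fluid sphere with fully mobile interface,
    1.5 × the Stokes value in the inviscid-gas limit.
    """

    STOKES = "stokes"
    HADAMARD_RYBCZYNSKI = "hadamard_rybczynski"

    @property
    def factor(self) -> float:
        return 1.5 if self is RiseLaw.HADAMARD_RYBCZYNSKI else 1.0


def bubble_pressure(d: float, z: float, medium: LiquidMedium, column: Column) -> float:
    """Internal pressure of a bubble of diameter ``d`` at height ``z``.

    P_b = P_atm + ρ_l g (h − z) + 4σ/d.
    """
    if not d > 0.0:
        raise InvalidDiameterError(f"diameter must be positive, got {d}")
    if not 0.0 <= z <= column.fill_height:
        raise ValueError(f"height {z} outside [0, {column.fill_height}]")
    head = medium.density * GRAVITY * (column.fill_height - z)
    return column.ambient_pressure + head + 4.0 * medium.surface_tension / d


def rise_velocity(
    d: float,
    medium: LiquidMedium,
    gas_density: float = 0.0,
    law: RiseLaw = RiseLaw.HADAMARD_RYBCZYNSKI,
) -> float:
    """Terminal rise velocity of a bubble of diameter ``d`` (m s⁻¹)."""
    if d < 0.0:
        raise InvalidDiameterError(f"diameter must be >= 0, got {d}")
    if not medium.dynamic_viscosity > 0.0:
        raise ValueError("medium viscosity must be positive")
    v = (
        GRAVITY
        * d * d
        * (medium.density - gas_density)
        / (18.0 * medium.dynamic_viscosity)
    )
    return max(RiseLaw(law).factor * v, 0.0)


def film_coefficient(
    d: float, v: float, species: GasSpecies, medium: LiquidMedium
) -> float:
    """Liquid-film mass-transfer coefficient k_L from Ranz–Marshall (m s⁻¹).

    Sh = 2 + 0.6 Re^½ Sc^⅓ with Re = ρ_l v d / η and Sc = η / (ρ_l D);
    k_L = Sh · D / d.  The stagnant limit (v = 0) gives Sh = 2, k_L = 2D/d,
    so k_L grows without bound as the bubble shrinks.
    """
    if not d > 0.0:
        raise InvalidDiameterError(f"diameter must be positive, got {d}")
    if v < 0.0:
        raise ValueError(f"velocity must be >= 0, got {v}")
    re = medium.density * v * d / medium.dynamic_viscosity
    sc = medium.dynamic_viscosity / (medium.density * species.diffusivity)
    sh = 2.0 + 0.6 * np.sqrt(re) * sc ** (1.0 / 3.0)
    return sh * species.diffusivity / d


def diameter_from_moles(
    n_total: float,
    z: float,
    medium: LiquidMedium,
    column: Column,
) -> float:
    """Invert the ideal-gas closure P_b(d) · (π/6) d³ = n R T for d.

    With the Laplace term the closure is the cubic
    P₀ d³ + 4σ d² = 6 n R T / π,  P₀ = P_atm + ρ_l g (h − z),
    which has exactly one positive root.  Solved by Newton iteration
    (monotone and convex for d > 0) with a bisection safeguard; relative
    tolerance 1e-12.
    """
    if n_total <= 0.0:
        return 0.0
    p0 = column.ambient_pressure + medium.density * GRAVITY * (column.fill_height - z)
    sig4 = 4.0 * medium.surface_tension
    c = 6.0 * n_total * R_GAS * medium.temperature / np.pi

    def f(d: float) -> float:
        return (p0 * d + sig4) * d * d - c

    d = (c / p0) ** (1.0 / 3.0)  # Laplace-free guess (upper bound on the root)
    for _ in range(100):
        step = f(d) / (3.0 * p0 * d * d + 2.0 * sig4 * d)
        d -= step
        if abs(step) <= 1e-12 * d:
            return d
    # Newton should always converge here; fall back to bisection if not.
    from scipy.optimize import brentq

    hi = (c / p0) ** (1.0 / 3.0)
    lo = hi * 1e-8
    while f(lo) > 0.0:
        lo *= 0.1
    return brentq(f, lo, hi, xtol=0.0, rtol=1e-13)


@dataclass(frozen=True)
class BubbleState:
    """Bubble snapshot: per-gas moles, height and derived geometry."""

    moles: dict[str, float]
    height: float
    diameter: float
    pressure: float
    mole_fractions: dict[str, float]

    @property
    def total_moles(self) -> float:
        return sum(self.moles.values())


@dataclass(frozen=True)
class BubbleTrajectory:
    """Result of one single-bubble integration.

    ``terminal_event`` is ``"dissolved"`` (diameter reached the cutoff),
    ``"surfaced"`` (z reached the fill height) or ``"time_limit"``.
    """

    species: tuple[str, ...]
    time: np.ndarray  # s, strictly increasing
    height: np.ndarray  # m
    diameter: np.ndarray  # m
    pressure: np.ndarray  # Pa
    moles: np.ndarray  # (n_steps, n_gas), mol
    terminal_event: str
    dissolution_time: float | None

    @property
    def mole_fractions(self) -> np.ndarray:
        tot = self.moles.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(tot > 0.0, self.moles / np.where(tot > 0, tot, 1.0), np.nan)
        return x

    @property
    def rise_distance(self) -> float:
        return float(self.height[-1] - self.height[0])

    def state(self, i: int) -> BubbleState:
        x = self.mole_fractions[i]
        return BubbleState(
            moles=dict(zip(self.species, self.moles[i])),
            height=float(self.height[i]),
            diameter=float(self.diameter[i]),
            pressure=float(self.pressure[i]),
            mole_fractions=dict(zip(self.species, x)),
        )

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a tidy table: t, z, d, P_b, x_i, n_total."""
        df = pd.DataFrame(
            {
                "t_s": self.time,
                "z_m": self.height,
                "d_m": self.diameter,
                "P_b_Pa": self.pressure,
            }
        )
        x = self.mole_fractions
        for j, name in enumerate(self.species):
            df[f"x_{name}"] = x[:, j]
        df["n_total_mol"] = self.moles.sum(axis=1)
        return df


def _normalized_composition(
    composition0: dict[str, float], names: tuple[str, ...]
) -> np.ndarray:
    unknown = set(composition0) - set(names)
    if unknown:
        raise ValueError(f"composition names gases without dissolved state: {sorted(unknown)}")
    x0 = np.array([float(composition0.get(n, 0.0)) for n in names])
    if np.any(x0 < 0.0):
        raise ValueError("mole fractions must be >= 0")
    total = x0.sum()
    if not np.isclose(total, 1.0, rtol=0.0, atol=1e-8):
        raise ValueError(f"composition must sum to 1, got {total}")
    return x0 / total


def simulate_bubble(
    d0: float,
    composition0: dict[str, float],
    medium: LiquidMedium,
    column: Column,
    law: RiseLaw = RiseLaw.HADAMARD_RYBCZYNSKI,
    *,
    z0: float = 0.0,
    t_max: float = 300.0,
    reference_pressure: str = "local",
    cutoff: float = DISSOLUTION_CUTOFF,
    rtol: float = 1e-8,
) -> BubbleTrajectory:
    """Integrate one bubble until dissolution, surfacing or ``t_max``.

    Parameters
    ----------
    d0
        Initial diameter, m (> ``cutoff``).
    composition0
        Initial mole fractions by gas name; must sum to 1.
    law
        Rise-velocity law; Hadamard–Rybczynski by default.
    z0
        Release height above the sparger, m.
    reference_pressure
        ``"local"`` (default): the bulk of each gas is saturated against
        the local hydrostatic pressure P_atm + ρ_l g (h − z).
        ``"atmospheric"``: saturated against P_atm regardless of depth.
    cutoff
        Dissolution cutoff on diameter, m.

    Returns
    -------
    BubbleTrajectory
        States at the solver's internal steps plus the terminal event; the
        ideal-gas closure holds at every stored step by construction.
    """
    if not d0 > cutoff:
        raise InvalidDiameterError(f"initial diameter {d0} must exceed cutoff {cutoff}")
    if reference_pressure not in {"local", "atmospheric"}:
        raise ValueError("reference_pressure must be 'local' or 'atmospheric'")
    names = tuple(s.species.name for s in medium.dissolved)
    if not names:
        raise ValueError("medium has no dissolved-gas states")
    x0 = _normalized_composition(composition0, names)

    H = np.array([s.species.henry_constant for s in medium.dissolved])
    D = np.array([s.species.diffusivity for s in medium.dissolved])
    M = np.array([s.species.molar_mass for s in medium.dissolved])
    S = np.array([s.saturation_ratio for s in medium.dissolved])
    x_ref = np.array([s.reference_fraction for s in medium.dissolved])

    rho, eta, sigma, T = (
        medium.density,
        medium.dynamic_viscosity,
        medium.surface_tension,
        medium.temperature,
    )
    h, p_atm = column.fill_height, column.ambient_pressure
    vfac = RiseLaw(law).factor
    local_ref = reference_pressure == "local"
    sc_cbrt = (eta / (rho * D)) ** (1.0 / 3.0)

    pb0 = bubble_pressure(d0, z0, medium, column)
    n0 = pb0 * np.pi / 6.0 * d0**3 / (R_GAS * T)
    y0 = np.concatenate([n0 * x0, [z0]])

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        n = np.maximum(y[:-1], 0.0)
        z = min(max(y[-1], 0.0), h)
        ntot = n.sum()
        if ntot <= 0.0:
            return np.zeros_like(y)
        d = diameter_from_moles(ntot, z, medium, column)
        p0 = p_atm + rho * GRAVITY * (h - z)
        pb = p0 + 4.0 * sigma / d
        x = n / ntot
        rho_g = pb * float(x @ M) / (R_GAS * T)
        v = max(vfac * GRAVITY * d * d * (rho - rho_g) / (18.0 * eta), 0.0)
        kl = (2.0 + 0.6 * np.sqrt(rho * v * d / eta) * sc_cbrt) * D / d
        p_ref = p0 if local_ref else p_atm
        dn = -kl * np.pi * d * d * (H * x * pb - S * H * x_ref * p_ref)
        return np.concatenate([dn, [v]])

    def dissolved_event(t: float, y: np.ndarray) -> float:
        ntot = np.maximum(y[:-1], 0.0).sum()
        if ntot <= 0.0:
            return -cutoff
        z = min(max(y[-1], 0.0), h)
        return diameter_from_moles(ntot, z, medium, column) - cutoff

    dissolved_event.terminal = True  # type: ignore[attr-defined]
    dissolved_event.direction = -1  # type: ignore[attr-defined]

    def surfaced_event(t: float, y: np.ndarray) -> float:
        return y[-1] - h

    surfaced_event.terminal = True  # type: ignore[attr-defined]
    surfaced_event.direction = 1  # type: ignore[attr-defined]

    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=np.concatenate([np.full(len(names), max(n0 * 1e-12, 1e-24)), [1e-12]]),
        events=[dissolved_event, surfaced_event],
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed for d0={d0}: {sol.message}")

    t = sol.t
    y = sol.y
    if sol.t_events[0].size:
        terminal, t_diss = "dissolved", float(sol.t_events[0][0])
        t = np.append(t, sol.t_events[0][0])
        y = np.column_stack([y, sol.y_events[0][0]])
    elif sol.t_events[1].size:
        terminal, t_diss = "surfaced", None
        t = np.append(t, sol.t_events[1][0])
        y = np.column_stack([y, sol.y_events[1][0]])
    else:
        terminal, t_diss = "time_limit", None

    # drop duplicated time points (event time may equal the last step)
    keep = np.concatenate([[True], np.diff(t) > 0.0])
    t, y = t[keep], y[:, keep]

    moles = np.maximum(y[:-1].T, 0.0)
    height = np.clip(y[-1], 0.0, h)
    diam = np.array(
        [diameter_from_moles(m.sum(), zz, medium, column) for m, zz in zip(moles, height)]
    )
    press = np.array(
        [
            p_atm + rho * GRAVITY * (h - zz) + (4.0 * sigma / dd if dd > 0 else np.inf)
            for zz, dd in zip(height, diam)
        ]
    )
    return BubbleTrajectory(
        species=names,
        time=t,
        height=height,
        diameter=diam,
        pressure=press,
        moles=moles,
        terminal_event=terminal,
        dissolution_time=t_diss,
    )


def surfacing_threshold(
    medium: LiquidMedium,
    column: Column,
    composition0: dict[str, float] | None = None,
    law: RiseLaw = RiseLaw.HADAMARD_RYBCZYNSKI,
    *,
    d_range: tuple[float, float] = (2e-6, 2e-3),
    tol: float = 1e-6,
    t_max: float = 900.0,
    reference_pressure: str = "local",
) -> float:
    """Critical initial diameter separating dissolution from surfacing.

    Bisects on d0 between ``d_range`` bounds, classifying each run by its
    terminal event; requires the lower bound to dissolve and the upper to
    surface (single dissolved→surfaced flip), else ``NoThresholdError``.
    Default tolerance 1 μm.
    """
    if composition0 is None:
        composition0 = {"CO2": 1.0}
    lo, hi = d_range
    if not 0.0 < lo < hi:
        raise ValueError(f"bad diameter range {d_range}")

    def run(d0: float) -> str:
        return simulate_bubble(
            d0,
            composition0,
            medium,
            column,
            law,
            t_max=t_max,
            reference_pressure=reference_pressure,
        ).terminal_event

    lo_ev, hi_ev = run(lo), run(hi)
    if lo_ev != "dissolved" or hi_ev != "surfaced":
        raise NoThresholdError(
            f"no dissolved→surfaced bracket in {d_range}: "
            f"d0={lo} → {lo_ev}, d0={hi} → {hi_ev}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if run(mid) == "surfaced":
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
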
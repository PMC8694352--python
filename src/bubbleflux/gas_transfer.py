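"""Volumetric mass-transfer coefficient (kLa) estimation and transfer
efficiencies.

The dynamic gassing-out method strips dissolved oxygen with nitrogen, then
re-aerates while logging dissolved oxygen.  A first-order saturation
response c_l(t) = c* − (c* − c₀) e^(−kLa·t) linearizes as

    ln( (c* − c_l) / (c* − c₀) ) = −kLa · t

and kLa is the negative slope of the least-squares line through the
windowed points.  The fitted O₂ kLa converts to another gas through the
penetration-theory diffusivity ratio kLa_target = kLa_ref ·
(D_target/D_ref)^½, valid when the specific interfacial area of the two
aerations is comparable.

Transfer rates and efficiencies:

    SOTR = kLa · c_∞ · V_l              (standard oxygen transfer rate)
    SOTE = SOTR / ẇ_O₂                  (fraction of supplied O₂ dissolved)

with the oxygen supply rate ẇ_O₂ = V̇ · y_O₂ · P/(R T) · M_O₂ evaluated at
column-inlet conditions.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .physical_system import R_GAS

__all__ = [
    "DOTimeSeries",
    "KLaEstimate",
    "TransferEfficiency",
    "InsufficientDataError",
    "estimate_kla",
    "convert_kla",
    "sotr",
    "oxygen_supply_rate",
    "sote",
    "transfer_efficiency",
    "O2_MOLAR_MASS",
    "O2_FRACTION_AIR",
]

O2_MOLAR_MASS = 31.998e-3  # kg mol⁻¹
O2_FRACTION_AIR = 0.2095


class InsufficientDataError(ValueError):
    """Raised when too few usable points remain for a regression."""


@dataclass
class DOTimeSeries:
    """A dissolved-oxygen (or other dissolved-gas) probe trace.

    ``concentration`` shares its unit with ``c_star`` and ``c0``; the unit
    tag is carried along and never converted (kLa is unit-free in
    concentration).  ``c0`` defaults to the first sample.
    """

    time: np.ndarray  # s, strictly increasing
    concentration: np.ndarray
    c_star: float
    c0: float | None = None
    unit: str = "mg_per_L"
    metadata: dict | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.time.shape != self.concentration.shape:
            raise ValueError("time and concentration must have equal length")
        if np.any(~np.isfinite(self.concentration)) or np.any(~np.isfinite(self.time)):
            raise ValueError("time series must be finite")
        if np.any(np.diff(self.time) <= 0.0):
            raise ValueError("time must be strictly increasing")
        if self.c0 is None:
            self.c0 = float(self.concentration[0])
        if self.c_star == self.c0:
            raise ValueError("c* must differ from c0 (no dynamics to fit)")
        if self.metadata is None:
            self.metadata = {}

    # -- file I/O -----------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        buf = io.StringIO()
        buf.write(f"# c_star: {self.c_star!r}\n")
        buf.write(f"# c0: {self.c0!r}\n")
        buf.write(f"# unit: {self.unit}\n")
        for k, v in self.metadata.items():
            buf.write(f"# {k}: {v!r}\n")
        pd.DataFrame({"time_s": self.time, "c": self.concentration}).to_csv(
            buf, index=False
        )
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_csv(cls, path: str | Path) -> "DOTimeSeries":
        meta: dict = {}
        rows = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                val = val.strip().strip("'\"")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    meta[key.strip()] = val
            elif line.strip():
                rows.append(line)
        df = pd.read_csv(io.StringIO("\n".join(rows)))
        return cls(
            time=df["time_s"].to_numpy(),
            concentration=df["c"].to_numpy(),
            c_star=meta.pop("c_star"),
            c0=meta.pop("c0", None),
            unit=str(meta.pop("unit", "mg_per_L")),
            metadata=meta,
        )


@dataclass(frozen=True)
class KLaEstimate:
    """Fitted volumetric mass-transfer coefficient with diagnostics."""

    kla: float  # s⁻¹
    r_squared: float
    n_points: int
    n_censored: int
    window: tuple[float, float]

    @property
    def kla_per_hour(self) -> float:
        return self.kla * 3600.0


def estimate_kla(
    series: DOTimeSeries,
    fit_window: tuple[float, float] = (0.1, 0.9),
) -> KLaEstimate:
    """Fit kLa to a probe trace by the gassing-out linearization.

    Points are windowed on the saturation approach fraction
    f = (c_l − c₀)/(c* − c₀): the default keeps 10–90 %, dropping the
    probe-lag-dominated start and the noise-dominated tail.  Points at or
    beyond saturation inside the window are censored with a warning.  The
    same formula handles stripping traces (c₀ > c*): f still runs 0 → 1.
    """
    lo, hi = fit_window
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError(f"bad fit window {fit_window}")
    t = series.time
    span = series.c_star - series.c0
    f = (series.concentration - series.c0) / span
    in_window = (f >= lo) & (f <= hi)
    saturated = f >= 1.0
    n_censored = int((in_window & saturated).sum())
    if n_censored:
        warnings.warn(
            f"censored {n_censored} point(s) at or beyond saturation",
            stacklevel=2,
        )
    use = in_window & ~saturated
    if use.sum() < 5:
        raise InsufficientDataError(
            f"only {int(use.sum())} usable points in window {fit_window}; need >= 5"
        )
    y = np.log(1.0 - f[use])
    fit = stats.linregress(t[use], y)
    return KLaEstimate(
        kla=-float(fit.slope),
        r_squared=float(fit.rvalue**2),
        n_points=int(use.sum()),
        n_censored=n_censored,
        window=fit_window,
    )


def convert_kla(
    kla_ref: float,
    d_ref: float,
    d_target: float,
    exponent: float = 0.5,
) -> float:
    """Convert kLa between gases via the diffusivity ratio.

    kLa_target = kLa_ref · (D_target / D_ref)^exponent.  The default
    exponent ½ follows penetration/surface-renewal theory; 1 recovers film
    theory.  Valid only when the specific interfacial area of both
    aerations is comparable.
    """
    if not (d_ref > 0.0 and d_target > 0.0):
        raise ValueError("diffusivities must be positive")
    return kla_ref * (d_target / d_ref) ** exponent


def sotr(kla: float, c_inf: float, v_liquid: float) -> float:
    """Standard oxygen transfer rate SOTR = kLa · c_∞ · V_l.

    With kLa in s⁻¹, c_∞ in kg m⁻³ and V_l in m³ the result is kg s⁻¹.
    """
    if kla < 0.0 or c_inf < 0.0 or v_liquid < 0.0:
        raise ValueError("kla, c_inf and V_l must be >= 0")
    return kla * c_inf * v_liquid


def oxygen_supply_rate(
    gassing_rate: float,
    o2_fraction: float = O2_FRACTION_AIR,
    temperature: float = 293.15,
    pressure: float = 1.013e5,
) -> float:
    """Oxygen mass supplied per unit time, ẇ_O₂ = V̇ y_O₂ P/(RT) M_O₂.

    ``gassing_rate`` in m³ s⁻¹ gives kg s⁻¹ (ideal-gas molar flow at the
    stated inlet conditions).
    """
    if not gassing_rate > 0.0:
        raise ValueError("gassing rate must be positive")
    if not 0.0 < o2_fraction <= 1.0:
        raise ValueError("oxygen fraction must be in (0, 1]")
    molar_flow = gassing_rate * pressure / (R_GAS * temperature)
    return molar_flow * o2_fraction * O2_MOLAR_MASS


def sote(
    sotr_value: float,
    gassing_rate: float,
    o2_fraction: float = O2_FRACTION_AIR,
    temperature: float = 293.15,
    pressure: float = 1.013e5,
) -> float:
    """Standard oxygen transfer efficiency SOTE = SOTR / ẇ_O₂ (fraction)."""
    w = oxygen_supply_rate(gassing_rate, o2_fraction, temperature, pressure)
    return sotr_value / w


@dataclass(frozen=True)
class TransferEfficiency:
    """SOTR / supply / SOTE bundle for one operating point."""

    sotr: float  # kg s⁻¹
    supply_rate: float  # kg s⁻¹
    sote: float  # fraction
    v_liquid: float  # m³


def transfer_efficiency(
    kla: float,
    c_inf: float,
    v_liquid: float,
    gassing_rate: float,
    o2_fraction: float = O2_FRACTION_AIR,
    temperature: float = 293.15,
    pressure: float = 1.013e5,
) -> TransferEfficiency:
    """Compute SOTR and SOTE for one operating point (all SI units)."""
    rate = sotr(kla, c_inf, v_liquid)
    supply = oxygen_supply_rate(gassing_rate, o2_fraction, temperature, pressure)
    return TransferEfficiency(
        sotr=rate, supply_rate=supply, sote=rate / supply, v_liquid=v_liquid
    )
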
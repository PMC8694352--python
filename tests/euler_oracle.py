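"""Independent fixed-step explicit-Euler integration of the bubble model.

Written from the governing equations with plain scalar arithmetic, without
touching the package's solver path, so it can serve as an oracle for the
adaptive integration in :mod:`bubbleflux.bubble_dynamics`.
"""

from math import pi, sqrt


def euler_dissolution_time(
    d0: float,
    medium,
    column,
    *,
    rise_factor: float = 1.5,
    dt: float = 1e-4,
    cutoff: float = 1e-6,
    reference_local: bool = True,
    t_max: float = 120.0,
) -> float:
    """Time for a pure-CO2 bubble released at the sparger to dissolve."""
    R = 8.314462618
    g = 9.81
    rho = medium.density
    eta = medium.dynamic_viscosity
    sig = medium.surface_tension
    T = medium.temperature
    h = column.fill_height
    p_atm = column.ambient_pressure
    H = [s.species.henry_constant for s in medium.dissolved]
    D = [s.species.diffusivity for s in medium.dissolved]
    M = [s.species.molar_mass for s in medium.dissolved]
    S = [s.saturation_ratio for s in medium.dissolved]
    xr = [s.reference_fraction for s in medium.dissolved]
    k = len(H)
    names = [s.species.name for s in medium.dissolved]
    i_co2 = names.index("CO2")

    pb0 = p_atm + rho * g * h + 4.0 * sig / d0
    n = [0.0] * k
    n[i_co2] = pb0 * pi / 6.0 * d0**3 / (R * T)
    z = 0.0
    t = 0.0
    while t < t_max:
        ntot = sum(n)
        if ntot <= 0.0:
            return t
        p0 = p_atm + rho * g * (h - z)
        c = 6.0 * ntot * R * T / pi
        d = (c / p0) ** (1.0 / 3.0)
        while True:
            f = (p0 * d + 4.0 * sig) * d * d - c
            step = f / (3.0 * p0 * d * d + 8.0 * sig * d)
            d -= step
            if abs(step) < 1e-12 * d:
                break
        if d <= cutoff:
            return t
        pb = p0 + 4.0 * sig / d
        rho_g = pb * sum(ni * mi for ni, mi in zip(n, M)) / ntot / (R * T)
        v = rise_factor * g * d * d * (rho - rho_g) / (18.0 * eta)
        area = pi * d * d
        p_ref = p0 if reference_local else p_atm
        for i in range(k):
            x = n[i] / ntot
            kl = (
                2.0 + 0.6 * sqrt(rho * v * d / eta) * (eta / (rho * D[i])) ** (1.0 / 3.0)
            ) * D[i] / d
            n[i] = max(n[i] - dt * kl * area * (H[i] * x * pb - S[i] * H[i] * xr[i] * p_ref), 0.0)
        z = min(z + dt * v, h)
        t += dt
    raise RuntimeError(f"no dissolution within {t_max} s")
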
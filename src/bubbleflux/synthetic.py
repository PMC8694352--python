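"""Seeded synthetic data with the statistical structure the analyses assume.

Stands in for instrument output so every pipeline stage is testable at the
desk: first-order dissolved-oxygen saturation curves with additive Gaussian
probe noise, and lognormal bubble-diameter samples truncated to the 9–1200
μm optical detection window and binned at the 10 μm instrument resolution.
Every generator takes an integer seed and is byte-deterministic; the true
generating parameters travel in the output metadata and round-trip through
file I/O, so recovery tests never hard-code them.

Not emulated: probe response lag, foam occlusion of the optics, image
artifacts, or any bubble–bubble interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bsd_analysis import BSD, DEFAULT_BIN_EDGES
from .gas_transfer import DOTimeSeries

__all__ = [
    "SyntheticSpec",
    "generate",
    "gen_do_curve",
    "gen_bsd_sample",
    "gen_bsd_pair",
    "gen_bimodal_bsd",
    "DETECTION_WINDOW",
]

#: Optical detection window of the emulated probe (m).
DETECTION_WINDOW = (9e-6, 1200e-6)


@dataclass(frozen=True)
class SyntheticSpec:
    """A reproducible scenario: seed + scenario name + parameters."""

    seed: int
    scenario: str  # do_curve | bsd_sample | bsd_pair | bimodal_bsd
    params: dict = field(default_factory=dict)


def generate(spec: SyntheticSpec):
    """Dispatch a :class:`SyntheticSpec` to its generator."""
    dispatch = {
        "do_curve": gen_do_curve,
        "bsd_sample": gen_bsd_sample,
        "bsd_pair": gen_bsd_pair,
        "bimodal_bsd": gen_bimodal_bsd,
    }
    try:
        fn = dispatch[spec.scenario]
    except KeyError:
        raise ValueError(
            f"unknown scenario {spec.scenario!r}; one of {sorted(dispatch)}"
        ) from None
    return fn(seed=spec.seed, **spec.params)


def gen_do_curve(
    kla: float,
    c_star: float = 8.0,
    c0: float = 0.0,
    duration: float | None = None,
    n_points: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DOTimeSeries:
    """First-order DO saturation curve with additive Gaussian noise.

    c_l(t) = c* − (c* − c₀) e^(−kLa·t) on a uniform grid over ``duration``
    (default 5/kLa, i.e. >99 % of the approach to saturation).  ``noise_sd``
    is in concentration units; the truth is recorded in metadata.
    """
    if not kla > 0.0:
        raise ValueError(f"kla must be positive, got {kla}")
    if c_star == c0:
        raise ValueError("c_star must differ from c0")
    if duration is None:
        duration = 5.0 / kla
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    c = c_star - (c_star - c0) * np.exp(-kla * t)
    if noise_sd > 0.0:
        c = c + rng.normal(0.0, noise_sd, size=c.shape)
    return DOTimeSeries(
        time=t,
        concentration=c,
        c_star=c_star,
        c0=c0,
        metadata={
            "truth_kla_per_s": kla,
            "truth_noise_sd": noise_sd,
            "seed": seed,
        },
    )


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, s: float, n: int
) -> np.ndarray:
    """Rejection-sample lognormal(μ, s) inside the detection window.

    Rejection (rather than clipping) keeps the within-window shape exactly
    lognormal; it slightly biases moments relative to the untruncated law.
    """
    lo, hi = DETECTION_WINDOW
    out = np.empty(0)
    # acceptance probability; guards against a window with negligible mass
    from scipy.stats import lognorm

    mass = lognorm.cdf(hi, s, scale=np.exp(mu)) - lognorm.cdf(lo, s, scale=np.exp(mu))
    if mass < 1e-3:
        raise ValueError(
            f"less than 0.1% of lognormal(mu={mu}, s={s}) mass lies in the "
            f"detection window {DETECTION_WINDOW}"
        )
    while out.size < n:
        draw = rng.lognormal(mu, s, size=max(int((n - out.size) / mass * 1.2), 16))
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:n]


def gen_bsd_sample(
    median_um: float = 100.0,
    s: float = 0.4,
    n: int = 5000,
    seed: int = 0,
    binned: bool = False,
) -> BSD:
    """Lognormal bubble-diameter sample within the detection window.

    ``median_um`` is the untruncated median e^μ in μm; ``s`` the log-scale
    shape.  With ``binned=True`` the sample is histogrammed on the default
    10 μm grid, as the instrument would report it.
    """
    if n < 1 or not s > 0.0 or not median_um > 0.0:
        raise ValueError("need n >= 1, s > 0, median_um > 0")
    rng = np.random.default_rng(seed)
    mu = np.log(median_um * 1e-6)
    d = _truncated_lognormal(rng, mu, s, n)
    meta = {
        "truth_median_um": median_um,
        "truth_s": s,
        "n": n,
        "seed": seed,
    }
    bsd = BSD.from_diameters(d, metadata=meta)
    return bsd.binned(DEFAULT_BIN_EDGES) if binned else bsd


def gen_bsd_pair(
    median_um: float = 100.0,
    s: float = 0.4,
    shift_um: float = 0.0,
    n: int = 5000,
    seed: int = 0,
) -> tuple[BSD, BSD]:
    """Two independent lognormal samples, the second shifted in median.

    With ``shift_um = 0`` the pair is a null draw for calibrating
    :func:`bubbleflux.bsd_analysis.compare_bsd`.
    """
    a = gen_bsd_sample(median_um, s, n, seed=seed)
    b = gen_bsd_sample(median_um + shift_um, s, n, seed=seed + 1)
    b.metadata["truth_shift_um"] = shift_um
    return a, b


def gen_bimodal_bsd(
    median_um: tuple[float, float] = (100.0, 300.0),
    s: tuple[float, float] = (0.3, 0.3),
    weight: float = 0.5,
    n: int = 10000,
    seed: int = 0,
) -> BSD:
    """Mixture of two truncated lognormals (e.g. micro- + submillibubble).

    ``weight`` is the fraction of bubbles in the first component; used to
    exercise how a unimodal lognormal regression degrades on bimodal data.
    """
    if not 0.0 < weight <= 1.0:
        raise ValueError("weight must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n1 = int(round(weight * n))
    parts = []
    if n1 > 0:
        parts.append(_truncated_lognormal(rng, np.log(median_um[0] * 1e-6), s[0], n1))
    if n - n1 > 0:
        parts.append(_truncated_lognormal(rng, np.log(median_um[1] * 1e-6), s[1], n - n1))
    d = np.concatenate(parts)
    meta = {
        "truth_median_um_1": median_um[0],
        "truth_median_um_2": median_um[1],
        "truth_s_1": s[0],
        "truth_s_2": s[1],
        "truth_weight": weight,
        "n": n,
        "seed": seed,
    }
    return BSD.from_diameters(d, metadata=meta)
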
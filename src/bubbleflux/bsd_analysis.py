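"""Bubble-size-distribution representation, statistics, fitting and evolution.

A :class:`BSD` holds either raw diameters (with optional counts) or a binned
frequency table, mirroring what a probe-based photo-optical instrument
reports over its 9–1200 μm detection window at 10 μm resolution.  All
statistics are number-weighted: the instrument counts bubbles.

Key quantities:

* d₅₀ — number median diameter;
* d₃₂ — Sauter mean diameter Σn d³ / Σn d², whose surface-to-volume ratio
  equals the population's;
* SV = 6/d₃₂ — specific surface of spheres, interfacial area per unit gas
  volume;
* ȧ = SV · V̇ — rate of gas–liquid interfacial-area generation at gassing
  rate V̇, the quantity correlated with interface-driven enzyme
  deactivation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bubble_dynamics import RiseLaw, simulate_bubble
from .physical_system import Column, LiquidMedium

__all__ = [
    "BSD",
    "LognormalFit",
    "AreaGenerationResult",
    "EmptyBSDError",
    "FitError",
    "GridRangeError",
    "DEFAULT_BIN_EDGES",
    "d50",
    "sauter_d32",
    "specific_surface",
    "area_generation_rate",
    "fit_lognormal",
    "compare_bsd",
    "evolve_bsd",
]

#: Default binning: 10 μm wide bins spanning the 9–1200 μm detection window.
DEFAULT_BIN_EDGES = np.arange(9e-6, 1209.1e-6, 10e-6)


class EmptyBSDError(ValueError):
    """Raised when an operation needs a non-empty distribution."""


class FitError(RuntimeError):
    """Raised when a distribution cannot support a regression fit."""


class GridRangeError(ValueError):
    """Raised when a BSD cannot be expressed on the comparison grid."""


@dataclass
class BSD:
    """A bubble-size distribution, raw or binned.

    Use :meth:`from_diameters` or :meth:`from_binned`.  Diameters and bin
    centers are in metres internally; file I/O converts from/to μm.
    ``metadata`` carries free-form context (gas, sparger, gassing rate,
    saturation state, generator truth values) and round-trips through the
    '#'-prefixed header of :meth:`to_csv`.
    """

    diameters: np.ndarray | None = None
    counts: np.ndarray | None = None
    bin_centers: np.ndarray | None = None
    frequencies: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_diameters(
        cls,
        diameters,
        counts=None,
        metadata: dict | None = None,
    ) -> "BSD":
        d = np.asarray(diameters, dtype=float)
        if d.size == 0:
            raise EmptyBSDError("no diameters")
        if np.any(d <= 0.0):
            raise ValueError("diameters must be positive")
        c = np.ones_like(d) if counts is None else np.asarray(counts, dtype=float)
        if c.shape != d.shape or np.any(c < 0.0) or c.sum() <= 0.0:
            raise ValueError("counts must be non-negative, same length, not all zero")
        return cls(diameters=d, counts=c, metadata=metadata or {})

    @classmethod
    def from_binned(
        cls,
        bin_centers,
        frequencies,
        metadata: dict | None = None,
    ) -> "BSD":
        centers = np.asarray(bin_centers, dtype=float)
        freq = np.asarray(frequencies, dtype=float)
        if centers.size == 0:
            raise EmptyBSDError("no bins")
        if centers.shape != freq.shape:
            raise ValueError("bin centers and frequencies must have equal length")
        if np.any(freq < 0.0) or freq.sum() <= 0.0:
            raise ValueError("frequencies must be >= 0 and not all zero")
        if np.any(np.diff(centers) <= 0.0):
            raise ValueError("bin centers must be strictly increasing")
        return cls(
            bin_centers=centers,
            frequencies=freq / freq.sum(),
            metadata=metadata or {},
        )

    # -- basic accessors ----------------------------------------------------

    @property
    def is_binned(self) -> bool:
        return self.bin_centers is not None

    @property
    def n_bubbles(self) -> float:
        return float(self.counts.sum()) if not self.is_binned else float("nan")

    def binned(self, edges: np.ndarray | None = None) -> "BSD":
        """Return a binned view (identity for already-binned input)."""
        if self.is_binned:
            return self
        edges = DEFAULT_BIN_EDGES if edges is None else np.asarray(edges, dtype=float)
        freq, _ = np.histogram(self.diameters, bins=edges, weights=self.counts)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = slice(None)
        if freq.sum() <= 0.0:
            raise GridRangeError("no diameters fall inside the binning window")
        return BSD.from_binned(centers[keep], freq[keep], metadata=dict(self.metadata))

    def _weights(self) -> tuple[np.ndarray, np.ndarray]:
        if self.is_binned:
            return self.bin_centers, self.frequencies
        return self.diameters, self.counts

    # -- file I/O ------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write as a delimited table with '#'-prefixed metadata header.

        Raw: columns ``diameter_um,count``; binned: ``bin_center_um,frequency``.
        """
        buf = io.StringIO()
        for k, v in self.metadata.items():
            buf.write(f"# {k}: {v}\n")
        if self.is_binned:
            pd.DataFrame(
                {"bin_center_um": self.bin_centers * 1e6, "frequency": self.frequencies}
            ).to_csv(buf, index=False)
        else:
            pd.DataFrame(
                {"diameter_um": self.diameters * 1e6, "count": self.counts}
            ).to_csv(buf, index=False)
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_csv(cls, path: str | Path) -> "BSD":
        text = Path(path).read_text().splitlines()
        meta: dict = {}
        rows = []
        for line in text:
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = _parse_meta(val.strip())
            elif line.strip():
                rows.append(line)
        df = pd.read_csv(io.StringIO("\n".join(rows)))
        if "diameter_um" in df.columns:
            counts = df["count"].to_numpy() if "count" in df.columns else None
            return cls.from_diameters(df["diameter_um"].to_numpy() * 1e-6, counts, meta)
        if "bin_center_um" in df.columns:
            return cls.from_binned(
                df["bin_center_um"].to_numpy() * 1e-6, df["frequency"].to_numpy(), meta
            )
        raise ValueError("expected diameter_um/count or bin_center_um/frequency columns")


def _parse_meta(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def d50(bsd: BSD) -> float:
    """Number-median diameter (m).

    For binned input the median is interpolated linearly inside the median
    bin (grouped-median formula).
    """
    if bsd.is_binned:
        centers, freq = bsd.bin_centers, bsd.frequencies
        width = np.diff(centers)
        width = np.append(width, width[-1]) if width.size else np.array([1.0])
        cum = np.cumsum(freq)
        i = int(np.searchsorted(cum, 0.5))
        below = cum[i - 1] if i > 0 else 0.0
        lower_edge = centers[i] - 0.5 * width[i]
        if freq[i] <= 0.0:
            return float(centers[i])
        return float(lower_edge + (0.5 - below) / freq[i] * width[i])
    d, w = bsd.diameters, bsd.counts
    order = np.argsort(d)
    d, w = d[order], w[order]
    cum = np.cumsum(w) / w.sum()
    # weighted median: first diameter with cumulative weight >= 1/2,
    # averaging across an exact 1/2 tie (matches np.median for unit counts)
    i = int(np.searchsorted(cum, 0.5))
    if np.isclose(cum[i], 0.5, rtol=0.0, atol=1e-12) and i + 1 < d.size:
        return float(0.5 * (d[i] + d[i + 1]))
    return float(d[i])


def sauter_d32(bsd: BSD) -> float:
    """Sauter mean diameter d₃₂ = Σ n d³ / Σ n d² (number-weighted, m)."""
    d, w = bsd._weights()
    return float((w * d**3).sum() / (w * d**2).sum())


def specific_surface(d32: float) -> float:
    """Specific surface of spheres SV = 6 / d₃₂ (m² per m³ of gas)."""
    if not d32 > 0.0:
        raise ValueError(f"d32 must be positive, got {d32}")
    return 6.0 / d32


@dataclass(frozen=True)
class AreaGenerationResult:
    """ȧ = SV · V̇ with its ingredients (d₃₂ m, V̇ m³ min⁻¹, ȧ m² min⁻¹)."""

    d32: float
    sv: float
    gassing_rate: float
    rate: float


def area_generation_rate(d32: float, gassing_rate: float) -> AreaGenerationResult:
    """Rate of interfacial-area generation ȧ = (6/d₃₂) · V̇.

    ``gassing_rate`` in m³ min⁻¹ gives ȧ in m² min⁻¹ (the bench convention).
    """
    if gassing_rate < 0.0:
        raise ValueError(f"gassing rate must be >= 0, got {gassing_rate}")
    sv = specific_surface(d32)
    return AreaGenerationResult(
        d32=d32, sv=sv, gassing_rate=gassing_rate, rate=sv * gassing_rate
    )


# ---------------------------------------------------------------------------
# Lognormal regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LognormalFit:
    """Lognormal regression of a binned BSD.

    ``mu`` and ``s`` are the log-scale location and shape (diameters in m);
    ``amplitude`` the free scale factor absorbing the unknown frequency-axis
    normalization; ``r_squared`` the coefficient of determination of the
    binned regression.
    """

    mu: float
    s: float
    amplitude: float
    r_squared: float

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))

    def curve(self, d) -> np.ndarray:
        """Fitted frequency curve evaluated at diameters ``d`` (m)."""
        d = np.asarray(d, dtype=float)
        return self.amplitude * stats.lognorm.pdf(d, self.s, scale=np.exp(self.mu))


def fit_lognormal(bsd: BSD, method: str = "curve") -> LognormalFit:
    """Fit a lognormal density to a BSD.

    ``method="curve"`` (default): nonlinear least squares of
    A·pdf(d; μ, s) against the normalized binned frequencies, reporting the
    regression R².  Raw input is binned first on the default 10 μm grid.
    ``method="mle"``: maximum likelihood on raw diameters (requires raw
    input); R² is still reported from the binned regression of the MLE
    curve, so the two methods are comparable.
    """
    if method not in {"curve", "mle"}:
        raise ValueError("method must be 'curve' or 'mle'")
    binned = bsd.binned()
    mask = binned.frequencies > 0.0
    centers = binned.bin_centers[mask]
    freq = binned.frequencies[mask]
    if centers.size < 2:
        raise FitError("need at least two occupied bins to fit")
    if not bsd.is_binned and bsd.diameters.size < 10 and centers.size < 5:
        raise FitError("need >= 5 occupied bins or >= 10 raw diameters")

    # moment-based starting point from the binned weights
    logd = np.log(binned.bin_centers)
    w = binned.frequencies
    mu0 = float((w * logd).sum())
    s0 = float(np.sqrt(max((w * (logd - mu0) ** 2).sum(), 1e-6)))

    if method == "mle":
        if bsd.is_binned:
            raise FitError("MLE fitting needs raw diameters")
        d = np.repeat(bsd.diameters, np.maximum(bsd.counts.astype(int), 1))
        s, _, scale = stats.lognorm.fit(d, floc=0.0)
        mu, s = float(np.log(scale)), float(s)
        # amplitude by linear least squares of the fixed-shape curve
        basis = stats.lognorm.pdf(centers, s, scale=np.exp(mu))
        amp = float((basis @ freq) / (basis @ basis))
    else:
        # parameterize with log(s), log(amp) so the search stays in-domain;
        # a misspecified model (e.g. flat histogram) keeps its best-found
        # parameters and simply reports a poor R² instead of failing
        amp0 = freq.max() / stats.lognorm.pdf(np.exp(mu0), s0, scale=np.exp(mu0))
        s0 = min(max(s0, 2e-3), 1.9)

        def residual(p):
            return p[2] * stats.lognorm.pdf(centers, np.exp(p[1]), scale=np.exp(p[0])) - freq

        res = optimize.least_squares(
            residual,
            x0=(mu0, np.log(s0), amp0),
            method="trf",
            # shape bounded to the range real bubble populations occupy, so a
            # degenerate near-constant lognormal cannot absorb a flat target
            bounds=([np.log(1e-8), np.log(1e-3), 0.0], [np.log(1.0), np.log(2.0), np.inf]),
            xtol=1e-15,
            max_nfev=20000,
        )
        mu, s, amp = float(res.x[0]), float(np.exp(res.x[1])), float(res.x[2])

    fitted = amp * stats.lognorm.pdf(centers, s, scale=np.exp(mu))
    ss_res = float(((freq - fitted) ** 2).sum())
    ss_tot = float(((freq - freq.mean()) ** 2).sum())
    if ss_tot > 0.0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        # a constant target has no variance to explain
        r2 = 1.0 if ss_res <= 1e-30 else 0.0
    return LognormalFit(mu=mu, s=s, amplitude=amp, r_squared=r2)


# ---------------------------------------------------------------------------
# Comparison
# ---------------------------------------------------------------------------

#: 80-point comparison grid: 10–800 μm at 10 μm resolution, the range in
#: which a probe detects all bubble classes.
COMPARISON_GRID = np.arange(10e-6, 800.1e-6, 10e-6)


@dataclass(frozen=True)
class BSDComparison:
    """Two-sample t-test of two BSDs on the cumulative comparison grid."""

    t_statistic: float
    p_value: float
    grid: np.ndarray
    cdf_a: np.ndarray
    cdf_b: np.ndarray
    paired: bool


def _cdf_on_grid(bsd: BSD, grid: np.ndarray) -> np.ndarray:
    d, w = bsd._weights()
    if d.min() > grid[-1] or d.max() < grid[0]:
        raise GridRangeError(
            f"BSD support [{d.min():.3g}, {d.max():.3g}] m does not reach the "
            f"comparison grid [{grid[0]:.3g}, {grid[-1]:.3g}] m"
        )
    order = np.argsort(d)
    cum = np.cumsum(w[order]) / w.sum()
    idx = np.searchsorted(d[order], grid, side="right")
    return np.concatenate([[0.0], cum])[idx]


def compare_bsd(
    bsd_a: BSD,
    bsd_b: BSD,
    grid: np.ndarray = COMPARISON_GRID,
    paired: bool = False,
) -> BSDComparison:
    """Double-sided t-test of two BSDs via their cumulative distributions.

    Both distributions are expressed as cumulative number fractions on the
    80-point 10–800 μm grid; the unpaired two-sample two-sided t statistic
    (pooled variance) is computed between the two gridded curves.  Set
    ``paired=True`` for a paired test on the grid points.
    """
    ca = _cdf_on_grid(bsd_a, grid)
    cb = _cdf_on_grid(bsd_b, grid)
    if paired:
        res = stats.ttest_rel(ca, cb)
    else:
        res = stats.ttest_ind(ca, cb, equal_var=True)
    t = float(res.statistic) if np.isfinite(res.statistic) else 0.0
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return BSDComparison(
        t_statistic=t, p_value=p, grid=grid, cdf_a=ca, cdf_b=cb, paired=paired
    )


# ---------------------------------------------------------------------------
# Evolution under the single-bubble model
# ---------------------------------------------------------------------------


def evolve_bsd(
    bsd0: BSD,
    t: float,
    medium: LiquidMedium,
    column: Column,
    law: RiseLaw = RiseLaw.HADAMARD_RYBCZYNSKI,
    composition0: dict[str, float] | None = None,
    *,
    reference_pressure: str = "local",
    peak_normalize: bool = False,
) -> BSD:
    """Advance every bubble of a BSD for duration ``t`` and re-collect.

    Each representative diameter (raw diameter or occupied bin center) is
    treated as an independent bubble released at the sparger and advanced
    with :func:`simulate_bubble`; bubbles that dissolve or surface within
    ``t`` leave the population.  Frequencies are renormalized over the
    survivors; metadata records the removed fractions so bubble identity is
    conserved (survivors + dissolved + surfaced = input).

    With ``peak_normalize=True`` the output frequencies are scaled to unit
    maximum instead of unit sum (convenient for overlaying distributions).
    """
    if t < 0.0:
        raise ValueError("t must be >= 0")
    if composition0 is None:
        composition0 = {"CO2": 1.0}
    if t == 0.0:
        out = BSD(
            diameters=None if bsd0.diameters is None else bsd0.diameters.copy(),
            counts=None if bsd0.counts is None else bsd0.counts.copy(),
            bin_centers=None if bsd0.bin_centers is None else bsd0.bin_centers.copy(),
            frequencies=None if bsd0.frequencies is None else bsd0.frequencies.copy(),
            metadata=dict(bsd0.metadata),
        )
        out.metadata.update(evolved_t_s=0.0, dissolved_fraction=0.0, surfaced_fraction=0.0)
        return out

    d_in, w_in = bsd0._weights()
    survivors_d, survivors_w = [], []
    dissolved_w = surfaced_w = 0.0
    for d0, w in zip(d_in, w_in):
        if w <= 0.0:
            continue
        try:
            traj = simulate_bubble(
                d0,
                composition0,
                medium,
                column,
                law,
                t_max=t,
                reference_pressure=reference_pressure,
            )
        except Exception as exc:
            raise RuntimeError(f"evolution failed for d0 = {d0:.3g} m: {exc}") from exc
        if traj.terminal_event == "dissolved":
            dissolved_w += w
        elif traj.terminal_event == "surfaced":
            surfaced_w += w
        else:
            survivors_d.append(traj.diameter[-1])
            survivors_w.append(w)
    total = w_in.sum()
    meta = dict(bsd0.metadata)
    meta.update(
        evolved_t_s=float(t),
        dissolved_fraction=dissolved_w / total,
        surfaced_fraction=surfaced_w / total,
    )
    if not survivors_d:
        raise RuntimeError(f"entire population dissolved or surfaced within {t} s")
    d_arr = np.array(survivors_d)
    w_arr = np.array(survivors_w)
    # merge representatives that collapsed onto the same diameter
    d_arr, inverse = np.unique(d_arr, return_inverse=True)
    w_arr = np.bincount(inverse, weights=w_arr)
    if bsd0.is_binned:
        freq = w_arr / w_arr.sum()
        if peak_normalize:
            freq = freq / freq.max()
            out = BSD(bin_centers=d_arr, frequencies=freq, metadata=meta)
            return out
        return BSD.from_binned(d_arr, freq, metadata=meta)
    return BSD.from_diameters(d_arr, w_arr, metadata=meta)
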
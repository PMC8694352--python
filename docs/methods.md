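# Methods

## Scope and state variables

The core object is a single spherical, isothermal, ideal-gas bubble in an
infinite bath. Its state is the per-gas mole inventory `n_i` (default gas
set CO₂/O₂/N₂; more species can be registered) plus the height `z` above
the sparger. Geometry is derived, not integrated: the diameter solves the
closure `P_b(d)·(π/6)d³ = Σnᵢ R T`, which with the Laplace term is the
cubic `P₀d³ + 4σd² = 6nRT/π` (`P₀` = ambient + hydrostatic pressure). The
cubic has one positive root, found by Newton iteration started from the
Laplace-free guess `(6nRT/πP₀)^⅓` — an upper bound, so the iteration
descends monotonically — with a bisection fallback; relative tolerance
1e-12.

## Mass balance

```
dn_i/dt = −k_L,i · π d² · ( H_i x_i P_b − S_i H_i x_ref,i P_ref(z) )
```

The gas-side interfacial concentration is Henry's law at the inner partial
pressure `x_i P_b`; the liquid side is the bulk concentration expressed
through the saturation ratio `S_i`. Conventions:

* **Reference composition** `x_ref,i`: what "saturated" means per gas.
  Air gases use their dry-air fractions (O₂ 0.2095, N₂ 0.7905); any other
  gas uses 1.0, i.e. saturation against the pure gas — matching columns
  sparged with pure CO₂.
* **Reference pressure** `P_ref(z)`: default `"local"`, the hydrostatic
  pressure `P_atm + ρ_l g(h − z)` at the bubble's current depth. The bulk
  in a sparged column is equilibrated in situ by bubbles dissolving at
  depth, so its saturation level carries the hydrostatic head. The
  alternative `"atmospheric"` (`P_ref = P_atm`) is selectable; in the
  reference TEA scenario it shortens the 100 μm bubble's life by ~12 %.
* **Film coefficient**: Ranz–Marshall, `Sh = 2 + 0.6 Re^½ Sc^⅓`,
  `k_L = Sh·D/d`. The stagnant limit `Sh = 2` makes `k_L ∝ 1/d`, which is
  what lets the Laplace term finish small bubbles in finite time.
* **Rise law**: Stokes or Hadamard–Rybczynski (1.5× Stokes; mobile
  interface). The API default is Hadamard–Rybczynski, the classical choice
  for clean microbubbles. For the reference TEA column, however, the
  Stokes configuration matches the documented single-bubble behaviour
  (dissolution time, rise distance and both surfacing thresholds) more
  closely, plausibly because surfactant-like TEA immobilizes the
  interface; the acceptance script therefore runs Stokes, and both laws are
  exercised in the tests. At threshold-scale diameters (≈0.5 mm) the
  creeping-flow assumption itself is stretched (Re ≈ 50); both laws should
  be read as model conventions, not hydrodynamic truth.
* **Gas density** for buoyancy is the ideal-gas mixture density at the
  current `P_b` and `T` (a <0.2 % effect on the density difference,
  included for reproducibility).
* **No chemical enhancement**: the Henry constants and diffusivities are
  pure-water values, and no CO₂–amine reaction factor multiplies the flux.
  The amine enters only through the bulk saturation ratio `S_CO₂`. The
  chemical interpretation of `C*` for CO₂ in TEA (physically dissolved vs
  bound) is left to the caller; the model only consumes the ratio.

Integration uses LSODA with relative tolerance 1e-8 and mole-scaled
absolute tolerance, with terminal event detection on the **dissolution
cutoff** `d ≤ 1 μm` (well below the 9 μm optical detection limit; avoids
the `4σ/d` singularity) and on surfacing `z ≥ h`. Remaining moles at the
cutoff are part of the transferred total, so conservation closes. An
independent fixed-step explicit-Euler integration (Δt = 1e-4 s, plain
scalar arithmetic, in the test suite) agrees with the adaptive solve to
~1e-5 relative on dissolution time.

## Surfacing thresholds

`surfacing_threshold` bisects the initial diameter between 2 μm and 2 mm,
classifying each run by terminal event, to a default 1 μm tolerance. A
`NoThresholdError` is raised unless the lower bracket dissolves and the
upper surfaces (this also catches the degenerate σ = 0, saturated-bulk
case where nothing dissolves). The outcome is monotone in d₀ within the
model, which a grid scan in the tests confirms.

The two bench scenarios are:

* **during saturation** — fresh, effectively CO₂-free bulk. The threshold
  (~540 μm under the Stokes configuration) is computed with a CO₂-only
  bulk inventory (dissolved air set to zero). With dissolved air at
  `S_air = 1` the counter-diffusing air recharges large bubbles on their
  way up and roughly one-third of that threshold results; the CO₂-only
  convention reflects how such threshold scans are classically run
  (single-gas mass balance) and is what the 100 μm showcase scenario is
  *not*: there, air-saturated bulk is essential (it is the counter-diffused
  air that lets the bubble live ~27 s).
* **at saturation** — `S_CO₂ = 1` with dissolved air stripped by prolonged
  CO₂ sparging (`S_air = 0`). Only the Laplace + hydrostatic overpressure
  still drives dissolution; threshold ≈ 140 μm. Any mixture of the two
  states can be built with `LiquidMedium.with_saturations`.

## BSD analytics

Number-weighted throughout (optical probes count bubbles). Default binning
is 10 μm from the 9 μm detection edge to 1200 μm. `d50` uses the grouped
(linearly interpolated) median for binned input. The Sauter diameter is
`d₃₂ = Σnd³/Σnd²`; `SV = 6/d₃₂`; `ȧ = SV·V̇` with V̇ in m³ min⁻¹ by bench
convention.

`fit_lognormal` regresses `A·lognorm_pdf(d; μ, s)` on the normalized bin
frequencies by bounded trust-region least squares (free amplitude `A`
because instrument frequency-axis normalization varies; shape bounded to
`s ≤ 2`, beyond anything a real bubble population shows, so a degenerate
near-flat lognormal cannot absorb a structureless histogram). R² is always
reported from this binned regression — also in the optional MLE mode — so
fits are comparable across methods. A flat histogram has zero variance to
explain and reports R² = 0. Bimodal populations are deliberately fit with
the unimodal model and report the degraded R² as-is; mixture fitting is out
of scope.

`compare_bsd` expresses both distributions as cumulative number fractions
on the 80-point 10–800 μm grid and applies an unpaired two-sided pooled-
variance t-test between the gridded curves (a paired mode is available;
whether grid points should be treated as paired is a judgment call, and the
unpaired reading is the default). `evolve_bsd` advances each occupied bin
center (or raw diameter) as an independent bubble under the single-bubble
model, removes dissolved and surfaced bubbles, renormalizes, and records
the removed fractions in metadata — no coalescence, breakup or flow-field
residence-time effects, mirroring the single-bubble model's limits.

## kLa and efficiencies

`estimate_kla` fits the gassing-out linearization
`ln((c*−c_l)/(c*−c₀)) = −kLa·t` by ordinary least squares on points whose
saturation-approach fraction lies in a window (default 10–90 %, dropping
probe-lag-dominated and noise-dominated ends); points at or beyond `c*`
are censored with a warning; fewer than 5 usable points is an error. The
estimate is invariant to affine rescaling of the concentration unit, and
handles stripping traces (`c₀ > c*`) identically. `convert_kla` uses the
penetration-theory exponent ½ by default (film-theory exponent 1 behind a
flag). SOTR = kLa·c_∞·V_l; SOTE divides by the O₂ supply rate
`V̇·y_O₂·P/(RT)·M_O₂` at inlet conditions (air `y_O₂ = 0.2095`). SOTE > 1
from inconsistent inputs is not clipped — it flags a nonphysical operating
point.

## Synthetic data

The generator emulates (a) first-order DO saturation curves with additive,
time-independent Gaussian probe noise, and (b) lognormal bubble-diameter
samples truncated to the 9–1200 μm window by rejection (keeping the
within-window shape exactly lognormal at the cost of a small moment bias
versus the untruncated law), optionally binned at 10 μm; plus two-component
mixtures for bimodality. Truth parameters ride in metadata and round-trip
through file I/O so recovery tests never hard-code them. Not emulated:
probe response lag, foam occlusion, image-analysis artifacts, any
bubble–bubble interaction — so passing recovery tests validates the
estimators against their own noise model, not against instrument
systematics.

## Default problem sizes

The test suite and acceptance script run desk-scale problems: single-bubble
integrations up to 2 mm initial diameter, ~13-run bisections per threshold,
BSD evolutions over ≤9 occupied bins, 100-seed calibration loops at n = 5000
samples. These sizes give sampling errors well inside the asserted
tolerances while keeping a full run in seconds.

## Known limitations

* Creeping-flow rise laws degrade above Re ≈ 1 (d ≳ 150 μm here); no drag
  correlation for the transitional regime is included.
* Constant bulk state during a run (infinite bath); saturation dynamics of
  the liquid must be imposed between runs, not within one.
* No heat balance (dissolution is treated isothermal), no sparger
  detachment physics, no foam-layer model, no amine speciation.
* The lognormal regression assumes independent bin errors; probe binning
  correlations are ignored.
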
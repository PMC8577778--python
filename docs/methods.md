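# Methods

This note documents the models, parameters and numerical choices behind
`aedosim`, and what the synthetic test fixtures do and do not establish
about real measurements.

## Dielectric model

Tissue is modeled as a homogeneous dielectric with a multi-relaxation
Debye response plus static ionic conduction:

ε′(ω) = ε∞ + Σᵢ Δεᵢ/(1+(ωτᵢ)²),
ε″(ω) = σs/(ωε₀) + Σᵢ Δεᵢωτᵢ/(1+(ωτᵢ)²),
σ(ω) = ε″ ω ε₀.

The built-in *A. aegypti* rows (`aedes_fit2_eps`, `aedes_fit2_sigma`)
come from two-relaxation fits of homogenized-mosquito spectroscopy at
22 °C; the real part and the conductivity were tabulated from separate
fits, so the pipeline evaluates ε′ from the ε′ row and σ from the σ row.
The conductivity row carries no ε∞ (the loss model does not contain it);
such loss-only parameter sets return NaN for ε′ by design.  Physical
consequences used as test anchors: ε′ decreases and σ increases
monotonically over 2–300 GHz; the loss factor of the σ row has a single
maximum near 9.5 GHz (the τ₂ relaxation emerging from the 1/ω static
conduction term); the in-medium wavelength c/(f√ε′) at 240 GHz is
573.5 μm, which sets the finest grid a simulation needs.

### Fitting

`fit_debye` minimizes relative residuals (divided by the observed value,
so ε′ and σ contribute on comparable scales) with
`scipy.optimize.least_squares` under bounds τ ∈ [0.1, 100] ps, Δε ≥ 0,
σs ≥ 0, ε∞ > 0.  Relaxation times are parameterized logarithmically and
initialized from a deterministic log-spaced ladder with a seeded jitter
(8 starts); multi-start prevents the two relaxation times from
collapsing onto one local minimum or swapping labels.  `mode="separate"`
(default) reproduces the two-row convention; `mode="joint"` shares
(Δεᵢ, τᵢ) between both observables.  R² is reported separately for ε′
and σ.  Degenerate (constant) spectra and spectra with fewer than
3× the free-parameter count are rejected.

## Synthetic data

`synth_spectrum` emulates open-coaxial-probe measurements: the Debye
truth model evaluated on the probe grid (5–6 GHz at 50 MHz steps,
6.25–67 GHz at 250 MHz steps; 265 points) with independent
multiplicative truncated-normal noise (±4 sd) per frequency.  Relative
noise was chosen because probe uncertainty budgets are quoted in
percent; the default magnitudes in tests (1–4%) match the inter-sample
deviations reported for such measurements.  The generator does **not**
emulate frequency-correlated calibration drift or probe–sample contact
artifacts, so fit-recovery tests establish identifiability under ideal
noise, not robustness to systematic error.

`make_phantom` builds a mosquito-like phantom from analytic solids:
spherical head and thorax, prolate-ellipsoid abdomen, six cylindrical
legs (radius 50 μm, length 3 mm, sprawled ±55° and tilted 35° down) and
an optional proboscis.  Defaults target a male mosquito: body length
3.5 mm, total volume 0.8 mm³ (the scale where millimeter-wave resonance
appears); a female-like phantom uses 4.0 mm / 1.2 mm³.  The trunk spans
exactly the requested body length; the abdomen's minor radius is solved
from the volume target.  Legs are ~15% of total volume, comparable to
real specimens.  The phantom is deterministic, voxelized at 25 μm by
default with one part label per occupied voxel, and its surface mesh is
extracted by marching cubes (watertight by construction).  It omits
wings, antennae, scales and all internal anatomy; protocol tests on the
phantom therefore validate scale- and shape-level physics (resonance
position, polarization bundling, volume monotonicity), not
specimen-level absolute powers.

## Geometry

Voxelization marks a voxel occupied iff its center lies inside the
closed surface, decided by parity ray casting along +x with a
deterministic sub-epsilon jitter on the column coordinates to avoid
edge/vertex degeneracies.  Non-watertight meshes are rejected in strict
mode (boundary edges listed) or handled tolerantly by dropping unpaired
crossings.  STL files carry no units; the CLI assumes millimeters with
an override.  Body length is measured as the occupied extent along the
declared body axis restricted to trunk labels (head/thorax/abdomen)
when labels exist — an automated approximation of the anatomical
pronotum-to-abdomen-tip measurement; the bounding-box diagonal includes
appendages and is therefore leg-sensitive.  Default pitch is 25 μm with
a refinement option used by the sensitivity suite.

## FDTD solver

Standard Yee leapfrog with a semi-implicit conductivity term.  Time
step: 0.98 of the 3D Courant limit h/(c√3), then rounded so an integer
number of steps fits one excitation period exactly (this makes the
per-period power averages and the DFT phasor projection alias-free).

* **Absorbing boundary.** Stretched-coordinate perfectly matched layer
  in convolutional form: 10 cells, polynomial grading of order 3,
  theoretical normal-incidence reflection 10⁻⁶, κ = 1, linear α-grading
  (α_max = 0.2) against late-time grazing reflections.  Measured
  residual field outside the source box in vacuum: ~10⁻⁴ of the
  incident amplitude.
* **Source.** Total-field/scattered-field injection on a box two cells
  inside the PML, with the incident plane wave evaluated analytically
  at the staggered boundary nodes and half-integer times.  Peak
  amplitude is √2·E_rms so all reported fields are RMS.  A raised-cosine
  ramp over two periods suppresses the turn-on transient.  Vacuum
  validation: the total-field region carries the incident RMS amplitude
  to within 0.3% (axis incidence) and 0.005% (oblique incidence).
* **Termination.** A run must cover at least the period floor
  (log-frequency interpolation from 7 periods at 2 GHz to 35 at
  240 GHz, always exceeding twice the body length over the wavelength)
  plus the domain transit and ramp; it then continues until the
  cycle-averaged absorbed power changes by <10⁻³ (relative) between
  consecutive periods.  Phasors are extracted by discrete Fourier
  projection over one final whole period.  Divergence and
  non-convergence raise errors carrying the partial power trace.
* **Materials.** Cellwise (staircase) assignment, matching voxel input
  models.  An optional per-edge averaging mode exists but is off by
  default: benchmarked against the sphere oracle it systematically
  enlarges compact bodies by a fraction of a cell and worsens the
  absorbed-power error.

### Accuracy characterization

Absorbed power of a homogeneous lossy sphere (tissue dielectric at
60 GHz, r = 0.5 mm) against the in-house Mie series:

| cells per radius | FDTD/Mie |
|---|---|
| 3.9 (λ_med/15 grid) | 1.15 |
| 6 | 1.15 |
| 12 | 1.04 |
| low-contrast sphere (ε′=2, σ=1), 12 | 1.00 |

The large coarse-grid error is geometric, not a solver defect: this
sphere sits on a steep interior-resonance flank (the analytic absorption
grows ≈23% per 5% radius), so the ±h/2 staircase ambiguity of a
4-cell-radius sphere translates into O(15%) power error.  The error
falls monotonically toward the analytic value under refinement, and the
Mie implementation itself is exact (Riccati–Bessel recurrences with
downward logarithmic derivative; agrees with the quasi-static
closed form to <1% in the Rayleigh limit and is truncation-converged to
10⁻⁹).  Whole-body powers at the protocol's coarse desk-scale grids
should therefore be read with ~10–20% absolute uncertainty, while
frequency *ratios* and trends — the quantities the protocol reports —
are far more stable because the geometric bias is common-mode across
frequencies.

## Exposure protocol

Twelve waves (±x, ±y, ±z × two polarizations in axis order, our
numbering) at 1 V/m RMS; random orientations draw k̂ uniformly on the
sphere with a uniform polarization angle.  Per frequency the grid pitch
is min(λ_medium/10, body length/12) — the λ/10 grid rule plus a floor
keeping the insect resolved at low frequencies; explicit pitches are
capped by the λ/10 rule.  These desk-scale grid sizes (domains of
~50³–130³ cells, single-CPU minutes per frequency) are the package's
default study conditions; production-fidelity runs at 25 μm everywhere
are possible through the same configuration surface but take hours.

Per-part absorption integrates σ|E|²h³ over label masks and reports both
the power and the volume-averaged power density (occupied-voxel volume;
bounding-region volumes are also available from the partition
operation, since published per-part averages are ambiguous between the
two conventions).  Group comparison pools per-wave whole-body powers
across the models of each group and applies the two-sample
Kolmogorov–Smirnov test (empirical-CDF statistic computed in-house, the
asymptotic p-value with the standard small-sample correction;
cross-checked against scipy).  Frequency-pair ratios divide overall
means across all models and waves.  The sensitivity suite reruns the
protocol under ±4.04% ε′ and ±5.81% σ (the inter-sample deviation of
the dielectric characterization), under a refined grid, and with the
phantom's legs removed.

## Known limitations

* Homogeneous tissue only; no dispersive-media updates within a run —
  each frequency uses its own (ε′, σ), exactly as a per-frequency
  protocol requires.
* Absolute absorbed powers at coarse grids carry the staircase
  uncertainty quantified above; specimen-level values additionally
  depend on real anatomy the phantom does not carry.
* Absorbed power is a proxy for dielectric heating; thermal modeling is
  out of scope.
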
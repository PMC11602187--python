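# Methods

## The model

`pcpsim` simulates a minimal kinetic model of planar cell polarity (PCP)
driven by the "global module" cadherins Fat (Ft) and Dachsous (Ds).  Each
cell holds a fixed total amount of each protein (`fT`, `dT`); cytoplasmic
protein binds to the cell membrane at rate `α` and unbinds at a bare rate
`β₀`.  Membrane-bound Ft is stabilized by Ds on the facing membrane of the
neighboring cell (and vice versa) through trans-heterodimer formation,
modeled as a repressive Hill factor on the unbinding rate:

    β(c) = β₀ / (1 + (γ c)^k),

where `c` is the partner's concentration across the interface and `k` is the
cooperativity (default 2; results are qualitatively insensitive to it).  All
quantities are non-dimensional: time in units of `1/β₀`, concentrations in
units of `1/γ`, lengths in cell diameters, leaving three free parameters —
`α`, the total concentrations, and (for gradient experiments) the gradient
steepness `ε`.

In 1D each cell has a left and a right membrane compartment
(`fl, fr, dl, dr`); the unbinding of `fl(i)` is repressed by `dr(i-1)`, of
`fr(i)` by `dl(i+1)`, and symmetrically for Ds.  Cell polarity is
`pf = fr - fl`, `pd = dr - dl`; tissue polarity is `p = ⟨pf - pd⟩`.  In 2D
cells are regular hexagons with the membrane discretized into six angular
bins at `θ ∈ {0, π/3, …, 5π/3}`; the bin at `θ` couples to the facing bin
`θ + π` of the neighbor across that edge, and polarity becomes the vector
first moment of the bin occupancies.  An optional diffusion of membrane
protein along the angular coordinate (`d_theta`, default 0) is implemented
as the cyclic second difference over bins; it conserves membrane-bound
protein per cell.

The positive feedback is mediated by pool depletion: a membrane-rich side
of a cell depletes the shared cytoplasmic pool, suppressing binding on the
opposite side.  Replacing the binding term `α (fT − fm)` by a constant
`α f∞` (the `unlimited_pool` switch) removes this feedback and abolishes
spontaneous polarization — the control used throughout.

## Continuum predictions (`theory`)

For uniform expression in 1D, coarse-graining gives (with `β₀ = γ = 1`,
`k = 2`):

* membrane loading `ρ̇_m = 2α(ρ − ρ_m) − 4ρ_m/(ρ_m² + 4)`, whose root
  `ρ_m(ρ, α)` is found by bracketed Brent iteration to 1e-12;
* linear instability of the unpolarized state at `ρ_m = 2`, giving the
  critical total concentration `ρ_c(α) = 2 + 1/(2α)` (infimum 2 at large α);
* below-threshold gradient susceptibility
  `p = (2ρ_m²/(ρ_m² − 4)) · 2αε/(2α + 1)` — negative for a positive Ft
  gradient, i.e. Ft polarizes down-gradient;
* above-threshold boundary decay length
  `d = ρ_m²/(ρ_m² + 4) · [α(ρ_m² − 4)/8]^(-1/2)`.

These formulas are hard-coded for the `k = 2` non-dimensional regime and
refuse other parameters rather than extrapolate.  The ambiguous typeset
grouping of the susceptibility is resolved as the product above; its sign
convention was fixed once against a single discrete simulation and then
frozen in the tests.

## Numerical integration

Deterministic 1D relaxation uses adaptive LSODA in geometrically growing
time windows, stopping when the max-norm rate of change per unit time drops
below `convergence_tol` (default 1e-8).  The 2D model and all stochastic
runs use fixed-step Euler (default `dt = 0.01` in 1D configs, 0.05 in the
2D experiments; stability was checked by step-halving).  Langevin noise is
additive Euler–Maruyama: each membrane compartment receives an independent
`η √dt N(0,1)` kick per step, negative amounts are clamped to zero (counted
and logged; at the small amplitudes studied clamping is rare).  Stochastic
runs last 1.5× the deterministic convergence time (or an explicit
duration) and report the state averaged over the final 1000 steps.
Simulations start from a nearly empty membrane with a 1% symmetry-breaking
asymmetry: a fraction of each cell's Ft on one edge and of its Ds on the
opposite edge, either a fixed direction or per-cell random under a seed.

Boundary conditions: periodic for uniform-expression experiments (cleanest
spontaneous-polarization setting), open for gradient and clone experiments
(a gradient is incompatible with periodicity).  A missing neighbor
contributes partner concentration 0, so edge membranes unbind at the full
bare rate.

The 2D lattice is stored in axial coordinates with basis `(1, 0)` and
`(1/2, √3/2)` (a rhombus of `nx × ny` cells, unit center spacing); the
neighbor across bin `b` sits at a fixed axial offset and faces bin
`(b + 3) mod 6`.

## Analyses

* **Correlation length.**  `C(r)` is the mean of `p_i · p_j` over all
  ordered cell pairs binned by Euclidean center distance (bin width one cell
  diameter, self-terms in the `r = 0` bin).  It is averaged over the last
  60% of saved frames (the full protocol uses 500 frames; reduced runs warn),
  normalized to `C(0) = 1` so ζ carries length units, and
  trapezoid-integrated to `r_max = L/2`.  For a uniform field ζ = L/2; for
  white noise it is of order one bin.
* **Decay fits.**  `|p(x)| = p0 e^{−x/d}` is fitted log-linearly over the
  contiguous above-floor run from the boundary.  Above threshold the
  converged profile tends to a polarized bulk, so the decaying observable is
  the boundary-layer deviation from the bulk value: `far_field='auto'`
  subtracts a robust interior median, raises the floor to the reference
  scatter, and drops the nonlinear core of the boundary domain wall before
  fitting.
* **Curl/divergence.**  Neighbor differences projected on the six edge
  directions, scaled so the operators reduce to the continuum curl and
  divergence for slowly varying fields; boundary cells use available
  neighbors (reweighted) and are flagged.
* **Radial profiles.**  `p · r̂` from the clone center, binned by distance;
  with a gradient the cells are split into up-gradient, down-gradient and
  normal sectors at ±45°.
* **Phase diagram / onset.**  Grid points are classified polarized iff
  `|p| > 1e-3` (three orders above solver tolerance, three below typical
  polarized magnitudes); the onset concentration is located by bisection to
  a requested resolution, with a shortened `max_time` (3000) because points
  at the exact threshold converge arbitrarily slowly and their
  classification only needs to be right to within the scan resolution.

## Observed model properties that shape the tests

* **Dimension-dependent threshold.**  On the hexagonal lattice the membrane
  is split over six bins instead of two, so spontaneous polarization
  requires roughly `ρ > 6 + 1/(2α)` (measured onset ≈ 6.4 at `α = 1`),
  compared with `2 + 1/(2α)` in 1D.  2D uniform/noise experiments therefore
  use total concentrations around 7–8, while clone experiments at `ρ = 4`
  probe the (sub-threshold) linear-response regime, which already shows the
  inward/outward radial polarity around deletion/up-regulation clones.
* **Boundary-layer decay vs the continuum formula.**  In the discrete model
  the half-deletion experiment converges to a polarized bulk with an
  exponential boundary layer.  The exact decay constant of that layer (the
  transfer-matrix root of the discrete linearization about the polarized
  state) is `d = 0.509` cells at `ρ = 4, α = 1`, and tends to `√(2/3)` times
  the continuum formula near threshold; the continuum expression therefore
  overestimates the discrete decay length by ~20–30% across the scanned
  range, and the log-linear fit r² saturates near 0.97 because the layer
  carries a period-two component (two spatial modes `±μ` of equal modulus).
  The corresponding acceptance test records this disagreement; it is a
  property of the model pair, not a solver artifact.
* **Metastability of the unpolarized interior.**  Above threshold the
  unpolarized state is linearly unstable, so a deletion boundary nucleates
  an invasion front and the far field's final pattern is sensitive to
  round-off when the initial state is exactly symmetric.  The deletion
  experiments therefore keep the standard 1% coherent seed, which makes the
  far field a reproducible uniform bulk.
* **Gradient experiments** keep every cell below threshold by placing the
  gradient reference at the tissue center, and measure the bulk response on
  an interior window (the open edges carry their own short-ranged layers).
  The measured susceptibility then matches the continuum slope within a few
  percent.
* **Noise protocols.**  Noise experiments use per-cell random initial
  asymmetry (a coherent seed would impose the very tissue-scale coordination
  whose loss is being measured).  The 2D correlation-length grid uses
  quenched expression noise with rows at `ρ ∈ {7.2, 7.6, 8.0}` — clearly
  above the 2D threshold, so noise acts as pinning rather than locally
  crossing the threshold — and amplitudes `S ∈ {0.02, 0.05, 0.1}` in the
  pinning-dominated regime; just-above-threshold rows mix the two
  transition mechanisms and do not show clean monotone trends.  Statistical
  claims use 50 seeds in 1D and 3 quenched realizations per 2D grid point.

## What the synthetic data do and do not emulate

All inputs are generated internally: uniform, linear-gradient,
quenched-noise and clone-masked expression profiles on ideal lattices.
They emulate the study conditions of the model — not real tissue: there is
no cell rearrangement, growth or flow, no irregular cell geometry, no
protein production/degradation, and noise is additive and Gaussian.
Passing tests demonstrate the internal consistency of the model, its
continuum limit and its statistics at desk scale; they say nothing about
parameter values in a real epithelium.

## Problem sizes

Default experiment scales follow the published protocol (500 cells in 1D,
50×50 in 2D, 50 realizations, 1% initial asymmetry, convergence 1e-8,
1.5× duration and 1000-step tail averaging for stochastic runs).  The test
suite and presets run the same pipelines at reduced scale — 40–100 cells in
1D scans, 20×20 to 25×25 lattices in 2D, 3 realizations per 2D grid point —
sizes chosen so the full suite completes on a single CPU while each
statistical trend remains resolvable.

## Known limitations

* The continuum formulas are implemented only for `k = 2`, `γ = β₀ = 1`.
* The cubic saturation coefficients of the polarity amplitude equation are
  not implemented (only the linear instability and its consequences); the
  supercritical amplitude is validated numerically from the discrete model.
* In 1D any nonzero noise destroys long-range order in the infinite-size
  limit; all noise results are finite-size statements.
* ζ depends mildly on the integration cutoff `r_max = L/2`; the pair-noise
  of the near-zero tail of `C(r)` enters ζ as correlated error.
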
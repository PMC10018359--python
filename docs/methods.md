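# Methods

This note documents the models implemented in `sedstoich`, their
assumptions, the numerical choices behind them, and what the synthetic data
do and do not establish about real experiments.

## Physical bookkeeping

All arithmetic is CGS: radii in cm, time in s, molar masses in g/mol, the
gas constant R = 8.31446×10⁷ erg mol⁻¹ K⁻¹, angular velocity
ω = 2π·rpm/60, and 1 S = 10⁻¹³ s. A solute's sedimentation is driven by
its buoyant molar mass M(1 − v̄ρ), where v̄ is the partial specific volume
(ml/g) and ρ the buffer density (g/ml). For a complex, v̄ is the
mass-weighted average of its components, v̄ = Σnᵢ Mᵢ v̄ᵢ / Σnᵢ Mᵢ,
assuming volume additivity — adequate for loosely coupled
protein–peptide–DNA assemblies, but it ignores hydration or packing
changes on binding.

Peptide and oligonucleotide masses come from average residue-mass tables
(`src/sedstoich/data/residue_masses.yaml`). Conventions: peptides gain one
water for free termini; oligodeoxynucleotides are treated as 5′-OH/3′-OH
chains of nucleoside-monophosphate residues (one water gained, one HPO₃
removed relative to the plain residue sum); the cyanine-3 label adds
507.66 g/mol as a phosphoramidite-coupled adduct. These end-chemistry
choices are documented assumptions — vendor synthesis conventions vary by
a few tens of g/mol, well below every mass window used here.

Buffer density, viscosity and temperature are user inputs, never estimated
from recipes. Defaults are ρ = 1.05 g/ml, η = 0.010 P, T = 298.15 K; the
density is a nominal glycerol-containing-buffer value and the viscosity a
round nominal figure. Neither is printed for the emulated experiments, and
the recovery results are invariant to these shared choices because the
generator and the fits use the same values (asserted by the round-trip
tests); absolute s and M values on *real* data would of course depend on
the true ρ and η.

## Lamm-equation forward model

Sedimentation velocity scans are simulated by solving the Lamm equation
for an ideal, non-interacting species in a sector-shaped cell,

    ∂c/∂t = (1/r) ∂/∂r [ r (D ∂c/∂r − s ω² r c) ],

with zero flux at the meniscus and base and a uniform initial
concentration (instantaneous rotor acceleration; no approach-to-speed
modelling). The discretisation is a conservative finite volume on a
uniform radial grid (default 400 cells over a 6.0–7.2 cm column) with
Scharfetter–Gummel (exponentially fitted) face fluxes and implicit-Euler
time stepping. This combination was chosen over a classical
Galerkin/Claverie scheme because it gives, by construction:

* exact conservation of the sector mass integral ∫c·r dr (to linear-solver
  round-off),
* unconditional stability (the default step is 0.4 Δr/v_max, capped at
  50 s, purely for accuracy),
* non-negative solutions for any s, D (the implicit system matrix is an
  M-matrix).

The face fluxes reproduce local exponential profiles exactly, which is
also the steady-state shape at the cell base; concentrations are
interpolated from cell centers to scan radii in log space for the same
reason. Self-convergence under simultaneous halving of the grid spacing
and time step is below 0.1 % relative RMS for typical conditions (tested).

The mapping from s to D uses the standard hydrodynamic scale relation:
a compact particle with frictional ratio f/f₀ (default 1.2) has
R₀ = (3Mv̄/4πN_A)^⅓, f = 6πη(f/f₀)R₀, D = kT/f, and M follows from the
Svedberg relation, giving M ∝ s^{3/2}.

## c(s) inversion

A scan set is fit as a superposition of single-species Lamm solutions on a
grid of s values (default 100 log-spaced points on 0.2–12 S, covering all
species of interest here), all sharing one frictional ratio. Amplitudes
solve a non-negative least-squares problem with a second-difference
smoothness penalty. Numerical choices:

* **Baselines.** A time-invariant radial baseline plus a per-scan offset
  are removed from data and basis by double-centering, the exact
  orthogonal projection onto the complement of those two subspaces —
  algebraically identical to co-fitting them as unpenalised linear
  parameters.
* **Fit range.** By default the first 0.05 cm after the meniscus and the
  last 0.10 cm before the base are excluded, as in standard boundary
  analysis: the base pile-up is steep, dominated by back-diffusion, and
  numerically the least reliable region of any solver.
* **Regularisation.** The penalty weight is the largest α whose χ²
  does not exceed the unregularised χ² by more than a one-sided F-ratio
  at confidence 0.68 (the conventional 1-σ criterion), found by log-scale
  bisection on the monotone function χ²(α).
* **Solver basis.** The inversion basis uses its own 200-cell solver — a
  deliberately different discretisation from the 400-cell generator, so
  round-trip tests do not commit an inverse crime.

The weight-average s is the trapezoidal ∫s·c(s)ds / ∫c(s)ds, over the
full grid unless a range is given. With noisy, low-signal data the
non-negativity constraint leaves small positive residual amplitudes at
the grid edges; these bias the full-grid weight average upward by a few
percent at signal-to-noise ≈ 20 (0.1 AU loading, 0.005 AU noise), which is
the dominant error in the velocity round trip and stays inside the 5 %
tolerance used for it.

## Global sedimentation-equilibrium fit

Equilibrium profiles are sums of exponentials in r²,

    A(r) = Σᵢ A_{r₀,i} exp[ Mᵢ(1 − v̄ᵢρ) ω²/(2RT) (r² − r₀²) ] + b,

fit globally across rotor speeds with shared molar masses. The baseline b
is one scalar per profile (a linear-in-r option exists behind a flag).
With mass conservation on, each species' baseline-subtracted sector
loading ∫A·r dr (meniscus→base, computed analytically) is constrained
equal across speeds, replacing per-speed amplitudes by one loading per
species — the cell contents cannot change between speeds.

The optimisation is variable projection: masses are the only nonlinear
parameters, searched on a log scale by trust-region least squares from
three starting values (10⁴, 7×10⁴, 5×10⁵ g/mol) spanning the plausible
range; loadings (bounded ≥ 0) and baselines are re-solved linearly at
every step. An amplitude pinned at zero is reported as a boundary
solution, not a failure; profiles whose fitted signal span is
indistinguishable from the residual noise raise an explicit
"unidentifiable" error instead of returning a meaningless mass.

Standard errors on the masses come from the finite-difference Jacobian of
the *profiled* residual (linear parameters re-solved at each perturbation)
and the covariance scaled by reduced χ²; they are 1-SE values and labelled
as such. A simulation calibration (40 seeds) gives a z-score spread of
≈0.9, i.e. the reported errors are mildly conservative. Fitted masses are
invariant to the choice of reference radius r₀ to ~10⁻⁹ relative
(asserted), since the amplitudes reparameterise exactly.

Two-species fits optionally hold the second mass fixed (e.g. at the known
free-DNA mass); the reported species fractions are shares of the total
fitted loading signal. When both masses coincide within 2 % the fit warns
that the amplitudes are degenerate.

## Stoichiometry inference

Candidate compositions are enumerated exhaustively over a bounded integer
lattice of copy numbers, filtered by declarative rules (allowed copy sets,
e.g. RecR ∈ {0,2,4}; inequalities, e.g. SSB-Ct ≤ RecO), ranked by
|predicted − fitted| mass with deterministic lexicographic tie-breaking.
A candidate is "within window" when its deviation is at most k standard
errors; the default k = 2 is the conventional ~95 % interval and is also
the smallest integer k under which a fitted 131.1 ± 9.2 kDa mass accepts a
121.2–121.5 kDa structure (a 1-SE window would reject it) while still
excluding the 155.3–155.6 kDa two-RecO alternative. The component
registry derives the unprinted protein monomer masses from the expected
complex masses by least squares on the linear composition equations;
both printed values for the RecR₄O complex (121.2 and 121.5 kDa) are
carried, and all mass-window logic tolerates the 0.3 kDa discrepancy.

## Titration analysis

Raw scattering intensities are normalised to (Iᵢ − I₀)/I₀, optionally
after buffer-reference subtraction and a V/V₀ dilution correction (off by
default). The aggregation onset is an empirical changepoint: a continuous
two-segment line fit by exhaustive search over observed ratios (leaving at
least 4 points per segment), with parabolic refinement through the three
best grid SSEs, accepted only if it beats a single straight line by an
F-ratio ≥ 4 (two extra parameters) *and* steepens after the break. The
threshold is a conservative default against noise-only false positives
(property-tested on seeded flat noise); the onset is reported from the
normalised curve. No aggregation kinetics are modelled.

The 1:1 binding saturation uses the exact closed form: the complex
concentration is the smaller root of C² − (R_t + L_t + 1/K)C + R_tL_t = 0,
evaluated in the numerically stable form 2R_tL_t/(b + √(b² − 4R_tL_t)).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study's stated conditions: equilibrium runs
at 18 000/23 000/28 000 rpm, velocity runs at 42 000 rpm scanned every
0.003 cm, 0.56 µM Cy3-labelled DNA monitored at 546 nm (≈0.10 AU with a
nominal Cy3 ε₅₄₆ = 1.5×10⁵ M⁻¹cm⁻¹ over 1.2 cm), complex masses of 33.8,
69.5 and 121.5 kDa with composite v̄ from the measured component values
(0.734/0.711/0.704/0.56 ml/g), titrations of 40 points over molar ratios
0–16 with onsets at 5.2/6/7.1 and post-onset slope 0.8. Noise is i.i.d.
Gaussian: 0.005 AU on absorbance (swept 0.002–0.01 in property tests) and
0.02 on the normalised scattering scale. All randomness flows from one
seed; per-scenario seeds are CRC-derived so every named scenario
regenerates bit-identically.

Choices the study does not state, fixed here once: the velocity column
spans 6.0–7.2 cm; the equilibrium column spans 6.8–7.2 cm (a 0.4 cm
column, typical of six-channel equilibrium centerpieces — an
identifiability calculation shows the free-DNA control needs at least
this much profile curvature for its fraction noise to sit safely below
1 %); equilibrium loading corresponds to a 0.5 AU column average, the
standard absorbance-optics loading regime — a Cramér–Rao calculation
with the complex mass free shows the free-DNA control fraction has a
noise floor of ~1.2 % at half this signal-to-noise, i.e. the sub-percent
discrimination the control is meant to demonstrate only exists at
signal-to-noise ≈ 100 (even so, roughly one seed in ten leaves the
truncated-Gaussian fraction estimate just above 1 %);
per-speed baseline offsets are drawn uniformly from ±0.02 AU; velocity
runs record 40 scans spanning 2–70 % of the meniscus-to-base traversal
time (a typical absorbance scan cadence).

Equilibrium profiles are generated from the closed-form exponential —
never from the Lamm solver — so equilibrium round trips are independent
of PDE discretisation error; velocity data conversely share the solver
with the analysis only up to a different grid resolution. The titration
generator uses the same hinge function the detector fits.

Not emulated: approach-to-equilibrium kinetics, rotor acceleration,
optical convolution and stray-light effects, radial-dependent (as opposed
to per-profile constant) baselines, concentration-dependent
non-ideality, and any interacting/reacting sedimentation. Passing round
trips therefore demonstrate the estimators are correct and well
calibrated under the stated noise model — not that real instrument
systematics would be handled; on real data the dominant risks (baseline
structure, meniscus artefacts, non-ideality) are exactly the ones the
generator idealises away.

## Degenerate inputs and error behaviour

Empty compositions, non-positive intensities, out-of-cell radius grids,
too-coarse s grids (< 20 points) and too-few scans (< 5) or titration
points raise `InvalidInputError` before any computation. All-zero scan
sets return an all-zero c(s) with a warning rather than an error.
Zero-amplitude equilibrium data raise `FitFailureError` carrying the best
residuals. Overflowing exponents raise `NumericalFailureError` naming the
offending quantity; the equilibrium generator refuses mass/speed
combinations whose exponent exceeds 600 and advises a lower speed.
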
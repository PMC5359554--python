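# Methods

`tlksim` estimates the radiobiological effect of photon radiotherapy at the
cellular scale. It takes the radiation pattern of a tissue voxel — the
spectrum of electrons traversing each cell nucleus — and converts it into a
predicted clonogenic survival fraction by chaining four models: a DSB
damage database, microdosimetric damage accumulation, two-lesion kinetic
(TLK) repair dynamics, and Monte Carlo per-cell survival sampling. This note
documents the models, their assumptions, the defaults, and the numerical
choices.

## Damage database

DNA double-strand breaks are split into simple DSBs (two opposite-strand
single-strand breaks within 10 bp) and complex DSBs (a simple DSB with at
least one additional nearby break). They are repaired by fast and slow
kinetics respectively. The database tabulates yields per cell per Gy on a
rectangular grid of electron kinetic energy (50 eV – 6 MeV) and oxygen
concentration (stored strictly positive; anoxia is represented by the
0.001 % floor so that log-axis interpolation stays defined).

Queries are interpolated bilinearly in (log10 E, log10 c): yields vary over
decades along both axes, so linear-in-log is the stable choice. Queries
outside the grid hull raise an error; nothing is extrapolated or clamped.

Real tables come from external damage-simulation codes and are imported via
a CSV exchange format (`energy_ev, oxygen_pct, sdsb_per_cell_gy,
cdsb_per_cell_gy`). For self-contained operation a phenomenological
generator produces tables with the qualitative shape of such databases:

* total yield Σtot(E, c) = Y∞ · (1 + A·(ε + max((E/E₀)^(−b) − 1, 0))) · g(c)
  with knee E₀ = 100 keV — approximately constant above the knee, rising
  steeply below it;
* oxygen factor g(c) = (1 + (m−1)·c/(c+K))/m, so g(0) = 1/m and g → 1 at
  full oxygenation (a saturating oxygen-enhancement curve);
* complex-DSB fraction 0.40 at high energy/normoxia, growing by up to +0.20
  toward low energy and +0.10 toward anoxia.

Defaults: Y∞ = 8 DSB/cell/Gy (60/40 sDSB/cDSB at high energy), A = 2.5,
b = 0.5, ε = 0.01, m = 3.0, K = 0.3 % O₂. These magnitudes are conventions
that reproduce the qualitative shapes only; they are not measurements, and
absolute survival levels computed from the fixture carry no physical claim.

## Microdosimetry

The specific energy z of a single traversal is the energy imparted divided
by the nucleus mass; the frequency-mean specific energy z̄F(E) is the mean
of the single-event distribution f(z), defined here over energy-depositing
events only (the standard microdosimetric convention). The nucleus is a
sphere, 10 μm diameter and unit density by default (mass 5.236e-13 kg).

Two z̄F sources exist. Tabulated curves from an external transport code are
interpolated linearly on log10 E. Without such a table, the chord-length
approximation z̄F = S(E)·l̄/m is used, with l̄ = (2/3)·d the Cauchy mean
chord of a sphere under surface randomness and S(E) a packaged synthetic
stopping-power curve for water (hand-digitised at the ~10 % level). z̄F is
capped at E/m: one traversal cannot impart more than the electron's kinetic
energy — the cap is what terminates the growth of z̄F at the lowest
energies, where the electron stops inside the nucleus.

## Damage accumulation

Per nucleus, microscopic dose D = Σ_E Φ(E)·z̄F(E) and lesion yields
Y = Σ_E Φ(E)·z̄F(E)·Σ(E, c) over the traversal spectrum Φ. `expected` mode
keeps the real-valued means; `sampled` mode draws Poisson counts with those
means. The Poisson choice is the standard independent-lesion-induction
assumption; it is needed to give integer per-cell damage for stochastic
survival, while expected mode keeps deterministic endpoints (calibration,
HRF/RBE root finding) smooth.

A voxel population is built from a shared spectrum by Poisson-fluctuating
the per-bin traversal counts per nucleus, accumulating expected damage, and
normalising by the population-mean microscopic dose. Damage then scales
linearly with prescribed macroscopic dose, mirroring the linear conversion
of damage patterns to macroscopic dose levels; per-nucleus heterogeneity
enters through the fluence fluctuation and through per-nucleus repair
half-times.

## Two-lesion kinetics and survival

With λᵢ = ln2/τᵢ:

    dL1/dt = −λ1·L1 − η·L1·(L1+L2)
    dL2/dt = −λ2·L2 − η·L2·(L1+L2)
    dL_lethal/dt = β1·λ1·L1 + β2·λ2·L2 + f_pair·η·(L1+L2)²

The βᵢ are lethal mis-repair probabilities of the linear channel, η the
second-order pairwise interaction rate (h⁻¹), and f_pair = 0.25 the
probability that a pairwise interaction forms a lethal (dicentric-type)
aberration. Irradiation is instantaneous: the system is an initial-value
problem with (L1(0), L2(0)) from the accumulation stage and no dose-rate
source term. Survival is the Poisson zero-event probability
p = exp(−L_lethal(T)).

The right-hand side is isolated in `tlk_rhs` so an alternative pairwise
bookkeeping (e.g. break-end pairing combinatorics) can be swapped in one
place.

Defaults for the kinetic parameters are the calibrated values for A549
lung-carcinoma cells: τ1 = 0.25 h, τ2 = 8 h, β1 = 2.6e-4, β2 = 0.011,
η = 1.6e-5 h⁻¹.

**Integrator.** Fixed-step classical RK4, vectorised over nuclei (and over
doses), with defaults matching the study settings: T = 24 h, dt = 0.005 h
for voxel estimation; T = 96 h, dt = 0.001 h for calibration. RK4 at these
steps is step-converged (halving dt changes finals by < 1e-6 relative) and
matches a fine-step Euler oracle to ~2e-6 at the calibrated parameters. If
a state dips below −1e-9 (too-large dt) the solver raises and advises a
smaller step; dips within the tolerance are clipped to zero.

## Population survival

Cell-to-cell diversity of repair capacity: per-nucleus (τ1, τ2) are drawn
from Gaussians (μ = 0.25 h, σ = 0.1 h fast; μ = 8 h, σ = 1 h slow)
truncated below at 0.01 h — an untruncated Gaussian has mass at τ ≤ 0 where
λ = ln2/τ diverges. The truncation shifts the fast mean by < 1e-3 h.

Survival fraction: solve the TLK system per nucleus, compute pᵢ, draw one
Bernoulli trial per cell; SF = survivors/n with binomial standard error,
reported next to the deterministic mean survival probability (1/n)Σpᵢ.
A master seed expands through `numpy` SeedSequence spawning into
independent child streams for repair-time assignment, fluence fluctuation
and the survival draws. Default population sizes follow the study: 1e5
nuclei per voxel, 3000 for the calibration plate.

## Calibration

The objective is least squares on log10 survival between measured and
expected-mode simulated curves; survival spans orders of magnitude over the
calibration doses (0.1–5 Gy), so log residuals weight the curve evenly
(plain-survival residuals are available behind `scale="linear"`).
Expected-mode simulation keeps the objective smooth and deterministic;
Bernoulli-sampled SF would need noisy-optimisation machinery.

Fitting (β1, β2, η): one-at-a-time sensitivity scans over a multiplicative
grid (default 10^±2 around the base value, grid points violating validity
such as β > 1 dropped), then coordinate descent in decreasing-sensitivity
order using bounded scalar minimisation in log10 space (parameters span
decades), then a joint Nelder–Mead polish in log10 space. Default bounds:
β ∈ [1e-5, 0.5], η ∈ [1e-7, 1e-3] h⁻¹. The fit never returns parameters
scoring worse than its initialisation.

On the packaged synthetic fixture, a noise-free recovery experiment returns
the generator's parameters to better than 0.01 % in log space.

**Identifiability.** A single survival curve at one spectrum and oxygen
level nearly confounds β1 and β2: both initial lesion pools grow
proportionally with dose, so to first order only the combined linear
lethality rate β1·L̄1/Gy + β2·L̄2/Gy is determined, with separation resting
on weak curvature effects from per-nucleus heterogeneity. Noise-free data
still identify all three parameters (the objective vanishes only at the
generating values), but with a few percent of measurement noise the fit may
trade β1 against β2 along this ridge while η — the only parameter that
bends the curve quadratically in dose — stays well determined. Separating
the β's robustly requires curves under conditions that change the
sDSB/cDSB ratio (e.g. different spectra or oxygen levels). Note the
sensitivity ordering on this fixture: with the symmetric ×10^±2 grids the
β2 scan dominates (its upper grid points reach β2 ≈ 0.35–1, where nearly
every slow-repair event is lethal), ahead of η and then β1. Which parameter
scans as "most sensitive" is not intrinsic to the model — it depends on the
per-parameter range deemed plausible and on the absolute lesion yields; at
the fixture's ~27 DSB/Gy the quadratic η channel is subdominant to the
linear β2 channel everywhere inside the grid.

## Endpoints

* **LQ comparison** — SF = exp(−αD − βD²); default α = 0.2432 Gy⁻¹,
  β = 0.0257 Gy⁻², the published coefficients for the comparison cell line.
* **Dose response** — expected-mode SF over an ascending dose list.
* **HRF** — for oxygen level c, the dose D* with SF(D*; c) = SF(D_ref; 21 %),
  divided by D_ref; solved by bracketed Brent root finding on the smooth
  expected-mode curve (bracket [D_ref, 20·D_ref]); the normoxic reference
  (21 %) returns exactly 1 by definition. The reference dose is an explicit
  input.
* **RBE** — iso-effect dose ratio: the reference-beam dose matching the
  test beam's survival at dose D, divided by D. This is the standard
  computable definition; a beam against itself returns exactly 1.

## Synthetic stand-ins and what passing tests show

The patient/linac transport, the plate geometry of the calibration
experiment, and the damage-simulation code itself are out of scope; their
outputs are emulated by analytic generators (spectrum families with a
controllable <100 keV traversal fraction, the water stopping-power curve,
the yield fixture, and pipeline-generated survival curves). Tests and the
acceptance checks therefore validate the *mechanics* of the chain — unit
arithmetic, oracle equivalence, closed-form limits, sampling consistency,
recovery of known parameters, and monotone orderings (softer spectrum →
lower survival → RBE > 1; less oxygen → higher survival → higher HRF) — not
absolute voxel survival levels, which require the real external databases
and transport output.

## Problem sizes

Module defaults keep the study conditions (1e5-nucleus voxels, 3000-nucleus
calibration plate, dt = 0.005/0.001 h). The test suite and worked examples
run scaled-down models chosen by the package as adequate for the properties
they check: 100–300 nuclei and dt = 0.01–0.1 h for calibration/endpoint
checks (the fit is self-consistent at any population size because generator
and objective share the configuration), and the full 1e5 nuclei at
dt = 0.005 h where sampling statistics are the point.

## Known limitations

* No dose-rate/protracted irradiation term, cell-cycle redistribution or
  bystander signalling in the kinetics.
* The chord-LET z̄F ignores energy-loss straggling and δ-ray escape; the
  packaged stopping-power curve is approximate by construction.
* Fixture yield magnitudes are conventions; absolute SF/HRF/RBE values
  computed from them are demonstrations, not predictions.
* Only electrons are considered to induce strand breaks at the micrometre
  scale; photon interactions inside the nucleus are neglected.
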
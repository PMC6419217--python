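# Methods

This note documents the models and estimators implemented in `nanothz`,
the numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Units and constants

File formats and public APIs use Å, ps, amu and elementary charges; the
dielectric chain converts to SI exactly once, inside `epsilon_imag`, using
CODATA 2018 constants (`nanothz.units`). Frequencies are ordinary
frequencies ν (THz) everywhere: the dielectric formulas are written with
explicit 2πν factors, and the identity α = 4πνk/c (419.2 cm⁻¹ for k = 1 at
1 THz) pins this convention down.

## Trajectory model

Trajectories are ordered frames with an orthorhombic box, uniform spacing
(relative tolerance 1e-6) and one shared atom count; topologies are static
per-atom tables (mass, charge, molecule id, hydrogen-bond role, bonded
hydrogens). Only orthorhombic boxes are supported — the confined-solution
geometries this package targets are all rectangular. `unwrap` removes
periodic-image jumps by minimum-image reconstruction of per-step
displacements; it is correct only while every true per-step displacement is
below half the box per axis, and a violation is undetectable from wrapped
data alone (documented hazard; with a 0.1 ps save interval and liquid-water
velocities the margin is large).

## Structure

`radius_of_gyration` is the mass-weighted RMS distance from the centre of
mass, with per-axis components using one coordinate each, so
rg_total² = rg_x² + rg_y² + rg_z² by construction. Tests pin it to the
pairwise identity Rg² = ½·Σᵢⱼ mᵢmⱼ|rᵢ−rⱼ|²/(Σm)². The end-to-end distance
uses the first and last atoms of the selection by default (whether terminal
caps belong to the chain is the caller's choice via the selection), and the
excluded volume is the sphere built on it, V_ex = 4/3·π·R_e³ — the standard
occupied-volume proxy when a single chain's dipole is correlated.
Molecules are assumed whole; unwrap first.

## Diffusion

The MSD averages over all time origins and selected atoms using the
Wiener–Khinchin FFT decomposition MSD(τ) = S₁(τ) − 2·S₂(τ); tests require
agreement with the O(N²) double loop to 1e-10. D is the slope/6 of an
unweighted linear fit; the default window is 10–50% of the maximum lag
(below that, ballistic/cage effects; above, origin starvation) and the
window actually used is always reported. Lags are capped at half the series
length to bound the origin-count imbalance. A relative D/D₀ is reported
when a bulk reference D₀ is supplied; D₀ is an input, not something the
package computes for you.

## Dielectric chain

`total_dipole` builds M(t) = Σ qᵢrᵢ(t) in e·Å (origin-dependent and
warned-about if the selection carries net charge). `dipole_acf` divides the
trace into equal contiguous blocks (default 20), averages ⟨M(t₀)·M(t₀+τ)⟩
over origins within each block only, then averages the blocks; the maximum
lag is the block length − 1, giving a frequency resolution of 1/(block
length·dt) — 2 GHz for 5000 frames at 0.1 ps, with Nyquist at 5 THz. The
mean dipole is subtracted by default: in anisotropic confined systems
⟨M⟩ ≠ 0 and the offset would otherwise alias into a spurious
zero-frequency feature (a flag restores the raw correlation).

`epsilon_imag` evaluates the two-sided Fourier integral of the (even) ACF
as twice its cosine transform by trapezoidal quadrature on the ACF's native
time grid — no zero padding, so the grid resolution equals the block
resolution. The prefactor 1/(6ε₀V)·2πν/(k_BT) is applied after SI
conversion. Against the analytic transform of an exponential ACF
(the Debye lobe Δε·x/(1+x²), x = 2πντ) the implementation is within 1%
for x ∈ [0.1, 10] when the ACF is tabulated to 10τ.

For noisy estimated ACFs the recommended practice (used in the package's
own end-to-end validation) is to truncate the lag axis near 10× the slowest
relaxation time before transforming: beyond that the block-averaged ACF is
statistically zero and contributes only noise to the spectrum.

The volume V is an explicit, user-chosen model — simulation box, confining
cylinder πr²L, or excluded volume 4/3·π·R_e³ — because the right choice
depends on whose dipole is correlated (whole solution vs. single chain).
Temperature is the ensemble's nominal value (default 298.15 K), not
estimated from velocities.

### Kramers–Kronig

ε′(ν) = 1 + (2/π)·PV∫ s·ε″(s)/(s²−ν²) ds is computed by Maclaurin's
skip-point rule: the integrand is sampled only at grid points of opposite
parity to the evaluation point, so the pole is never touched and the
effective step is 2h. The grid must be uniform and start at 0.

Debye-class loss spectra decay only as 1/s, so truncating the integral at
the grid end would bias ε′ down by O(ε″(F)) at *every* frequency — about
6% at high interior frequencies for a water-like double-Debye on a grid
spanning 100× the fast relaxation frequency. The transform therefore adds
the analytic remainder of a 1/s tail, ∫_F^∞ A/(s²−ν²) ds =
A·ln((F+ν)/(F−ν))/(2ν), with A estimated from s·ε″ at the last grid
points. With the correction the double-Debye ε′ is recovered to well under
1% on the interior grid; without it (`tail_correction=False`) a warning
flags an undecayed ε″. Values in the outer 20% of the grid are flagged
untrusted in `DielectricSpectrum.trusted` regardless.

### Optical constants

From ε = ε′ − iε″ = (n + ik)²: n = √((|ε|+ε′)/2), k = √((|ε|−ε′)/2),
both non-negative by the absorptive sign convention; α = 4πνk/c, reported
in cm⁻¹. The direct form α = 2πν/c·√(2(|ε|−ε′)) is algebraically identical
and tested as such.

## Two-process Debye fit

The model ε(ν) = ε∞ + (ε₁−ε₂)/(1+i2πντ₁) + (ε₂−ε∞)/(1+i2πντ₂) is fit by
joint least squares on the concatenated (ε′, ε″) residuals with equal
weights (no weighting scheme is canonical here; equal weights keep the fit
auditable). Internally the parameters are (ε∞, a₁, a₂, τ₁, ρ) with
a₁ = ε₁−ε₂ ≥ 0, a₂ = ε₂−ε∞ ≥ 0, ε∞ ≥ 1 (vacuum floor) and τ₂ = ρτ₁,
ρ ∈ (0,1): the physical ordering ε₁ ≥ ε₂ ≥ ε∞ ≥ 1 and τ₁ > τ₂ holds by
construction and the two processes cannot label-switch. Initialisation is
feature-based (ε₁ from the lowest-frequency ε′, ε∞ from the highest, τ₁
from the loss peak); standard errors come from the Gauss–Newton covariance
via the delta method. Noiseless model data are recovered to machine
precision; with 1% multiplicative noise the median τ₁ error is ≈0.2%.
The fit frequency band is an explicit input — the package does not guess
which part of a spectrum is trustworthy.

## Hydrogen bonds

A bond (D,H,A) exists when the minimum-image D–A distance is ≤ 3.5 Å and
the angle at the hydrogen between H→D and H→A is ≥ 135°, with D and A in
different molecules. The angle vertex is at H, reading "donor–H–acceptor"
literally; note that some MD packages instead cut on the H–D–A or D–A–H
angle, so counts are not directly comparable across conventions. The
hydrogen's own position is used as stored (the covalent O–H bond is
intramolecular), while the two rays are minimum-imaged.

C_HB is intermittent: the bond universe is the union of bonds ever
detected, presence is the per-frame geometric test with no history
condition, and both sums of C_HB(τ) = Σh(t₀)h(t₀+τ)/Σh(t₀)² run over the
origins valid at each lag, making C_HB(0) = 1 exact. Rows that are never
detected are excluded so they cannot deflate the denominator. The lifetime
is the trapezoidal integral of C_HB over the available lags, flagged as
truncated when C_HB(end) > 0.05.

## VDOS

The VDOS is the real one-sided Fourier transform of the velocity ACF,
computed as a type-I DCT of the VACF times dt/2; the grid runs from 0 to
the Nyquist frequency 1/(2dt) in steps of 1/(2M·dt) (M = lag count − 1).
The normalization satisfies a discrete Parseval identity: the
half-end-weighted sum of intensities divided by M·dt equals VACF(0)/2
(tested to 1e-6). No window is applied by default — the raw transform is
the auditable baseline — and a Hann taper is available to suppress
truncation ripple. Oxygen-velocity selection is the conventional choice
for water below 200 cm⁻¹ (hydrogen motions dominate above 400 cm⁻¹,
outside the THz band of interest); the selection is a parameter, not
hard-coded. The prefactor is omitted: only relative intensities and peak
positions are meaningful.

## Synthetic generators: what they emulate, and what they do not

All generators are deterministic under a single seed, split internally per
process/particle/mode so results do not depend on evaluation order.

- **OU dipole** (`gen_ou_dipole`): each Cartesian component is the sum of
  two independent stationary Ornstein–Uhlenbeck processes (exact
  discretisation, stationary start), so the ensemble ACF is exactly
  A₁e^(−t/τ₁) + A₂e^(−t/τ₂). Defaults are the package's reference study
  condition: τ₁ = 8 ps, τ₂ = 0.5 ps (water-like slow/fast pair),
  amplitudes (270, 19) (e·Å)² chosen once so that in a (30 Å)³ volume at
  298.15 K the implied relaxation strengths are solution-like (Δε₁ ≈ 70,
  Δε₂ ≈ 5), dt = 0.05 ps (< τ₂/5, resolving the fast process) and
  5×10⁵ steps (25 ns). A Gaussian process with exactly exponential ACF
  verifies the transform chain against closed forms, but real dipole
  dynamics have inertial short-time structure, cross-correlations and
  non-exponential tails the OU model deliberately lacks.
- **Brownian walkers** (`gen_brownian`): Gaussian steps with per-axis
  variance 2D·dt, wrapped into the box, unwrapped ground truth retained on
  request. Pure diffusion — no ballistic regime, no caging.
- **Harmonic velocities** (`gen_harmonic_velocities`): thermal-amplitude
  cosine modes with random phases; per-axis mean-square velocity k_BT/m.
  Delta-like VDOS peaks, no line broadening.
- **Water chains** (`gen_water_cluster`): rigid 3-site waters placed so
  the consecutive O–O distance and donor–H–acceptor angle are *exactly*
  the requested values (the donor hydrogen is positioned by root-finding
  on the angle; infeasible combinations raise). The second hydrogen is
  tilted out of the chain plane and the terminal water points away from
  the chain, so the designed bonds are the only candidates.
- **Poisson breaking** (`gen_breaking_bonds`): exponential lifetimes, no
  reformation, hence C_HB(t) = e^(−kt) exactly in expectation. Real
  intermittent dynamics reform bonds; reformation is exercised only
  qualitatively by the tracking tests.
- **Zigzag nanotubes** (`build_zigzag_cnt`): a 4-atom graphene cell rolled
  onto a cylinder of radius √3·n·cc/(2π), axial period 3·cc. The default
  cc = 1.44 Å is a reconciliation: it reproduces the conventional
  one-decimal radii of all six tubes from (18,0) to (35,0), which 1.42 Å
  does not. The builder exposes cc rather than asserting a bond length.

Passing the synthetic suites shows the estimators and transforms are
correct on processes that obey their assumptions; it does not validate
force fields, sampling adequacy, or any absolute spectrum of a real
system — those require the MD data themselves.

## Statistical tolerances in the test suite

Single-trajectory correlation estimators have irreducible noise: the ACF
of an OU process estimated from one 25-ns series has ~4% (1σ) scatter at
lag τ₁/2 and ~11% at 2τ₁ even after 3-component averaging, and the
survival curve of 5000 Poisson bonds has ~3.6% relative (0.005 absolute)
scatter at kt = 2. Test tolerances are set where the check is
statistically meaningful: ACF closed forms at lags ≤ τ₁/2, survival curves
within 0.03 absolute, end-to-end relaxation-time recovery within 15% (τ₁)
and 25% (τ₂) at fixed seeds. The end-to-end pipeline typically recovers
both times to ~2%.

## Known limitations

- Orthorhombic boxes and uniform timesteps only; no DL_POLY/AMBER/GROMACS
  binary formats (convert to extended XYZ + topology table first).
- The unwrapping precondition (jumps < box/2) is not verifiable from
  wrapped data.
- The Kramers–Kronig tail correction assumes a 1/s decay beyond the grid;
  spectra with structure past the grid end need a wider grid, and the
  outer 20% of any grid remains untrusted.
- Dielectric spectra of real confined systems need 10s of ns of sampling;
  the package quantifies transform accuracy, not sampling error (the
  block count in `CorrelationSeries` is the hook for block-based error
  bars, which are not yet computed automatically).
- C_HB uses the geometric criterion only; energetic definitions and
  reactive-flux rate constants are out of scope.
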
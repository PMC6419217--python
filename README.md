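# nanothz

Terahertz-band observables from molecular-dynamics trajectories of aqueous
solutions, free or confined in nanochannels such as carbon nanotubes.

THz spectroscopy (0.1–10 THz) probes the collective low-frequency motions of
biomolecules and their hydration water. Because bulk water absorbs THz
radiation strongly, measurements are often done in nanofluidic channels —
which themselves perturb the water dynamics. `nanothz` provides the complete
post-processing chain that turns an atomistic trajectory (positions,
velocities, partial charges) into the quantities such a study needs:

- **per-axis radius of gyration** `R_g = √(Σᵢ mᵢ|rᵢ−r_cm|²/Σᵢ mᵢ)` of a
  confined chain, resolving axial elongation vs. radial compression;
- **water diffusion coefficient** from the Einstein relation
  `D = lim_{t→∞} ⟨|r(t)−r(0)|²⟩/6t`, with an FFT multiple-origin MSD;
- **complex dielectric spectrum**: block-averaged dipole autocorrelation
  `⟨M(t)·M(0)⟩`, then

  `ε″(ν) = 1/(6ε₀V) · 2πν/(k_BT) · ∫₋∞^∞ ⟨M(t)·M(0)⟩ e^(−i2πνt) dt`,

  then `ε′(ν) = 1 + (2/π)·PV∫₀^∞ s·ε″(s)/(s²−ν²) ds` (Kramers–Kronig), and
  the absorption coefficient `α(ν) = 2πν/c·√(2(√(ε′²+ε″²)−ε′)) = 4πνk/c`;
- **two-process Debye fit**
  `ε(ν) = ε∞ + (ε₁−ε₂)/(1+i2πντ₁) + (ε₂−ε∞)/(1+i2πντ₂)`, yielding the slow
  (cooperative hydrogen-bond network) relaxation time τ₁ and the fast
  (quasi-free water reorientation) time τ₂;
- **intermittent hydrogen-bond correlation**
  `C_HB(t) = ⟨h(0)h(t)⟩/⟨h²(0)⟩` with the geometric 3.5 Å / 135°
  donor–H–acceptor criterion, and the lifetime `∫C_HB dt`;
- **vibrational density of states** as the cosine transform of the velocity
  autocorrelation function (oxygen velocities by default).

A synthetic-data module generates inputs with closed-form ground truths —
Ornstein–Uhlenbeck dipole series with exactly two-exponential ACF, Brownian
walkers with known D, harmonic velocity ensembles, rigid water chains with
exact hydrogen-bond geometry, Poisson bond breaking, and zigzag (n,0)
carbon-nanotube coordinates — so every stage of the chain is verifiable
without running MD.

## Worked example

Recover the two dielectric relaxation times from a synthetic dipole series
with known τ₁ = 8 ps, τ₂ = 0.5 ps (25 ns at 0.05 ps, water-like relaxation
strengths, volume (30 Å)³ at 298.15 K):

```python
import numpy as np, nanothz as nz
from nanothz.correlation import CorrelationSeries

spec = nz.OUDipoleSpec(seed=42)          # taus=(8, 0.5) ps, n_steps=5e5
trace = nz.gen_ou_dipole(spec)
acf = nz.dipole_acf(trace, n_blocks=20)  # block-averaged <M(t)·M(0)>
n_lag = int(10 * 8.0 / spec.dt) + 1      # keep lags to 10*tau1
acf = CorrelationSeries(acf.lags[:n_lag], acf.values[:n_lag])

f = np.linspace(0.0, 8.0, 2001)                              # THz
e2 = nz.epsilon_imag(acf, nz.box_volume(30, 30, 30), 298.15, f)
e1 = nz.kramers_kronig(f, e2)
band = (f > 0) & (f <= 5.0)
fit = nz.fit_debye(f[band], e1[band], e2[band])
```

This prints (via the fitted parameters):

```
tau1 = 7.89 ps   (true 8.0)
tau2 = 0.509 ps  (true 0.5)
eps1 = 76.3  eps2 = 6.4  eps_inf = 1.29
alpha(1 THz) = 367 cm^-1
```

τ₁ is recovered to 1.4% and τ₂ to 1.7%; ε₁ ≈ 76 reflects the generator's
water-like relaxation strengths. The slowdown signature of confinement is a
growing τ₁ at stable τ₂ across systems.

The same analyses are available from the shell. For example, the Fourier
grid of the standard block layout (5000 frames saved every 0.1 ps), and a
(18,0) zigzag nanotube:

```
$ nanothz grid 5000 0.1
resolution_GHz  2
f_max_THz       5
$ nanothz synth cnt --n 18 --out cnt18.xyz
radius_A        7.145222
wrote cnt18.xyz
```

Other subcommands: `rg`, `extent`, `msd`, `diffusion`, `vacf`, `vdos`,
`dielectric`, `debyefit`, `debye-eval`, `hbond`, and the `synth` generators.
Trajectories are extended XYZ (comment line `time=<ps> box="Lx Ly Lz"`,
optional velocity columns); topologies are tab-separated tables with atom
name, element, mass (amu), charge (e), molecule id, hydrogen-bond role and
bonded hydrogens. All analyses accept a YAML config (`--config`), write
tab-separated tables with unit headers, and log every derived grid
parameter so runs are reproducible bit-for-bit.

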
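# kdtli — quantum-interference-assisted metrology of molecular beams

`kdtli` models a **Kapitza–Dirac–Talbot–Lau interferometer (KDTLI)**: a
three-grating near-field matter-wave interferometer whose central grating is
an optical standing wave, used as a metrology instrument for neutral
molecules in the gas phase.  The package provides the forward model of the
molecular fringe pattern and the inverse procedures that turn measured data
into molecular electronic properties:

* **fringe scans** (counts vs position of the third grating) → fringe
  visibility *V* with 68% confidence intervals,
* **visibility-vs-laser-power curves** *V(P)* → optical polarizability
  magnitude |α_opt(532 nm)| and absorption cross section σ(532 nm),
* **fringe-shift-vs-voltage curves** from an electrostatic deflector →
  electric susceptibility χ,
* **pseudo-random-chopper time-of-flight records** → beam velocity
  distribution,
* **conformational property time series** (μ(t), α_stat(t), α_opt(t)) →
  van Vleck susceptibility χ = α_stat + ⟨μ²⟩/3k_BT.

It is aimed at matter-wave interferometrists and computational chemists who
want to simulate such an instrument, validate inversion pipelines, or
benchmark calculated polarizabilities and dipole fluctuations of flexible
molecules (the vitamins α-tocopherol, phylloquinone and β-carotene are the
worked study system) against beam measurements.

## The physics in brief

A molecule of mass *m* and speed *v* has de Broglie wavelength
λ_dB = *h*/(*mv*) (3–6 pm for a ~500 amu molecule at 200 m/s).  Passing the
110 nm slits of grating G1 delocalizes it transversely; after
*L* = 10.5 cm its coherence width 2λ_dB*L*/*s* covers several periods of the
optical grating G2, a retro-reflected 532 nm standing wave of period
*d* = λ_L/2 = 266 nm.  The dipole potential W = −α_opt E²(x)/4 imprints the
eikonal phase φ(x) = φ₀cos²(πx/d) with

    φ₀ = √(8/π) · α_opt P / (ħ c ε₀ w_y v),

and photon absorption (mean number n₀ ∝ σP/v at an antinode) acts as a
second, number-conserving beam-splitting channel.  Near-field evolution over
the Talbot length L_T = d²/λ_dB forms a molecular density pattern of period
*d*, detected by scanning mask G3.  The signal harmonics are products
S_m = A_m·B_m(L/L_T)·C_m of the mask coefficients and the G2 two-point
kernel coefficients; the visibility V = (S_max−S_min)/(S_max+S_min) as a
function of P encodes α_opt and σ.  An electrode pair shifts the fringes by
Δx = K(χ/m)·∂ₓE_d²·v⁻², quadratic in the voltage, from which χ follows once
K is calibrated with a reference species; for a floppy polar molecule
χ exceeds α_stat by the thermally averaged dipole term ⟨μ²⟩/3k_BT.

## Worked example

Generate a synthetic high-contrast interferogram (24 points over two fringe
periods, ~300 counts/point over a 50 counts/s dark rate) and fit it:

```bash
$ kdtli synth-fringe --visibility 0.32 --seed 1 --out demo
$ kdtli fit-fringe demo/fringe.csv --out demo
visibility = 0.3424 ± 0.0174
```

The Poisson-weighted sinusoid fit recovers the generating 32% modulation
within its 68% interval.  Measure the beam with the pseudo-random chopper:

```bash
$ kdtli synth-tof --seed 1 --out demo
$ kdtli fit-tof demo/tof.csv --out demo
mean = 200.6 m/s, FWHM/mean = 45.1%
```

and run the full end-to-end recovery suite for the three configured
vitamins (synthetic V(P) and deflection data generated at the configured
truths, then inverted):

```bash
$ kdtli recover-all --config examples/vitamins.toml --seed 1 --out demo
alpha_tocopherol: alpha_opt_A3_true=58.00, alpha_opt_A3_recovered=59.05, chi_A3_true=80.00, chi_A3_recovered=80.83
phylloquinone:    alpha_opt_A3_true=52.00, alpha_opt_A3_recovered=52.25, chi_A3_true=80.00, chi_A3_recovered=80.20
beta_carotene:    alpha_opt_A3_true=83.00, alpha_opt_A3_recovered=85.12, chi_A3_true=229.00, chi_A3_recovered=228.06
```

Each recovered value sits within the single-experiment statistical scatter
(≈2–3 Å³ at 0.02 visibility noise and 0.05 rad phase noise) of its
generating truth.  The same operations are available as a library:

```python
from kdtli import (InterferometerGeometry, LaserSettings, MoleculeSpec,
                   make_velocity_distribution, visibility_vs_power)

mol = MoleculeSpec.from_formula("vitamin E", "C29H50O2",
                                alpha_opt_A3=58.0, sigma_abs_m2=0.0)
beam = make_velocity_distribution(180.0, 0.45)
curve = visibility_vs_power(mol, InterferometerGeometry(),
                            LaserSettings(power_W=1.0), beam,
                            powers=[2.0, 4.0, 6.0, 8.0, 10.0])
print(curve.visibilities.round(3))   # [0.015 0.058 0.12  0.192 0.261]
```

## Package layout

| module | contents |
| --- | --- |
| `kdtli.physics` | constants, unit conversions, molecule/geometry/beam types, kinematics |
| `kdtli.gratings` | mask Fourier coefficients, eikonal phase, absorption, G2 two-point kernel |
| `kdtli.engine` | fringe model, visibility, V(P) curves, classical comparison, Fresnel oracle |
| `kdtli.deflectometry` | electrode model, quadratic shift law, velocity-spread dephasing |
| `kdtli.inversion` | all fits and calibrations with 68% confidence intervals |
| `kdtli.conformers` | van Vleck averaging and fluctuation statistics of property series |
| `kdtli.synthetic` | seeded generators for every input the pipeline consumes |
| `kdtli.dataio`, `kdtli.cli` | CSV dialects, TOML configuration, `kdtli` command line |

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.
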
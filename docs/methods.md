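# Methods

This note records the physical model, the numerical choices and the design
decisions behind `kdtli`, at the level of detail a user needs to judge what
the computations do and do not show.

## Forward model of the interferometer

**Geometry.** Three gratings of equal period *d* = 266 nm at equal
separations *L* = 10.5 cm.  G1 and G3 are ideal binary masks (G1 slit width
*s* = 110 nm, G3 open fraction *s/d* by default); no van der Waals
slit-narrowing is modeled.  G2 is the optical standing wave formed by
retro-reflecting a Gaussian 532 nm beam (horizontal waist w_x = 20 µm along
the molecular flight direction, vertical waist w_y = 920 µm).  Because
w_y ≫ w_x, trajectories are treated as straight lines at the vertical beam
center and the vertical profile is ignored in fringe formation; the Gaussian
envelope enters only through the transit-time integral over w_x.

**Optical grating strength.** The eikonal phase accumulated at an antinode
is computed by adaptive quadrature of the dipole potential
W = −α_opt E²/4 along the transit (the squared field amplitude at a
standing-wave antinode is 8I/cε₀ with I = 2P/πw_xw_y the running-wave center
intensity).  The quadrature agrees with the closed-form Gaussian transit
integral φ₀ = √(8/π)·α_opt P/(ħcε₀w_y v) to 10⁻⁶ relative; the closed form
is kept in the tests as an independent oracle, not in the implementation.
The mean absorbed photon number n₀ is σ(ω) times the antinode fluence over
the photon energy hc/λ_L.  Both are exactly ∝ P/v, which the vectorized
paths exploit.

**G2 density-transform kernel.** The literature the instrument builds on
does not print a closed form for the combined phase + absorption grating, so
the kernel is *defined* here operationally: coherent phase modulation
exp[iφ(x) − iφ(x′)] with φ(x) = φ₀cos²(πx/d), times a position-correlated
Poisson absorption channel with jump amplitude equal to the local field,
giving

    K(x, x′) = e^{iφ(x) − iφ(x′)} · e^{ n₀ [c(x)c(x′) − (c(x)² + c(x′)²)/2] },
    c(x) = cos(πx/d).

K(x, x) = 1: absorption conserves molecule number (absorbers remain in the
beam and are detected), so the mean transmitted flux is independent of laser
power.  Each photon exchange transfers one grating half-momentum ħk_L
coherently through the cos(πx/d) amplitude.  Whether the real absorption
channel includes stimulated redistribution between the standing-wave arms is
not modeled; the kernel's correctness is anchored to its limits (pure-phase
reduction at n₀ = 0, identity at φ₀ = n₀ = 0, Hermiticity, number
conservation) and to the wave-optics oracle below.

**Fringe coefficients.** With incoherent illumination of G1, the detected
signal while scanning G3 is periodic with harmonics
S_m = A_m·B_m(ξ)·C_m, where A, C are the binary-mask coefficients
f·sinc(mf), ξ = L/L_T(λ_dB) is the Talbot argument, and B_m is the numerical
Fourier transform of K at the order-dependent two-point separation m·ξ·d
(midpoint rule over one period; spectrally accurate for this smooth periodic
integrand; 128–256 samples by default, scaled with the order cutoff).  The
Fourier cutoff defaults to |m| ≤ 10 and doubles automatically until the
coefficient tail falls below 10⁻⁶ of the mean flux.  Visibility is
(max−min)/(max+min) of a 2048-point reconstruction, which for a {0, ±1}
signal reduces to |first harmonic|/mean.

**Velocity averaging.** Fringe coefficients are averaged coefficient-wise
over a discretized speed distribution: 41 Gauss–Legendre nodes spanning
mean ± 3σ (σ = FWHM/2.355) with Gaussian-density weights.  The quadrature
cell widths are stored with the distribution so the density (and hence the
FWHM) can be recovered from the discrete object.

**Validation oracles.** Two independent routes check the Fourier pipeline:
(i) a closed-form Jacobi–Anger reduction of the pure-phase kernel,
B_m = J_{2m}(φ₀ sin(πmξ)), used only in tests; (ii) a brute-force Fresnel
propagator that sums intensities of point sources across one G1 opening,
each propagated L → multiplied by the G2 transmission → propagated L, on a
grid that resolves the aperture-edge chirp (the two Fresnel steps collapse
into a single chirp transform, so one FFT serves all sources).  A doubling
test on the grid step guards its resolution; the oracle reproduces the
textbook Talbot self-image of a binary mask at L = L_T and agrees with the
engine to ≤10⁻³ in visibility for φ₀ up to 4.

**Classical comparison model.** A ballistic point particle crossing the
standing wave receives the dipole-force momentum kick ∂ₓ(ħφ); the geometric
shadow of the three masks then yields
B_m^cl = ⟨exp[im(2ψ − πξφ₀ sinψ)]⟩_ψ.  The classical model is the ξ → 0
limit of the quantum kernel at fixed φ₀ (verified to 10⁻² and better), and
at the instrument's ξ ≈ 5–8 its V(P) curve differs from the quantum one by
up to ~0.3 in visibility — the discriminating signature of interference.
At P = 0 the uniform-illumination shadow of three equal-period,
equally-spaced masks has zero contrast.

## Deflectometry

The deflector is a thin phase element acting on the formed fringe:
Δx = K·(χ/m)·g·U²/v², with ∂ₓ(E_d²) = g·U² and K the geometry factor.  K and
g enter only through their product and are not separable from one species'
data; K is calibrated against a reference molecule of known χ and g is a
configuration constant.  In strict SI the product K·g carries the
squared-interaction-length bookkeeping; the defaults (K = 2×10⁻³,
g = 4.8×10⁶) place the 6 kV shift of a χ = 80 Å³, 430.7 amu molecule at
180 m/s near half a grating period, the scale at which such instruments
operate.  Velocity spread dephases the deflected fringe: the apparent phase
is arg⟨e^{iφ(v)}⟩ and the contrast shrinks by |⟨e^{iφ(v)}⟩|.  For a 45%
FWHM beam the apparent phase follows its low-voltage U² slope within 1%
only while the contrast factor stays above ≈0.975 (deviation −1.4% at
contrast 0.96, −6% at 0.82); the inversion therefore fits the full
dephasing model, never the linearized law, and the statistical fits are
unaffected by the bending.

## Inversion and uncertainties

* **Fringe scans**: Poisson-weighted linear least squares of
  a + b·sin(2πx/d + φ) on dark-subtracted counts, iterated with
  variance = expected counts.  At ≥100 counts/point this is
  indistinguishable from the full Poisson likelihood, matching the
  "sinusoidal fit" treatment such data receive.  V = b/a; 68% intervals by
  the delta method from the parameter covariance.  Coverage is verified by
  simulation: 60–76% empirical coverage of nominal 68% intervals over 500
  replicates.
* **V(P) inversion**: weighted least squares of the forward model over
  |α_opt| (the instrument is insensitive to the sign of α_opt when σ = 0 —
  the visibility depends on it only through even kernel coefficients).  σ
  can be fit jointly when the power grid resolves curve shape beyond the
  first visibility maximum; otherwise it is held at a configured value and
  the result is flagged (`sigma_fixed`).  The 68% interval is a profile
  likelihood interval at Δχ² = 1.
* **Deflection series**: measured phases are unwrapped sequentially along
  the monotone voltage grid; a residual neighbour-to-neighbour jump above
  π/2 raises an error rather than guessing.  A single slope parameter
  κ = 2πK(χ/m)g/d is fit through the full velocity-averaged phase model;
  1σ from the Gauss–Newton covariance.
* **Calibrations**: `calibrate_intensity` fits the dimensionless
  intensity-scale factor to a reference V(P) curve of a species with known
  α_opt (the in-situ laser calibration); `calibrate_K` fits the geometry
  factor to a reference deflection series of a species with known χ.  Both
  recover generating values to 1% on noiseless input and transfer across
  species (verified in tests).
* **Van Vleck inversion**: ⟨μ²⟩^{1/2} = √(3k_BT(χ − α_stat)_SI), the exact
  inverse of the forward average; χ < α_stat is rejected as unphysical.

## Synthetic data

Generators are pure functions of (parameters, seed) and default to the
study conditions the pipeline is built for:

* **beam**: truncated-at-zero Gaussian with mean 200 m/s and 45% FWHM.  A
  Gaussian (rather than a v³-weighted effusive law) is the minimal
  assumption matching the two printed moments; it is a deliberate,
  swappable choice.
* **fringe scans**: Poisson counts around
  dark + a(1 + V sin(2πx/d + φ)), default 24 points over two periods,
  300 counts/point, 50 counts/s dark rate — the regime of a typical
  high-contrast interferogram with V = 32%.
* **V(P) curves**: forward model plus Gaussian visibility noise
  (sd 0.02), clipped to [0, 1]; powers 1–10 W by default, spanning the
  rising flank of the visibility curve at these polarizabilities.
* **deflection series**: velocity-averaged phases at 0–6 kV in 500 V steps
  plus Gaussian phase noise (sd 0.05 rad), reported wrapped to (−π, π] as a
  relative-phase measurement delivers them.
* **chopper records**: a maximal-length sequence (order 7 by default,
  Fibonacci LFSR) circularly convolved with the single-shot TOF density
  (0.5 m flight path, 50 µs bins), Poisson counts, 2×10⁶ detected molecules
  per sequence period (a long velocimetry integration).  Reconstruction
  uses the exact balanced-sequence correlation identity of m-sequences — no
  regularized deconvolution; bins compatible with the analytic correlation
  noise (σ = √total counts) outside the main lobe are suppressed before the
  t → v = path/t change of variables with Jacobian cell widths.  Round
  trips recover the mean to ~0.3% and the FWHM fraction to ~0.3 points.
* **property time series**: 100 ns at 2 ns steps, correlation time 4 ns.
  Polarizabilities follow Gaussian Ornstein–Uhlenbeck processes calibrated
  by Monte-Carlo lookup of the expected path range so that the mean
  peak-to-peak excursion matches a few percent (default 3%).  The dipole
  magnitude follows a mean-reverting process on log μ (geometric OU).  A
  reflected-at-zero Gaussian OU cannot reach a 400% expected peak-to-peak
  range with ~50 samples — the mean of |X| is bounded below by ≈0.8·sd, which
  caps the ratio near 310% — whereas the log-process both dives toward zero
  and spikes to several times its mean, as conformational dynamics of a
  floppy polar molecule do, and calibrates cleanly to the 400% target.
  The Monte-Carlo calibration bank uses a fixed internal seed so the
  generator remains a deterministic function of its arguments and the user
  seed.

What the synthetic data do **not** emulate: detector mass-filter
transmission and fragmentation, collisional or thermal-radiation
decoherence, grating misalignment, van der Waals interactions in the
nanomechanical slits, field-dependent polarizability (relevant for a fully
conjugated chromophore like β-carotene in strong fields), and
cis–trans isomer populations.  Passing recovery tests therefore demonstrate
the *statistical consistency* of the inversion chain under the stated noise
model, not the absence of systematic effects in a real instrument.

## Numerical conventions and degenerate inputs

* All internal computation is SI; Å³, debye, amu appear only at I/O
  boundaries (one conversion site, 4πε₀×10⁻³⁰ per Å³).
* Grating coordinate: x along the grating axis, phase origin at a
  standing-wave antinode; fringe positions reported modulo d.
* Fourier-order cutoffs always end with a decay check; an expansion that
  has not converged raises an error instead of returning a truncation.
* Zero laser power, zero voltage, single-velocity beams and constant
  property series are exact special cases, not limits (V(0) = 0,
  contrast factor 1 at U = 0, identity velocity average).
* The transverse-coherence helper implements 2λ_dB L/s exactly as the
  kinematic definition; with the default geometry and a 537 amu molecule at
  200 m/s it evaluates to ≈7 µm, comfortably covering several G2 periods.

## Problem sizes

The statistical suites use 500 replicates for fringe-fit coverage, 200 for
the polarizability and susceptibility recoveries, 50 for velocimetry and
the dipole-fluctuation calibration — sizes at which the standard error of
each reported mean is an order of magnitude below the tolerance it is
compared against, while the full test suite and the acceptance script each
complete in minutes on one CPU.

## Known limitations

* The G2 absorption kernel is a declared modelling choice (single-photon
  coherent recoil, no stimulated redistribution); its validation is through
  limits and oracles, not an external closed form.
* Confidence intervals are frequentist 1σ equivalents; no systematic-error
  budget beyond velocity spread and dark counts is propagated.
* The classical shadow model shares the eikonal transit integral with the
  quantum path; it is a limit check, not an independent re-derivation of
  the dipole force.
* K and g are degenerate by construction; only their product is ever
  measurable, exactly as in the calibration pathway it mirrors.
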
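"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and the seed, and its
output satisfies the invariants of the type that consumes it.  The defaults
are the study conditions of the experiment being emulated: a thermal beam
with mean speed ≈200 m/s and ≈45% FWHM spread, fringe scans of ~300 counts
per point over two grating periods with dark counts, deflection scans from
0 to 6 kV, and 100 ns property trajectories sampled every 2 ns whose dipole
moment fluctuates by several hundred percent peak to peak while the
polarizabilities stay constant within a few percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

from .deflectometry import DeflectionSeries, ElectrodeModel, response_curve
from .engine import VisibilityCurve, visibility_vs_power
from .errors import DeconvolutionError, ValidationError
from .conformers import PropertyTimeSeries
from .gratings import LaserSettings
from .physics import InterferometerGeometry, MoleculeSpec, VelocityDistribution

__all__ = [
    "FringeScan",
    "TOFRecord",
    "make_velocity_distribution",
    "make_fringe_scan",
    "make_visibility_curve",
    "make_deflection_series",
    "make_tof_record",
    "reconstruct_velocities",
    "make_property_series",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass
class FringeScan:
    """Raw fringe scan: G3 positions vs detected counts."""

    positions_m: np.ndarray
    counts: np.ndarray
    dwell_s: float
    dark_rate_cps: float

    def __post_init__(self) -> None:
        self.positions_m = np.asarray(self.positions_m, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.positions_m.shape != self.counts.shape:
            raise ValidationError("positions and counts must match in length")
        if np.any(self.counts < 0) or not np.allclose(
            self.counts, np.round(self.counts)
        ):
            raise ValidationError("counts must be nonnegative integers")
        self.counts = self.counts.astype(float)
        if self.dwell_s <= 0:
            raise ValidationError("dwell time must be > 0")
        if self.dark_rate_cps < 0:
            raise ValidationError("dark rate must be >= 0")

    def __len__(self) -> int:
        return self.positions_m.size


@dataclass
class TOFRecord:
    """Pseudo-random-chopper time-of-flight record."""

    prbs: np.ndarray
    bin_s: float
    counts_vs_time: np.ndarray
    path_length_m: float

    def __post_init__(self) -> None:
        self.prbs = np.asarray(self.prbs, dtype=int)
        self.counts_vs_time = np.asarray(self.counts_vs_time, dtype=float)
        if not np.all((self.prbs == 0) | (self.prbs == 1)):
            raise ValidationError("prbs entries must be 0 or 1")
        if self.counts_vs_time.size != self.prbs.size:
            raise ValidationError("counts histogram must have one bin per chip")
        if np.any(self.counts_vs_time < 0):
            raise ValidationError("counts must be >= 0")
        if self.bin_s <= 0 or self.path_length_m <= 0:
            raise ValidationError("bin width and path length must be > 0")


def make_velocity_distribution(
    mean_mps: float,
    fwhm_fraction: float,
    n_nodes: int = 41,
    seed: int | None = None,
) -> VelocityDistribution:
    """Discretize a truncated-at-zero Gaussian speed distribution.

    Gauss-Legendre nodes span mean ± 3σ (σ = FWHM/2.355), weighted by the
    Gaussian density; the construction is deterministic (``seed`` is accepted
    for interface uniformity but has no effect).
    """
    if mean_mps <= 0:
        raise ValidationError("mean velocity must be > 0")
    if not (0.0 <= fwhm_fraction < 1.5):
        raise ValidationError("fwhm_fraction must be in [0, 1.5)")
    if fwhm_fraction < 1e-9:
        return VelocityDistribution.single(mean_mps)
    sigma = fwhm_fraction * mean_mps / _FWHM_TO_SIGMA
    lo = max(mean_mps - 3.0 * sigma, 0.02 * mean_mps)
    hi = mean_mps + 3.0 * sigma
    nodes, gl_weights = leggauss(n_nodes)
    half_span = (hi - lo) / 2.0
    v = (hi + lo) / 2.0 + half_span * nodes
    cell = gl_weights * half_span
    density = np.exp(-((v - mean_mps) ** 2) / (2.0 * sigma**2))
    return VelocityDistribution(
        velocities_mps=v, weights=density * cell, cell_widths=cell
    )


def make_fringe_scan(
    true_visibility: float,
    mean_counts: float = 300.0,
    n_points: int = 24,
    dark_rate_cps: float = 50.0,
    dwell_s: float = 1.0,
    period_m: float = 266e-9,
    phase_rad: float = 0.0,
    n_periods: float = 2.0,
    seed: int | None = None,
) -> FringeScan:
    """Poisson fringe scan: counts ~ Poisson(dark + a(1 + V sin(2πx/d + φ)))."""
    if not (0.0 <= true_visibility <= 1.0):
        raise ValidationError("visibility must be in [0, 1]")
    if mean_counts <= 0:
        raise ValidationError("mean_counts must be > 0")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, n_periods * period_m, n_points, endpoint=False)
    signal = mean_counts * (
        1.0 + true_visibility * np.sin(2.0 * math.pi * x / period_m + phase_rad)
    )
    expected = dark_rate_cps * dwell_s + signal
    return FringeScan(
        positions_m=x,
        counts=rng.poisson(expected),
        dwell_s=dwell_s,
        dark_rate_cps=dark_rate_cps,
    )


def make_visibility_curve(
    molecule_truth: MoleculeSpec,
    geometry: InterferometerGeometry,
    laser_template: LaserSettings,
    distribution: VelocityDistribution,
    powers: Sequence[float],
    noise_sd: float = 0.02,
    seed: int | None = None,
) -> VisibilityCurve:
    """Forward V(P) curve plus Gaussian visibility noise, clipped to [0, 1]."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    clean = visibility_vs_power(
        molecule_truth, geometry, laser_template, distribution, powers
    )
    noisy = np.clip(
        clean.visibilities + rng.normal(0.0, noise_sd, size=len(clean)), 0.0, 1.0
    )
    return VisibilityCurve(
        powers_W=clean.powers_W,
        visibilities=noisy,
        sigmas=np.full(len(clean), max(noise_sd, 1e-6)),
    )


def make_deflection_series(
    molecule_truth: MoleculeSpec,
    electrode: ElectrodeModel,
    distribution: VelocityDistribution,
    voltages: Sequence[float],
    phase_noise_sd: float = 0.05,
    period_m: float = 266e-9,
    seed: int | None = None,
) -> DeflectionSeries:
    """Velocity-averaged deflection phases plus Gaussian phase noise.

    Phases are reported wrapped to (−π, π], as a relative-phase measurement
    between two interferograms would deliver them.
    """
    if phase_noise_sd < 0:
        raise ValidationError("phase_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    voltages = np.asarray(list(voltages), dtype=float)
    phases, _ = response_curve(
        molecule_truth, electrode, voltages, period_m, distribution
    )
    noisy = phases + rng.normal(0.0, phase_noise_sd, size=voltages.size)
    wrapped = np.mod(noisy + math.pi, 2.0 * math.pi) - math.pi
    return DeflectionSeries(
        voltages_V=voltages,
        phases_rad=wrapped,
        phase_sigmas_rad=np.full(voltages.size, max(phase_noise_sd, 1e-6)),
    )


_LFSR_TAPS = {5: (5, 3), 6: (6, 5), 7: (7, 6), 8: (8, 6, 5, 4),
              9: (9, 5), 10: (10, 7)}


def m_sequence(order: int) -> np.ndarray:
    """Maximal-length binary sequence of length 2^order − 1 (Fibonacci LFSR)."""
    if order not in _LFSR_TAPS:
        raise ValidationError(f"prbs order must be one of {sorted(_LFSR_TAPS)}")
    taps = _LFSR_TAPS[order]
    state = [1] * order
    out = np.empty(2**order - 1, dtype=int)
    for i in range(out.size):
        out[i] = state[-1]
        feedback = 0
        for t in taps:
            feedback ^= state[t - 1]
        state = [feedback] + state[:-1]
    return out


def _is_m_sequence(prbs: np.ndarray) -> bool:
    """Check the delta-like circular autocorrelation of a ±1 m-sequence."""
    n = prbs.size
    if abs(int(prbs.sum()) - (n + 1) // 2) != 0:
        return False
    balanced = 2.0 * prbs - 1.0
    spectrum = np.abs(np.fft.rfft(balanced)) ** 2
    # autocorrelation of an m-sequence: n at lag 0, −1 elsewhere, i.e. a flat
    # power spectrum of value n+1 away from DC
    return bool(np.allclose(spectrum[1:], n + 1.0, atol=1e-6))


def _tof_density(
    distribution: VelocityDistribution, n_bins: int, bin_s: float, path_length_m: float
) -> np.ndarray:
    """Single-shot time-of-flight probability per bin.

    The velocity density is interpolated between its quadrature nodes and
    transformed with the Jacobian of t = path/v, p_t(t) = p_v(path/t)·path/t²,
    so the time histogram is smooth rather than a comb of node masses.
    """
    t_nodes = path_length_m / distribution.velocities_mps
    if np.any(t_nodes >= n_bins * bin_s):
        raise ValidationError(
            "slowest molecules arrive after one full sequence period; "
            "increase the bin width or shorten the flight path"
        )
    if distribution.singleton():
        q = np.zeros(n_bins)
        pos = t_nodes[0] / bin_s - 0.5
        i0 = int(np.floor(pos))
        frac = pos - i0
        q[i0 % n_bins] = 1.0 - frac
        q[(i0 + 1) % n_bins] = frac
        return q
    t_centers = (np.arange(n_bins) + 0.5) * bin_s
    v_of_t = path_length_m / t_centers
    p_v = np.interp(v_of_t, distribution.velocities_mps, distribution.density(),
                    left=0.0, right=0.0)
    q = p_v * path_length_m / t_centers**2 * bin_s
    total = q.sum()
    if total <= 0:
        raise ValidationError("velocity distribution has no support in the record")
    return q / total


def make_tof_record(
    distribution: VelocityDistribution,
    prbs_order: int = 7,
    bin_s: float = 50e-6,
    path_length_m: float = 0.5,
    mean_counts: float = 2e6,
    seed: int | None = None,
) -> TOFRecord:
    """Synthesize a chopper record: the m-sequence gate circularly convolved
    with the single-shot TOF density, with Poisson counting noise.

    ``mean_counts`` is the expected total number of detected molecules in one
    sequence period.
    """
    if not 5 <= prbs_order <= 10:
        raise ValidationError("prbs_order must be within [5, 10]")
    if mean_counts <= 0:
        raise ValidationError("mean_counts must be > 0")
    rng = np.random.default_rng(seed)
    prbs = m_sequence(prbs_order)
    n = prbs.size
    q = _tof_density(distribution, n, bin_s, path_length_m)
    # circular convolution gate ⊛ density
    conv = np.real(np.fft.ifft(np.fft.fft(prbs) * np.fft.fft(q)))
    conv = np.maximum(conv, 0.0)
    expected = mean_counts * conv / conv.sum()
    return TOFRecord(
        prbs=prbs,
        bin_s=bin_s,
        counts_vs_time=rng.poisson(expected),
        path_length_m=path_length_m,
    )


def reconstruct_velocities(
    record: TOFRecord, mass_threshold: float = 2e-3
) -> VelocityDistribution:
    """Recover the beam velocity distribution from a chopper TOF record.

    The circular cross-correlation of the count histogram with the balanced
    (±1) chopper sequence is, by the m-sequence autocorrelation identity,
    proportional to the single-shot TOF density.  Negative reconstructed
    densities are clipped at zero; bins below ``mass_threshold`` of the peak
    are dropped as correlation noise; times map to speeds via v = path/t with
    the bin-width Jacobian carried by the quadrature cell widths.
    """
    if not _is_m_sequence(record.prbs):
        raise DeconvolutionError(
            "chopper sequence is not a maximal-length sequence; "
            "correlation deconvolution is not exact"
        )
    n = record.prbs.size
    balanced = 2.0 * record.prbs - 1.0
    counts = record.counts_vs_time
    # q̂[k] = Σ_i counts[i] · balanced[(i−k) mod n]
    qhat = np.real(
        np.fft.ifft(np.fft.fft(counts) * np.conj(np.fft.fft(balanced)))
    )
    qhat = np.maximum(qhat, 0.0)
    if qhat.max() <= 0:
        raise DeconvolutionError("reconstructed TOF density is empty")
    # the correlation noise per bin has variance = total counts (each value is
    # a ±1-weighted sum of independent Poisson bins); suppress bins compatible
    # with noise and keep the contiguous lobe around the density maximum
    noise_sigma = math.sqrt(max(counts.sum(), 1.0))
    cut = max(3.0 * noise_sigma, mass_threshold * qhat.max())
    above = qhat > cut
    ipk = int(np.argmax(qhat))
    lo = ipk
    while lo > 1 and above[lo - 1]:
        lo -= 1
    hi = ipk
    while hi < n - 1 and above[hi + 1]:
        hi += 1
    # recover the sub-threshold tails of the lobe down to the zero crossings;
    # clipped noise there is symmetric and carries little mass
    while lo > 1 and qhat[lo - 1] > 0.0:
        lo -= 1
    while hi < n - 1 and qhat[hi + 1] > 0.0:
        hi += 1
    mask = np.zeros(n, dtype=bool)
    mask[lo:hi + 1] = True
    qhat[~mask] = 0.0
    keep = np.nonzero(qhat)[0]
    keep = keep[keep > 0]  # t = 0 carries no velocity information
    t = (keep + 0.5) * record.bin_s
    v = record.path_length_m / t
    cell = record.bin_s * record.path_length_m / t**2  # |dv| per time bin
    order = np.argsort(v)
    return VelocityDistribution(
        velocities_mps=v[order], weights=qhat[keep][order], cell_widths=cell[order]
    )


# --- property time series ---------------------------------------------------

_CAL_PATHS = 400
_CAL_SEED = 20170728  # fixed: calibration is a deterministic function of shape


@lru_cache(maxsize=16)
def _standardized_ou_paths(n: int, rho_key: float) -> np.ndarray:
    """Monte-Carlo bank of standardized (mean 0, sd 1) OU paths."""
    rng = np.random.default_rng(_CAL_SEED)
    z = np.empty((_CAL_PATHS, n))
    z[:, 0] = rng.standard_normal(_CAL_PATHS)
    innovation = math.sqrt(1.0 - rho_key**2)
    for i in range(1, n):
        z[:, i] = rho_key * z[:, i - 1] + innovation * rng.standard_normal(_CAL_PATHS)
    return z


def _ou_path(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    z = np.empty(n)
    z[0] = rng.standard_normal()
    innovation = math.sqrt(1.0 - rho**2)
    for i in range(1, n):
        z[i] = rho * z[i - 1] + innovation * rng.standard_normal()
    return z


def make_property_series(
    means: tuple[float, float, float],
    fluctuation_targets: tuple[float, float, float] = (400.0, 3.0, 3.0),
    correlation_time_ns: float = 4.0,
    duration_ns: float = 100.0,
    dt_ns: float = 2.0,
    temperature_K: float = 450.0,
    seed: int | None = None,
) -> PropertyTimeSeries:
    """Stationary mean-reverting property trajectories (µ, α_stat, α_opt).

    The polarizabilities follow Gaussian Ornstein-Uhlenbeck processes; the
    dipole magnitude follows a mean-reverting process on log µ (geometric OU)
    so that it is nonnegative by construction and can both dive toward zero
    and spike to several times its mean, as the conformational dynamics of a
    flexible polar molecule produce.  For each property the process scale is
    calibrated by Monte-Carlo lookup so that the *expected* peak-to-peak
    percent over the requested duration matches ``fluctuation_targets``
    (in percent of the mean).
    """
    mu_mean, astat_mean, aopt_mean = means
    if min(mu_mean, astat_mean, aopt_mean) <= 0:
        raise ValidationError("property means must be > 0")
    if dt_ns <= 0 or duration_ns < dt_ns or correlation_time_ns <= 0:
        raise ValidationError("invalid time grid")
    rng = np.random.default_rng(seed)
    n = int(round(duration_ns / dt_ns)) + 1
    times = np.arange(n) * dt_ns
    rho = math.exp(-dt_ns / correlation_time_ns)
    bank = _standardized_ou_paths(n, round(rho, 12))

    def gaussian_series(mean: float, target_pct: float) -> np.ndarray:
        if target_pct <= 0:
            return np.full(n, mean)
        expected_range = float(np.mean(np.ptp(bank, axis=1)))
        sd = target_pct / 100.0 * mean / expected_range
        return mean + sd * _ou_path(rng, n, rho)

    def lognormal_series(mean: float, target_pct: float) -> np.ndarray:
        if target_pct <= 0:
            return np.full(n, mean)

        def expected_p2p(log_sd: float) -> float:
            series = np.exp(log_sd * bank)
            return float(
                np.mean(100.0 * np.ptp(series, axis=1) / np.mean(series, axis=1))
            )

        if expected_p2p(3.0) < target_pct:
            raise ValidationError(
                f"peak-to-peak target {target_pct}% unreachable for this grid"
            )
        log_sd = brentq(lambda s: expected_p2p(s) - target_pct, 1e-6, 3.0,
                        xtol=1e-6)
        level = math.log(mean) - 0.5 * log_sd**2
        return np.exp(level + log_sd * _ou_path(rng, n, rho))

    return PropertyTimeSeries(
        times_ns=times,
        mu_debye_t=lognormal_series(mu_mean, fluctuation_targets[0]),
        alpha_stat_A3_t=gaussian_series(astat_mean, fluctuation_targets[1]),
        alpha_opt_A3_t=gaussian_series(aopt_mean, fluctuation_targets[2]),
        temperature_K=temperature_K,
    )
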
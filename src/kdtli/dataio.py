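"""File formats and configuration.

CSV dialects (comma separated, ``.`` decimal, mandatory header, UTF-8):

========== =====================================================
fringe      position_m, counts
vp          power_W, visibility, visibility_sigma
deflection  voltage_V, phase_rad, phase_sigma_rad
tof         bin_index, time_s, counts, prbs
velocity    velocity_mps, weight, cell_width_mps
property    time_ns, mu_D, alpha_stat_A3, alpha_opt_A3
========== =====================================================

Extra columns are preserved on read and ignored; a missing column is a
schema error naming the column.  Every artifact written by the command line
carries a JSON sidecar with the generating parameters, the seed and the
configuration hash, so that deterministic runs are byte-reproducible.

Configuration is a flat TOML file with sections [molecule], [geometry],
[laser], [electrode], [beam], [fit]; multiple molecules may be given as
[molecule.<name>] tables for the end-to-end recovery command.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .conformers import PropertyTimeSeries
from .deflectometry import DeflectionSeries, ElectrodeModel
from .engine import VisibilityCurve
from .errors import ConfigurationError, SchemaError
from .gratings import LaserSettings
from .physics import InterferometerGeometry, MoleculeSpec, VelocityDistribution
from .synthetic import FringeScan, TOFRecord

__all__ = [
    "DIALECTS",
    "read_csv",
    "write_csv",
    "RunConfig",
    "load_config",
    "config_hash",
    "write_result_json",
]

DIALECTS: Mapping[str, tuple[str, ...]] = {
    "fringe": ("position_m", "counts"),
    "vp": ("power_W", "visibility", "visibility_sigma"),
    "deflection": ("voltage_V", "phase_rad", "phase_sigma_rad"),
    "tof": ("bin_index", "time_s", "counts", "prbs"),
    "velocity": ("velocity_mps", "weight", "cell_width_mps"),
    "property": ("time_ns", "mu_D", "alpha_stat_A3", "alpha_opt_A3"),
}


def read_csv(path: str | Path, dialect: str) -> pd.DataFrame:
    """Read one of the defined CSV dialects with schema validation."""
    if dialect not in DIALECTS:
        raise SchemaError(f"unknown CSV dialect {dialect!r}")
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"{path}: not a parseable CSV file: {exc}") from exc
    for column in DIALECTS[dialect]:
        if column not in frame.columns:
            raise SchemaError(
                f"{path}: missing required column {column!r} "
                f"for dialect {dialect!r}"
            )
        converted = pd.to_numeric(frame[column], errors="coerce")
        if converted.isna().any() and not frame[column].isna().any():
            bad = frame[column][converted.isna()].iloc[0]
            raise SchemaError(
                f"{path}: column {column!r} contains non-numeric value "
                f"{bad!r} (note: the decimal separator must be '.')"
            )
        frame[column] = converted
    return frame


def write_csv(frame: pd.DataFrame, path: str | Path, dialect: str) -> None:
    """Write a dialect CSV (validates that the required columns are present)."""
    if dialect not in DIALECTS:
        raise SchemaError(f"unknown CSV dialect {dialect!r}")
    for column in DIALECTS[dialect]:
        if column not in frame.columns:
            raise SchemaError(f"cannot write {dialect!r} CSV: missing {column!r}")
    frame.to_csv(path, index=False)


# --- converters between dialect frames and domain objects -------------------

def fringe_scan_to_frame(scan: FringeScan) -> pd.DataFrame:
    return pd.DataFrame(
        {"position_m": scan.positions_m, "counts": scan.counts.astype(int)}
    )


def frame_to_fringe_scan(
    frame: pd.DataFrame, dwell_s: float, dark_rate_cps: float
) -> FringeScan:
    return FringeScan(
        positions_m=frame["position_m"].to_numpy(),
        counts=frame["counts"].to_numpy(),
        dwell_s=dwell_s,
        dark_rate_cps=dark_rate_cps,
    )


def curve_to_frame(curve: VisibilityCurve) -> pd.DataFrame:
    sig = curve.sigmas if curve.sigmas is not None else np.full(len(curve), np.nan)
    return pd.DataFrame(
        {"power_W": curve.powers_W, "visibility": curve.visibilities,
         "visibility_sigma": sig}
    )


def frame_to_curve(frame: pd.DataFrame) -> VisibilityCurve:
    sig = frame["visibility_sigma"].to_numpy()
    return VisibilityCurve(
        powers_W=frame["power_W"].to_numpy(),
        visibilities=frame["visibility"].to_numpy(),
        sigmas=None if np.all(np.isnan(sig)) else sig,
    )


def deflection_to_frame(series: DeflectionSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {"voltage_V": series.voltages_V, "phase_rad": series.phases_rad,
         "phase_sigma_rad": series.phase_sigmas_rad}
    )


def frame_to_deflection(frame: pd.DataFrame) -> DeflectionSeries:
    return DeflectionSeries(
        voltages_V=frame["voltage_V"].to_numpy(),
        phases_rad=frame["phase_rad"].to_numpy(),
        phase_sigmas_rad=frame["phase_sigma_rad"].to_numpy(),
    )


def tof_to_frame(record: TOFRecord) -> pd.DataFrame:
    n = record.prbs.size
    return pd.DataFrame(
        {"bin_index": np.arange(n),
         "time_s": (np.arange(n) + 0.5) * record.bin_s,
         "counts": record.counts_vs_time, "prbs": record.prbs}
    )


def frame_to_tof(frame: pd.DataFrame, path_length_m: float) -> TOFRecord:
    times = frame["time_s"].to_numpy()
    bin_s = float(times[1] - times[0]) if times.size > 1 else float(2 * times[0])
    return TOFRecord(
        prbs=frame["prbs"].to_numpy().astype(int),
        bin_s=bin_s,
        counts_vs_time=frame["counts"].to_numpy(),
        path_length_m=path_length_m,
    )


def property_to_frame(series: PropertyTimeSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {"time_ns": series.times_ns, "mu_D": series.mu_debye_t,
         "alpha_stat_A3": series.alpha_stat_A3_t,
         "alpha_opt_A3": series.alpha_opt_A3_t}
    )


def frame_to_property(frame: pd.DataFrame, temperature_K: float) -> PropertyTimeSeries:
    return PropertyTimeSeries(
        times_ns=frame["time_ns"].to_numpy(),
        mu_debye_t=frame["mu_D"].to_numpy(),
        alpha_stat_A3_t=frame["alpha_stat_A3"].to_numpy(),
        alpha_opt_A3_t=frame["alpha_opt_A3"].to_numpy(),
        temperature_K=temperature_K,
    )


def velocity_to_frame(dist: VelocityDistribution) -> pd.DataFrame:
    cw = dist.cell_widths
    if cw is None:
        cw = np.gradient(dist.velocities_mps) if len(dist) > 1 else np.array([np.nan])
    return pd.DataFrame(
        {"velocity_mps": dist.velocities_mps, "weight": dist.weights,
         "cell_width_mps": cw}
    )


# --- configuration -----------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved run configuration."""

    molecules: dict[str, MoleculeSpec]
    geometry: InterferometerGeometry
    electrode: ElectrodeModel
    laser_power_W: float
    intensity_scale: float
    beam_mean_mps: float
    beam_fwhm_fraction: float
    beam_nodes: int
    seed: int
    fit: dict[str, Any] = field(default_factory=dict)
    raw: dict[str, Any] = field(default_factory=dict)

    @property
    def molecule(self) -> MoleculeSpec:
        """The first configured molecule (single-molecule commands)."""
        return next(iter(self.molecules.values()))

    def laser(self, power_W: float | None = None) -> LaserSettings:
        return LaserSettings(
            power_W=self.laser_power_W if power_W is None else power_W,
            wavelength_m=self.geometry.laser_wavelength_m,
            waist_x_m=self.geometry.waist_x_m,
            waist_y_m=self.geometry.waist_y_m,
            intensity_scale=self.intensity_scale,
        )

    def distribution(self, mean_mps: float | None = None) -> VelocityDistribution:
        from .synthetic import make_velocity_distribution

        return make_velocity_distribution(
            self.beam_mean_mps if mean_mps is None else mean_mps,
            self.beam_fwhm_fraction,
            self.beam_nodes,
        )


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    try:
        raw = tomllib.loads(path.read_text(encoding="utf-8"))
    except tomllib.TOMLDecodeError as exc:
        raise ConfigurationError(f"{path}: invalid TOML: {exc}") from exc

    mol_section = raw.get("molecule")
    molecules: dict[str, MoleculeSpec] = {}
    if mol_section is None:
        raise ConfigurationError(f"{path}: missing [molecule] section")
    if any(isinstance(v, dict) for v in mol_section.values()):
        for name, sub in mol_section.items():
            if not isinstance(sub, dict):
                raise ConfigurationError(
                    f"{path}: [molecule] mixes scalar keys with sub-tables"
                )
            sub = dict(sub)
            sub.setdefault("name", name)
            molecules[name] = MoleculeSpec.from_dict(sub)
    else:
        spec = MoleculeSpec.from_dict(mol_section)
        molecules[spec.name] = spec

    geometry = InterferometerGeometry.from_dict(raw.get("geometry", {}))
    electrode = ElectrodeModel.from_dict(raw.get("electrode", {}))
    laser = raw.get("laser", {})
    beam = raw.get("beam", {})
    return RunConfig(
        molecules=molecules,
        geometry=geometry,
        electrode=electrode,
        laser_power_W=float(laser.get("power_W", 8.0)),
        intensity_scale=float(laser.get("intensity_scale", 1.0)),
        beam_mean_mps=float(beam.get("mean_mps", 200.0)),
        beam_fwhm_fraction=float(beam.get("fwhm_fraction", 0.45)),
        beam_nodes=int(beam.get("n_nodes", 41)),
        seed=int(raw.get("seed", 0)),
        fit=dict(raw.get("fit", {})),
        raw=raw,
    )


def config_hash(raw: Mapping[str, Any]) -> str:
    """Stable short hash of a configuration mapping."""
    canonical = json.dumps(raw, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_result_json(
    path: str | Path,
    payload: Mapping[str, Any],
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    """Write a JSON result record with reproducibility metadata."""
    record = dict(payload)
    if seed is not None:
        record["seed"] = seed
    if cfg_hash is not None:
        record["config_hash"] = cfg_hash

    def default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(record, indent=2, default=default) + "\n",
                          encoding="utf-8")
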